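"""Composition-event calling, background separation, inheritance tracing.

Working on the filtered, A-counting dosage matrix, maximal positional runs
of two or more markers sharing the same non-2 score become draft event
calls (score 1 -> ABBB, 3 -> AAAB, 0 -> BBBB, 4 -> AAAA). Runs dominated by
low-intensity cells are deletion candidates: the array cannot distinguish a
lost homeolog pair from a homeologous exchange by theta alone. Calls shared
cohort-wide are ancestral background; the rest are candidates whose novelty
is decided against the pedigree — a candidate matching an ancestor's call is
inherited, otherwise it is one independent origin. The instability rate is
independent origins per plant assayed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .pedigree import Pedigree, PlantID, parse_plant_id  # noqa: F401  (re-export)

__all__ = [
    "EventCall",
    "RateSummary",
    "SCORE_COMPOSITION",
    "call_runs",
    "call_all_runs",
    "classify_background",
    "trace_inheritance",
    "compute_rate",
    "detect_events",
    "evaluate_origins",
]

SCORE_COMPOSITION = {0: "BBBB", 1: "ABBB", 3: "AAAB", 4: "AAAA"}

#: truth-event kind -> array/WGS composition labels that correctly report it
KIND_COMPATIBLE = {
    "DELETION_B": {"DELETION_CANDIDATE", "AA_DELETION", "DELETION_B"},
    "DELETION_A": {"DELETION_CANDIDATE", "BB_DELETION", "DELETION_A"},
    "ABBB": {"ABBB"},
    "AAAB": {"AAAB"},
    "AAAA": {"AAAA"},
    "BBBB": {"BBBB"},
    "TRISOMY_A": {"TRISOMY_A"},
    "TRISOMY_B": {"TRISOMY_B"},
}


@dataclass(frozen=True)
class EventCall:
    plant: str
    chrom_set: int
    start: int
    end: int
    composition: str
    n_markers: int
    status: str | None = None  # background / candidate / novel / inherited

    def overlaps(self, other: "EventCall") -> bool:
        return (
            self.chrom_set == other.chrom_set
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class RateSummary:
    n_events: int
    n_plants: int

    @property
    def rate_percent(self) -> float:
        frac = Decimal(100) * Decimal(self.n_events) / Decimal(self.n_plants)
        return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def call_runs(
    plant: str,
    row: pd.Series,
    marker_map: pd.DataFrame,
    flags_row: pd.Series | None = None,
    min_run: int = 2,
) -> list[EventCall]:
    """Draft event calls for one plant from its A-counting dosage row.

    Maximal runs of >= ``min_run`` consecutive markers sharing the same non-2
    score become one call spanning [first marker position, last + 1). A run
    whose low-intensity flags cover at least half its markers is a
    DELETION_CANDIDATE regardless of its apparent score.
    """
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    mm = marker_map.loc[row.index]
    calls: list[EventCall] = []
    for cs, sub in mm.groupby("chrom_set"):
        pos = sub["position"].to_numpy()
        if not (np.diff(pos) > 0).all():
            raise ValueError(f"markers unordered in chromosome set {cs}")
        vals = row[sub.index].to_numpy(dtype=float)
        flags = (
            flags_row[sub.index].to_numpy(dtype=bool)
            if flags_row is not None
            else np.zeros(len(sub), dtype=bool)
        )
        i, n = 0, len(vals)
        while i < n:
            j = i + 1
            while j < n and vals[j] == vals[i]:
                j += 1
            v = vals[i]
            if not np.isnan(v) and v != 2 and (j - i) >= min_run:
                comp = SCORE_COMPOSITION[int(v)]
                if flags[i:j].mean() >= 0.5:
                    comp = "DELETION_CANDIDATE"
                calls.append(
                    EventCall(
                        plant=plant,
                        chrom_set=int(cs),
                        start=int(pos[i]),
                        end=int(pos[j - 1]) + 1,
                        composition=comp,
                        n_markers=j - i,
                    )
                )
            i = j
    return calls


def call_all_runs(
    scores: pd.DataFrame,
    marker_map: pd.DataFrame,
    flags: pd.DataFrame | None = None,
    min_run: int = 2,
) -> list[EventCall]:
    """Draft calls for every column (plant) of an A-counting score matrix."""
    calls: list[EventCall] = []
    for plant in scores.columns:
        frow = flags[plant] if flags is not None else None
        calls.extend(call_runs(plant, scores[plant], marker_map, frow, min_run))
    return calls


def classify_background(
    calls: list[EventCall],
    n_plants: int,
    threshold: float = 0.5,
    reference_profile: list[tuple[int, int, int, str]] | None = None,
) -> list[EventCall]:
    """Separate cohort-wide ancestral compositions from candidate events.

    A call is background when the fraction of plants holding an overlapping
    same-composition call exceeds ``threshold``, or when it overlaps an entry
    of an explicit reference profile ``(chrom_set, start, end, composition)``.
    """
    if not calls:
        return []
    out: list[EventCall] = []
    by_group: dict[tuple[int, str], list[EventCall]] = {}
    for c in calls:
        by_group.setdefault((c.chrom_set, c.composition), []).append(c)
    for c in calls:
        background = False
        if reference_profile is not None:
            background = any(
                cs == c.chrom_set and comp == c.composition and s < c.end and c.start < e
                for cs, s, e, comp in reference_profile
            )
        else:
            peers = by_group[(c.chrom_set, c.composition)]
            plants = {p.plant for p in peers if p.overlaps(c)}
            background = len(plants) / n_plants > threshold
        out.append(replace(c, status="background" if background else "candidate"))
    return out


def trace_inheritance(
    candidates: list[EventCall], pedigree: Pedigree
) -> tuple[list[EventCall], list[EventCall]]:
    """Resolve candidates into novel origins and inherited copies.

    A candidate whose ancestor (nearest first) holds an overlapping
    same-composition candidate is inherited; otherwise it is one independent
    origin. Transient events — present in one plant but absent from its
    progeny — therefore count once. Returns (final calls, origin ledger).
    """
    by_plant: dict[str, list[EventCall]] = {}
    for c in candidates:
        if c.status == "background":
            continue
        if c.plant not in pedigree:
            raise KeyError(f"plant {c.plant!r} missing from pedigree")
        by_plant.setdefault(c.plant, []).append(c)

    final: list[EventCall] = []
    ledger: list[EventCall] = []
    for c in candidates:
        if c.status == "background":
            final.append(c)
            continue
        inherited = False
        for anc in pedigree.ancestors(c.plant):
            anc_calls = by_plant.get(anc.label, [])
            if any(a.overlaps(c) and a.composition == c.composition for a in anc_calls):
                inherited = True
                break
        resolved = replace(c, status="inherited" if inherited else "novel")
        final.append(resolved)
        if resolved.status == "novel":
            ledger.append(resolved)
    return final, ledger


def compute_rate(n_origins: int, n_plants: int) -> RateSummary:
    """Instability rate: independent origins per 100 plants, 1 decimal,
    half away from zero."""
    if n_plants <= 0:
        raise ValueError("n_plants must be > 0")
    if n_origins < 0:
        raise ValueError("n_origins must be >= 0")
    return RateSummary(n_events=n_origins, n_plants=n_plants)


def detect_events(
    scores: pd.DataFrame,
    marker_map: pd.DataFrame,
    pedigree: Pedigree,
    flags: pd.DataFrame | None = None,
    min_run: int = 2,
    background_threshold: float = 0.5,
    reference_profile: list[tuple[int, int, int, str]] | None = None,
    n_plants: int | None = None,
) -> tuple[list[EventCall], list[EventCall], RateSummary]:
    """Full detection pass: runs -> background -> inheritance -> rate.

    ``n_plants`` defaults to the pedigree size (the whole cohort is the rate
    denominator even when some samples were excluded from genotyping).
    """
    drafts = call_all_runs(scores, marker_map, flags, min_run)
    classified = classify_background(
        drafts, n_plants=len(pedigree), threshold=background_threshold,
        reference_profile=reference_profile,
    )
    final, ledger = trace_inheritance(classified, pedigree)
    rate = compute_rate(len(ledger), n_plants if n_plants is not None else len(pedigree))
    return final, ledger, rate


def evaluate_origins(ledger: list[EventCall], truth_events, pedigree: Pedigree) -> dict:
    """Compare a detected origin ledger against the implanted truth.

    A truth origin is recovered when some novel call overlaps it on the same
    chromosome set with a compatible composition, in the origin plant or one
    of its descendants. Novel calls matching no truth event are false
    origins.
    """
    truths = [t for t in truth_events if not t.is_background]
    matched = 0
    used: set[int] = set()
    for t in truths:
        ok_plants = {t.plant.label} | {p.label for p in pedigree.descendants(t.plant)}
        hit = False
        for i, c in enumerate(ledger):
            if (
                c.chrom_set == t.chrom_set
                and c.start < t.end
                and t.start < c.end
                and c.composition in KIND_COMPATIBLE[t.kind]
                and c.plant in ok_plants
            ):
                hit = True
                used.add(i)
        if hit:
            matched += 1
    false_origins = [
        c
        for i, c in enumerate(ledger)
        if i not in used
    ]
    return {
        "n_truth": len(truths),
        "n_detected": matched,
        "sensitivity": matched / len(truths) if truths else float("nan"),
        "n_false": len(false_origins),
        "false_origins": false_origins,
    }
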