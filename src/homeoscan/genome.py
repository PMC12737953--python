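"""Genome layout, subgenome copy-number compositions, and truth events.

The tetraploid genome is modeled as homeologous *chromosome sets* 1..10; each
set holds two A-subgenome and two B-subgenome copies in the euploid state
(AABB). Marker and site positions are expressed on the B-subgenome anchor,
0-based half-open. A composition is a pair ``(a_copies, b_copies)``; the
euploid expectation is (2, 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import PlantID, Pedigree, parse_plant_id

__all__ = [
    "GenomeLayout",
    "COMPOSITION_COPIES",
    "KIND_COPIES",
    "EUPLOID",
    "expected_theta",
    "expected_intensity",
    "build_marker_map",
    "validate_marker_map",
    "TruthEvent",
    "implant_events",
    "copy_numbers",
]

#: composition -> (A copies, B copies)
COMPOSITION_COPIES: dict[str, tuple[int, int]] = {
    "AABB": (2, 2),
    "ABBB": (1, 3),
    "AAAB": (3, 1),
    "AAAA": (4, 0),
    "BBBB": (0, 4),
    "AA_DELETION": (2, 0),
    "BB_DELETION": (0, 2),
    "TRISOMY_A": (3, 2),
    "TRISOMY_B": (2, 3),
}

#: truth-event kind -> (A copies, B copies) in the affected interval
KIND_COPIES: dict[str, tuple[int, int]] = {
    "DELETION_B": (2, 0),  # B homeolog lost, A pair intact
    "DELETION_A": (0, 2),
    "ABBB": (1, 3),
    "AAAB": (3, 1),
    "AAAA": (4, 0),
    "BBBB": (0, 4),
    "TRISOMY_A": (3, 2),
    "TRISOMY_B": (2, 3),
}

EUPLOID: tuple[int, int] = (2, 2)


def expected_theta(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """A-signal fraction a/(a+b); 0.5 where a+b == 0 (no material)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    tot = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(tot > 0, a / np.where(tot > 0, tot, 1.0), 0.5)
    return theta


def expected_intensity(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Total-copy intensity (a+b)/4; 1.0 is the euploid expectation."""
    return (np.asarray(a, dtype=float) + np.asarray(b, dtype=float)) / 4.0


@dataclass(frozen=True)
class GenomeLayout:
    """Size of the simulated genome.

    The real genome's marker density is not needed; ten 10-Mb sets at 140
    markers each give ~1400 markers, the scale of the filtered study panel.
    """

    n_sets: int = 10
    set_length: int = 10_000_000
    markers_per_set: int = 140

    @property
    def n_markers(self) -> int:
        return self.n_sets * self.markers_per_set


def build_marker_map(
    layout: GenomeLayout = GenomeLayout(),
    b_high_frac: float = 0.4,
    seed: int = 0,
) -> pd.DataFrame:
    """Evenly spaced markers per chromosome set with random orientation.

    Returns a frame indexed by marker id with columns ``chrom_set``,
    ``position`` and ``orientation`` (``A_high`` markers count A alleles in
    their raw score, ``B_high`` markers count B alleles).
    """
    if not 0.0 <= b_high_frac <= 1.0:
        raise ValueError("b_high_frac must be in [0, 1]")
    rng = np.random.default_rng(seed)
    spacing = layout.set_length / layout.markers_per_set
    rows = []
    for cs in range(1, layout.n_sets + 1):
        for i in range(layout.markers_per_set):
            rows.append(
                {
                    "marker_id": f"AX_{cs:02d}_{i:04d}",
                    "chrom_set": cs,
                    "position": int((i + 0.5) * spacing),
                }
            )
    mm = pd.DataFrame(rows).set_index("marker_id")
    flip = rng.random(len(mm)) < b_high_frac
    mm["orientation"] = np.where(flip, "B_high", "A_high")
    validate_marker_map(mm)
    return mm


def validate_marker_map(marker_map: pd.DataFrame) -> None:
    required = {"chrom_set", "position"}
    if not required.issubset(marker_map.columns):
        raise ValueError(f"marker map needs columns {sorted(required)}")
    if not marker_map["chrom_set"].between(1, 10).all():
        raise ValueError("chrom_set must be in [1, 10]")
    for cs, sub in marker_map.groupby("chrom_set"):
        pos = sub["position"].to_numpy()
        if not (np.diff(pos) > 0).all():
            raise ValueError(f"positions not strictly increasing in set {cs}")


@dataclass(frozen=True)
class TruthEvent:
    """One implanted structural event plus its carrier set.

    ``heritable`` events propagate to every descendant of the origin plant;
    transient ones affect the origin only. An event whose origin is the
    founder is carried by the whole cohort and models an ancestral
    (background) composition rather than a novel instability.
    """

    plant: PlantID
    kind: str
    chrom_set: int
    start: int
    end: int
    heritable: bool
    carriers: frozenset[PlantID] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.kind not in KIND_COPIES:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if not 0 <= self.start < self.end:
            raise ValueError("need 0 <= start < end")

    @property
    def copies(self) -> tuple[int, int]:
        return KIND_COPIES[self.kind]

    @property
    def origin_generation(self) -> int:
        return self.plant.generation

    @property
    def is_background(self) -> bool:
        return self.plant.is_founder

    def overlaps(self, chrom_set: int, start: int, end: int) -> bool:
        return self.chrom_set == chrom_set and self.start < end and start < self.end


def implant_events(
    pedigree: Pedigree,
    event_spec,
    seed: int = 0,
    layout: GenomeLayout = GenomeLayout(),
) -> list[TruthEvent]:
    """Build the truth ledger from an explicit list or a per-plant rate.

    ``event_spec`` is either a list of dicts with keys
    ``plant, kind, chrom_set, start, end, heritable`` (plant given as a label)
    or a dict ``{"rate": p, ...}`` drawing at most one random event per plant
    with probability ``p``. Each independent origin appears exactly once in
    the ledger, with its full carrier set attached.
    """
    rng = np.random.default_rng(seed)
    specs: list[dict]
    if isinstance(event_spec, dict):
        rate = float(event_spec.get("rate", 0.0))
        kinds = list(event_spec.get("kinds", ["DELETION_B", "ABBB", "AAAB", "AAAA", "BBBB"]))
        specs = []
        for plant in pedigree.plants:
            if rng.random() < rate:
                cs = int(rng.integers(1, layout.n_sets + 1))
                start = int(rng.integers(0, layout.set_length // 2))
                end = int(rng.integers(start + layout.set_length // 10, layout.set_length + 1))
                specs.append(
                    {
                        "plant": plant.label,
                        "kind": kinds[int(rng.integers(len(kinds)))],
                        "chrom_set": cs,
                        "start": start,
                        "end": min(end, layout.set_length),
                        "heritable": bool(rng.random() < 0.5),
                    }
                )
    else:
        specs = [dict(s) for s in event_spec]

    events: list[TruthEvent] = []
    for s in specs:
        plant = parse_plant_id(s["plant"]) if isinstance(s["plant"], str) else s["plant"]
        if not (0 <= s["start"] < s["end"] <= layout.set_length):
            raise ValueError(
                f"event interval [{s['start']}, {s['end']}) outside chromosome set "
                f"of length {layout.set_length}"
            )
        if not 1 <= s["chrom_set"] <= layout.n_sets:
            raise ValueError(f"chrom_set {s['chrom_set']} outside [1, {layout.n_sets}]")
        if plant.is_founder:
            carriers = frozenset(pedigree.plants)
        else:
            carriers = frozenset({plant})
            if s["heritable"]:
                carriers |= frozenset(pedigree.descendants(plant))
        events.append(
            TruthEvent(
                plant=plant,
                kind=s["kind"],
                chrom_set=int(s["chrom_set"]),
                start=int(s["start"]),
                end=int(s["end"]),
                heritable=bool(s["heritable"]),
                carriers=carriers,
            )
        )
    return events


def copy_numbers(
    samples: list[PlantID],
    events: list[TruthEvent],
    loci: pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray]:
    """Per (locus, sample) A- and B-copy counts implied by the truth ledger.

    ``loci`` needs ``chrom_set`` and ``position`` columns. Later events
    override earlier ones where intervals overlap. Returns two integer arrays
    of shape (n_loci, n_samples).
    """
    n_loci = len(loci)
    n_samples = len(samples)
    a = np.full((n_loci, n_samples), EUPLOID[0], dtype=np.int64)
    b = np.full((n_loci, n_samples), EUPLOID[1], dtype=np.int64)
    cs = loci["chrom_set"].to_numpy()
    pos = loci["position"].to_numpy()
    col_of = {s: j for j, s in enumerate(samples)}
    for ev in events:
        rows = np.flatnonzero((cs == ev.chrom_set) & (pos >= ev.start) & (pos < ev.end))
        cols = [col_of[s] for s in ev.carriers if s in col_of]
        if len(rows) and cols:
            a[np.ix_(rows, cols)] = ev.copies[0]
            b[np.ix_(rows, cols)] = ev.copies[1]
    return a, b
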