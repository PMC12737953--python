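"""Window-level subgenome dosage from WGS allele depths.

Raw A/B allele counts at diagnostic sites are normalized against a
synthetic-tetraploid 1:1 baseline so a euploid site reads (2, 2) copies:
``norm_x = 2 * s * raw_x / baseline_x`` with a per-sample scalar ``s`` fixing
the genome-wide median of (norm_a + norm_b)/2 at 2. Sites are aggregated
into fixed windows; each window's robust (median) center is matched to the
nearest expected composition — including single-homeolog deletions (2,0) /
(0,2) and trisomies (3,2)/(2,3) — within a copy tolerance. Window calls then
arbitrate array events: an apparent AAAB/AAAA run over AA-deletion windows
is relabeled as a B-subgenome deletion, resolving the array's blind spot.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .events import EventCall
from .simulate import ReadCounts

__all__ = [
    "select_sites",
    "normalize_counts",
    "window_classify",
    "classify_sample",
    "reconcile",
    "WINDOW_MATCH_SET",
]

#: composition label -> expected (norm_a, norm_b) window center
WINDOW_MATCH_SET: dict[str, tuple[float, float]] = {
    "AABB": (2.0, 2.0),
    "ABBB": (1.0, 3.0),
    "AAAB": (3.0, 1.0),
    "AAAA": (4.0, 0.0),
    "BBBB": (0.0, 4.0),
    "AA_DELETION": (2.0, 0.0),
    "BB_DELETION": (0.0, 2.0),
    "TRISOMY_A": (3.0, 2.0),
    "TRISOMY_B": (2.0, 3.0),
}

#: array-side labels that an AA_DELETION (resp. BB_DELETION) window set may
#: legitimately correct; the array renders a lost homeolog as an unbalanced run
_RELABEL = {
    "AA_DELETION": ({"DELETION_CANDIDATE", "AAAB", "AAAA"}, "DELETION_B"),
    "BB_DELETION": ({"DELETION_CANDIDATE", "ABBB", "BBBB"}, "DELETION_A"),
}


def select_sites(
    candidates: pd.DataFrame,
    consensus: float = 0.95,
    min_depth: int = 1,
) -> pd.DataFrame:
    """Filter candidate positions down to usable A/B-diagnostic sites.

    ``candidates`` carries per position the best-supported allele and its
    support fraction for reads of A- and B-subgenome origin
    (``a_allele, a_consensus, a_depth, b_allele, b_consensus, b_depth``).
    A site is diagnostic when both sources reach the consensus threshold on
    *different* alleles at sufficient depth. An empty result is allowed.
    """
    keep = (
        (candidates["a_consensus"] >= consensus)
        & (candidates["b_consensus"] >= consensus)
        & (candidates["a_depth"] >= min_depth)
        & (candidates["b_depth"] >= min_depth)
        & (candidates["a_allele"] != candidates["b_allele"])
    )
    return candidates[keep].copy()


def normalize_counts(counts: ReadCounts, sample: str) -> pd.DataFrame:
    """Baseline-normalized copy estimates per site for one sample.

    Sites with a zero baseline count on either allele are masked (dropped).
    Raises when no usable shared site remains. The per-sample scalar makes
    the genome-wide median of (norm_a + norm_b)/2 equal 2.0, so uniform
    depth rescaling of the sample cancels exactly.
    """
    if sample not in counts.raw_a.columns:
        raise KeyError(f"sample {sample!r} not in count table")
    base_a = counts.raw_a[counts.baseline].to_numpy(dtype=float)
    base_b = counts.raw_b[counts.baseline].to_numpy(dtype=float)
    usable = (base_a > 0) & (base_b > 0)
    if not usable.any():
        raise ValueError("no shared usable sites between sample and baseline")
    ra = counts.raw_a[sample].to_numpy(dtype=float)[usable]
    rb = counts.raw_b[sample].to_numpy(dtype=float)[usable]
    u_a = 2.0 * ra / base_a[usable]
    u_b = 2.0 * rb / base_b[usable]
    med = np.median((u_a + u_b) / 2.0)
    if med <= 0:
        raise ValueError(f"sample {sample!r} has no coverage at usable sites")
    s = 2.0 / med
    out = counts.sites.loc[usable, ["chrom_set", "position"]].copy()
    out["norm_a"] = s * u_a
    out["norm_b"] = s * u_b
    return out


def window_classify(
    normalized: pd.DataFrame,
    window_size: int = 1_000_000,
    min_sites: int = 20,
    tolerance: float = 0.35,
) -> pd.DataFrame:
    """Classify fixed genomic windows by their median normalized counts.

    Windows with fewer than ``min_sites`` usable sites, or whose center is
    farther than ``tolerance`` copies (in either coordinate) from every
    expected composition, are UNCLASSIFIED.
    """
    if window_size <= 0:
        raise ValueError("window_size must be > 0")
    df = normalized.copy()
    df["window"] = (df["position"] // window_size).astype(int)
    rows = []
    for (cs, w), sub in df.groupby(["chrom_set", "window"], sort=True):
        med_a = float(sub["norm_a"].median())
        med_b = float(sub["norm_b"].median())
        comp = "UNCLASSIFIED"
        if len(sub) >= min_sites:
            best, best_d = None, np.inf
            for name, (ea, eb) in WINDOW_MATCH_SET.items():
                d = max(abs(med_a - ea), abs(med_b - eb))
                if d < best_d:
                    best, best_d = name, d
            if best_d <= tolerance:
                comp = best
        rows.append(
            {
                "chrom_set": int(cs),
                "start": int(w * window_size),
                "end": int((w + 1) * window_size),
                "n_sites": len(sub),
                "norm_a": med_a,
                "norm_b": med_b,
                "composition": comp,
            }
        )
    return pd.DataFrame(rows)


def classify_sample(
    counts: ReadCounts,
    sample: str,
    window_size: int = 1_000_000,
    min_sites: int = 20,
    tolerance: float = 0.35,
) -> pd.DataFrame:
    """Normalize one sample and classify its windows in one step."""
    return window_classify(
        normalize_counts(counts, sample), window_size, min_sites, tolerance
    )


def reconcile(
    array_calls: list[EventCall],
    windows: pd.DataFrame,
    plant: str,
) -> pd.DataFrame:
    """Arbitrate one plant's array events against its WGS window calls.

    Per array event, overlapping classified windows vote by majority.
    Matching compositions confirm the call; an AA/BB-deletion majority under
    a compatible unbalanced array run relabels it as the corresponding
    single-homeolog deletion; anything else is recorded as a conflict (the
    array label is kept). Raises if the calls belong to another plant.
    """
    for c in array_calls:
        if c.plant != plant:
            raise ValueError(f"call for {c.plant!r} passed to reconcile({plant!r})")
    if windows is None or len(windows) == 0:
        raise ValueError(f"no WGS windows for plant {plant!r}")
    rows = []
    for c in array_calls:
        over = windows[
            (windows["chrom_set"] == c.chrom_set)
            & (windows["start"] < c.end)
            & (windows["end"] > c.start)
            & (windows["composition"] != "UNCLASSIFIED")
        ]
        if len(over) == 0:
            verdict, wgs_comp, final = "no_coverage", None, c.composition
        else:
            votes = over["composition"].value_counts()
            wgs_comp = votes.index[0]
            if len(votes) > 1 and votes.iloc[0] == votes.iloc[1]:
                verdict, final = "conflict", c.composition
            elif wgs_comp == c.composition:
                verdict, final = "confirmed", c.composition
            elif wgs_comp in _RELABEL and c.composition in _RELABEL[wgs_comp][0]:
                verdict, final = "relabeled", _RELABEL[wgs_comp][1]
            else:
                verdict, final = "conflict", c.composition
        rows.append(
            {
                "plant": plant,
                "chrom_set": c.chrom_set,
                "start": c.start,
                "end": c.end,
                "array_composition": c.composition,
                "wgs_composition": wgs_comp,
                "final_composition": final,
                "verdict": verdict,
                "n_windows": int(len(over)),
            }
        )
    return pd.DataFrame(rows)
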