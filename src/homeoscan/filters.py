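"""Marker-filter cascade and orientation standardization.

Retained markers must (in order): be completely scored across all lineage
plants; show uniform, dosage-consistent control behavior (A- and B-parent
scores at least two apart, the 3:1 and 1:3 DNA mixtures distinguishable, the
1:1 mixture modal at 2); agree between duplicated generation-1 samples; and
either have lineage modal score 2 or sit in a positional run of two or more
markers deviating in the same subgenome direction. Scores are then flipped
where needed so that every marker counts A-subgenome alleles (BBBB=0 ..
AAAA=4). Finally, samples with many *isolated* non-modal cells — scattered
deviations that form no positional run, the signature of poor DNA rather
than a structural event — can be excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dosage import DosageCalls

__all__ = [
    "FilterConfig",
    "StageRecord",
    "FilterReport",
    "CascadeResult",
    "modal_scores",
    "filter_complete",
    "filter_controls",
    "filter_replicates",
    "filter_modal_rule",
    "standardize_orientation",
    "exclude_noisy_samples",
    "run_cascade",
]

CONTROL_ROLES = ("A_parent", "B_parent", "mix_1_1", "mix_3_1", "mix_1_3")

# tie-break preference for modal scores: euploid first, then closeness to 2
_MODAL_PREFERENCE = (2, 1, 3, 0, 4)


@dataclass
class FilterConfig:
    qc_fail_samples: tuple[str, ...] = ()
    exclude_noisy_samples: bool = True
    noisy_sample_k_sd: float = 4.0
    min_run: int = 2


@dataclass
class StageRecord:
    stage: str
    n_in: int
    n_out: int
    dropped: dict[str, str] = field(default_factory=dict)


@dataclass
class FilterReport:
    stages: list[StageRecord] = field(default_factory=list)
    excluded_samples: dict[str, str] = field(default_factory=dict)

    def add(self, stage: str, before: pd.Index, kept: pd.Index, reasons: dict[str, str]):
        self.stages.append(StageRecord(stage, len(before), len(kept), reasons))

    def validate_telescoping(self) -> None:
        for prev, nxt in zip(self.stages, self.stages[1:]):
            if prev.n_out != nxt.n_in:
                raise AssertionError(
                    f"counts do not telescope: {prev.stage} out {prev.n_out} "
                    f"!= {nxt.stage} in {nxt.n_in}"
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"stage": s.stage, "markers_in": s.n_in, "markers_out": s.n_out,
                 "dropped": s.n_in - s.n_out}
                for s in self.stages
            ]
        )

    def to_dict(self) -> dict:
        return {
            "stages": [
                {"stage": s.stage, "markers_in": s.n_in, "markers_out": s.n_out,
                 "dropped": s.dropped}
                for s in self.stages
            ],
            "excluded_samples": self.excluded_samples,
        }


@dataclass
class CascadeResult:
    calls: DosageCalls  # oriented scores, retained markers/samples plus controls
    report: FilterReport
    lineage_samples: list[str]
    marker_map: pd.DataFrame

    @property
    def lineage_scores(self) -> pd.DataFrame:
        return self.calls.scores[self.lineage_samples]


def modal_scores(scores: pd.DataFrame, prefer: tuple[int, ...] = _MODAL_PREFERENCE) -> pd.Series:
    """Per-marker modal score across columns, NaN-ignoring.

    Ties break by the preference order (euploid 2 first, then values closest
    to 2), the conservative choice toward the balanced null.
    """
    arr = scores.to_numpy(dtype=float)
    counts = np.zeros((arr.shape[0], 5), dtype=np.int64)
    for s in range(5):
        counts[:, s] = (arr == s).sum(axis=1)
    maxc = counts.max(axis=1)
    modal = np.full(arr.shape[0], np.nan)
    remaining = maxc > 0
    for p in prefer:
        hit = remaining & (counts[:, p] == maxc)
        modal[hit] = p
        remaining &= ~hit
    return pd.Series(modal, index=scores.index, name="modal")


def filter_complete(scores: pd.DataFrame, lineage_samples: list[str]) -> pd.Series:
    """Keep markers with no missing cell among lineage samples."""
    if not lineage_samples:
        raise ValueError("no lineage samples declared")
    return scores[lineage_samples].notna().all(axis=1)


def _uniform(sub: pd.DataFrame) -> pd.Series:
    complete = sub.notna().all(axis=1)
    same = sub.eq(sub.iloc[:, 0], axis=0).all(axis=1)
    return complete & same


def filter_controls(scores: pd.DataFrame, roles: pd.Series) -> tuple[pd.Series, dict[str, str]]:
    """Keep markers whose control samples behave as their known compositions.

    Requires uniformity within each control group, parent separation >= 2
    score units, distinguishable 3:1 vs 1:3 mixtures, and a 1:1-mixture modal
    score of 2.
    """
    cols_of = {role: [s for s in scores.columns if roles.get(s) == role] for role in CONTROL_ROLES}
    for role, cols in cols_of.items():
        if not cols:
            raise ValueError(f"missing control role {role!r}")
    uni = {role: _uniform(scores[cols]) for role, cols in cols_of.items()}
    val = {role: scores[cols].iloc[:, 0] for role, cols in cols_of.items()}

    uniform_all = pd.concat(uni.values(), axis=1).all(axis=1)
    separation = (val["A_parent"] - val["B_parent"]).abs() >= 2
    mixes_differ = val["mix_3_1"] != val["mix_1_3"]
    mix11_modal2 = modal_scores(scores[cols_of["mix_1_1"]]) == 2

    keep = uniform_all & separation & mixes_differ & mix11_modal2
    reasons: dict[str, str] = {}
    for m in scores.index[~keep]:
        if not uniform_all[m]:
            reasons[m] = "controls_not_uniform"
        elif not separation[m]:
            reasons[m] = "parent_separation_lt_2"
        elif not mixes_differ[m]:
            reasons[m] = "mix31_equals_mix13"
        else:
            reasons[m] = "mix11_modal_not_2"
    return keep, reasons


def filter_replicates(
    scores: pd.DataFrame, replicate_pairs: list[tuple[str, str]]
) -> pd.Series:
    """Keep markers where every duplicated sample pair has matching scores."""
    if not replicate_pairs:
        raise ValueError("no replicate pairs declared")
    keep = pd.Series(True, index=scores.index)
    for a, b in replicate_pairs:
        if a not in scores.columns or b not in scores.columns:
            raise ValueError(f"unpaired replicate id in pair ({a!r}, {b!r})")
        keep &= scores[a].notna() & scores[b].notna() & (scores[a] == scores[b])
    return keep


def filter_modal_rule(
    scores: pd.DataFrame,
    lineage_samples: list[str],
    marker_map: pd.DataFrame,
    min_run: int = 2,
    flip: pd.Series | None = None,
) -> pd.Series:
    """Modal-2 / consecutive-deviation rule.

    A marker survives if the lineage modal score is 2, or if it belongs to a
    positional run of >= ``min_run`` markers (among those still under
    consideration, ordered by position within a chromosome set) whose modal
    scores deviate from 2 in the same *subgenome* direction (toward the
    A-genome parent or toward the B-genome parent). ``flip`` marks markers
    whose raw scores count B alleles, so their deviation direction is
    mirrored before run finding — raw scores alternate for a real unbalanced
    region covered by mixed-orientation markers, but the subgenome direction
    is coherent. Isolated deviations are the signature of mis-scored
    markers; coherent runs are real unbalanced compositions.
    """
    mm = marker_map.loc[scores.index]
    for cs, sub in mm.groupby("chrom_set"):
        if not sub["position"].is_monotonic_increasing:
            raise ValueError(f"marker map not position-ordered in set {cs}")
    modal = modal_scores(scores[lineage_samples])
    direction = np.sign(modal - 2)  # >0 toward A, <0 toward B
    if flip is not None:
        direction = direction * np.where(flip.reindex(scores.index).fillna(False), -1, 1)
    keep = modal == 2
    cs_arr = mm["chrom_set"].to_numpy()
    d = direction.to_numpy()
    n = len(d)
    run_ok = np.zeros(n, dtype=bool)
    i = 0
    while i < n:
        j = i + 1
        while j < n and cs_arr[j] == cs_arr[i] and d[j] == d[i]:
            j += 1
        if d[i] != 0 and not np.isnan(d[i]) and (j - i) >= min_run:
            run_ok[i:j] = True
        i = j
    return keep | pd.Series(run_ok, index=scores.index)


def standardize_orientation(
    scores: pd.DataFrame, roles: pd.Series
) -> tuple[pd.DataFrame, pd.Series, dict[str, str]]:
    """Flip markers so higher scores always count A-subgenome alleles.

    Markers whose A-parent score is below the B-parent score map s -> 4 - s
    (all samples); markers with equal parent scores cannot be oriented and
    are dropped.
    """
    a_cols = [s for s in scores.columns if roles.get(s) == "A_parent"]
    b_cols = [s for s in scores.columns if roles.get(s) == "B_parent"]
    if not a_cols or not b_cols:
        raise ValueError("parent controls required for orientation")
    a_val = modal_scores(scores[a_cols])
    b_val = modal_scores(scores[b_cols])
    keep = a_val != b_val
    reasons = {m: "unorientable_equal_parents" for m in scores.index[~keep]}
    flip = (a_val < b_val) & keep
    oriented = scores.copy()
    oriented.loc[flip] = 4.0 - oriented.loc[flip]
    return oriented[keep], keep, reasons


def exclude_noisy_samples(
    scores: pd.DataFrame,
    lineage_samples: list[str],
    marker_map: pd.DataFrame,
    k_sd: float = 4.0,
    min_run: int = 2,
) -> tuple[list[str], dict[str, str]]:
    """Drop samples whose isolated non-modal fraction exceeds mean + k_sd * sd.

    A non-modal cell counts as isolated when no positionally adjacent marker
    (same chromosome set, among retained markers) deviates in the same
    direction in that sample — so genuine multi-marker events never penalize
    their carrier.
    """
    sub = scores[lineage_samples]
    modal = modal_scores(sub).to_numpy()
    arr = sub.to_numpy(dtype=float)
    dev = np.sign(arr - modal[:, None])
    dev = np.nan_to_num(dev, nan=0.0)
    mm = marker_map.loc[scores.index]
    cs = mm["chrom_set"].to_numpy()
    same_next = np.zeros_like(dev, dtype=bool)
    same_set = cs[1:] == cs[:-1]
    agree = (dev[1:] == dev[:-1]) & (dev[1:] != 0)
    same_next[:-1] = agree & same_set[:, None]
    in_run = np.zeros_like(dev, dtype=bool)
    in_run[:-1] |= same_next[:-1]
    in_run[1:] |= same_next[:-1]
    isolated = (dev != 0) & ~in_run
    frac = isolated.mean(axis=0)
    cutoff = frac.mean() + k_sd * frac.std()
    dropped = {
        s: f"isolated_nonmodal_fraction_{frac[j]:.4f}_gt_{cutoff:.4f}"
        for j, s in enumerate(lineage_samples)
        if frac[j] > cutoff
    }
    kept = [s for s in lineage_samples if s not in dropped]
    return kept, dropped


def run_cascade(
    calls: DosageCalls,
    roles: pd.Series,
    replicate_pairs: list[tuple[str, str]],
    marker_map: pd.DataFrame,
    config: FilterConfig = FilterConfig(),
) -> CascadeResult:
    """Apply the full cascade in order and return the oriented, filtered calls.

    Order: array-QC sample exclusion -> complete scoring -> control
    consistency -> replicate concordance -> modal/consecutive rule ->
    orientation -> noisy-sample exclusion. The report telescopes: each
    stage's marker-out count is the next stage's marker-in count.
    """
    report = FilterReport()
    scores = calls.scores
    # sort markers genomically so positional rules see true adjacency
    order = marker_map.loc[scores.index].sort_values(["chrom_set", "position"]).index
    scores = scores.loc[order]

    drop_cols = [s for s in config.qc_fail_samples if s in scores.columns]
    for s in drop_cols:
        report.excluded_samples[s] = "array_qc_fail"
    scores = scores.drop(columns=drop_cols)
    roles = roles.drop(index=drop_cols)
    lineage = [s for s in scores.columns if roles.get(s) == "lineage"]

    keep = filter_complete(scores, lineage)
    report.add("complete_scoring", scores.index, scores.index[keep],
               {m: "missing_cell" for m in scores.index[~keep]})
    scores = scores[keep]

    keep, reasons = filter_controls(scores, roles)
    report.add("control_consistency", scores.index, scores.index[keep], reasons)
    scores = scores[keep]

    keep = filter_replicates(scores, replicate_pairs)
    report.add("replicate_concordance", scores.index, scores.index[keep],
               {m: "replicate_mismatch" for m in scores.index[~keep]})
    scores = scores[keep]

    # deviation direction is judged in A-counting space: the parent controls
    # tell us which markers count B alleles before orientation is applied
    a_cols = [s for s in scores.columns if roles.get(s) == "A_parent"]
    b_cols = [s for s in scores.columns if roles.get(s) == "B_parent"]
    flip = modal_scores(scores[a_cols]) < modal_scores(scores[b_cols])
    keep = filter_modal_rule(scores, lineage, marker_map, config.min_run, flip=flip)
    report.add("modal_rule", scores.index, scores.index[keep],
               {m: "isolated_modal_deviation" for m in scores.index[~keep]})
    scores = scores[keep]

    scores, keep, reasons = standardize_orientation(scores, roles)
    report.add("orientation", keep.index, keep.index[keep], reasons)

    if config.exclude_noisy_samples:
        kept_lineage, dropped = exclude_noisy_samples(
            scores, lineage, marker_map, config.noisy_sample_k_sd, config.min_run
        )
        report.excluded_samples.update(dropped)
        scores = scores.drop(columns=list(dropped))
        lineage = kept_lineage

    report.validate_telescoping()
    filtered = DosageCalls(
        scores=scores,
        confidence=calls.confidence.loc[scores.index, scores.columns],
        low_intensity=calls.low_intensity.loc[scores.index, scores.columns],
    )
    return CascadeResult(
        calls=filtered,
        report=report,
        lineage_samples=lineage,
        marker_map=marker_map.loc[scores.index],
    )
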