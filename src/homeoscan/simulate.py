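"""Synthetic SNP-array signals and WGS allele depths with known truth.

The array model is deliberately simple: per (marker, sample) cell the
A-signal fraction ``theta`` is a censored normal around the composition's
expectation a/(a+b) and the total ``intensity`` is normal around (a+b)/4.
Control samples emulate the study design: diploid A- and B-genome parents
and 1:1 / 3:1 / 1:3 DNA mixtures, plus duplicated generation-1 plants.

WGS allele depths at A/B-diagnostic sites are Poisson totals thinned
binomially by the A-copy fraction, with a synthetic-tetraploid (1:1 A:B)
baseline sample always included for downstream normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import (
    GenomeLayout,
    TruthEvent,
    copy_numbers,
    expected_intensity,
    expected_theta,
)
from .pedigree import PlantID, Pedigree

__all__ = [
    "ArrayNoise",
    "SignalSet",
    "CONTROL_COMPOSITION",
    "simulate_array",
    "ReadCounts",
    "default_sites",
    "simulate_wgs",
    "BASELINE_SAMPLE",
]

#: control role -> (A copies, B copies) rendered on the tetraploid scale
CONTROL_COMPOSITION: dict[str, tuple[int, int]] = {
    "A_parent": (4, 0),
    "B_parent": (0, 4),
    "mix_1_1": (2, 2),
    "mix_3_1": (3, 1),
    "mix_1_3": (1, 3),
}

#: control role -> number of replicate samples, mirroring the study design
CONTROL_COUNTS: dict[str, int] = {
    "A_parent": 3,
    "B_parent": 4,
    "mix_1_1": 2,
    "mix_3_1": 2,
    "mix_1_3": 2,
}

BASELINE_SAMPLE = "synthetic_tetraploid"


@dataclass(frozen=True)
class ArrayNoise:
    """Noise model for the array simulator.

    All magnitudes are calibration choices (the assay's error structure is
    not published); zero everywhere gives a noise-free rendering in which
    every expectation is exact.

    ``deletion_miscall`` reproduces the observed array behavior on
    single-homeolog deletions: a (2,0) region is rendered at the 3:1 theta
    expectation (an apparent AAAB run) while the intensity still drops to
    0.5, so only the low-intensity flag betrays the deletion until WGS
    resolves it.
    """

    theta_sd: float = 0.03
    intensity_cv: float = 0.05
    cell_misscore_prob: float = 2e-4
    bad_marker_frac: float = 0.02
    missing_rate: float = 5e-4
    deletion_miscall: bool = True

    def __post_init__(self) -> None:
        for name in ("theta_sd", "intensity_cv", "cell_misscore_prob",
                     "bad_marker_frac", "missing_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def none(cls, deletion_miscall: bool = True) -> "ArrayNoise":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, deletion_miscall)


@dataclass
class SignalSet:
    """Array signal matrices plus sample metadata.

    ``theta`` and ``intensity`` are (markers x samples) frames sharing index
    and columns; ``roles`` maps each sample to one of ``lineage``,
    ``replicate`` or a control role; ``replicate_pairs`` lists (plant sample,
    duplicate sample) column pairs.
    """

    theta: pd.DataFrame
    intensity: pd.DataFrame
    roles: pd.Series
    replicate_pairs: list[tuple[str, str]]
    bad_markers: list[str] = field(default_factory=list)

    @property
    def samples(self) -> list[str]:
        return list(self.theta.columns)

    @property
    def lineage_samples(self) -> list[str]:
        return [s for s in self.samples if self.roles[s] == "lineage"]

    def control_samples(self, role: str) -> list[str]:
        return [s for s in self.samples if self.roles[s] == role]


def _control_layout() -> list[tuple[str, str]]:
    out = []
    for role, n in CONTROL_COUNTS.items():
        for i in range(n):
            out.append((f"{role}_{i + 1}", role))
    return out


def simulate_array(
    pedigree: Pedigree,
    events: list[TruthEvent],
    marker_map: pd.DataFrame,
    noise: ArrayNoise = ArrayNoise(),
    seed: int = 0,
    extra_cell_noise: dict[str, float] | None = None,
) -> SignalSet:
    """Render array signals for the whole cohort plus controls.

    ``extra_cell_noise`` maps sample labels to an additional per-cell
    mis-score probability, used to emulate low-quality DNA samples that the
    sample-exclusion filter must remove. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    plants = pedigree.plants
    lineage_cols = [p.label for p in plants]
    gen1 = pedigree.by_generation(1)
    rep_pairs = [(p.label, f"{p.label}_rep") for p in gen1]
    control_cols = _control_layout()

    columns = lineage_cols + [r for _, r in rep_pairs] + [c for c, _ in control_cols]
    roles = pd.Series(
        ["lineage"] * len(lineage_cols)
        + ["replicate"] * len(rep_pairs)
        + [role for _, role in control_cols],
        index=columns,
        name="role",
    )

    n_markers = len(marker_map)
    a_lin, b_lin = copy_numbers(plants, events, marker_map)
    a_rep, b_rep = copy_numbers([p for p, _ in [(pedigree.get(x), y) for x, y in rep_pairs]],
                                events, marker_map)
    a_ctrl = np.empty((n_markers, len(control_cols)), dtype=np.int64)
    b_ctrl = np.empty_like(a_ctrl)
    for j, (_, role) in enumerate(control_cols):
        a_ctrl[:, j], b_ctrl[:, j] = CONTROL_COMPOSITION[role]
    a = np.concatenate([a_lin, a_rep, a_ctrl], axis=1)
    b = np.concatenate([b_lin, b_rep, b_ctrl], axis=1)

    theta = expected_theta(a, b)
    intensity = expected_intensity(a, b)
    if noise.deletion_miscall:
        theta = np.where((a == 2) & (b == 0), 0.75, theta)
        theta = np.where((a == 0) & (b == 2), 0.25, theta)

    # raw array scores count whichever allele the probe favors
    b_high = (marker_map["orientation"].to_numpy() == "B_high")[:, None]
    theta = np.where(b_high, 1.0 - theta, theta)

    # systematically mis-scored markers: the whole marker reports a wrong,
    # uniform composition for every sample
    bad_markers: list[str] = []
    n_bad = int(round(noise.bad_marker_frac * n_markers))
    if n_bad:
        bad_idx = rng.choice(n_markers, size=n_bad, replace=False)
        wrong = rng.integers(0, 5, size=n_bad) / 4.0
        theta[bad_idx, :] = wrong[:, None]
        bad_markers = [marker_map.index[i] for i in sorted(bad_idx)]

    # sporadic per-cell mis-scores: swap to a different dosage expectation
    p_cell = np.full(len(columns), noise.cell_misscore_prob)
    if extra_cell_noise:
        for s, p in extra_cell_noise.items():
            p_cell[columns.index(s)] = p
    if (p_cell > 0).any():
        hit = rng.random(theta.shape) < p_cell[None, :]
        shift = rng.integers(1, 5, size=theta.shape)
        wrong = ((np.round(theta * 4) + shift) % 5) / 4.0
        theta = np.where(hit, wrong, theta)

    if noise.theta_sd > 0:
        theta = np.clip(theta + rng.normal(0.0, noise.theta_sd, theta.shape), 0.0, 1.0)
    if noise.intensity_cv > 0:
        intensity = np.clip(
            intensity * (1.0 + rng.normal(0.0, noise.intensity_cv, intensity.shape)),
            1e-6,
            None,
        )

    if noise.missing_rate > 0:
        miss = rng.random(theta.shape) < noise.missing_rate
        theta = np.where(miss, np.nan, theta)
        intensity = np.where(miss, np.nan, intensity)

    theta_df = pd.DataFrame(theta, index=marker_map.index, columns=columns)
    intensity_df = pd.DataFrame(intensity, index=marker_map.index, columns=columns)
    return SignalSet(theta_df, intensity_df, roles, rep_pairs, bad_markers)


# ---------------------------------------------------------------------------
# WGS


@dataclass
class ReadCounts:
    """Raw A/B allele depths at diagnostic sites for a set of samples.

    ``sites`` is indexed by site id with columns ``chrom_set``, ``position``,
    ``a_allele``, ``b_allele``; ``raw_a``/``raw_b`` share that index with one
    column per sample. The synthetic-tetraploid baseline column is always
    present.
    """

    sites: pd.DataFrame
    raw_a: pd.DataFrame
    raw_b: pd.DataFrame
    baseline: str = BASELINE_SAMPLE

    @property
    def samples(self) -> list[str]:
        return list(self.raw_a.columns)


def default_sites(
    layout: GenomeLayout = GenomeLayout(),
    spacing: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """Evenly spaced A/B-diagnostic sites with distinct alleles."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    rows = []
    for cs in range(1, layout.n_sets + 1):
        for k, pos in enumerate(range(spacing // 2, layout.set_length, spacing)):
            rows.append({"site_id": f"S{cs:02d}_{k:05d}", "chrom_set": cs, "position": pos})
    sites = pd.DataFrame(rows).set_index("site_id")
    i = rng.integers(0, 4, size=len(sites))
    j = (i + rng.integers(1, 4, size=len(sites))) % 4
    sites["b_allele"] = bases[i]  # B-subgenome allele is the anchor reference
    sites["a_allele"] = bases[j]
    return sites


def simulate_wgs(
    samples: list[PlantID],
    events: list[TruthEvent],
    sites: pd.DataFrame,
    depth: float = 30.0,
    seed: int = 0,
) -> ReadCounts:
    """Draw allele depths at diagnostic sites for the given plants.

    Per site the total read count is Poisson(depth * (a+b)/4) and the A-allele
    depth is Binomial(total, a/(a+b)); a euploid synthetic-tetraploid baseline
    sample is always appended. Deterministic for a fixed seed.
    """
    if len(sites) == 0:
        raise ValueError("empty site list")
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rng = np.random.default_rng(seed)
    a, b = copy_numbers(list(samples), events, sites)
    # baseline is euploid AABB at every site
    a = np.concatenate([a, np.full((len(sites), 1), 2, dtype=np.int64)], axis=1)
    b = np.concatenate([b, np.full((len(sites), 1), 2, dtype=np.int64)], axis=1)

    lam = depth * (a + b) / 4.0
    total = rng.poisson(lam)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(a + b > 0, a / np.where(a + b > 0, (a + b).astype(float), 1.0), 0.0)
    raw_a = rng.binomial(total, p)
    raw_b = total - raw_a

    cols = [s.label for s in samples] + [BASELINE_SAMPLE]
    return ReadCounts(
        sites=sites.copy(),
        raw_a=pd.DataFrame(raw_a, index=sites.index, columns=cols),
        raw_b=pd.DataFrame(raw_b, index=sites.index, columns=cols),
    )
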