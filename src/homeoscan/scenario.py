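"""The emulated study: cohort conditions, end-to-end pipeline, truth scoring.

This module wires the simulators to the analysis stages under the study's
design: one founder advanced seven generations by single-seed descent (233
plants), diploid-parent and DNA-mixture controls, duplicated generation-1
samples, three implanted instability events (a heritable generation-4
B-homeolog terminal deletion, a whole-set ABBB in a generation-7 plant, a
transient ABBB in a generation-6 plant) on top of two ancestral terminal
tetrasomic background regions, and 30x WGS of five selected plants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .dosage import DosageCalls, call_dosage
from .events import (
    EventCall,
    RateSummary,
    detect_events,
    evaluate_origins,
)
from .filters import CascadeResult, FilterConfig, run_cascade
from .genome import TruthEvent, build_marker_map, implant_events
from .pedigree import Pedigree, generate_pedigree, parse_plant_id
from .simulate import ReadCounts, SignalSet, default_sites, simulate_array, simulate_wgs
from .wgs import classify_sample, reconcile

__all__ = [
    "CohortData",
    "GenotypeResult",
    "WgsResult",
    "build_cohort",
    "run_genotype_pipeline",
    "run_wgs_pipeline",
    "run_study",
    "window_truth_agreement",
    "KIND_WINDOW_LABEL",
]

#: truth kind -> the window composition a correct WGS classification shows
KIND_WINDOW_LABEL = {
    "DELETION_B": "AA_DELETION",
    "DELETION_A": "BB_DELETION",
    "ABBB": "ABBB",
    "AAAB": "AAAB",
    "AAAA": "AAAA",
    "BBBB": "BBBB",
    "TRISOMY_A": "TRISOMY_A",
    "TRISOMY_B": "TRISOMY_B",
}


def derive_seed(seed: int, stream: int) -> int:
    """Deterministic sub-seed below 2**31 for one named random stream."""
    return int(np.random.SeedSequence([int(seed), int(stream)]).generate_state(1)[0] % (2**31))


@dataclass
class CohortData:
    pedigree: Pedigree
    marker_map: pd.DataFrame
    events: list[TruthEvent]
    signals: SignalSet
    qc_fail_samples: list[str]
    noisy_samples: list[str]


@dataclass
class GenotypeResult:
    calls: DosageCalls
    cascade: CascadeResult
    final_calls: list[EventCall]
    ledger: list[EventCall]
    rate: RateSummary

    @property
    def n_plants_retained(self) -> int:
        return len(self.cascade.lineage_samples)


@dataclass
class WgsResult:
    counts: ReadCounts
    windows: dict[str, pd.DataFrame]
    reconciliation: pd.DataFrame = field(default_factory=pd.DataFrame)


def build_cohort(config: RunConfig) -> CohortData:
    """Simulate pedigree, truth events and array signals under the config."""
    seed = config.seed
    pedigree = generate_pedigree(seed=derive_seed(seed, 1))
    marker_map = build_marker_map(
        config.layout, b_high_frac=config.b_high_frac, seed=derive_seed(seed, 2)
    )
    events = implant_events(
        pedigree, config.events, seed=derive_seed(seed, 3), layout=config.layout
    )

    carriers = set()
    for ev in events:
        if not ev.is_background:
            carriers |= set(ev.carriers)
    eligible = [
        p.label
        for p in pedigree.plants
        if p.generation >= 2 and p not in carriers
    ]
    rng = np.random.default_rng(derive_seed(seed, 4))
    n_pick = config.n_qc_fail_samples + config.n_noisy_samples
    picked: list[str] = []
    if n_pick:
        idx = rng.choice(len(eligible), size=n_pick, replace=False)
        picked = [eligible[i] for i in sorted(idx)]
    qc_fail = picked[: config.n_qc_fail_samples]
    noisy = picked[config.n_qc_fail_samples :]

    signals = simulate_array(
        pedigree,
        events,
        marker_map,
        noise=config.noise,
        seed=derive_seed(seed, 5),
        extra_cell_noise={s: config.noisy_cell_prob for s in noisy} or None,
    )
    return CohortData(pedigree, marker_map, events, signals, qc_fail, noisy)


def run_genotype_pipeline(config: RunConfig, cohort: CohortData) -> GenotypeResult:
    """Dosage calling, filter cascade and event detection for one cohort."""
    calls = call_dosage(
        cohort.signals,
        method=config.caller.method,
        low_intensity_threshold=config.caller.low_intensity_threshold,
        min_confidence=config.caller.min_confidence,
        seed=derive_seed(config.seed, 6),
    )
    cascade = run_cascade(
        calls,
        cohort.signals.roles,
        cohort.signals.replicate_pairs,
        cohort.marker_map,
        FilterConfig(
            qc_fail_samples=tuple(cohort.qc_fail_samples),
            exclude_noisy_samples=config.filters.exclude_noisy_samples,
            noisy_sample_k_sd=config.filters.noisy_sample_k_sd,
            min_run=config.detect.min_run,
        ),
    )
    flags = cascade.calls.low_intensity[cascade.lineage_samples]
    final_calls, ledger, rate = detect_events(
        cascade.lineage_scores,
        cascade.marker_map,
        cohort.pedigree,
        flags=flags,
        min_run=config.detect.min_run,
        background_threshold=config.detect.background_threshold,
        n_plants=len(cohort.pedigree),
    )
    return GenotypeResult(calls, cascade, final_calls, ledger, rate)


def run_wgs_pipeline(
    config: RunConfig,
    cohort: CohortData,
    genotype: GenotypeResult | None = None,
) -> WgsResult:
    """Simulate WGS for the sequenced plants, classify windows, reconcile."""
    plants = [cohort.pedigree.get(lab) for lab in config.wgs.sequenced_plants]
    sites = default_sites(
        config.layout, spacing=config.wgs.site_spacing, seed=derive_seed(config.seed, 7)
    )
    counts = simulate_wgs(
        plants, cohort.events, sites, depth=config.wgs.depth, seed=derive_seed(config.seed, 8)
    )
    windows = {
        p.label: classify_sample(
            counts,
            p.label,
            window_size=config.wgs.window_size,
            min_sites=config.wgs.min_sites,
            tolerance=config.wgs.tolerance,
        )
        for p in plants
    }
    recon = pd.DataFrame()
    if genotype is not None:
        frames = []
        for p in plants:
            calls_p = [
                c
                for c in genotype.final_calls
                if c.plant == p.label and c.status != "background"
            ]
            if calls_p:
                frames.append(reconcile(calls_p, windows[p.label], p.label))
        if frames:
            recon = pd.concat(frames, ignore_index=True)
    return WgsResult(counts, windows, recon)


@dataclass
class StudyResult:
    cohort: CohortData
    genotype: GenotypeResult
    wgs: WgsResult | None
    truth_evaluation: dict


def run_study(config: RunConfig) -> StudyResult:
    """The whole pipeline under one config: simulate -> genotype -> WGS."""
    cohort = build_cohort(config)
    genotype = run_genotype_pipeline(config, cohort)
    wgs = run_wgs_pipeline(config, cohort, genotype) if config.wgs.enabled else None
    evaluation = evaluate_origins(genotype.ledger, cohort.events, cohort.pedigree)
    return StudyResult(cohort, genotype, wgs, evaluation)


def window_truth_agreement(
    windows: dict[str, pd.DataFrame],
    events: list[TruthEvent],
    min_windows: int = 1,
) -> dict:
    """Fraction of event windows whose WGS classification matches the truth.

    Considers, for each sequenced plant carrying a non-background event,
    every window fully inside the event interval; events spanning fewer than
    ``min_windows`` windows are skipped.
    """
    n_total = 0
    n_match = 0
    for plant, wdf in windows.items():
        pid = parse_plant_id(plant)
        for ev in events:
            if ev.is_background or pid not in ev.carriers:
                continue
            inside = wdf[
                (wdf["chrom_set"] == ev.chrom_set)
                & (wdf["start"] >= ev.start)
                & (wdf["end"] <= ev.end)
            ]
            if len(inside) < min_windows:
                continue
            n_total += len(inside)
            n_match += int((inside["composition"] == KIND_WINDOW_LABEL[ev.kind]).sum())
    return {
        "n_windows": n_total,
        "n_matching": n_match,
        "agreement": n_match / n_total if n_total else float("nan"),
    }
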