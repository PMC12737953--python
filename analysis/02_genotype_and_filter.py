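#!/usr/bin/env python
"""Score the array and run the marker-filter cascade.

Reads the simulated signals from results/cohort/, calls 0..4 tetraploid
dosages (fixed-bin caller), applies the filter cascade — complete scoring,
control consistency, replicate concordance, the modal-2 / consecutive-
deviation rule, orientation to A-allele counting — and excludes array-QC
failures and scattered-noise samples. Writes the raw and filtered dosage
matrices, the low-intensity flags and the telescoping filter report under
results/genotype/.
"""

import argparse
from pathlib import Path

import pandas as pd

from homeoscan import io
from homeoscan.config import RunConfig
from homeoscan.dosage import call_dosage
from homeoscan.filters import FilterConfig, run_cascade
from homeoscan.scenario import build_cohort, derive_seed

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "genotype")
    args = ap.parse_args()

    cfg = RunConfig.from_yaml(args.cohort / "config.yaml")
    signals = io.read_signals(args.cohort / "signals")
    mm = pd.read_csv(args.cohort / "marker_map.tsv", sep="\t", index_col=0)
    # the QC-failed sample list is part of the scenario, rebuilt from config
    qc_fail = build_cohort(cfg).qc_fail_samples

    calls = call_dosage(
        signals,
        method=cfg.caller.method,
        low_intensity_threshold=cfg.caller.low_intensity_threshold,
        min_confidence=cfg.caller.min_confidence,
        seed=derive_seed(cfg.seed, 6),
    )
    cascade = run_cascade(
        calls, signals.roles, signals.replicate_pairs, mm,
        FilterConfig(
            qc_fail_samples=tuple(qc_fail),
            exclude_noisy_samples=cfg.filters.exclude_noisy_samples,
            noisy_sample_k_sd=cfg.filters.noisy_sample_k_sd,
            min_run=cfg.detect.min_run,
        ),
    )

    out = args.out
    out.mkdir(parents=True, exist_ok=True)
    io.write_dosage(calls.scores, out / "dosage_raw.tsv")
    io.write_dosage(cascade.calls.scores, out / "dosage_filtered.tsv")
    cascade.calls.low_intensity.astype(int).to_csv(out / "low_intensity.tsv", sep="\t")
    cascade.report.to_frame().to_csv(out / "filter_report.tsv", sep="\t", index=False)
    io.write_json(cascade.report.to_dict(), out / "filter_report.json")

    print(cascade.report.to_frame().to_string(index=False))
    print(f"excluded samples: {sorted(cascade.report.excluded_samples)}")
    print(f"retained {len(cascade.calls.scores)} markers, "
          f"{len(cascade.lineage_samples)} lineage plants")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
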