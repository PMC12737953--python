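#!/usr/bin/env python
"""Call composition events, trace them through the pedigree, compute rates.

Reads the filtered A-counting dosage matrix from results/genotype/, finds
positional runs of non-euploid scores, separates cohort-wide ancestral
background from candidate events, resolves novelty against the pedigree and
computes the instability rate (independent origins per plant). Also writes
the composition matrix and genotype PCA. Outputs under results/events/.
"""

import argparse
from pathlib import Path

import pandas as pd

from homeoscan import io
from homeoscan.config import RunConfig
from homeoscan.events import detect_events
from homeoscan.report import composition_matrix, genotype_pca

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    ap.add_argument("--genotype", type=Path, default=ROOT / "results" / "genotype")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "events")
    args = ap.parse_args()

    cfg = RunConfig.from_yaml(args.cohort / "config.yaml")
    pedigree = io.read_pedigree(args.cohort / "pedigree.tsv")
    mm = pd.read_csv(args.cohort / "marker_map.tsv", sep="\t", index_col=0)
    scores = io.read_dosage(args.genotype / "dosage_filtered.tsv")
    flags = pd.read_csv(args.genotype / "low_intensity.tsv", sep="\t", index_col=0).astype(bool)
    lineage = [c for c in scores.columns if c in pedigree]

    final, ledger, rate = detect_events(
        scores[lineage], mm, pedigree,
        flags=flags[lineage],
        min_run=cfg.detect.min_run,
        background_threshold=cfg.detect.background_threshold,
        n_plants=len(pedigree),
    )

    out = args.out
    out.mkdir(parents=True, exist_ok=True)
    io.write_event_calls(final, out / "event_calls.tsv")
    io.write_event_calls(ledger, out / "origin_ledger.tsv")
    matrix = composition_matrix(scores[lineage], mm)
    matrix.to_csv(out / "composition_matrix.tsv", sep="\t", float_format="%g")
    coords, var = genotype_pca(scores[lineage])
    coords.to_csv(out / "genotype_pca.tsv", sep="\t", float_format="%.6g")
    io.write_json(
        {"n_origins": rate.n_events, "n_plants": rate.n_plants,
         "rate_percent": rate.rate_percent,
         "pca_variance_fractions": [float(v) for v in var[:5]]},
        out / "rate.json",
    )

    print("independent novel origins:")
    for c in ledger:
        print(f"  {c.plant}: {c.composition} on chromosome set {c.chrom_set:02d} "
              f"[{c.start:,}-{c.end:,}), {c.n_markers} markers")
    print(f"rate: {rate.n_events}/{rate.n_plants} plants = {rate.rate_percent}%")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
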