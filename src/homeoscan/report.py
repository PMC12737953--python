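"""Cohort-level reporting: composition matrix, genotype PCA, full-run driver.

The composition matrix is the markers-by-plants grid of A-counting dosage
scores ordered by genomic position — the standard visualization in which
unbalanced compositions appear as colored column blocks. PCA of the same
matrix separates plants by their structural changes; it is reporting only,
no inference hangs on it.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .io import (
    write_dosage,
    write_event_calls,
    write_json,
    write_pedigree,
    write_signals,
    write_truth_events,
    write_counts_tsv,
    write_counts_vcf,
)
from .scenario import StudyResult, run_study, window_truth_agreement

__all__ = ["composition_matrix", "genotype_pca", "run_all", "plot_composition_matrix"]


def composition_matrix(
    scores: pd.DataFrame, marker_map: pd.DataFrame
) -> pd.DataFrame:
    """Markers-by-plants score grid with rows in strict genomic order."""
    if scores.empty:
        raise ValueError("empty dosage matrix")
    order = marker_map.loc[scores.index].sort_values(["chrom_set", "position"]).index
    out = scores.loc[order].copy()
    out.insert(0, "chrom_set", marker_map.loc[order, "chrom_set"])
    out.insert(1, "position", marker_map.loc[order, "position"])
    return out


def plot_composition_matrix(
    matrix: pd.DataFrame, path: str | Path
) -> None:
    """Best-effort image of the composition grid (0..4 color coded)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import BoundaryNorm, ListedColormap

    data = matrix.drop(columns=["chrom_set", "position"]).to_numpy(dtype=float)
    # dark red (BBBB) .. grey (AABB) .. dark blue (AAAA)
    cmap = ListedColormap(["#8b0000", "#f08080", "#d3d3d3", "#87cefa", "#00008b"])
    norm = BoundaryNorm([-0.5, 0.5, 1.5, 2.5, 3.5, 4.5], cmap.N)
    fig, ax = plt.subplots(figsize=(10, 6))
    ax.imshow(data, aspect="auto", interpolation="nearest", cmap=cmap, norm=norm)
    ax.set_xlabel("plant")
    ax.set_ylabel("marker (genomic order)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def genotype_pca(scores: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered PCA of the plants x markers dosage matrix.

    ``scores`` is markers x plants; missing cells are mean-imputed per
    marker. Returns (coordinates indexed by plant, per-axis variance
    fractions). A constant matrix yields all-zero coordinates, not an error.
    """
    if scores.shape[1] < 3 or scores.shape[0] < 2:
        raise ValueError("PCA needs >= 3 plants and >= 2 markers")
    x = scores.to_numpy(dtype=float).T  # plants x markers
    col_mean = np.nanmean(x, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    inds = np.where(np.isnan(x))
    x[inds] = col_mean[inds[1]]
    x = x - x.mean(axis=0)
    n_comp = min(x.shape[0] - 1, x.shape[1], 10)
    if not np.any(x):
        coords = np.zeros((x.shape[0], n_comp))
        var = np.zeros(n_comp)
    else:
        from sklearn.decomposition import PCA

        pca = PCA(n_components=n_comp, svd_solver="full")
        coords = pca.fit_transform(x)
        var = pca.explained_variance_ratio_
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=scores.columns, columns=cols), var


def run_all(config: RunConfig, outdir: str | Path, make_plots: bool = False) -> dict:
    """Simulate, genotype, detect, (optionally) sequence, and write a report.

    All tabular outputs are deterministic for a fixed config + seed. Returns
    the summary dict that is also written to ``summary.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result: StudyResult = run_study(config)
    cohort, genotype = result.cohort, result.genotype

    write_pedigree(cohort.pedigree, outdir / "pedigree.tsv")
    write_truth_events(cohort.events, outdir / "truth_events.tsv")
    mm = cohort.marker_map.copy()
    mm.index.name = "marker_id"
    mm.to_csv(outdir / "marker_map.tsv", sep="\t")
    write_signals(cohort.signals, outdir / "signals")
    write_dosage(genotype.calls.scores, outdir / "dosage_raw.tsv")
    write_dosage(genotype.cascade.lineage_scores, outdir / "dosage_filtered.tsv")
    genotype.cascade.report.to_frame().to_csv(outdir / "filter_report.tsv", sep="\t", index=False)
    write_json(genotype.cascade.report.to_dict(), outdir / "filter_report.json")
    write_event_calls(genotype.final_calls, outdir / "event_calls.tsv")
    write_event_calls(genotype.ledger, outdir / "origin_ledger.tsv")

    matrix = composition_matrix(genotype.cascade.lineage_scores, cohort.marker_map)
    matrix.to_csv(outdir / "composition_matrix.tsv", sep="\t", float_format="%g")
    if make_plots:
        try:
            plot_composition_matrix(matrix, outdir / "composition_matrix.png")
        except Exception:
            pass  # images are best effort, nothing downstream depends on them
    coords, var = genotype_pca(genotype.cascade.lineage_scores)
    coords.to_csv(outdir / "genotype_pca.tsv", sep="\t", float_format="%.6g")

    summary: dict = {
        "n_plants": len(cohort.pedigree),
        "n_plants_retained": genotype.n_plants_retained,
        "n_markers_retained": int(len(genotype.cascade.calls.scores)),
        "n_origins": len(genotype.ledger),
        "rate_percent": genotype.rate.rate_percent,
        "pca_variance_fractions": [float(v) for v in var[:5]],
        "truth_evaluation": {
            k: v for k, v in result.truth_evaluation.items() if k != "false_origins"
        },
    }
    if result.wgs is not None:
        write_counts_tsv(result.wgs.counts, outdir / "wgs_counts.tsv")
        write_counts_vcf(
            result.wgs.counts, outdir / "wgs_counts.vcf", set_length=config.layout.set_length
        )
        all_windows = pd.concat(
            [w.assign(plant=p) for p, w in result.wgs.windows.items()], ignore_index=True
        )
        all_windows.to_csv(outdir / "wgs_windows.tsv", sep="\t", index=False,
                           float_format="%.6g")
        result.wgs.reconciliation.to_csv(outdir / "reconciliation.tsv", sep="\t", index=False)
        agree = window_truth_agreement(result.wgs.windows, cohort.events)
        summary["wgs_window_agreement"] = agree
        recon = result.wgs.reconciliation
        if len(recon):
            summary["n_relabeled_deletions"] = int((recon["verdict"] == "relabeled").sum())
            summary["n_confirmed"] = int((recon["verdict"] == "confirmed").sum())

    manifest = {
        "config_hash": config.config_hash(),
        "homeoscan_version": __version__,
        "seed": config.seed,
        "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()),
    }
    write_json(manifest, outdir / "manifest.json")
    write_json(summary, outdir / "summary.json")
    return summary
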