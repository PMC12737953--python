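"""Plain-text readers/writers for the pipeline's tables.

Everything is TSV except allele depths, which can also round-trip through a
minimal VCF: one record per diagnostic site on the B-subgenome anchor
(contigs B01..B10), REF = B allele, ALT = A allele, per-sample allele depths
in the AD field. Positions are 1-based in VCF, 0-based half-open internally.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .events import EventCall
from .genome import TruthEvent
from .pedigree import Pedigree, parse_plant_id
from .simulate import BASELINE_SAMPLE, ReadCounts, SignalSet

__all__ = [
    "write_pedigree",
    "read_pedigree",
    "write_truth_events",
    "write_signals",
    "read_signals",
    "write_dosage",
    "read_dosage",
    "write_event_calls",
    "write_counts_tsv",
    "read_counts_tsv",
    "write_counts_vcf",
    "read_counts_vcf",
    "write_json",
]

_FLOAT_FMT = "%.6g"


def write_pedigree(pedigree: Pedigree, path: str | Path) -> None:
    pedigree.to_frame().to_csv(path, sep="\t", index=False)


def read_pedigree(path: str | Path) -> Pedigree:
    df = pd.read_csv(path, sep="\t")
    return Pedigree(parse_plant_id(lab) for lab in df["label"])


def write_truth_events(events: list[TruthEvent], path: str | Path) -> None:
    rows = [
        {
            "chrom_set": ev.chrom_set,
            "start": ev.start,
            "end": ev.end,
            "kind": ev.kind,
            "plant": ev.plant.label,
            "heritable": ev.heritable,
            "n_carriers": len(ev.carriers),
        }
        for ev in events
    ]
    pd.DataFrame(
        rows, columns=["chrom_set", "start", "end", "kind", "plant", "heritable", "n_carriers"]
    ).to_csv(path, sep="\t", index=False)


def write_signals(signals: SignalSet, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    signals.theta.to_csv(outdir / "theta.tsv", sep="\t", float_format=_FLOAT_FMT)
    signals.intensity.to_csv(outdir / "intensity.tsv", sep="\t", float_format=_FLOAT_FMT)
    meta = signals.roles.rename("role").to_frame()
    meta.index.name = "sample"
    meta["replicate_of"] = ""
    for a, b in signals.replicate_pairs:
        meta.loc[b, "replicate_of"] = a
    meta.to_csv(outdir / "samples.tsv", sep="\t")
    with open(outdir / "bad_markers.txt", "w") as fh:
        fh.write("\n".join(signals.bad_markers) + ("\n" if signals.bad_markers else ""))


def read_signals(outdir: str | Path) -> SignalSet:
    outdir = Path(outdir)
    theta = pd.read_csv(outdir / "theta.tsv", sep="\t", index_col=0)
    intensity = pd.read_csv(outdir / "intensity.tsv", sep="\t", index_col=0)
    meta = pd.read_csv(outdir / "samples.tsv", sep="\t", index_col=0, keep_default_na=False)
    pairs = [(row["replicate_of"], s) for s, row in meta.iterrows() if row["replicate_of"]]
    bad_path = outdir / "bad_markers.txt"
    bad = bad_path.read_text().split() if bad_path.exists() else []
    return SignalSet(theta, intensity, meta["role"], pairs, bad)


def write_dosage(scores: pd.DataFrame, path: str | Path) -> None:
    out = scores.copy()
    out.index.name = "marker_id"
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%g")


def read_dosage(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values="NA").astype(float)


def write_event_calls(calls: list[EventCall], path: str | Path) -> None:
    rows = [
        {
            "chrom_set": c.chrom_set,
            "start": c.start,
            "end": c.end,
            "composition": c.composition,
            "plant": c.plant,
            "n_markers": c.n_markers,
            "status": c.status or "",
        }
        for c in calls
    ]
    pd.DataFrame(
        rows,
        columns=["chrom_set", "start", "end", "composition", "plant", "n_markers", "status"],
    ).to_csv(path, sep="\t", index=False)


def write_counts_tsv(counts: ReadCounts, path: str | Path) -> None:
    long = counts.sites[["chrom_set", "position", "a_allele", "b_allele"]].copy()
    for s in counts.samples:
        long[f"{s}:A"] = counts.raw_a[s]
        long[f"{s}:B"] = counts.raw_b[s]
    long.index.name = "site_id"
    long.to_csv(path, sep="\t")


def read_counts_tsv(path: str | Path) -> ReadCounts:
    df = pd.read_csv(path, sep="\t", index_col=0)
    sites = df[["chrom_set", "position", "a_allele", "b_allele"]].copy()
    samples = sorted({c[:-2] for c in df.columns if c.endswith(":A")})
    raw_a = pd.DataFrame({s: df[f"{s}:A"] for s in samples})
    raw_b = pd.DataFrame({s: df[f"{s}:B"] for s in samples})
    return ReadCounts(sites, raw_a, raw_b)


def _contig(chrom_set: int) -> str:
    return f"B{chrom_set:02d}"


def write_counts_vcf(counts: ReadCounts, path: str | Path, set_length: int = 10_000_000) -> None:
    """Minimal uncompressed VCF with per-sample AD (B-reference, A-alternate)."""
    samples = counts.samples
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
    ]
    for cs in sorted(counts.sites["chrom_set"].unique()):
        lines.append(f"##contig=<ID={_contig(int(cs))},length={set_length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    ra = counts.raw_a.to_numpy()
    rb = counts.raw_b.to_numpy()
    for i, (sid, row) in enumerate(counts.sites.iterrows()):
        fields = [
            _contig(int(row["chrom_set"])),
            str(int(row["position"]) + 1),
            str(sid),
            str(row["b_allele"]),
            str(row["a_allele"]),
            ".",
            "PASS",
            ".",
            "AD",
        ]
        fields.extend(f"{rb[i, j]},{ra[i, j]}" for j in range(len(samples)))
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def read_counts_vcf(path: str | Path) -> ReadCounts:
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        site_rows, a_rows, b_rows, ids = [], [], [], []
        for rec in vf:
            ids.append(rec.id)
            site_rows.append(
                {
                    "chrom_set": int(rec.chrom.lstrip("B")),
                    "position": rec.pos - 1,
                    "b_allele": rec.ref,
                    "a_allele": rec.alts[0],
                }
            )
            ad = [rec.samples[s]["AD"] for s in samples]
            b_rows.append([d[0] for d in ad])
            a_rows.append([d[1] for d in ad])
    sites = pd.DataFrame(site_rows, index=pd.Index(ids, name="site_id"))
    raw_a = pd.DataFrame(np.asarray(a_rows), index=sites.index, columns=samples)
    raw_b = pd.DataFrame(np.asarray(b_rows), index=sites.index, columns=samples)
    baseline = BASELINE_SAMPLE if BASELINE_SAMPLE in samples else samples[-1]
    return ReadCounts(sites, raw_a, raw_b, baseline=baseline)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
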