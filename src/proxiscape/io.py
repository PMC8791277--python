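"""Readers and writers for the plain-text formats the pipeline consumes.

Gene tables, chrom.sizes, enrichment TSVs, BED interval/repeat/edit files,
contact and Pol II TSVs, and a minimal Ensembl-dialect GTF gene reader.  All
genomic coordinates are 0-based half-open internally; GTF (1-based closed)
is converted on read, BED needs no conversion.
"""
from __future__ import annotations

import re
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import (
    ContactVector,
    CoverageTrack,
    EditEvent,
    GeneTable,
    Interval,
    IntervalSet,
    LabelStatus,
    RepeatInterval,
)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df.chrom.astype(str), df["size"].astype(int)))


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    pd.DataFrame(sorted(sizes.items())).to_csv(path, sep="\t", header=False, index=False)


def read_gene_table(genes_path: str | Path, chrom_sizes_path: str | Path) -> GeneTable:
    # round_trip parsing keeps tpm bit-exact across a write/read cycle
    df = pd.read_csv(genes_path, sep="\t", float_precision="round_trip")
    return GeneTable.from_frame(df, read_chrom_sizes(chrom_sizes_path))


def write_gene_table(genes: GeneTable, path: str | Path) -> None:
    # %.17g keeps float64 tpm values bit-exact across a write/read cycle
    genes.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_gtf_genes(path: str | Path, chrom_sizes: Mapping[str, int]) -> GeneTable:
    """One record per gene from an Ensembl-dialect GTF: outermost transcript
    bounds, converted to 0-based half-open coordinates."""
    bounds: dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] not in ("transcript", "gene"):
                continue
            attrs = dict(_GTF_ATTR.findall(f[8]))
            gid = attrs.get("gene_id")
            if gid is None:
                continue
            start0, end = int(f[3]) - 1, int(f[4])
            cur = bounds.get(gid)
            if cur is None:
                bounds[gid] = [f[0], start0, end, f[6]]
            else:
                cur[1] = min(cur[1], start0)
                cur[2] = max(cur[2], end)
    rows = [
        {"gene_id": gid, "chrom": c, "start": s, "end": e, "strand": st, "tpm": 0.0}
        for gid, (c, s, e, st) in bounds.items()
    ]
    return GeneTable.from_frame(pd.DataFrame(rows), chrom_sizes)


def read_enrichment(path: str | Path, log2: bool = False) -> pd.DataFrame:
    """Enrichment TSV with columns feature_id, fold_enrichment (or log2fc
    when ``log2`` is set), fdr; returns linear fold_enrichment."""
    df = pd.read_csv(path, sep="\t")
    if log2 or "log2fc" in df.columns and "fold_enrichment" not in df.columns:
        df["fold_enrichment"] = 2.0 ** df["log2fc"]
    return df[["feature_id", "fold_enrichment", "fdr"]]


def read_status(path: str | Path) -> dict[str, LabelStatus]:
    df = pd.read_csv(path, sep="\t")
    return {str(r.gene_id): LabelStatus(r.status) for r in df.itertuples(index=False)}


def write_status(status: Mapping[str, LabelStatus], path: str | Path) -> None:
    pd.DataFrame(
        {"gene_id": list(status), "status": [str(v) for v in status.values()]}
    ).to_csv(path, sep="\t", index=False)


def read_bed_intervals(path: str | Path, name: str = "") -> IntervalSet:
    ivs = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            ivs.append(Interval(f[0], int(f[1]), int(f[2])))
    return IntervalSet(ivs, name=name or Path(path).stem)


def write_bed_intervals(intervals: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals.intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_repeats_bed(path: str | Path) -> list[RepeatInterval]:
    """BED6+family: chrom, start, end, name, score, strand[, family]; when no
    7th column is present the name column is used as the family."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            family = f[6] if len(f) > 6 else f[3]
            out.append(RepeatInterval(f[0], int(f[1]), int(f[2]), f[5], family))
    return out


def write_repeats_bed(repeats: Sequence[RepeatInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(repeats):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.family}\t0\t{r.strand}\t{r.family}\n")


def read_edit_events(path: str | Path) -> list[EditEvent]:
    df = pd.read_csv(path, sep="\t")
    return [
        EditEvent(
            str(r.chrom), int(r.pos), str(r.ref_base), str(r.alt_base),
            int(r.alt_count), int(r.coverage), str(r.gene_strand),
        )
        for r in df.itertuples(index=False)
    ]


def write_edit_events(events: Sequence[EditEvent], path: str | Path) -> None:
    pd.DataFrame([e.__dict__ for e in events]).to_csv(path, sep="\t", index=False)


def read_snp_positions(path: str | Path) -> set[tuple[str, int]]:
    """SNP positions from a two-column (chrom, pos) TSV/BED-like file; a
    third BED end column is ignored."""
    out = set()
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            out.add((f[0], int(f[1])))
    return out


def read_contacts(path: str | Path) -> dict[str, ContactVector]:
    """Contacts TSV with columns chrom, bin_start, value (constant bin size
    inferred per chromosome)."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for chrom, grp in df.groupby("chrom", sort=True):
        grp = grp.sort_values("bin_start")
        starts = grp.bin_start.to_numpy()
        bin_bp = int(starts[1] - starts[0]) if len(starts) > 1 else int(starts[0]) or 1
        out[str(chrom)] = ContactVector(str(chrom), bin_bp, grp.value.to_numpy(float))
    return out


def write_contacts(contacts: Mapping[str, ContactVector], path: str | Path) -> None:
    frames = []
    for chrom in sorted(contacts):
        cv = contacts[chrom]
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "bin_start": np.arange(cv.values.size) * cv.bin_bp,
                    "value": cv.values,
                }
            )
        )
    pd.concat(frames).to_csv(path, sep="\t", index=False)


def read_bedgraph(path: str | Path, chrom: str, start: int, end: int, strand: str) -> CoverageTrack:
    """Per-base coverage over [start, end) materialized from a bedGraph."""
    values = np.zeros(end - start)
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if f[0] != chrom:
                continue
            s, e, v = int(f[1]), int(f[2]), float(f[3])
            lo, hi = max(s, start), min(e, end)
            if hi > lo:
                values[lo - start : hi - start] = v
    return CoverageTrack(chrom=chrom, strand=strand, start=start, values=values)
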