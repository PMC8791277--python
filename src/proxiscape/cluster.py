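"""Genomic clustering scans for proximity-labeled genes.

Per-chromosome enrichment, the 5 Mb / 2.5 Mb sliding-window Fisher scan, and
a telomere-proximity rank test.  All tests contrast LABELED genes against the
other detectably expressed genes; UNDETECTED genes are excluded first and
genes are assigned to windows by midpoint.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import bh_adjust, fisher_one_sided, rank_sum_less
from .types import GeneTable, LabelStatus

CANONICAL_POOL = "chrUn"


@dataclass(frozen=True)
class ChromResult:
    chrom: str
    n_labeled: int
    n_expressed: int
    p: float
    q: float


@dataclass(frozen=True)
class WindowResult:
    chrom: str
    start: int
    end: int
    n_labeled_in: int
    n_expressed_in: int
    p: float
    q: float
    selected: bool


def _expressed_mask(status: Mapping[str, LabelStatus], gene_ids: Sequence[str]) -> np.ndarray:
    return np.array([status.get(g, LabelStatus.UNDETECTED) != LabelStatus.UNDETECTED for g in gene_ids])


def _labeled_mask(status: Mapping[str, LabelStatus], gene_ids: Sequence[str]) -> np.ndarray:
    return np.array([status.get(g) == LabelStatus.LABELED for g in gene_ids])


def chromosome_enrichment(
    genes: GeneTable,
    status: Mapping[str, LabelStatus],
    pool_noncanonical: bool = True,
) -> list[ChromResult]:
    """Per-chromosome over-representation of labeled genes.

    One-sided Fisher per chromosome against the rest of the genome; q-values
    are BH-adjusted across chromosomes.  Chromosomes with no expressed genes
    are omitted.  When ``pool_noncanonical`` is set, contigs whose names do
    not match chr1..chr22/chrX/chrY/chrM (or the plain 1..22/X/Y/MT forms)
    are pooled into a single "chrUn" stratum.
    """
    gene_ids = genes.gene_ids
    expressed = _expressed_mask(status, gene_ids)
    labeled = _labeled_mask(status, gene_ids)
    if labeled.sum() == 0:
        raise ValueError("no labeled genes")

    canonical = {f"chr{i}" for i in list(range(1, 23)) + ["X", "Y", "M"]}
    canonical |= {str(i) for i in range(1, 23)} | {"X", "Y", "MT"}

    chroms = []
    for rec in genes:
        c = rec.chrom
        if pool_noncanonical and c not in canonical:
            c = CANONICAL_POOL
        chroms.append(c)
    chroms = np.array(chroms)

    total_labeled = int(labeled[expressed].sum())
    total_expressed = int(expressed.sum())

    rows = []
    for chrom in sorted(set(chroms)):
        on = (chroms == chrom) & expressed
        n_lab = int((on & labeled).sum())
        n_exp = int(on.sum())
        if n_exp == 0:
            continue
        a = n_lab
        b = n_exp - n_lab
        c = total_labeled - n_lab
        d = (total_expressed - n_exp) - c
        rows.append((chrom, n_lab, n_exp, fisher_one_sided(a, b, c, d)))
    q = bh_adjust(np.array([r[3] for r in rows]))
    return [ChromResult(chrom, n_lab, n_exp, p, float(qv)) for (chrom, n_lab, n_exp, p), qv in zip(rows, q)]


def tile_windows(chrom_length: int, window_bp: int, step_bp: int) -> list[tuple[int, int]]:
    """Sliding windows anchored at 0; the last partial window is included."""
    if not window_bp >= step_bp > 0:
        raise ValueError("need window_bp >= step_bp > 0")
    windows = []
    start = 0
    while start < chrom_length:
        windows.append((start, min(start + window_bp, chrom_length)))
        if start + window_bp >= chrom_length:
            break
        start += step_bp
    return windows


def window_scan(
    genes: GeneTable,
    status: Mapping[str, LabelStatus],
    window_bp: int = 5_000_000,
    step_bp: int = 2_500_000,
    q_thresh: float = 0.05,
    use_raw_p: bool = False,
) -> list[WindowResult]:
    """Sliding-window scan for regions over-represented in labeled genes.

    Each window is tested by one-sided Fisher against the rest of the genome
    (genes assigned by midpoint); q-values are BH-adjusted genome-wide across
    all windows.  ``selected`` marks a greedy maximal set of non-overlapping
    windows below the significance threshold, chosen in ascending p (ties:
    leftmost, then smallest chromosome name).  By default selection uses
    q < ``q_thresh``; ``use_raw_p`` switches the criterion to raw p.
    """
    gene_ids = genes.gene_ids
    expressed = _expressed_mask(status, gene_ids)
    labeled = _labeled_mask(status, gene_ids)
    if expressed.sum() == 0:
        raise ValueError("no expressed genes")

    mids = genes.midpoints()
    chrom_arr = np.array([r.chrom for r in genes])
    total_labeled = int(labeled[expressed].sum())
    total_expressed = int(expressed.sum())

    raw = []
    for chrom in sorted(genes.chrom_sizes):
        on_chrom = chrom_arr == chrom
        for w_start, w_end in tile_windows(genes.chrom_sizes[chrom], window_bp, step_bp):
            in_win = on_chrom & (mids >= w_start) & (mids < w_end) & expressed
            n_lab = int((in_win & labeled).sum())
            n_exp = int(in_win.sum())
            a, b = n_lab, n_exp - n_lab
            c = total_labeled - n_lab
            d = (total_expressed - n_exp) - c
            raw.append([chrom, w_start, w_end, n_lab, n_exp, fisher_one_sided(a, b, c, d)])

    q = bh_adjust(np.array([r[5] for r in raw]))

    # greedy non-overlapping selection in ascending p, ties leftmost then chrom
    order = sorted(
        range(len(raw)), key=lambda i: (raw[i][5], raw[i][1], raw[i][0])
    )
    selected = [False] * len(raw)
    taken: dict[str, list[tuple[int, int]]] = {}
    for i in order:
        chrom, w_start, w_end = raw[i][0], raw[i][1], raw[i][2]
        crit = raw[i][5] if use_raw_p else q[i]
        if crit >= q_thresh:
            continue
        if any(w_start < e and s < w_end for s, e in taken.get(chrom, [])):
            continue
        selected[i] = True
        taken.setdefault(chrom, []).append((w_start, w_end))

    return [
        WindowResult(chrom, s, e, n_lab, n_exp, p, float(qv), sel)
        for (chrom, s, e, n_lab, n_exp, p), qv, sel in zip(raw, q, selected)
    ]


def telomere_proximity_test(
    genes: GeneTable, status: Mapping[str, LabelStatus]
) -> tuple[pd.DataFrame, float]:
    """Are labeled genes closer to chromosome ends than unlabeled genes?

    Distance is min(midpoint, chrom_length - midpoint).  Returns the per-gene
    distance table and a one-sided Wilcoxon rank-sum p-value for labeled
    distances being smaller.
    """
    rows = []
    for rec in genes:
        st = status.get(rec.gene_id, LabelStatus.UNDETECTED)
        if st not in (LabelStatus.LABELED, LabelStatus.UNLABELED):
            continue
        length = genes.chrom_sizes[rec.chrom]
        dist = min(rec.midpoint, length - rec.midpoint)
        rows.append((rec.gene_id, rec.chrom, rec.midpoint, dist, str(st)))
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "midpoint", "telomere_distance", "status"])
    lab = df.loc[df.status == "LABELED", "telomere_distance"].to_numpy(float)
    unlab = df.loc[df.status == "UNLABELED", "telomere_distance"].to_numpy(float)
    if lab.size == 0 or unlab.size == 0:
        raise ValueError("both labeled and unlabeled groups must be non-empty")
    p = rank_sum_less(lab, unlab)
    return df, p


def window_results_to_frame(results: Sequence[WindowResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def chrom_results_to_frame(results: Sequence[ChromResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
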