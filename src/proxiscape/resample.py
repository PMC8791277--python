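"""Random-sampling null for genomic clustering.

The observed statistic is the pooled median intergenic distance between the
midpoints of labeled genes.  The null resamples, on every qualifying
chromosome (> 1 labeled gene), the same number of midpoints without
replacement from all detectably expressed genes on that chromosome, pools the
consecutive-midpoint distances across chromosomes and takes their median.
Significance is P = (k + 1) / (n + 1) with k the number of simulated medians
strictly below the real one; Δmed = median(simulated medians) − real median,
so positive values indicate tighter-than-random clustering.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .types import GeneTable, LabelStatus


@dataclass
class ResampleResult:
    real_median: float
    sim_medians: np.ndarray
    k: int
    n: int
    p: float
    delta_med: float

    def __post_init__(self) -> None:
        assert self.p == (self.k + 1) / (self.n + 1), "P=(k+1)/(n+1) identity violated"
        assert 0 <= self.k <= self.n


def pooled_median_intergenic_distance(midpoints_by_chrom: Mapping[str, Sequence[int]]) -> float:
    """Median of consecutive-midpoint distances pooled across chromosomes.

    Every included chromosome must carry >= 2 midpoints.  The median of an
    even-length pool is the mean of the two central values.
    """
    pooled: list[np.ndarray] = []
    for chrom, mids in midpoints_by_chrom.items():
        arr = np.sort(np.asarray(mids, dtype=np.int64))
        if arr.size < 2:
            raise ValueError(f"chromosome {chrom} has fewer than 2 midpoints")
        pooled.append(np.diff(arr))
    if not pooled:
        raise ValueError("no qualifying chromosome")
    return float(np.median(np.concatenate(pooled)))


def _qualifying_inputs(
    genes: GeneTable, status: Mapping[str, LabelStatus]
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Expressed midpoints and labeled midpoints per qualifying chromosome."""
    expressed: dict[str, list[int]] = {}
    labeled: dict[str, list[int]] = {}
    for rec in genes:
        st = status.get(rec.gene_id, LabelStatus.UNDETECTED)
        if st == LabelStatus.UNDETECTED:
            continue
        expressed.setdefault(rec.chrom, []).append(rec.midpoint)
        if st == LabelStatus.LABELED:
            labeled.setdefault(rec.chrom, []).append(rec.midpoint)
    qual = {c for c, mids in labeled.items() if len(mids) > 1}
    if not qual:
        raise ValueError("no chromosome with > 1 labeled gene")
    exp = {c: np.sort(np.array(expressed[c], dtype=np.int64)) for c in sorted(qual)}
    lab = {c: np.sort(np.array(labeled[c], dtype=np.int64)) for c in sorted(qual)}
    return exp, lab


def _simulate_medians(
    expressed: Mapping[str, np.ndarray],
    n_per_chr: Mapping[str, int],
    n_iter: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized without-replacement sampling of pooled medians.

    For each chromosome, ranks of i.i.d. uniforms give n_iter independent
    without-replacement draws at once; distances are pooled column-wise.
    """
    diff_blocks: list[np.ndarray] = []
    for chrom in sorted(expressed):
        coord = expressed[chrom]
        m = n_per_chr[chrom]
        keys = rng.random((n_iter, coord.size))
        idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
        sampled = np.sort(coord[idx], axis=1)
        diff_blocks.append(np.diff(sampled, axis=1))
    pooled = np.concatenate(diff_blocks, axis=1)
    return np.median(pooled, axis=1)


def enumerate_medians(
    expressed: Mapping[str, np.ndarray], n_per_chr: Mapping[str, int]
) -> np.ndarray:
    """Pooled medians of *every* possible sampling outcome.

    Exhaustive replacement for the Monte-Carlo sampler, feasible only for
    small instances: the Cartesian product of per-chromosome subsets.
    """
    per_chrom_diffs = []
    for chrom in sorted(expressed):
        coord = np.sort(np.asarray(expressed[chrom]))
        m = n_per_chr[chrom]
        per_chrom_diffs.append(
            [np.diff(np.sort(np.array(sub))) for sub in itertools.combinations(coord, m)]
        )
    medians = []
    for combo in itertools.product(*per_chrom_diffs):
        medians.append(float(np.median(np.concatenate(combo))))
    return np.array(medians)


def cluster_resampling_test(
    genes: GeneTable,
    status: Mapping[str, LabelStatus],
    n_iter: int = 10_000,
    seed: int | None = None,
    delta_stat: str = "median",
    exhaustive: bool = False,
) -> ResampleResult:
    """Monte-Carlo clustering test on labeled-gene intergenic distances.

    ``delta_stat`` selects how Δmed summarizes the simulated distribution:
    "median" (default) or "mean" of the simulated medians, minus the real
    median.  With ``exhaustive`` the sampler is replaced by full enumeration
    of all per-chromosome subsets (small instances only) and ``n_iter`` /
    ``seed`` are ignored.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if delta_stat not in ("median", "mean"):
        raise ValueError("delta_stat must be 'median' or 'mean'")
    expressed, labeled = _qualifying_inputs(genes, status)
    n_per_chr = {c: labeled[c].size for c in expressed}
    real_median = pooled_median_intergenic_distance(labeled)

    if exhaustive:
        sim_medians = enumerate_medians(expressed, n_per_chr)
        n_iter = sim_medians.size
    else:
        rng = np.random.default_rng(seed)
        sim_medians = _simulate_medians(expressed, n_per_chr, n_iter, rng)
    k = int((sim_medians < real_median).sum())  # strictly smaller; ties are not smaller
    p = (k + 1) / (n_iter + 1)
    center = float(np.median(sim_medians)) if delta_stat == "median" else float(np.mean(sim_medians))
    return ResampleResult(
        real_median=real_median,
        sim_medians=sim_medians,
        k=k,
        n=n_iter,
        p=p,
        delta_med=center - real_median,
    )
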