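"""RNA-processing feature analyses around proximity-labeled genes.

Pol II density matching, 3' read-through quantification, intron-retention
incidence, inverted-SINE pair detection and strand-aware A-to-I editing
filtering.  Transcribed-strand A-to-I editing appears in sequencing data as
genomic A>G on '+' genes and genomic T>C on '-' genes.
"""
from __future__ import annotations

import itertools
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import fisher_one_sided, incidence_chi2
from .types import CoverageTrack, EditEvent, GeneRecord, RepeatInterval

logger = logging.getLogger(__name__)


def cpmk(count: int, gene_length_bp: int, total_aligned: int) -> float:
    """Counts per million aligned reads per kilobase of gene length."""
    if gene_length_bp <= 0:
        raise ValueError("gene length must be positive")
    if total_aligned <= 0:
        raise ValueError("empty library")
    return (count * 1e6 / total_aligned) / (gene_length_bp / 1000)


def match_unlabeled_by_median(
    labeled_values: Sequence[float],
    unlabeled_values: Sequence[float],
    tol: float,
) -> np.ndarray:
    """Select the control subset with the highest values whose median matches
    the labeled median.

    Unlabeled values are sorted descending; over k = 1..N the top-k prefix
    whose median is within ``tol`` of the labeled median is chosen, first
    minimizing the absolute median difference and preferring larger k on
    ties.  Raises if no prefix gets within ``tol`` (the best achievable
    difference is reported).
    """
    lab = np.asarray(labeled_values, dtype=float)
    unlab = np.asarray(unlabeled_values, dtype=float)
    if lab.size == 0 or unlab.size == 0:
        raise ValueError("both labeled and unlabeled values must be non-empty")
    target = float(np.median(lab))
    ordered = np.sort(unlab)[::-1]
    best_k, best_diff = 0, np.inf
    for k in range(1, ordered.size + 1):
        diff = abs(float(np.median(ordered[:k])) - target)
        if diff < best_diff or (diff == best_diff and k > best_k):
            best_k, best_diff = k, diff
    if best_diff > tol:
        raise ValueError(
            f"no subset matches the labeled median within tol={tol}; "
            f"best achievable |difference| = {best_diff}"
        )
    subset = ordered[:best_k]
    assert abs(float(np.median(subset)) - target) <= tol
    return subset


def readthrough_ratio(
    track: CoverageTrack,
    gene: GeneRecord,
    downstream_bp: int = 10_000,
    chrom_length: int | None = None,
) -> float:
    """Transcriptional read-through past the 3' end of a gene.

    Ratio of mean coverage in the ~10 kb window downstream of the gene end
    (downstream in the direction of transcription: [end, end+downstream_bp)
    for '+' genes, [start-downstream_bp, start) for '-' genes, clipped to
    chromosome bounds) over mean gene-body coverage.  Returns NaN (flagged,
    excluded from group statistics) when the gene body has zero coverage.
    """
    if downstream_bp <= 0:
        raise ValueError("downstream_bp must be positive")
    body_mean = track.region_mean(gene.start, gene.end)
    if body_mean == 0:
        logger.warning("%s: zero gene-body coverage; read-through undefined", gene.gene_id)
        return float("nan")
    if gene.strand == "+":
        lo, hi = gene.end, gene.end + downstream_bp
        if chrom_length is not None:
            hi = min(hi, chrom_length)
    else:
        lo, hi = max(gene.start - downstream_bp, 0), gene.start
    if lo >= hi:
        return 0.0
    return track.region_mean(lo, hi) / body_mean


def find_inverted_sine_pairs(
    repeats: Sequence[RepeatInterval],
    region: tuple[str, int, int],
    same_family: bool = True,
    max_gap: int | None = None,
) -> list[tuple[RepeatInterval, RepeatInterval]]:
    """All unordered repeat pairs inside a region in inverted orientation.

    A pair qualifies when both repeats lie fully inside the region, are on
    opposite strands and (by default) belong to the same family (e.g. two
    Alus).  ``max_gap`` optionally bounds the distance between the elements.
    Pair order within the result follows genomic position, so the count is
    invariant to the input order of ``repeats``.
    """
    chrom, start, end = region
    if start >= end:
        raise ValueError("invalid region")
    inside = sorted(
        (r for r in repeats if r.chrom == chrom and r.start >= start and r.end <= end),
        key=lambda r: (r.start, r.end, r.strand, r.family),
    )
    pairs = []
    for r1, r2 in itertools.combinations(inside, 2):
        if r1.strand == r2.strand:
            continue
        if same_family and r1.family != r2.family:
            continue
        if max_gap is not None and max(r2.start - r1.end, r1.start - r2.end, 0) > max_gap:
            continue
        pairs.append((r1, r2))
    return pairs


def has_inverted_pair(
    repeats: Sequence[RepeatInterval],
    region: tuple[str, int, int],
    **kwargs,
) -> bool:
    return len(find_inverted_sine_pairs(repeats, region, **kwargs)) > 0


def filter_edit_events(
    events: Sequence[EditEvent],
    snp_positions: set[tuple[str, int]],
) -> list[EditEvent]:
    """Shortlist strand-consistent A-to-I editing candidates.

    Drops events at known SNP positions (position match only, alleles
    ignored), then keeps only events consistent with transcript-strand A>G:
    genomic ref A / alt G on '+' genes, genomic ref T / alt C on '-' genes.
    """
    kept = []
    for ev in events:
        if (ev.chrom, ev.pos) in snp_positions:
            continue
        if ev.gene_strand == "+" and (ev.ref_base, ev.alt_base) == ("A", "G"):
            kept.append(ev)
        elif ev.gene_strand == "-" and (ev.ref_base, ev.alt_base) == ("T", "C"):
            kept.append(ev)
    return kept


def summarize_repeat_editing(
    kept_events: Sequence[EditEvent],
    repeats: Sequence[RepeatInterval],
    all_positions: bool = False,
    position_coverage: Mapping[tuple[str, int], int] | None = None,
) -> pd.DataFrame:
    """Per-repeat edited fraction: sum(alt counts) / sum(coverage).

    By default the denominator sums coverage over the kept edited positions
    inside each repeat; with ``all_positions`` it sums ``position_coverage``
    over every covered position of the repeat instead.  Repeats with no kept
    events get fraction 0; a repeat with events but zero summed coverage is
    flagged NaN.
    """
    if not repeats:
        raise ValueError("repeats must be non-empty")
    rows = []
    for i, rep in enumerate(repeats):
        evs = [e for e in kept_events if e.chrom == rep.chrom and rep.start <= e.pos < rep.end]
        alt = sum(e.alt_count for e in evs)
        if all_positions:
            if position_coverage is None:
                raise ValueError("all_positions requires position_coverage")
            cov = sum(
                c for (chrom, pos), c in position_coverage.items()
                if chrom == rep.chrom and rep.start <= pos < rep.end
            )
        else:
            cov = sum(e.coverage for e in evs)
        if not evs:
            frac = 0.0
        elif cov == 0:
            logger.warning("repeat %s:%d-%d has events but zero coverage", rep.chrom, rep.start, rep.end)
            frac = float("nan")
        else:
            frac = alt / cov
        rows.append((rep.chrom, rep.start, rep.end, rep.strand, rep.family, len(evs), alt, cov, frac))
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "strand", "family",
            "n_edited_positions", "alt_sum", "coverage_sum", "edited_fraction",
        ],
    )


def apply_ir_cutoffs(
    ir_table: pd.DataFrame,
    delta_psi_thresh: float = 0.10,
    fdr_thresh: float = 0.05,
) -> pd.Series:
    """Per-gene retained-intron flag from an intron-retention caller's table.

    ``ir_table`` needs columns intron_id, gene_id, delta_psi, fdr; a gene is
    flagged when it has >= 1 intron with ΔPSI strictly above
    ``delta_psi_thresh`` and FDR strictly below ``fdr_thresh``.
    """
    hit = (ir_table.delta_psi > delta_psi_thresh) & (ir_table.fdr < fdr_thresh)
    return ir_table.assign(hit=hit).groupby("gene_id")["hit"].any()


def ir_incidence_test(
    labeled_ir_flags: Sequence[bool],
    matched_ir_flags: Sequence[bool],
) -> tuple[np.ndarray, float, float]:
    """Contrast intron-retention incidence between labeled genes and their
    Pol II density-matched controls.

    Builds the (with-IR, without-IR) x (labeled, matched) table and applies
    the chi-squared test; when any expected cell is below 5 the one-sided
    exact test is used instead (logged) and the chi2 statistic is NaN.
    Returns (table, chi2, p).
    """
    lab = np.asarray(labeled_ir_flags, dtype=bool)
    mat = np.asarray(matched_ir_flags, dtype=bool)
    a, b = int(lab.sum()), int(mat.sum())
    c, d = int(lab.size - lab.sum()), int(mat.size - mat.sum())
    table = np.array([[a, b], [c, d]])
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    if (expected < 5).any():
        logger.info("expected cell < 5; using one-sided exact test instead of chi-squared")
        return table, float("nan"), fisher_one_sided(a, b, c, d)
    chi2, p = incidence_chi2(a, b, c, d)
    return table, chi2, p
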