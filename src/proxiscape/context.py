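"""Spatial-context tests: interval overlap, contact-vector normalization and
group comparison, and hybrid-read density ranking."""
from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import fisher_one_sided, rank_sum_greater
from .types import ContactVector, GeneTable, IntervalSet, LabelStatus


def interval_overlap_test(
    genes: GeneTable,
    status: Mapping[str, LabelStatus],
    intervals: IntervalSet,
    any_overlap: bool = False,
) -> tuple[pd.Series, float]:
    """Enrichment of labeled genes inside an interval annotation.

    By default a gene overlaps iff its midpoint lies inside a merged interval;
    ``any_overlap`` switches to >= 1 bp of gene-body overlap.  Returns a
    per-gene boolean overlap flag (labeled and unlabeled genes only) and a
    one-sided Fisher p-value for labeled genes being inside more often.
    """
    if len(genes) == 0:
        raise ValueError("empty gene set")
    merged = intervals.merged()
    flags = {}
    classes = {}
    for rec in genes:
        st = status.get(rec.gene_id, LabelStatus.UNDETECTED)
        if st not in (LabelStatus.LABELED, LabelStatus.UNLABELED):
            continue
        if any_overlap:
            hit = any(
                iv.chrom == rec.chrom and iv.start < rec.end and rec.start < iv.end
                for iv in merged.intervals
            )
        else:
            hit = merged.contains_point(rec.chrom, rec.midpoint)
        flags[rec.gene_id] = hit
        classes[rec.gene_id] = st
    flag_s = pd.Series(flags, name="in_interval")
    lab_in = sum(1 for g, f in flags.items() if f and classes[g] == LabelStatus.LABELED)
    lab_out = sum(1 for g, f in flags.items() if not f and classes[g] == LabelStatus.LABELED)
    unlab_in = sum(1 for g, f in flags.items() if f and classes[g] == LabelStatus.UNLABELED)
    unlab_out = sum(1 for g, f in flags.items() if not f and classes[g] == LabelStatus.UNLABELED)
    p = fisher_one_sided(lab_in, lab_out, unlab_in, unlab_out)
    return flag_s, p


def normalize_contact_vector(
    contacts: ContactVector,
    cutoff: float = 1.5,
    include_zero_bins: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalize a per-bin contact vector to its chromosome median.

    The median is taken over non-zero bins by default (zero bins typically
    mark unmappable regions and would depress it); ``include_zero_bins``
    uses all bins.  Returns (normalized values, indices of peak bins), where
    peaks strictly exceed ``cutoff`` after normalization.
    """
    values = contacts.values
    ref = values if include_zero_bins else values[values > 0]
    if ref.size == 0 or float(np.median(ref)) <= 0:
        raise ValueError("degenerate contact vector")
    med = float(np.median(ref))
    normalized = values / med
    peaks = np.flatnonzero(normalized > cutoff)
    return normalized, peaks


def contact_group_test(
    genes: GeneTable,
    status: Mapping[str, LabelStatus],
    contacts: ContactVector | Mapping[str, ContactVector],
    cutoff: float = 1.5,
) -> float:
    """Do labeled genes sit in bins with higher normalized contact signal
    than the detectably expressed background?

    Each expressed gene is mapped to the median-normalized value of its
    midpoint bin (per-chromosome normalization when a vector set covering
    the genome is supplied; genes on chromosomes without a vector are
    skipped).  One-sided rank-sum, labeled greater than all expressed genes
    (the background includes the labeled genes themselves).
    """
    if isinstance(contacts, ContactVector):
        vectors = {contacts.chrom: contacts}
    else:
        vectors = dict(contacts)
    normalized = {c: normalize_contact_vector(cv, cutoff)[0] for c, cv in vectors.items()}
    lab, background = [], []
    for rec in genes:
        if rec.chrom not in vectors:
            continue
        st = status.get(rec.gene_id, LabelStatus.UNDETECTED)
        if st == LabelStatus.UNDETECTED:
            continue
        norm = normalized[rec.chrom]
        b = vectors[rec.chrom].bin_of(rec.midpoint)
        if b >= norm.size:
            continue
        v = norm[b]
        background.append(v)
        if st == LabelStatus.LABELED:
            lab.append(v)
    if not lab or not background:
        raise ValueError("both groups must be non-empty")
    return rank_sum_greater(np.array(lab), np.array(background))


def hybrid_density_rank(
    hybrid_counts: pd.DataFrame,
    genes: GeneTable,
    top_n: int,
) -> tuple[pd.DataFrame, set[str]]:
    """Rank genes by RNA-RNA hybrid read density.

    ``hybrid_counts`` needs columns gene_id, reads_rep1, reads_rep2; only
    genes detected (> 0 reads) in both replicates are retained (replicate
    intersection).  density = total reads / gene length in kb; expr_norm =
    total reads / tpm (NaN-flagged when tpm = 0).  The top-n set is taken by
    density, ties broken by expr_norm then gene_id.
    """
    by_id = {r.gene_id: r for r in genes}
    df = hybrid_counts.copy()
    df = df[(df.reads_rep1 > 0) & (df.reads_rep2 > 0)]
    df = df[df.gene_id.isin(by_id)]
    if top_n > len(df):
        raise ValueError(f"top_n {top_n} exceeds the {len(df)} genes detected in both replicates")
    rows = []
    for r in df.itertuples(index=False):
        rec = by_id[r.gene_id]
        reads = int(r.reads_rep1) + int(r.reads_rep2)
        length_kb = rec.length_bp / 1000
        density = reads / length_kb
        expr_norm = reads / rec.tpm if rec.tpm > 0 else np.nan
        rows.append((r.gene_id, reads, length_kb, rec.tpm, density, expr_norm))
    out = pd.DataFrame(
        rows, columns=["gene_id", "hybrid_reads", "length_kb", "tpm", "density", "expr_norm"]
    )
    out = out.sort_values(
        by=["density", "expr_norm", "gene_id"], ascending=[False, False, True]
    ).reset_index(drop=True)
    top = set(out.gene_id.iloc[:top_n])
    return out, top
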