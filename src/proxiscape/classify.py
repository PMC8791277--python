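"""Classification and normalization rules applied before any statistics.

Boundary semantics are strict everywhere ("< 5 reads", "> 50% of samples",
"> 1.5-fold", "FDR < 1e-10"): equality at a threshold falls on the
non-significant side.
"""
from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import EnrichmentRow, LabelStatus


def classify_expression(
    counts_matrix: pd.DataFrame | np.ndarray,
    min_reads: int = 5,
    frac: float = 0.5,
) -> pd.Series:
    """Flag detectably expressed genes from a gene x sample count matrix.

    A gene is *not* detectably expressed when the fraction of samples with
    fewer than ``min_reads`` reads is strictly greater than ``frac``.

    Returns a boolean Series (True = detectable) indexed by gene.
    """
    df = pd.DataFrame(counts_matrix)
    if df.shape[1] == 0:
        raise ValueError("no samples")
    if df.shape[0] == 0:
        raise ValueError("no genes")
    if (df.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    frac_below = (df < min_reads).sum(axis=1) / df.shape[1]
    return frac_below <= frac


def classify_seq_status(
    row: EnrichmentRow,
    detectable: bool,
    labeled_fc: float = 1.5,
    labeled_fdr: float = 1e-10,
    unlabeled_fc_lo: float = 1.0,
    unlabeled_fc_hi: float = 1.5,
    unlabeled_fdr: float = 0.1,
) -> LabelStatus:
    """Classify one gene from its fold enrichment versus the infusion control.

    LABELED: fold enrichment > ``labeled_fc`` and FDR < ``labeled_fdr``.
    UNLABELED: depleted (fold enrichment < ``unlabeled_fc_lo``) or failing to
    show significant enrichment (fold enrichment < ``unlabeled_fc_hi`` and
    FDR > ``unlabeled_fdr``).  Detectable genes matching neither predicate are
    AMBIGUOUS; undetectable genes are UNDETECTED regardless of enrichment.
    """
    if not detectable:
        return LabelStatus.UNDETECTED
    fc, fdr = row.fold_enrichment, row.fdr
    if fc > labeled_fc and fdr < labeled_fdr:
        return LabelStatus.LABELED
    if fc < unlabeled_fc_lo or (fc < unlabeled_fc_hi and fdr > unlabeled_fdr):
        return LabelStatus.UNLABELED
    return LabelStatus.AMBIGUOUS


def classify_ms_enriched(row: EnrichmentRow, fc: float = 2.0, fdr: float = 0.05) -> bool:
    """Proteomics enrichment call: fold enrichment > fc and FDR < fdr."""
    return row.fold_enrichment > fc and row.fdr < fdr


def rpm_normalize(count: float | np.ndarray, total_aligned: int) -> float | np.ndarray:
    """Reads-per-million scaling: count * 1e6 / total aligned reads."""
    if total_aligned <= 0:
        raise ValueError("empty library")
    if np.isscalar(count):
        if count < 0:
            raise ValueError("count must be non-negative")
        return count * 1_000_000 / total_aligned
    arr = np.asarray(count, dtype=float)
    if (arr < 0).any():
        raise ValueError("count must be non-negative")
    return arr * 1_000_000 / total_aligned


def classify_table(
    enrichment: pd.DataFrame,
    detectable: Mapping[str, bool] | pd.Series,
    **thresholds: float,
) -> pd.Series:
    """Vector version of :func:`classify_seq_status` over an enrichment table.

    ``enrichment`` needs columns ``feature_id``, ``fold_enrichment``, ``fdr``.
    Genes absent from ``detectable`` are treated as undetected.
    """
    out = {}
    det = dict(detectable) if not isinstance(detectable, pd.Series) else detectable
    for row in enrichment.itertuples(index=False):
        er = EnrichmentRow(str(row.feature_id), float(row.fold_enrichment), float(row.fdr))
        is_det = bool(det.get(er.feature_id, False)) if not isinstance(det, pd.Series) else bool(
            det.get(er.feature_id, False)
        )
        out[er.feature_id] = classify_seq_status(er, is_det, **thresholds)
    return pd.Series(out, name="status")
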