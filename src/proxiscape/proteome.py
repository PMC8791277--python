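"""Multi-compartment proteomics post-processing.

The specificity index (SI) of protein j for compartment k is its non-negative
log2 fold-enrichment (LFE, clipped at zero) in k divided by the sum of its
LFE values over all compartments:

    SI[j, k] = LFE[j, k] / sum_i LFE[j, i]

Rows whose LFE sums to zero have no defined SI and are flagged instead of
imputed.  The module is generic in the number of compartments.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import rank_sum_greater
from .types import ChartMsRow


@dataclass
class ProteomeMatrix:
    """Protein x compartment log2 fold-enrichments versus the infusion control."""

    protein_ids: list[str]
    compartments: list[str]
    raw_log2fe: np.ndarray
    fdr: np.ndarray

    def __post_init__(self) -> None:
        self.raw_log2fe = np.asarray(self.raw_log2fe, dtype=float)
        self.fdr = np.asarray(self.fdr, dtype=float)
        n_p, n_c = len(self.protein_ids), len(self.compartments)
        if self.raw_log2fe.shape != (n_p, n_c) or self.fdr.shape != (n_p, n_c):
            raise ValueError("matrix dimensions inconsistent with protein/compartment lists")

    @property
    def lfe(self) -> np.ndarray:
        """Non-negative LFE: non-positive log2 fold-enrichments set to 0."""
        return np.maximum(self.raw_log2fe, 0.0)


@dataclass
class SpecificityTable:
    si: pd.DataFrame  # protein x compartment; NaN rows for undefined
    defined: pd.Series  # bool per protein

    def __post_init__(self) -> None:
        sums = self.si.loc[self.defined].sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("defined SI rows must sum to 1")


def to_ppm(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Proteins-per-million: fraction of the total, times 1e6."""
    arr = np.asarray(values, dtype=float)
    if (arr < 0).any():
        raise ValueError("quantitative values must be non-negative")
    total = arr.sum()
    if total <= 0:
        raise ValueError("all-zero input")
    return arr / total * 1e6


def specificity_index(matrix: ProteomeMatrix) -> SpecificityTable:
    """Compute per-protein specificity indices across compartments."""
    if len(matrix.compartments) < 2:
        raise ValueError("need >= 2 compartments")
    lfe = matrix.lfe
    sums = lfe.sum(axis=1)
    defined = sums > 0
    si = np.full_like(lfe, np.nan)
    si[defined] = lfe[defined] / sums[defined, None]
    return SpecificityTable(
        si=pd.DataFrame(si, index=matrix.protein_ids, columns=matrix.compartments),
        defined=pd.Series(defined, index=matrix.protein_ids),
    )


def high_confidence_sets(
    si_table: SpecificityTable,
    enriched: pd.DataFrame,
) -> dict[str, set[str]]:
    """Per-compartment high-confidence protein sets.

    A protein is assigned to compartment k iff it is enriched in k and its SI
    for k strictly exceeds its SI for every other compartment.  Ties are
    assigned nowhere.  ``enriched`` is a boolean protein x compartment frame.
    """
    out: dict[str, set[str]] = {c: set() for c in si_table.si.columns}
    si = si_table.si
    for pid in si.index[si_table.defined]:
        row = si.loc[pid]
        best = row.idxmax()
        if (row.drop(best) < row[best]).all() and bool(enriched.loc[pid, best]):
            out[best].add(pid)
    return out


def si_group_test(
    si_table: SpecificityTable,
    labeled: Mapping[str, bool] | pd.Series,
    compartment: str,
) -> float:
    """One-sided rank-sum test: labeled proteins have higher SI in
    ``compartment`` than unlabeled ones.  Undefined-SI proteins are excluded."""
    lab_vals, unlab_vals = [], []
    labeled = pd.Series(dict(labeled)) if not isinstance(labeled, pd.Series) else labeled
    for pid in si_table.si.index:
        if not si_table.defined[pid]:
            continue
        v = si_table.si.loc[pid, compartment]
        (lab_vals if bool(labeled.get(pid, False)) else unlab_vals).append(v)
    if not lab_vals or not unlab_vals:
        raise ValueError("both groups must be non-empty")
    return rank_sum_greater(np.array(lab_vals), np.array(unlab_vals))


def chart_ms_filter(rows: Sequence[ChartMsRow]) -> list[ChartMsRow]:
    """Shortlist proteins from an RNA-capture MS experiment.

    Kept iff abundance in both capture-oligo pulldowns exceeds input > 2-fold,
    both input-normalized pulldown signals strictly exceed the sense-oligo
    control, and at least one pulldown exceeds the sense control > 2-fold.
    """
    kept = []
    for r in rows:
        co1_r, co2_r, sense_r = r.co1 / r.input, r.co2 / r.input, r.sense / r.input
        if (
            co1_r > 2
            and co2_r > 2
            and co1_r > sense_r
            and co2_r > sense_r
            and max(r.co1, r.co2) / r.sense > 2
        ):
            kept.append(r)
    return kept
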