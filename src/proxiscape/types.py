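"""Domain types shared across the package.

Coordinates are 0-based half-open (BED convention) everywhere; GTF input is
converted on read.  A gene's midpoint is ``floor((start + end) / 2)`` — a
deterministic integer coordinate used for window assignment, interval overlap
and the resampling null alike.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "tpm"]


class LabelStatus(str, enum.Enum):
    """Per-gene, per-compartment proximity-labeling class.

    LABELED / UNLABELED follow the enrichment-table cutoffs; UNDETECTED marks
    genes below the expression-detection rule; AMBIGUOUS is the remainder —
    detectable genes that satisfy neither the labeled nor the unlabeled
    predicate (this package's term; such genes are excluded from
    labeled-vs-unlabeled contrasts).
    """

    LABELED = "LABELED"
    UNLABELED = "UNLABELED"
    AMBIGUOUS = "AMBIGUOUS"
    UNDETECTED = "UNDETECTED"

    def __str__(self) -> str:  # TSV-friendly
        return self.value


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    tpm: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"{self.gene_id}: need 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if self.tpm < 0:
            raise ValueError(f"{self.gene_id}: tpm must be non-negative")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def length_bp(self) -> int:
        return self.end - self.start


@dataclass
class GeneTable:
    """Ordered gene records plus the chromosome sizes they live on."""

    records: list[GeneRecord]
    chrom_sizes: dict[str, int]

    def __post_init__(self) -> None:
        ids = [r.gene_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("gene_id values must be unique")
        for r in self.records:
            size = self.chrom_sizes.get(r.chrom)
            if size is None:
                raise ValueError(f"{r.gene_id}: chromosome {r.chrom} missing from chrom_sizes")
            if r.end > size:
                raise ValueError(f"{r.gene_id}: end {r.end} exceeds {r.chrom} length {size}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def gene_ids(self) -> list[str]:
        return [r.gene_id for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [r.gene_id for r in self.records],
                "chrom": [r.chrom for r in self.records],
                "start": [r.start for r in self.records],
                "end": [r.end for r in self.records],
                "strand": [r.strand for r in self.records],
                "tpm": [r.tpm for r in self.records],
            }
        )

    def midpoints(self) -> np.ndarray:
        return np.array([r.midpoint for r in self.records], dtype=np.int64)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, chrom_sizes: Mapping[str, int]) -> "GeneTable":
        records = [
            GeneRecord(
                gene_id=str(row.gene_id),
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                strand=str(row.strand),
                tpm=float(row.tpm),
            )
            for row in df.itertuples(index=False)
        ]
        return cls(records=records, chrom_sizes=dict(chrom_sizes))


@dataclass(frozen=True)
class EnrichmentRow:
    """One row of a differential-abundance output: linear fold enrichment of a
    feature in the labeled sample versus the infusion control, with its FDR."""

    feature_id: str
    fold_enrichment: float
    fdr: float

    def __post_init__(self) -> None:
        if self.fold_enrichment <= 0:
            raise ValueError(f"{self.feature_id}: fold_enrichment must be > 0")
        if not 0 <= self.fdr <= 1:
            raise ValueError(f"{self.feature_id}: fdr must lie in [0, 1]")


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"interval start {self.start} >= end {self.end}")


@dataclass
class IntervalSet:
    """Named set of genomic intervals (NADs, capture peaks, ...)."""

    intervals: list[Interval]
    name: str = ""

    def merged(self) -> "IntervalSet":
        """Union of the intervals, merged per chromosome."""
        out: list[Interval] = []
        by_chrom: dict[str, list[Interval]] = {}
        for iv in self.intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom in sorted(by_chrom):
            ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
            cur_s, cur_e = ivs[0].start, ivs[0].end
            for iv in ivs[1:]:
                if iv.start <= cur_e:
                    cur_e = max(cur_e, iv.end)
                else:
                    out.append(Interval(chrom, cur_s, cur_e))
                    cur_s, cur_e = iv.start, iv.end
            out.append(Interval(chrom, cur_s, cur_e))
        return IntervalSet(out, name=self.name)

    def contains_point(self, chrom: str, pos: int) -> bool:
        for iv in self.intervals:
            if iv.chrom == chrom and iv.start <= pos < iv.end:
                return True
        return False


@dataclass(frozen=True)
class RepeatInterval:
    """RepeatMasker-style repeat annotation (e.g. Alu or MIR SINE)."""

    chrom: str
    start: int
    end: int
    strand: str
    family: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("repeat start must precede end")
        if self.strand not in ("+", "-"):
            raise ValueError("repeat strand must be '+' or '-'")


@dataclass(frozen=True)
class EditEvent:
    """A candidate RNA-editing call at a genomic position.

    ``ref_base``/``alt_base`` are genomic-strand alleles; the transcript-strand
    interpretation (A-to-I read as A>G on '+' genes, T>C on '-' genes) is
    applied at filtering time.
    """

    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    alt_count: int
    coverage: int
    gene_strand: str

    def __post_init__(self) -> None:
        bases = {"A", "C", "G", "T"}
        if self.ref_base not in bases or self.alt_base not in bases:
            raise ValueError("ref/alt must be one of A, C, G, T")
        if self.ref_base == self.alt_base:
            raise ValueError("ref and alt must differ")
        if not 0 <= self.alt_count <= self.coverage:
            raise ValueError("need 0 <= alt_count <= coverage")
        if self.gene_strand not in ("+", "-"):
            raise ValueError("gene_strand must be '+' or '-'")


@dataclass
class ContactVector:
    """Per-bin proximity-ligation contact signal along one chromosome."""

    chrom: str
    bin_bp: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.bin_bp <= 0:
            raise ValueError("bin_bp must be positive")
        if (self.values < 0).any():
            raise ValueError("contact values must be non-negative")

    def bin_of(self, pos: int) -> int:
        return int(pos // self.bin_bp)


@dataclass
class CoverageTrack:
    """Strand-specific rpm coverage over a genomic region.

    ``values[i]`` is the coverage at genomic position ``start + i``; the
    covered region is [start, start + len(values)).
    """

    chrom: str
    strand: str
    start: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if self.start < 0:
            raise ValueError("start must be non-negative")
        if (self.values < 0).any():
            raise ValueError("coverage values must be non-negative")

    @property
    def end(self) -> int:
        return self.start + self.values.size

    def region_mean(self, start: int, end: int) -> float:
        """Mean coverage over [start, end) clipped to the covered region;
        positions outside the track count as zero coverage."""
        if start >= end:
            raise ValueError("empty region")
        lo = max(start, self.start)
        hi = min(end, self.end)
        total = self.values[lo - self.start : hi - self.start].sum() if hi > lo else 0.0
        return float(total) / (end - start)


@dataclass(frozen=True)
class ChartMsRow:
    """Abundances of one protein in an RNA-capture mass-spec experiment:
    two antisense capture oligo pulldowns (co1, co2), the sense-oligo
    control, and the input sample."""

    protein_id: str
    co1: float
    co2: float
    sense: float
    input: float

    def __post_init__(self) -> None:
        if self.input <= 0 or self.sense <= 0:
            raise ValueError(f"{self.protein_id}: sense and input abundances must be > 0")
        if self.co1 < 0 or self.co2 < 0:
            raise ValueError(f"{self.protein_id}: abundances must be non-negative")
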