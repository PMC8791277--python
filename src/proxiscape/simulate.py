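"""Synthetic data generators for every pipeline input.

The generators emulate the statistical structure the downstream analyses
assume — genes scattered along chromosomes with a clustered subset of
proximity-labeled targets, compartment-specific proteome enrichment, contact
vectors peaking over planted clusters, inverted-SINE pairs downstream of
labeled genes, and editing-event tables contaminated with SNPs.  Every
generator is a pure function of (config, seed): identical inputs give
identical outputs, and ground-truth labels are always emitted alongside the
data so recovery tests never re-derive truth.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .proteome import ProteomeMatrix
from .types import (
    ContactVector,
    EditEvent,
    GeneRecord,
    GeneTable,
    Interval,
    IntervalSet,
    LabelStatus,
    RepeatInterval,
)

DEFAULT_GENE_SPAN_BP = 2_000  # fixed span keeps density arithmetic hand-checkable


@dataclass
class SimulationConfig:
    """Layout of the synthetic gene universe and its planted label structure."""

    n_chroms: int = 3
    chrom_length_bp: int = 100_000_000
    n_genes: int = 3_000
    n_labeled: int = 60
    cluster_regions: list[tuple[str, int, int]] = field(default_factory=list)
    cluster_fraction: float = 0.8
    tpm_log_mean: float = 1.0
    tpm_log_sd: float = 1.0
    gene_span_bp: int = DEFAULT_GENE_SPAN_BP
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_labeled > self.n_genes:
            raise ValueError("n_labeled cannot exceed n_genes")
        if not 0 <= self.cluster_fraction <= 1:
            raise ValueError("cluster_fraction must lie in [0, 1]")
        chrom_names = set(self.chrom_names())
        for chrom, start, end in self.cluster_regions:
            if chrom not in chrom_names:
                raise ValueError(f"cluster region chromosome {chrom} not in the genome")
            if not 0 <= start < end <= self.chrom_length_bp:
                raise ValueError("cluster region outside chromosome bounds")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    def chrom_sizes(self) -> dict[str, int]:
        return {c: self.chrom_length_bp for c in self.chrom_names()}


@dataclass
class EditSimConfig:
    """Counts and depth ranges for the synthetic editing-event table."""

    n_true_edits: int = 100
    n_snps: int = 50
    alt_fraction_range: tuple[float, float] = (0.1, 0.6)
    coverage_range: tuple[int, int] = (10, 100)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_true_edits < 0 or self.n_snps < 0:
            raise ValueError("counts must be non-negative")
        if self.alt_fraction_range[0] > self.alt_fraction_range[1]:
            raise ValueError("alt_fraction_range must be ordered")
        if self.coverage_range[0] > self.coverage_range[1]:
            raise ValueError("coverage_range must be ordered")


@dataclass
class PlantResult:
    """Planted label assignment with ground truth."""

    status: dict[str, LabelStatus]
    labeled_ids: list[str]
    in_cluster_ids: list[str]  # the labeled genes placed inside cluster regions


@dataclass
class ContextBundle:
    contacts: dict[str, ContactVector]
    intervals: IntervalSet
    repeats: list[RepeatInterval]
    polii_density: pd.Series
    inverted_pair_truth: set[str]  # gene_ids that received a planted inverted pair


@dataclass
class EditSimResult:
    events: list[EditEvent]
    snp_positions: set[tuple[str, int]]
    truth: np.ndarray  # bool per event: planted true edit
    position_coverage: dict[tuple[str, int], int]


def simulate_gene_universe(config: SimulationConfig) -> GeneTable:
    """Scatter genes with distinct uniform-random midpoints over the genome.

    Genes get a fixed span (default 2 kb) centred on the midpoint, clipped to
    chromosome bounds, random strand, and log-normal TPM.
    """
    rng = np.random.default_rng(config.seed)
    sizes = config.chrom_sizes()
    names = config.chrom_names()
    capacity = sum(sizes.values())
    if config.n_genes > capacity:
        raise ValueError(f"{config.n_genes} genes cannot fit on {capacity} bp of genome")

    lengths = np.array([sizes[c] for c in names], dtype=float)
    alloc = rng.multinomial(config.n_genes, lengths / lengths.sum())
    # rebalance any chromosome allocated more genes than positions
    while True:
        over = alloc - lengths.astype(int)
        if (over <= 0).all():
            break
        excess = over.clip(min=0)
        alloc = alloc - excess
        room = (lengths.astype(int) - alloc).clip(min=0)
        redistribute = rng.multinomial(int(excess.sum()), room / room.sum())
        alloc = alloc + redistribute

    half = config.gene_span_bp // 2
    records: list[GeneRecord] = []
    gi = 0
    for chrom, n_on_chrom in zip(names, alloc):
        n_on_chrom = int(n_on_chrom)
        if n_on_chrom == 0:
            continue
        length = sizes[chrom]
        mids: np.ndarray = np.empty(0, dtype=np.int64)
        while mids.size < n_on_chrom:
            extra = rng.integers(0, length, size=n_on_chrom - mids.size)
            mids = np.unique(np.concatenate([mids, extra]))
        mids = np.sort(rng.permutation(mids)[:n_on_chrom]) if mids.size > n_on_chrom else np.sort(mids)
        strands = rng.choice(["+", "-"], size=n_on_chrom)
        tpms = rng.lognormal(config.tpm_log_mean, config.tpm_log_sd, size=n_on_chrom)
        for mid, strand, tpm in zip(mids, strands, tpms):
            start = max(int(mid) - half, 0)
            end = min(int(mid) + half, length)
            if start >= end:  # degenerate clip at a chromosome edge
                start, end = max(end - 1, 0), max(end, 1)
            records.append(GeneRecord(f"gene_{gi:05d}", chrom, start, end, str(strand), float(tpm)))
            gi += 1
    return GeneTable(records=records, chrom_sizes=sizes)


def _genes_in_regions(genes: GeneTable, regions: Sequence[tuple[str, int, int]]) -> list[str]:
    ivset = IntervalSet([Interval(c, s, e) for c, s, e in regions]).merged()
    return [r.gene_id for r in genes if ivset.contains_point(r.chrom, r.midpoint)]


def plant_labeled_clusters(genes: GeneTable, config: SimulationConfig) -> PlantResult:
    """Assign LABELED to ``n_labeled`` genes, concentrating an expected
    ``cluster_fraction`` of them (binomially drawn, without replacement)
    inside the configured cluster regions; everything else is UNLABELED."""
    rng = np.random.default_rng(config.seed + 1)
    inside = _genes_in_regions(genes, config.cluster_regions)
    if config.cluster_regions:
        for region in config.cluster_regions:
            if not _genes_in_regions(genes, [region]):
                raise ValueError(f"cluster region {region} contains no genes")
    outside = [g for g in genes.gene_ids if g not in set(inside)]

    if config.cluster_regions and config.cluster_fraction > 0:
        n_in = int(rng.binomial(config.n_labeled, config.cluster_fraction))
    else:
        n_in = 0
    n_in = min(n_in, len(inside))
    n_out = config.n_labeled - n_in
    if n_out > len(outside):
        raise ValueError("not enough genes outside cluster regions to label")
    chosen_in = list(rng.choice(inside, size=n_in, replace=False)) if n_in else []
    chosen_out = list(rng.choice(outside, size=n_out, replace=False)) if n_out else []
    labeled = set(chosen_in) | set(chosen_out)
    status = {
        g: (LabelStatus.LABELED if g in labeled else LabelStatus.UNLABELED)
        for g in genes.gene_ids
    }
    return PlantResult(status=status, labeled_ids=sorted(labeled), in_cluster_ids=sorted(chosen_in))


def simulate_proteome(
    n_proteins: int,
    n_compartments: int,
    n_specific_per_compartment: int,
    effect_log2: float = 2.0,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[ProteomeMatrix, pd.Series]:
    """Proteome log2 fold-enrichment matrix with planted compartment
    specificity.

    Planted proteins draw Normal(effect_log2, noise_sd) in their own
    compartment and Normal(0, noise_sd) elsewhere; background proteins are
    Normal(0, noise_sd) everywhere.  FDR is small where the effect is planted
    and large otherwise.  Returns the matrix and a truth Series mapping each
    protein to its compartment name (background proteins map to "").
    """
    if n_specific_per_compartment * n_compartments > n_proteins:
        raise ValueError("more planted-specific proteins than proteins")
    rng = np.random.default_rng(seed)
    compartments = [f"comp{i + 1}" for i in range(n_compartments)]
    protein_ids = [f"prot_{i:04d}" for i in range(n_proteins)]
    log2fe = rng.normal(0.0, noise_sd, size=(n_proteins, n_compartments))
    fdr = rng.uniform(0.2, 1.0, size=(n_proteins, n_compartments))
    truth = [""] * n_proteins
    row = 0
    for k, comp in enumerate(compartments):
        for _ in range(n_specific_per_compartment):
            log2fe[row, k] = rng.normal(effect_log2, noise_sd)
            fdr[row, k] = rng.uniform(0.0, 0.01)
            truth[row] = comp
            row += 1
    matrix = ProteomeMatrix(
        protein_ids=protein_ids, compartments=compartments, raw_log2fe=log2fe, fdr=fdr
    )
    return matrix, pd.Series(truth, index=protein_ids, name="truth_compartment")


def simulate_context(
    genes: GeneTable,
    status: Mapping[str, LabelStatus],
    cluster_regions: Sequence[tuple[str, int, int]],
    bin_bp: int = 500_000,
    peak_gain: float = 4.0,
    inverted_pair_fraction_labeled: float = 0.8,
    inverted_pair_fraction_unlabeled: float = 0.0,
    polii_log2_shift: float = 1.0,
    background_repeats_per_mb: float = 0.2,
    seed: int = 0,
) -> ContextBundle:
    """Genomic-context tracks consistent with the planted label structure.

    Contact vectors are exponential(1) baseline per bin with a multiplicative
    ``peak_gain`` on bins overlapping cluster regions; the interval set covers
    the cluster regions; SINE repeats include inverted Alu pairs planted in
    the 10 kb downstream region of a configurable fraction of labeled (and
    optionally unlabeled) genes plus sparse random background repeats; Pol II
    densities are log-normal with a log2 shift for labeled genes.
    """
    if bin_bp <= 0:
        raise ValueError("bin_bp must be positive")
    rng = np.random.default_rng(seed)
    region_set = IntervalSet([Interval(c, s, e) for c, s, e in cluster_regions], name="clusters")

    contacts: dict[str, ContactVector] = {}
    for chrom, length in genes.chrom_sizes.items():
        n_bins = -(-length // bin_bp)
        vals = rng.exponential(1.0, size=n_bins)
        for c, s, e in cluster_regions:
            if c != chrom:
                continue
            lo, hi = s // bin_bp, min(-(-e // bin_bp), n_bins)
            vals[lo:hi] *= peak_gain
        contacts[chrom] = ContactVector(chrom=chrom, bin_bp=bin_bp, values=vals)

    repeats: list[RepeatInterval] = []
    truth: set[str] = set()
    for rec in genes:
        st = status.get(rec.gene_id)
        frac = (
            inverted_pair_fraction_labeled
            if st == LabelStatus.LABELED
            else inverted_pair_fraction_unlabeled
        )
        if frac <= 0 or rng.random() >= frac:
            continue
        length = genes.chrom_sizes[rec.chrom]
        if rec.strand == "+":
            lo, hi = rec.end, min(rec.end + 10_000, length)
        else:
            lo, hi = max(rec.start - 10_000, 0), rec.start
        if hi - lo < 4_000:  # not enough room near a chromosome edge
            continue
        repeats.append(RepeatInterval(rec.chrom, lo + 500, lo + 800, "+", "Alu"))
        repeats.append(RepeatInterval(rec.chrom, lo + 1_500, lo + 1_800, "-", "Alu"))
        truth.add(rec.gene_id)
    for chrom, length in genes.chrom_sizes.items():
        n_bg = rng.poisson(background_repeats_per_mb * length / 1e6)
        for _ in range(n_bg):
            start = int(rng.integers(0, max(length - 300, 1)))
            family = str(rng.choice(["Alu", "MIR"]))
            strand = str(rng.choice(["+", "-"]))
            repeats.append(RepeatInterval(chrom, start, start + 300, strand, family))

    base = rng.lognormal(2.0, 1.0, size=len(genes))
    shift = np.array(
        [
            2.0**polii_log2_shift if status.get(r.gene_id) == LabelStatus.LABELED else 1.0
            for r in genes
        ]
    )
    polii = pd.Series(base * shift, index=genes.gene_ids, name="polii_cpmk")

    return ContextBundle(
        contacts=contacts,
        intervals=region_set.merged(),
        repeats=repeats,
        polii_density=polii,
        inverted_pair_truth=truth,
    )


def simulate_editing(
    genes: GeneTable,
    repeats: Sequence[RepeatInterval],
    config: EditSimConfig,
) -> EditSimResult:
    """Editing-event table with planted true A-to-I edits plus SNP noise.

    True edits land inside repeat elements and carry the transcribed-strand
    A>G signature (genomic A>G on '+' host genes, T>C on '-'); SNP
    contaminants sit at disjoint positions with arbitrary substitutions and
    their positions populate the SNP filter list.
    """
    if config.n_true_edits > 0 and not repeats:
        raise ValueError("repeats must be non-empty when planting true edits")
    rng = np.random.default_rng(config.seed)
    cov_lo, cov_hi = config.coverage_range
    af_lo, af_hi = config.alt_fraction_range

    used: set[tuple[str, int]] = set()
    events: list[EditEvent] = []
    truth: list[bool] = []
    coverage_map: dict[tuple[str, int], int] = {}

    def draw_depth() -> tuple[int, int]:
        cov = int(rng.integers(cov_lo, cov_hi + 1))
        alt = max(1, int(round(cov * rng.uniform(af_lo, af_hi))))
        return min(alt, cov), cov

    strand_by_gene = {r.gene_id: r.strand for r in genes}
    gene_ids = genes.gene_ids
    for _ in range(config.n_true_edits):
        for _attempt in range(1000):
            rep = repeats[int(rng.integers(0, len(repeats)))]
            pos = int(rng.integers(rep.start, rep.end))
            if (rep.chrom, pos) not in used:
                break
        else:
            raise RuntimeError("could not place a unique edit position")
        used.add((rep.chrom, pos))
        host = strand_by_gene[gene_ids[int(rng.integers(0, len(gene_ids)))]]
        ref, alt_b = ("A", "G") if host == "+" else ("T", "C")
        alt, cov = draw_depth()
        events.append(EditEvent(rep.chrom, pos, ref, alt_b, alt, cov, host))
        truth.append(True)
        coverage_map[(rep.chrom, pos)] = cov

    snp_positions: set[tuple[str, int]] = set()
    chroms = sorted(genes.chrom_sizes)
    for _ in range(config.n_snps):
        for _attempt in range(1000):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            pos = int(rng.integers(0, genes.chrom_sizes[chrom]))
            if (chrom, pos) not in used:
                break
        else:
            raise RuntimeError("could not place a unique SNP position")
        used.add((chrom, pos))
        snp_positions.add((chrom, pos))
        # half the contaminants mimic the true-edit signature so the SNP
        # filter (not the allele rule) is what removes them
        host = "+" if rng.random() < 0.5 else "-"
        if rng.random() < 0.5:
            ref, alt_b = ("A", "G") if host == "+" else ("T", "C")
        else:
            ref = str(rng.choice(["A", "C", "G", "T"]))
            alt_b = str(rng.choice([b for b in "ACGT" if b != ref]))
        alt, cov = draw_depth()
        events.append(EditEvent(chrom, pos, ref, alt_b, alt, cov, host))
        truth.append(False)
        coverage_map[(chrom, pos)] = cov

    order = rng.permutation(len(events))
    events = [events[i] for i in order]
    truth_arr = np.array(truth, dtype=bool)[order]
    return EditSimResult(
        events=events,
        snp_positions=snp_positions,
        truth=truth_arr,
        position_coverage=coverage_map,
    )
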