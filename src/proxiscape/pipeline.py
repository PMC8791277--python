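"""End-to-end synthetic pipeline: generate every input, run every analysis
stage, and emit the full set of report tables.

This is the driver behind ``proxiscape pipeline`` and the acceptance script.
All randomness flows from a single seed through named child streams, so a
run is fully reproducible.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io
from .cluster import (
    chrom_results_to_frame,
    chromosome_enrichment,
    telomere_proximity_test,
    window_results_to_frame,
    window_scan,
)
from .context import (
    contact_group_test,
    hybrid_density_rank,
    interval_overlap_test,
    normalize_contact_vector,
)
from .features import (
    apply_ir_cutoffs,
    filter_edit_events,
    has_inverted_pair,
    ir_incidence_test,
    match_unlabeled_by_median,
    readthrough_ratio,
    summarize_repeat_editing,
)
from .proteome import high_confidence_sets, si_group_test, specificity_index
from .resample import cluster_resampling_test
from .simulate import (
    ContextBundle,
    EditSimConfig,
    SimulationConfig,
    plant_labeled_clusters,
    simulate_context,
    simulate_editing,
    simulate_gene_universe,
    simulate_proteome,
)
from .stats import rank_sum_greater
from .types import CoverageTrack, GeneTable, LabelStatus


@dataclass
class PipelineConfig:
    """Study-scale defaults for the synthetic end-to-end run."""

    genome: SimulationConfig = field(
        default_factory=lambda: SimulationConfig(
            n_chroms=3,
            chrom_length_bp=100_000_000,
            n_genes=3_000,
            n_labeled=60,
            cluster_regions=[("chr1", 20_000_000, 25_000_000), ("chr2", 60_000_000, 65_000_000)],
            cluster_fraction=0.8,
        )
    )
    editing: EditSimConfig = field(default_factory=EditSimConfig)
    n_iter: int = 10_000
    n_proteins: int = 300
    n_compartments: int = 3
    n_specific_per_compartment: int = 50
    proteome_effect_log2: float = 2.0
    proteome_noise_sd: float = 0.3
    contact_bin_bp: int = 500_000
    contact_peak_gain: float = 4.0
    hybrid_top_n: int = 50
    match_tol_frac: float = 0.05
    readthrough_labeled: float = 0.5
    readthrough_unlabeled: float = 0.1
    ir_p_labeled: float = 0.3
    ir_p_unlabeled: float = 0.1


def _simulate_hybrid_counts(
    genes: GeneTable, contacts, seed: int, rate_scale: float = 3.0
) -> pd.DataFrame:
    """Two-replicate hybrid-read counts, Poisson with rate tied to the
    contact signal at each gene's bin (so contact-proximal genes rank high)."""
    rng = np.random.default_rng(seed)
    rows = []
    for rec in genes:
        cv = contacts[rec.chrom]
        b = min(cv.bin_of(rec.midpoint), cv.values.size - 1)
        lam = rate_scale * cv.values[b]
        rows.append(
            (rec.gene_id, int(rng.poisson(lam)), int(rng.poisson(lam)))
        )
    return pd.DataFrame(rows, columns=["gene_id", "reads_rep1", "reads_rep2"])


def _simulate_ir_table(
    genes: GeneTable,
    status: Mapping[str, LabelStatus],
    p_labeled: float,
    p_unlabeled: float,
    seed: int,
) -> pd.DataFrame:
    """Per-intron retention table (ΔPSI, FDR) with a higher retained-intron
    rate for labeled genes; 4 introns per gene."""
    rng = np.random.default_rng(seed)
    rows = []
    for rec in genes:
        p_ir = p_labeled if status.get(rec.gene_id) == LabelStatus.LABELED else p_unlabeled
        for j in range(4):
            if rng.random() < p_ir:
                dpsi = rng.uniform(0.11, 0.6)
                fdr = rng.uniform(0.0, 0.049)
            else:
                dpsi = rng.uniform(0.0, 0.10)
                fdr = rng.uniform(0.05, 1.0)
            rows.append((f"{rec.gene_id}_intron{j}", rec.gene_id, dpsi, fdr))
    return pd.DataFrame(rows, columns=["intron_id", "gene_id", "delta_psi", "fdr"])


def _readthrough_for_gene(
    rec, genes: GeneTable, rt_level: float, rng: np.random.Generator
) -> float:
    """Synthesize a coverage track around one gene and measure read-through."""
    body = float(rng.lognormal(1.0, 0.3))
    down = body * rt_level * float(rng.lognormal(0.0, 0.2))
    length = genes.chrom_sizes[rec.chrom]
    lo = max(rec.start - 10_000, 0)
    hi = min(rec.end + 10_000, length)
    values = np.zeros(hi - lo)
    values[rec.start - lo : rec.end - lo] = body
    if rec.strand == "+":
        values[rec.end - lo :] = down
    else:
        values[: rec.start - lo] = down
    track = CoverageTrack(chrom=rec.chrom, strand=rec.strand, start=lo, values=values)
    return readthrough_ratio(track, rec, downstream_bp=10_000, chrom_length=length)


def run_pipeline(config: PipelineConfig, outdir: str | Path, seed: int = 0) -> dict:
    """Run the full synthetic analysis and write every report table.

    Returns a summary dict of headline statistics (also written to
    ``summary.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.default_rng(seed)
    streams = {
        name: int(s)
        for name, s in zip(
            ["genome", "plant", "context", "proteome", "editing", "hybrid", "ir", "rt"],
            root.integers(0, 2**31 - 1, size=8),
        )
    }

    # --- gene universe and planted labels -------------------------------
    gcfg = SimulationConfig(**{**asdict(config.genome), "seed": streams["genome"]})
    genes = simulate_gene_universe(gcfg)
    plant = plant_labeled_clusters(genes, gcfg)
    status = plant.status
    io.write_gene_table(genes, outdir / "genes.tsv")
    io.write_chrom_sizes(genes.chrom_sizes, outdir / "chrom.sizes")
    io.write_status(status, outdir / "status.tsv")

    # --- clustering statistics ------------------------------------------
    windows = window_scan(genes, status)
    window_results_to_frame(windows).to_csv(outdir / "windows.tsv", sep="\t", index=False)
    chroms = chromosome_enrichment(genes, status)
    chrom_results_to_frame(chroms).to_csv(outdir / "chromosomes.tsv", sep="\t", index=False)
    resample = cluster_resampling_test(genes, status, n_iter=config.n_iter, seed=seed)
    pd.DataFrame(
        [
            {
                "real_median": resample.real_median,
                "n": resample.n,
                "k": resample.k,
                "p": resample.p,
                "delta_med": resample.delta_med,
            }
        ]
    ).to_csv(outdir / "resample.tsv", sep="\t", index=False)
    telo_df, telo_p = telomere_proximity_test(genes, status)
    telo_df.to_csv(outdir / "telomere.tsv", sep="\t", index=False)

    # --- proteome --------------------------------------------------------
    matrix, prot_truth = simulate_proteome(
        config.n_proteins,
        config.n_compartments,
        config.n_specific_per_compartment,
        config.proteome_effect_log2,
        config.proteome_noise_sd,
        seed=streams["proteome"],
    )
    si_table = specificity_index(matrix)
    si_out = si_table.si.copy()
    si_out.insert(0, "protein_id", si_out.index)
    si_out.to_csv(outdir / "si.tsv", sep="\t", index=False)
    enriched = pd.DataFrame(
        (matrix.raw_log2fe > 1.0) & (matrix.fdr < 0.05),
        index=matrix.protein_ids,
        columns=matrix.compartments,
    )
    hc = high_confidence_sets(si_table, enriched)
    pd.DataFrame(
        [(c, p) for c, ps in hc.items() for p in sorted(ps)], columns=["compartment", "protein_id"]
    ).to_csv(outdir / "high_confidence.tsv", sep="\t", index=False)
    comp0 = matrix.compartments[0]
    si_p = si_group_test(si_table, (prot_truth == comp0), comp0)

    # --- genomic context -------------------------------------------------
    ctx = simulate_context(
        genes,
        status,
        gcfg.cluster_regions,
        bin_bp=config.contact_bin_bp,
        peak_gain=config.contact_peak_gain,
        seed=streams["context"],
    )
    flags, overlap_p = interval_overlap_test(genes, status, ctx.intervals)
    flags.rename_axis("gene_id").reset_index().to_csv(outdir / "overlap.tsv", sep="\t", index=False)
    cluster_chrom = gcfg.cluster_regions[0][0]
    normalized, peaks = normalize_contact_vector(ctx.contacts[cluster_chrom])
    pd.DataFrame(
        {
            "chrom": cluster_chrom,
            "bin_start": np.arange(normalized.size) * config.contact_bin_bp,
            "normalized": normalized,
            "is_peak": np.isin(np.arange(normalized.size), peaks),
        }
    ).to_csv(outdir / "contacts_norm.tsv", sep="\t", index=False)
    contact_p = contact_group_test(genes, status, ctx.contacts)

    hybrid = _simulate_hybrid_counts(genes, ctx.contacts, streams["hybrid"])
    hybrid_table, top = hybrid_density_rank(hybrid, genes, top_n=config.hybrid_top_n)
    hybrid_table.assign(in_top=hybrid_table.gene_id.isin(top)).to_csv(
        outdir / "hybrid_rank.tsv", sep="\t", index=False
    )

    # --- Pol II matching and read-through --------------------------------
    labeled_ids = [g for g, s in status.items() if s == LabelStatus.LABELED]
    unlabeled_ids = [g for g, s in status.items() if s == LabelStatus.UNLABELED]
    polii = ctx.polii_density
    lab_vals = polii[labeled_ids].to_numpy()
    unlab_series = polii[unlabeled_ids].sort_values(ascending=False)
    tol = config.match_tol_frac * float(np.median(lab_vals))
    matched_vals = match_unlabeled_by_median(lab_vals, unlab_series.to_numpy(), tol=tol)
    matched_ids = list(unlab_series.index[: matched_vals.size])
    pd.DataFrame({"gene_id": matched_ids, "polii_cpmk": matched_vals}).to_csv(
        outdir / "matched.tsv", sep="\t", index=False
    )

    rt_rng = np.random.default_rng(streams["rt"])
    by_id = {r.gene_id: r for r in genes}
    rt_rows = []
    for gid in labeled_ids:
        rt_rows.append((gid, "LABELED", _readthrough_for_gene(by_id[gid], genes, config.readthrough_labeled, rt_rng)))
    for gid in matched_ids:
        rt_rows.append((gid, "MATCHED", _readthrough_for_gene(by_id[gid], genes, config.readthrough_unlabeled, rt_rng)))
    rt_df = pd.DataFrame(rt_rows, columns=["gene_id", "group", "readthrough_ratio"])
    rt_df.to_csv(outdir / "readthrough.tsv", sep="\t", index=False)
    rt_p = rank_sum_greater(
        rt_df.loc[rt_df.group == "LABELED", "readthrough_ratio"].dropna().to_numpy(),
        rt_df.loc[rt_df.group == "MATCHED", "readthrough_ratio"].dropna().to_numpy(),
    )

    # --- intron retention -------------------------------------------------
    ir_table = _simulate_ir_table(
        genes, status, config.ir_p_labeled, config.ir_p_unlabeled, streams["ir"]
    )
    ir_flags = apply_ir_cutoffs(ir_table)
    lab_flags = [bool(ir_flags.get(g, False)) for g in labeled_ids]
    mat_flags = [bool(ir_flags.get(g, False)) for g in matched_ids]
    ir_2x2, ir_chi2, ir_p = ir_incidence_test(lab_flags, mat_flags)
    pd.DataFrame(
        [
            {
                "labeled_with_ir": ir_2x2[0, 0],
                "matched_with_ir": ir_2x2[0, 1],
                "labeled_without_ir": ir_2x2[1, 0],
                "matched_without_ir": ir_2x2[1, 1],
                "chi2": ir_chi2,
                "p": ir_p,
            }
        ]
    ).to_csv(outdir / "ir.tsv", sep="\t", index=False)

    # --- inverted SINEs and editing --------------------------------------
    sine_rows = []
    for gid, grp in [(g, "LABELED") for g in labeled_ids] + [(g, "MATCHED") for g in matched_ids]:
        rec = by_id[gid]
        length = genes.chrom_sizes[rec.chrom]
        if rec.strand == "+":
            region = (rec.chrom, rec.end, min(rec.end + 10_000, length))
        else:
            region = (rec.chrom, max(rec.start - 10_000, 0), rec.start)
        sine_rows.append((gid, grp, has_inverted_pair(ctx.repeats, region)))
    sine_df = pd.DataFrame(sine_rows, columns=["gene_id", "group", "has_inverted_pair"])
    sine_df.to_csv(outdir / "sines.tsv", sep="\t", index=False)
    sine_2x2, sine_chi2, sine_p = ir_incidence_test(
        sine_df.loc[sine_df.group == "LABELED", "has_inverted_pair"].tolist(),
        sine_df.loc[sine_df.group == "MATCHED", "has_inverted_pair"].tolist(),
    )

    ecfg = EditSimConfig(**{**asdict(config.editing), "seed": streams["editing"]})
    edit_sim = simulate_editing(genes, ctx.repeats, ecfg)
    io.write_edit_events(edit_sim.events, outdir / "edit_events.tsv")
    kept = filter_edit_events(edit_sim.events, edit_sim.snp_positions)
    editing_summary = summarize_repeat_editing(kept, ctx.repeats)
    editing_summary.to_csv(outdir / "editing.tsv", sep="\t", index=False)
    truth_ids = {(e.chrom, e.pos) for e, t in zip(edit_sim.events, edit_sim.truth) if t}
    kept_ids = {(e.chrom, e.pos) for e in kept}
    precision = len(kept_ids & truth_ids) / len(kept_ids) if kept_ids else float("nan")
    recall = len(kept_ids & truth_ids) / len(truth_ids) if truth_ids else float("nan")

    summary = {
        "n_genes": len(genes),
        "n_labeled": len(labeled_ids),
        "n_selected_windows": int(sum(w.selected for w in windows)),
        "resample_p": resample.p,
        "resample_delta_med": resample.delta_med,
        "telomere_p": telo_p,
        "si_group_p": si_p,
        "overlap_p": overlap_p,
        "contact_p": contact_p,
        "n_matched": len(matched_ids),
        "readthrough_p": rt_p,
        "ir_chi2": ir_chi2,
        "ir_p": ir_p,
        "sine_p": sine_p,
        "editing_precision": precision,
        "editing_recall": recall,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
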