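# proxiscape

Statistical post-processing for proximity-labeling experiments that map the
RNA and protein neighbourhoods of nuclear bodies (nucleoli, paraspeckles,
perinucleolar compartments).  Given per-gene fold-enrichment tables from a
labeled-versus-infusion-control contrast, `proxiscape` classifies
transcripts, asks whether the labeled genes cluster along the genome, scores
compartment specificity of co-purified proteins, and tests downstream
RNA-processing signatures (Pol II density, 3′ read-through, intron
retention, A-to-I editing over inverted SINEs).  It is aimed at analysts of
RNA-proximity sequencing/mass-spec data who have enrichment tables in hand
and need the downstream statistics, plus synthetic-data generators to
validate every stage without any external download.

## What it computes

**Classification.** A gene is detectably expressed unless it has < 5 reads
in > 50% of samples.  A detectable gene is *labeled* when fold enrichment
FC > 1.5 with FDR < 10⁻¹⁰, *unlabeled* when FC < 1 (depleted) or FC < 1.5
with FDR > 0.1, and *ambiguous* otherwise.  Proteins are *enriched* at
FC > 2, FDR < 0.05.  All thresholds are strict inequalities.

**Genomic clustering.** Labeled genes are contrasted against all other
expressed genes by one-sided Fisher's exact test, per chromosome and in a
5 Mb sliding window advanced by 2.5 Mb (genes assigned by midpoint,
Benjamini–Hochberg q across all windows, greedy non-overlapping selection of
significant windows).  A resampling null draws, per chromosome with > 1
labeled gene, the same number of midpoints from all expressed genes without
replacement, and compares pooled median intergenic distances:

    P = (k + 1) / (n + 1),   k = #{ simulated median < observed median },

with Δmed = median(simulated medians) − observed median (> 0 means
tighter-than-random clustering), at n = 10,000 iterations by default.

**Compartment specificity.** With LFE the non-negative log₂ fold-enrichment
(negative values set to 0), the specificity index of protein *j* for
compartment *k* is SI·(j,k) = LFE(j,k) / Σᵢ LFE(j,i).  High-confidence sets
require enrichment plus a strict SI maximum; an RNA-capture MS shortlist
filter (CO1/CO2 versus input and sense-oligo controls) is included.

**Context and RNA processing.** Interval-overlap (NAD/peak) Fisher tests;
contact vectors normalized to the chromosome median with a strict 1.5×
peak cutoff; hybrid-read density ranking; median-matched Pol II control
selection; read-through ratio over the 10 kb downstream window;
intron-retention incidence (ΔPSI > 10%, FDR < 0.05; χ² without continuity
correction); strand-aware A-to-I editing filtering (A→G on +, T→C on −
genes, SNP positions removed) and per-repeat edited fractions; inverted
same-family SINE pair detection.

## Worked example

```python
from proxiscape import cluster_resampling_test, window_scan
from proxiscape.simulate import (SimulationConfig, simulate_gene_universe,
                                 plant_labeled_clusters)

cfg = SimulationConfig(
    n_chroms=3, chrom_length_bp=100_000_000, n_genes=3000, n_labeled=60,
    cluster_regions=[("chr1", 20_000_000, 25_000_000),
                     ("chr2", 60_000_000, 65_000_000)],
    cluster_fraction=0.8, seed=1)
genes = simulate_gene_universe(cfg)
plant = plant_labeled_clusters(genes, cfg)

for w in window_scan(genes, plant.status):
    if w.selected:
        print(f"{w.chrom}:{w.start//10**6}-{w.end//10**6} Mb  "
              f"labeled {w.n_labeled_in}/{w.n_expressed_in}  p={w.p:.3g}  q={w.q:.3g}")

res = cluster_resampling_test(genes, plant.status, n_iter=10_000, seed=1)
print(f"real median intergenic distance: {res.real_median/1e6:.3f} Mb")
print(f"resampling P = (k+1)/(n+1) = {res.p:.3g}   delta_med = {res.delta_med/1e6:.2f} Mb")
```

prints

```
chr1:20-25 Mb  labeled 21/37  p=4.4e-28  q=2.58e-26
chr2:60-65 Mb  labeled 29/49  p=3.9e-40  q=4.56e-38
real median intergenic distance: 0.144 Mb
resampling P = (k+1)/(n+1) = 0.0001   delta_med = 2.40 Mb
```

The scan recovers exactly the two planted 5 Mb clusters (21 and 29 of the 60
labeled genes fall inside them), and the resampling null says such tight
median intergenic spacing (0.14 Mb observed versus ≈2.5 Mb simulated) never
occurred in 10,000 random chromosome-matched draws, so P bottoms out at
1/10,001 with a positive Δmed of 2.4 Mb.

A command-line interface mirrors the library: `proxiscape simulate`,
`proxiscape classify`, `proxiscape cluster scan|chrom|resample`,
`proxiscape proteome si|filter-chart`, `proxiscape context
overlap|contacts|hybrid`, `proxiscape features editing|match`, and
`proxiscape pipeline` for the full synthetic run.

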