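# Methods

## Scope and model

`proxiscape` implements the downstream statistics of a proximity-labeling
experiment: transcripts and proteins near a probe-targeted RNA are
biotinylated in situ and quantified against an enzyme-infusion control, and
everything here starts from the resulting per-feature fold-enrichment/FDR
tables.  Upstream steps — alignment, quantification, differential-abundance
modelling, variant calling, intron-retention calling — are out of scope;
their output tables are inputs.

## Coordinate and classification conventions

All genomic coordinates are 0-based half-open (BED convention); GTF input is
converted on read.  A gene's midpoint is `floor((start+end)/2)` and is the
single coordinate used for window assignment, interval overlap, contact-bin
lookup and the resampling null, so the different stages cannot disagree
about where a gene "is".

Thresholds are strict everywhere: a gene is not detectably expressed when
the fraction of samples with fewer than 5 reads exceeds 50% (exactly 50% is
detectable); labeled requires FC > 1.5 *and* FDR < 1e-10; unlabeled requires
FC < 1, or FC < 1.5 and FDR > 0.1.  Equality at any threshold falls on the
non-significant side.  Detectable genes matching neither predicate are
called AMBIGUOUS — this package's own term, since the source analysis names
only the two contrasted classes — and are excluded from every
labeled-versus-unlabeled comparison.  The two predicates cannot both hold
(labeled needs FC > 1.5, unlabeled needs FC < 1.5), which a property test
asserts over random inputs.

## Clustering statistics

Per-chromosome and per-window enrichment use the one-sided Fisher's exact
test, computed as the hypergeometric upper tail P(X ≥ a) with the table
oriented (labeled-in, other-in; labeled-out, other-out).  The implementation
delegates to `scipy.stats.hypergeom`; the test suite checks it against an
exhaustive binomial-coefficient oracle on every 2×2 table with N ≤ 30.

Windows are anchored at 0 on each chromosome, span 5 Mb, advance by 2.5 Mb,
and the trailing partial window is kept.  q-values are Benjamini–Hochberg
across all windows genome-wide; the source analysis annotates raw p and does
not state a window-level correction, so both are reported and selection uses
q < 0.05 by default with a raw-p override.  Selection is greedy: windows are
taken in ascending p (ties: leftmost start, then chromosome name) subject to
not overlapping an already-selected window.  Non-canonical contigs can be
pooled into a single `chrUn` stratum for the chromosome test (default on).

The resampling null samples, for every chromosome carrying more than one
labeled gene, the same number of midpoints without replacement from that
chromosome's expressed genes, pools consecutive-midpoint distances across
chromosomes, and takes the median.  Significance is exactly
P = (k+1)/(n+1) with k the count of simulated medians *strictly* below the
observed one (ties count as not smaller); the identity is asserted on every
result object.  Δmed is median(simulated medians) − observed median; a
`delta_stat="mean"` option exists because the source describes Δmed on
distribution plots without a formula, and medians-of-medians matched the
framing best.  The sampler is vectorized (uniform keys + argpartition per
chromosome), and an exhaustive-enumeration mode replaces it on small
instances for oracle tests.  n = 10,000 iterations by default.

The telomere-proximity statistic is a one-sided Wilcoxon rank-sum on
min(midpoint, chromosome length − midpoint); the source reports the
enrichment without naming a test, so the rank-sum is this package's choice.
Rank-sum tests use exact enumeration when the combined sample is ≤ 20
without ties and the tie-corrected normal approximation otherwise.

## Proteome statistics

Quantitative values are scaled to proteins-per-million (fraction of total ×
1e6).  The specificity index divides a protein's non-negative log2
fold-enrichment (negatives clipped to 0) in one compartment by its sum
across all compartments; zero-sum rows are flagged undefined rather than
imputed, and the implementation is generic in the number of compartments
(three in the motivating design).  High-confidence assignment requires
enrichment (FC > 2, FDR < 0.05) plus a strictly maximal SI; ties assign
nowhere.  The capture-oligo MS shortlist keeps a protein when both
pulldowns exceed input > 2-fold, both input-normalized pulldowns strictly
exceed the sense control (strict inequality chosen where the source wording
is ambiguous), and at least one pulldown exceeds the sense control > 2-fold.

## Context and RNA-processing features

Gene–interval overlap uses midpoint-in-merged-interval (an any-overlap flag
switches to ≥ 1 bp), keeping the midpoint convention.  Contact vectors are
normalized to the per-chromosome median of non-zero bins (zero bins usually
mark unmappable regions and would depress the median; a flag includes them);
peaks strictly exceed 1.5× the median.  The contact group test maps each
expressed gene to its midpoint bin's normalized value and runs a one-sided
rank-sum of labeled genes against the full expressed background.  Hybrid-read
ranking requires detection in both replicates, defines density as reads per
kb of gene and expression-normalized count as reads per TPM — the source
names both quantities without formulas, so these are this package's
definitions, both reported.

Pol II matching sorts candidate control genes by density (cpmk: counts per
million per kb) descending and picks the largest top-k prefix whose median
is within a caller-supplied tolerance of the labeled median (the source
states the matching goal but no tolerance, so it is an explicit required
parameter); the returned subset's median is asserted within tolerance on
every call.  Read-through is the mean rpm over the 10 kb window downstream
of the annotated 3′ end (direction of transcription; clipped at chromosome
ends) divided by the mean gene-body rpm; zero-body genes are flagged NaN and
excluded from group statistics.  Intron-retention incidence applies strict
ΔPSI > 10% / FDR < 0.05 cutoffs to an external caller's per-intron table and
contrasts labeled versus matched genes with Pearson's χ² (no continuity
correction), falling back to the one-sided exact test when any expected cell
is below 5.  Editing events store genomic ref/alt; filtering drops events at
SNP positions (position only, alleles ignored) and keeps the
transcribed-strand A-to-I signature: A→G on +, T→C on − genes.  Per-repeat
edited fraction is Σ alt / Σ coverage over kept edited positions (an
all-positions denominator is available; the source does not specify which).
Inverted SINE pairs are two same-family repeats on opposite strands fully
inside the queried region, with optional family relaxation and a maximum-gap
bound; no maximum separation is imposed by default.

## Synthetic data

The generators produce every input with the statistical structure the
analyses assume, with truth labels always emitted: a gene universe with
distinct uniform midpoints, fixed 2 kb spans (hand-checkable density
arithmetic) and log-normal TPM; a labeled subset with a binomially drawn
number of genes placed in configured cluster regions (defaults: 3 × 100 Mb
chromosomes, 3,000 genes, 60 labeled, two 5 Mb clusters, cluster fraction
0.8 — the scale at which the clustering analyses are exercised); a proteome
with Normal(effect, σ) planted enrichment (defaults effect = 2 log2 units,
σ = 0.3); contact vectors with exponential(1) baseline and a multiplicative
gain (default 4) on cluster bins; inverted Alu pairs planted in the 10 kb
downstream window of labeled genes plus sparse background repeats; Pol II
densities log-normal with a 1-log2 shift for labeled genes; and editing
tables with 100 true strand-consistent edits inside repeats plus 50 SNP
contaminants at disjoint positions (half of which mimic the A→G signature so
the SNP filter, not the allele rule, must remove them).

Every generator is a pure function of (config, seed); the pipeline derives
independent child streams from one root seed.  Determinism is guaranteed per
numpy version; cross-version bit-identity is not promised.

What the synthetic benchmark does *not* emulate: realistic gene-length and
expression distributions, chromatin-driven contact structure beyond flat
exponential noise, repeat-family genomic biases, coverage-dependent editing
detectability, or correlated replicate noise.  Passing recovery tests
therefore demonstrates correctness of the statistics under their stated
assumptions, not performance on real libraries.

## Numerical choices and problem sizes

BH adjustment comes from statsmodels; χ² from `scipy.stats.chi2_contingency`
with `correction=False`.  Exact rank-sum enumeration is limited to combined
n ≤ 20 without ties.  The test suite runs the resampling null calibration at
200 replicates × 500 iterations on a 1,000-gene genome (Kolmogorov–Smirnov
uniformity at α = 0.01) and the recovery simulations at 100 seeds each with
500 resampling iterations — sizes chosen so the full suite completes in
under a minute while keeping Monte-Carlo error well below the asserted
margins.  The acceptance script runs the full pipeline at the default study
scale with 10,000 resampling iterations.

## Known limitations

- The resampling null pools intergenic distances across chromosomes before
  taking one median (per the quoted sampling procedure); per-chromosome
  medians are not offered.
- Window selection is greedy, not an optimal weighted-interval cover; with
  half-overlapping windows the greedy ascending-p rule matches the intended
  "non-overlapping significant windows" readout but is not unique under
  ties.
- The contact group test treats the labeled genes as part of the expressed
  background (one-sample-versus-population framing), which is slightly
  conservative.
- Undefined specificity indices (all-zero enrichment) are excluded, not
  imputed; with few defined proteins the group test loses power.
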