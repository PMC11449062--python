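# Methods

This note documents the models and procedures camevo implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical choices that matter.

## Study design being modeled

Two congeneric genomes with divergent photosynthetic physiology (a
CAM-leaning and a C3-leaning species, labels F and L) plus an outgroup
(label A) are compared along five axes: gene-family size, diel expression,
coding-sequence selection, promoter motif composition, and TE insertions.
Expression comes from a 24-h time course: 6 genotypes (accessions) per
species sampled every 4 h (6 time points), with time encoded as hours
after the first sampled point (one hour after lights-off).  Metabolites
come from the same design, with timepoints D+1..N+9 mapped to 1, 5, 9, 13,
17, 21 h after lights-on under a 12-h light cycle.

## Gene curation

A gene model is ROBUST if all of its exons are expressed, or if it has
both a start and a stop codon and a CDS of at least 50 amino acids.
"Expressed" defaults to a summed raw exon count > 0 across all samples;
the threshold is a parameter because any fixed cutoff is arbitrary at
typical sequencing depths.  Genes whose functional annotation matches a
repeat vocabulary (default: transposon, transposase, retrotransposon,
viral, virus, gag, pol, integrase — configurable, since annotation
pipelines vary in wording) are flagged NO_ORTHOLOGY together with every
gene in their orthogroup; the flag set is therefore a union of whole
orthogroups and the operation is idempotent.

## Family-size correction

The coverage model: a true single-copy gene attracts the genome-wide
single-copy mean coverage c̄_sc; a region assembled twice (haplotig pair)
splits its reads, so each copy shows ≈ c̄_sc/2.  For an orthogroup with n
member genes in one species, the corrected count is

    round(Σ_g cov_g / c̄_sc)

with rounding half away from zero and a floor of 1 whenever the orthogroup
has members with nonzero coverage.  Rounding is a design choice (the
correction ratio itself does not dictate an integerization); half-away
keeps the estimator unbiased at the midpoint and the floor prevents
annihilating genes that demonstrably exist.  c̄_sc is estimated from
orthogroups with exactly one gene in every species.  Correction applies
only to orthogroups containing multicopy genes, so clean single-copy
counts are never perturbed.  The set-level z-score for a gene set against
a background uses d = F − L per orthogroup:
z = (mean(d_set) − mean(d_bg)) / (sd(d_bg)/√|set|); negative values mean
larger families in species L.

## Diel differential expression

Counts are summed from exons to genes, normalized with TMM
(Robinson–Oshlack: reference = sample whose upper-quartile count fraction
is closest to the mean; genes zero in either library dropped; 30% M-value
and 5% A-value tails trimmed; inverse delta-method variances as weights;
factors rescaled to geometric mean 1), filtered at mean cpm ≥ 1, and
tested on log₂(cpm+1) with a two-stage polynomial regression:

1. full model y = β₀ + β₁S + Σ_{k≤3}(γₖtᵏ + δₖStᵏ), S = 0 for the baseline
   species (L); overall-regression F-test per gene, BH across genes, keep
   p_adj ≤ 0.05;
2. backward elimination of terms at α = 0.05; a gene is DE iff the final
   model keeps the species main effect or any species×time interaction and
   R² ≥ 0.6.

Least squares on transformed cpm rather than a count GLM: at 36 samples
per species the transformed model is well behaved, and calibration is
verified empirically (null false-call rate ≤ 8% at nominal 5% on 2,000
simulated null genes).  Degree 3 suits 6 time points — it can express one
asymmetric peak–trough cycle without saturating the design.  R² ≥ 0.6
mirrors the conventional default of time-course regression screens.  Time
is rescaled to [0,1] before building the polynomial to keep the design
matrix well conditioned.

DE profiles are clustered on 1 − Pearson distance of concatenated
per-species mean median-centered log-TPM curves with average-linkage
hierarchical clustering; the module count K is the k-means elbow — the
smallest k whose within-cluster-SS gain over k−1 falls below 10% of the
total spread (WSS at k = 1) — capped at 12.  The gain is measured against
the total spread because successive relative gains on tight clusters never
fall below a fixed fraction of the shrinking remainder.

## Pairwise dN/dS

The codon model acts on the 61 sense codons of the universal code with
rates q_ij = π_j·κ^[transition]·ω^[nonsynonymous] for single-nucleotide
changes and 0 otherwise; π is F3x4 estimated jointly from both sequences
(the common default for this model family); Q is scaled to one expected
substitution per codon per unit time.  The model is reversible, so the
pair likelihood depends only on total divergence t:
lnL = Σ_sites log(π_a P(t)_{a,b}), computed from site-pattern counts with
P(t) obtained by symmetrized eigendecomposition.  Optimization is bounded
L-BFGS-B over (t, κ, ω) from three ω starts {0.2, 1, 3}; the null fixes
ω = 1; 2ΔlnL is referred to χ²(1) — the conventional reference for this
test even though ω = 1 is interior.  dN and dS are derived with
denominators at ω = 1 (mutational opportunity), making dN/dS ≡ ω̂.  dS
below 1e-6 sets a dS_zero flag and caps ω at 999, operationalizing
"infinite" ratios.  Terminal stop codons are stripped; internal stops
invalidate the pair rather than being repaired.

Pair filters: both-incomplete pairs are removed, as are pairs whose length
difference reaches 20% of the shorter gene.  Per-scaffold comparisons use
only pairs with ≥ 5 variant sites.  The Nei–Gojobori (1986) counting
estimator with Jukes–Cantor correction is an independent cross-check; it
assumes no transition bias, so quantitative agreement with the ML estimate
is expected (and tested) only at κ = 1 — under κ ≈ 2 it underestimates ω
by ~15–20%, which is a property of the counting method, not a defect.

Codon alignment is protein-guided: global alignment of the translations
under BLOSUM62 with gap open 10 / extend 0.5, back-translated into codon
triples; columns with a gap in either sequence are excluded from the
likelihood.

## Promoter motifs

Motifs are the four circadian elements MOE CCACAC, EE AAAATATC, CBS
AAAAATCT, G-box CACGTG.  Scanning counts overlapping exact matches on the
promoter's sense strand, ignoring soft-mask case; N never matches.
Sense-strand-only is the default because only the G-box is its own reverse
complement; a both-strands flag exists.  Per-kb frequencies use the fixed
denominator 2.0 kb × n_genes even when promoters are clipped at scaffold
edges (a flag switches to actual summed length).  The DE-vs-background
test is a two-sided Mann–Whitney on per-promoter counts with the
background subsampled without replacement to 5,000.  Upstream regions are
not trimmed at neighboring genes — no masking rule is imposed.

## TE insertions

Overlap is ≥ 1 bp on half-open intervals (bedtools-intersect semantics);
"rate" is the raw overlap count, not length-normalized.  Query regions are
the gene span, introns only (span minus exons), or the span extended
3,000 bp on the 5′ side only (bedtools slop -l 3000 -r 0 -s semantics),
clipped at scaffold edges.  A TE overlapping several query intervals of
one gene counts once per queried region set.  Presence uses a 2×2
chi-square with Yates correction, falling back to Fisher's exact when an
expected cell is below 1; the per-gene rate uses Mann–Whitney.  High-TE
genes are those strictly above twice the genome-wide mean.

## Landscape and shared statistics

Windows tile from position 0 with the final partial window kept at its
actual length; a gene belongs to the window containing its start.  GC is
computed over A/C/G/T only (N excluded from the denominator); repeat
content is the soft-masked lowercase fraction; genic fraction merges
overlapping gene spans first.  Kendall τ_b (tie-corrected, asymptotic p)
is the correlation of record, with Shapiro–Wilk p-values reported as the
normality diagnostic motivating the rank test.  The 2×2 chi-square applies
the Yates correction by default, matching R's behaviour on 2×2 tables;
Mann–Whitney is exact when both n ≤ 20 and the pooled data are tie-free,
otherwise tie-corrected asymptotic.  BH adjustment is the standard step-up
with enforced monotonicity.  GO enrichment is classic per-term Fisher with
ancestor propagation over is_a/part_of; eliminating/weighted variants are
out of scope.

## Metabolites

Abundances are compound peak areas divided by each sample's main total ion
count (MTIC).  The accumulation statistic is max − min over an accession's
time series; the species comparison is an exact Mann–Whitney on
per-accession accumulations (n = 6 vs 6 enumerates all C(12,6) splits).
PCA standardizes compounds to unit variance before the SVD because
abundances span orders of magnitude; missing values are imputed with the
compound median; zero-variance compounds are dropped.

## Synthetic-data generator

The generator emulates, at desk scale, the inputs the analyses consume:

- genomes as random nucleotide sequences with a linear 30→50% GC gradient,
  soft-masked TE intervals of four classes at configurable densities, and
  non-overlapping genes of 1–8 exons placed on a fixed 2-kb stride;
- orthogroups drawn from configurable category fractions (1:1, F>L, F<L,
  F=L>1, unique; defaults 0.7/0.1/0.1/0.05/0.05, dominated by single-copy
  groups as in real orthology tables), with 20% of multicopy orthogroups
  carrying one artifactual haplotig copy whose coverage is halved;
- per-gene coverage at a 30× mean with 10% multiplicative Gaussian noise;
- negative-binomial diel counts with gene means
  b·exp(A·sin(2π(t−φ)/24)), baseline b = 500, dispersion 0.1, 6 replicates
  × 6 time points per species; planted DE genes get amplitude 1.5 in
  species F and 0 in L (≈ 4.5-fold peak-to-trough vs flat), non-DE genes
  share a mild common rhythm (A ≤ 0.5) between species;
- codon pairs evolved from a uniform sense-codon ancestor under the scaled
  codon model, so stop codons cannot occur and t is directly the expected
  divergence;
- promoters as motif-free random sequence (rejection resampling) with
  occurrences planted into disjoint slots at Poisson per-kb rates, making
  planted rates near-exact targets (junction effects contribute ≤ ~5%);
- metabolite tables with a CAM-like malate curve (3× peak/trough, peak at
  midday) in species F, flat in L, lognormal noise with cv 0.2.

One global seed expands into fixed per-stream child seeds (genome,
orthogroups, coverage, counts, codons, promoters, metabolites), so adding
a stream never perturbs the others and a fixed seed reproduces outputs
byte for byte.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: read-level sequencing error and mapping
bias between the two reference genomes, assembly fragmentation beyond
simple haplotig duplication, realistic codon usage or selection
heterogeneity along genes, linkage between TE insertions and expression,
positionally structured motif grammar, and batch effects in metabolite
measurements.  The tests establish that each algorithm recovers the truth
its own model class plants, at the stated effect sizes.

## Problem sizes and calibration checks

The recovery and calibration quantities recomputed by
`scripts/acceptance.py` use: 500 orthogroups (family-size recovery), 6
replicate alignments of 10,000 codons per ω ∈ {0.3, 1, 3} (estimator
bias), 500 neutral pairs of 300 codons (LRT size), 2,000 null and 600
(120 planted) genes (DE calibration and power), 1,000 promoters and 10
test replicates (motifs), 1,000 random gene/TE fixtures (intersection
oracle), ~4,000 enumerated 2×2 tables (Fisher oracle), and 20 replicates
each for the category-enrichment and metabolite calibrations.  These sizes
give stable estimates of the rates being measured while keeping a full run
in the low minutes on a single CPU.

## Known limitations

- The DE caller's least-squares stage assumes roughly constant variance of
  log-cpm; very low counts (near the cpm filter) are noisier than the
  model assumes.
- The dN/dS machinery is pairwise only; branch or site models and
  phylogeny-wide inference are out of scope.
- The k-means elbow rule for K is a heuristic; for flat WSS profiles it
  returns small K by construction.
- GO enrichment treats terms independently (classic Fisher); parent-child
  dependence inflates correlated discoveries.
- Orthology inference, read alignment and TE discovery are inputs, not
  computations — the package starts where those pipelines end.
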