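# Methods

## Scope and data model

The package analyzes population methylation data in three layers: array
beta values (samples × probes, β ∈ [0, 1]), genotype dosages (samples ×
SNPs, values in [0, 2]), and bisulfite read counts per (sample, CpG).
Probes and SNPs live on a shared coordinate system via a BED-like probe
manifest (0-based CpG cytosine positions).  All containers are pandas
DataFrames; `GenotypeTable` recomputes the folded allele frequency
maf = min(f, 1 − f), f = mean(dosage)/2, on construction so the MAF filter
can never drift out of sync with the dosages.

## Normalization

Beta values are non-Gaussian (bounded, bimodal), so the scan operates on
rank-normal scores Φ⁻¹((rank − 0.5)/n) with average ranks for ties.  The
default is two-stage: across probes within each individual first (removing
individual-level intensity differences), then across individuals at each
probe (making each probe marginally standard normal).  `by_individual`,
`by_probe` and `none` are available for sensitivity analyses.  Missing beta
values are a hard error: the simulator never emits them and imputation is
deliberately out of scope, so real-data users must pre-impute.

After two-stage normalization every probe column is an exact permutation of
the rank-normal score set — unless ties occur.  Ties are possible because
stage-one output is discrete (one of n_probes values); with realistically
many probes they are rare, and tied entries receive averaged ranks.

## Confounder removal

Sample-space principal components of the (column-centered) normalized
matrix are removed by projection: residual = X_c − U_k U_kᵀ X_c.  The
regression includes the intercept implicitly (centering), so residual
columns are exactly orthogonal to the removed components.  K is selected by
rerunning the full scan on a grid and keeping the K that maximizes the
number of probes with an association at FDR 10%, ties toward smaller K —
the same yield criterion used to justify the choice in array meQTL studies.
A companion report tests each leading PC against known covariates (Pearson
for continuous, one-way ANOVA for categorical) so that a selected PC can be
inspected before being discarded as "hidden".

The TF-expression analysis deliberately uses the matrix *without* PC
removal: a TF acting in trans shifts methylation at many sites at once and
that signal is exactly what the leading PCs absorb.

## The cis scan

For every (probe, SNP) pair with |pos_SNP − pos_CpG| ≤ 3000 (inclusive;
equivalently a 6 kb window centered on the probe) and maf > 0.05 (strict),
ordinary least squares of normalized methylation on dosage, two-sided p
from t with n − 2 df.  Dosage is continuous (imputed values allowed); no
additional covariates, since confounding is handled upstream.  Pairs with a
constant predictor are skipped and logged; constancy is detected exactly
(range = 0), not via a variance epsilon, so an affinity covariate with
delta = 0 is skipped rather than tested against numerical noise.

Multiple testing uses Storey q-values computed once over all cis tests in
the scan.  π₀ is estimated on the λ grid 0.05…0.95 (step 0.05) by a cubic
polynomial fit to π₀(λ) evaluated at the largest λ, clipped to (0, 1];
with π₀ = 1 the q-values reduce exactly to Benjamini–Hochberg, which is the
branch the tests pin numerically.  A probe is an meQTL probe if its minimum
q ≤ 0.10; the lead SNP is the smallest p, ties broken by smaller distance
and then smaller position (the tie-break is a package convention; ties are
measure-zero in continuous data).

Candidate causal SNPs: within a widened scan (±5 kb), a probe qualifies
when p_best ≤ p_second × 10⁻² (inclusive "at least two orders" boundary).
Probes with a single tested SNP are excluded — there is no runner-up to
compare against.

## Enrichment of foreground SNP sets

Each foreground (eQTLs, histone-mark QTLs, GWAS hits, …) is tested by
regressing every probe within 3 kb of each foreground SNP, with q-values
computed over that foreground's tests only (its own FDR).  A SNP counts as
significant if any of its probes reaches q ≤ 0.10.  The null is matched
sampling: B draws of the same number of SNPs, without replacement, from the
universe of MAF-passing SNPs within 3 kb of at least one probe — matching
count and testability only, nothing else.  Empirical
P = (#{null ≥ observed} + 1)/(B + 1), never zero by construction.  One scan
over the universe is cached and the B draws regroup its p-values; a test
verifies this is bit-identical to rescanning the drawn subset.  Because the
proportion significant is discrete, the empirical P under a true null has
mean slightly above 0.5 (ties count toward the tail); this conservatism is
inherent to the estimator.  Direction counts use the sign of each
significant SNP's most significant slope times the foreground phenotype's
effect sign when supplied; with no signs supplied, raw methylation-slope
signs are reported.

Annotation enrichment is the Pearson chi-square (no continuity correction,
1 df) on the 2×2 table of meQTL probes vs all other probes, inside vs
outside a feature; any expected cell below 1 raises rather than silently
reporting an invalid asymptotic p.

## Bisulfite sequencing

Site-level methylation is n_meth/n_total, undefined below a read-count
minimum.  Array/sequencing concordance compares, per site, the mean raw
beta across all individuals with the mean of per-individual levels over
individuals with ≥ 5 reads, by Spearman correlation (the levels are bounded
and bimodal).  Co-located probes collapse to one site by averaging.

The stratified aggregation pools reads in sliding windows (51 bp, step
25 bp — the step is a package default; the curve is insensitive to it at
aggregate scale) across a span centered on each meQTL CpG.  Individuals are
assigned to genotype classes by rounded dosage, oriented per meQTL by the
sign of the array effect so "high" is always the homozygote with the higher
array methylation; allele-label flips therefore cannot change the curves.
Pooling order is fixed and tested against a brute-force oracle: sum reads
within (meQTL, class, window) first, divide, then average the pooled levels
across meQTLs without weighting.  Windows with no reads at a given meQTL
drop out of that meQTL's mean rather than contributing zeros.

## TF binding and expression

PWM scores are log₂ odds against a background (uniform by default) with a
pseudocount mixed into each column (default 10⁻³; pass 0 to score a matrix
exactly as written).  Allele scoring substitutes ref/alt at the SNP offset
and scores on the annotated motif strand, reverse-complementing window and
alleles for minus-strand sites; an involution test guarantees strand
symmetry.  The per-individual affinity covariate is additive in dosage,
score_ref + (g/2)·Δ, which makes the regression equivalent to the dosage
regression up to scale — the least-assumptive reading of scoring "each
genotype" — and is verified numerically.  Per-TF summaries use the same
per-foreground FDR convention as the enrichment module; a SNP is counted
once however many probes sit within 500 bp.

TF-expression association is a per-probe Pearson correlation between the
TF's (RPKM-standardized, quantile-normalized) expression and methylation
near that TF's binding-site intervals, with pointwise 2.5/97.5% null bands
from permutations of the expression vector holding methylation fixed.

## The synthetic generator

The generator is first-class code and defines the study conditions the
tests run under: 64 samples by default, cis effects of 1.5 sd on the latent
(logit) scale, regional spans of 1.5 kb on each side, bisulfite coverage
2.4× with conversion efficiency 0.99 (conversion failure adds
false-methylated calls only, matching the chemistry of incomplete
conversion of unmethylated cytosines).

Genotypes: SNP positions uniform; within each LD block two complementary
haplotype pools at a block frequency drawn from the MAF range, plus a 5%
per-allele flip so within-block dosage correlation is ≈ 0.81 — strong
enough to make causal-SNP identification nontrivial, imperfect enough that
the candidate-causal filter has something to find.  This deliberately
replaces coalescent simulation with a desk-scale mechanism.

Methylation: latent = bimodal baseline (two components at logit ±2)
+ dosage·effect + confounders + N(0, 1), mapped through the inverse logit.
A causal probe's shift is shared by all probes within the regional span
(boxcar by default, Gaussian decay optional — the true decay profile of
regional methylation correlation is only known visually, so the boxcar is
an explicit stand-in).  Planted regions are kept disjoint: overlapping
shifts of opposite sign would cancel and leave probes recorded as causal
with no recoverable signal.  The truth table records every shifted probe,
its driving SNP and signed effect, plus confounder loadings and the
shared-QTL SNP set consumed by the linked-phenotype and enrichment
fixtures.

What the generator does **not** emulate: array probe chemistry (type I/II
design, dye bias), realistic recombination maps or phased output, missing
beta values, cell-type heterogeneity, and sequence-dependent read bias.
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated generative model, not robustness to every
artifact of real arrays.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale — hundreds of probes and
SNPs over sub-megabase regions, B = 199–999 permutation draws (100,000 is
supported), 20-replicate null calibrations — chosen so the full suite
completes in well under a minute of compute per module while keeping every
statistical check well-powered.  Calibration checks (KS uniformity of null
p-values) use fixtures with independent SNPs and no planted effects,
because the KS test assumes exchangeable tests; LD and regional structure
make scan p-values clustered even when each is marginally uniform.

Degenerate inputs fail loudly: fewer than 4 samples, q-values requested
before they exist, p-values outside [0, 1], corrupt read counts
(n_meth > n_total), zero-variance expression, indel alleles, ambiguous
bases.  Empty results (no SNP passing MAF, no probe in a window) return
empty tables with a logged warning rather than raising, since they are
legitimate outcomes of strict filters on small regions.

## Known limitations

* The pooled-FDR convention (one q-value computation over all cis tests)
  controls FDR per test, not per probe; the probe-level false proportion
  can exceed the nominal level when many SNPs are tested per probe, which
  the parameter-recovery test bounds empirically rather than analytically.
* π₀ estimation by cubic polynomial is a smoother choice; other smoothers
  give slightly different π₀ on small inputs.  The BH branch (π₀ = 1) is
  exact and is the one used inside permutation loops.
* Candidate-causal precision depends on the LD structure; the ≈ 0.81
  within-block correlation of the generator is favorable compared to long
  human LD blocks, and precision on real data will be lower.
* The aggregation treats CpGs symmetrically (no strand flipping), which is
  correct for CpG methylation but would not be for non-CpG contexts.
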