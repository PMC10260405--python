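# Methods

This package re-implements, end to end, the analytic chain of a paired
plasma/urine metabolite GWAS (mGWAS) and exercises it on a synthetic
cohort with a machine-readable truth table. This note records the models,
the parameter choices that matter, the numerical decisions, and what the
synthetic data can and cannot show.

## Synthetic cohort

**Genotypes.** Diploid dosages are built from phased haplotypes under
Hardy-Weinberg equilibrium. Each LD block has a latent "core" haplotype
allele drawn at a frequency sampled from the block's range; each SNP
copies the core allele with a per-site flip probability ε solved
numerically from the block's target within-block r². With flip noise the
inter-SNP haplotype correlation is

    r = (1-2ε)² v / ((1-2ε)² v + ε(1-ε)),   v = p(1-p),

so ε is the root of r(ε) = √(r²_target) on (0, 1/2); ε = 0 reproduces a
perfect-copy block. Blocks are mutually independent. This gives
controllable, exchangeable within-block LD — it makes no attempt at
coalescent realism (no recombination maps, no allele-frequency spectrum,
no demography), which is out of scope. Positions are evenly spaced
(5 kb), per-SNP "imputation quality" tags are drawn uniformly from a
configurable range so quality filters are exercisable.

**Metabolites.** log2 abundance = intercept + Σ dosage·β (+ dosage·sex
interaction terms) + covariate effects + Gaussian noise. Noise variance
is set per metabolite and matrix so the planted SNPs explain the target
h² of the genetic-plus-residual variance. Covariate coefficients (age,
sex, PC1) are drawn per metabolite from zero-centered normals with fixed
scales (0.01/decade-free age units, 0.25 for sex, 0.1 for PC1): effects
differ in sign and size across metabolites as in real data, which keeps
stage-1 residualization non-trivial while preventing a sample's covariate
profile from masquerading as a global dilution shift. Raw abundances are
2^(log2 value); urine rows are multiplied by a per-sample log-normal
dilution factor (median 1, σ_log = 0.5) and missing-at-random dropout is
applied per cell. A configurable fraction of metabolites (default 50%,
85% in the PQN calibration study) stays fully observed, mirroring the
near-complete endogenous metabolites that anchor quotient normalization
in real cohorts. The truth table lists every planted
(SNP, metabolite, matrix, β, sex-β, h² target) and carries the realized
dilution factors.

What this generator does *not* emulate: batch/run-day effects,
left-censored (limit-of-detection) missingness, heavy-tailed abundance
distributions, correlated metabolite families, population structure or
relatedness. Passing tests therefore demonstrate correctness of the
statistical machinery under a well-specified model, not robustness to
every real-data pathology.

## Metabolite QC

Cleaning follows a fixed, logged order: duplicate samples → sample
missingness (>50%) → metabolite observed count (<300 samples) → PQN
(urine only) → log2 → low variance (<0.01) → outlier metabolites (>5% of
samples beyond 5 s.d.) → PC-outlier samples (>5 s.d. on any of the first
15 PCs of the complete-information metabolites). Each removal is
attributed to exactly one rule, and re-running on cleaned output removes
nothing further.

Duplicate detection correlates per-metabolite *standardized log2*
profiles (pairwise-complete Pearson r > 0.9). On raw profiles the
statistic is degenerate — with realistic inter-metabolite scale spread
every sample pair correlates near 1, and with artificially equal scales
the correlation is pure noise — whereas z-scored profiles give r ≈ 0 for
unrelated samples and r ≈ 1 for true duplicates.

PQN: the reference spectrum is the per-metabolite median over samples of
metabolites with <1% missingness; a sample's dilution factor is the
median of its observed value/reference quotients; all its values are
divided by that factor. Division precedes the log2 transform, and the
variance filter is applied post-PQN, post-log2 (the alternative —
pre-normalization — was open; filtering on the scale actually analyzed
is the consistent choice). Plasma is not quotient-normalized: dilution
is a urine phenomenon. Zero or negative abundances are rejected at load
(log2 undefined).

## mGWAS

Two-stage design: traits are residualized on age, sex and three genetic
PCs (plasma additionally on ln(eGFR) and serum albumin), then residuals
are regressed SNP-by-SNP on alt-allele dosage with an intercept.
Two-sided p-values use the t reference with n−2 df. The two-stage slope
equals the joint-fit SNP coefficient up to O(1/n) (asserted in tests).
Monomorphic SNPs yield flagged records, never silent drops. Genome-wide
significance is 5×10⁻⁸ divided by the number of traits in the matrix,
compared strictly.

The inverse-normal transform is Φ⁻¹((rank−0.5)/n) with average ranks on
ties; the offset convention was open and c = 0.5 is the documented
choice. Sex-interaction tests refit from the raw trait with sex excluded
from stage-1 residualization and included (with dosage×sex) in the
interaction model, so sex is adjusted exactly once; the bound is
0.05 / n_mQTLs, with per-sex stratified effects reported for significant
interactions.

## Locus calling

Iterative peak picking per trait: take the lowest-p unassigned
significant SNP, claim every significant SNP within ±500 kb on the same
chromosome, repeat; merge per-trait overlapping 1-Mb intervals
(intervals are 1-based inclusive, clipped at 1; overlap = shared base
pair) and re-select the merged locus's index SNP as the lowest-p member
of the union (re-selection vs. keeping the first-iteration index was
open; re-selection keeps the invariant "index = minimal p among
members"). Ties break by (p, position, SNP id). All significant SNPs in
the extended MHC (chr6: 25.5–34 Mb) form one region regardless of
spacing; its interval may then merge with overlapping neighbours.
Index SNPs with MAF < 3% must stay significant after an inverse-normal
re-test of the trait or the locus is dropped. Variance explained is the
squared dosage-trait Pearson correlation, covariate-free.

## Fine mapping

Independent signals come from forward stepwise selection on
individual-level data: at each step every candidate (excluding SNPs with
r² > 0.1 to the selected set) is added to a joint regression and the
smallest conditional p wins if it clears the genome-wide threshold.
Exact joint regression replaces the summary-plus-LD conditional
approximation: at this scale the individual-level fit is simpler and
strictly more accurate, and a summary-statistic mode remains an
extension point. Per-signal Wakefield ABFs,

    ABF = √(V/(V+W)) · exp(z²W / 2(V+W)),  V = SE², W = prior sd²,

use conditional effect/SE when a region holds several signals and
marginal otherwise, with prior s.d. 1.33 applied to effects on the
residual (log2) scale — whether the prior refers to raw or standardized
effects was open; residual-scale traits here have s.d. ≈ 1 so the two
coincide to good approximation. PPAs normalize ABFs over the region
(uniform prior); the credible set is the minimal PPA-descending prefix
with cumulative PPA strictly > 0.99, with a 1e-9 guard so floating
round-off at exactly the boundary does not count as exceeding it.
Regions whose index SNPs are in LD (r² > 0.8) are grouped by single
linkage and fine-mapped over the union of their intervals. The
credible-set-size-versus-MAF regression is reported, not asserted — its
sign in the source study is a property of the real data.

## Colocalization

For two traits over a shared region, per-SNP log-ABFs enter the
five-hypothesis enumeration (H0 none, H1/H2 one trait, H3 two distinct
causal variants, H4 one shared) with per-SNP priors p1 = p2 = 1e-4,
p12 = 1e-5, all sums in log space; a positive call is PP(H4) > 0.8. The
per-trait effect prior inside coloc was open (the upstream wrapper's
defaults are undocumented): we use 0.15 × sdY on standardized effects,
with sdY estimated from the summary statistics themselves via
median(se²·n·2p(1−p)) — the same device the canonical implementation
uses — which makes posteriors invariant to a uniform rescaling of a
trait's effects and SEs. This prior is deliberately narrower than the
fine-mapping 1.33, which the source analysis specifies only for fine
mapping. SNPs match on (chrom, pos, unordered alleles) with effect signs
flipped when the effect alleles are swapped; palindromic SNPs are kept
(the synthetic data is strand-safe) with a documented flag point for
real data. mQTL pairs are tested when ±500 kb index windows overlap,
over the union of windows; positives classify into intraplasma,
intraurine, intermatrix-same- and intermatrix-different-metabolite.
External-trait coloc runs only when the external table has a variant
with MAF > 0.01 and p < 0.05/n_index within ±100 kb of the index SNP;
the phenotype trigger and the eQTL/pQTL trigger share this one code
path with configurable n_index and windows.

## Gene prioritization

Candidate genes carry evidence codes {h, r, e, p, m, c, E, P}; the score
counts h, r, m, c plus one for e-or-E and one for p-or-P. Ties resolve
in order: has E → has P → inborn-error match → Ee over E → Pp over P →
smallest distance → lexicographic id (deterministic, logged). "Closest"
uses gene-body distance (0 inside the body), configurable to TSS.
Evidence codes arrive as an input annotation table; E/P can be
auto-populated from this package's own coloc output, and manual
reassignment is an explicit override, never silent.

## Enrichment

The matched permutation test redraws, within every (independent-SNP-count
decile × gene-length decile) stratum, as many universe genes as the
source list holds there, without replacement, using genuine random
k-subsets (top-k of random keys) rather than a distributional shortcut —
so the closed-form hypergeometric comparison in tests is an independent
route. Empirical p = (1 + #{overlap ≥ observed}) / (1 + draws); the +1
smoothing (an open convention) keeps p > 0 at finite draws. Default
draws are 10⁵ at desk scale with the reference 10⁸ reachable by
configuration. Fisher's exact test is the hypergeometric upper tail on a
fixed universe; BH adjustment via the standard step-up.

## EHH

EHH(x) for a core allele is the fraction of carrier-haplotype pairs
identical at every marker from the core through x, computed by partition
refinement (split carrier groups at each successive marker; EHH =
Σ C(|g|,2)/C(n,2)), with a brute-force pair-enumeration oracle retained
in the tests. Haplotypes with a missing call are dropped from that side
onward while the denominator stays C(n,2), which preserves exact
monotone non-increase. Distances are base pairs (no genetic map);
derived/ancestral orientation is caller-supplied; the integrated-EHH
contrast is a trapezoid area ratio.

## Heritability

The GRM is the standard estimator
A_jk = (1/M) Σ_i (x_ij−2p_i)(x_ik−2p_i)/(2p_i(1−p_i)) over SNPs with
imputation quality > 0.6, monomorphic SNPs excluded, with p_i the sample
alt frequency — note this centering forces a mean off-diagonal of
−1/(n−1), which the tests assert around rather than zero. h² is
estimated by restricted maximum likelihood of y = Xβ + g + e,
g ~ N(0, σ²_g A). Because there is one genetic component, A is
eigendecomposed once and the restricted likelihood is profiled to a 1-D
criterion in h² ∈ [0,1], minimized by bounded scalar search (xatol
1e-6): this reaches the REML optimum without the divergence modes of
iterative AI-REML and makes per-metabolite fits O(n) after the O(n³)
setup. Boundary estimates are flagged; the SE comes from the
finite-difference curvature of the profiled −2 log-RL. Covariates reuse
the per-matrix GWAS sets (the source's GREML covariates are unstated).

## Problem sizes and calibration results

All simulation studies are seeded and sized for a desk-scale single-CPU
run, chosen once as this package's study conditions: credible-set
coverage over 500 single-causal simulations (n = 2,000, one 50-SNP
r² ≈ 0.9 block, β = 0.35); coloc discrimination over 200 shared-causal
pairs (n = 2,000, 40 SNPs, β = 0.6, conditioning on both z-peaks ≥ 8)
plus 50 distinct-causal pairs; GWAS type-I error over 10,000 independent
null SNPs at n = 1,000; REML recovery of h² = 0.5 over 20 seeds
(n = 1,000, 200 causal of 1,000 SNPs); PQN recovery at n = 500 with 600
metabolites (≈510 complete). Every number these studies produce is
computed at run time by `analysis/09_calibration_studies.py`, the
acceptance tests, and `scripts/acceptance.py`; none is stored.

## Known limitations

The LD model cannot produce long-range decay patterns or realistic
haplotype diversity, so EHH curves on the neutral synthetic cohort decay
fast and the sweep contrast uses a constructed fixture. The two-stage
GWAS ignores covariate-dosage correlation beyond O(1/n). Conditional
selection assumes individual-level data are available. The coloc engine
is single-causal-variant per trait per hypothesis (no SuSiE-style
multi-signal coloc), and conditioning on external index SNPs is not
implemented. X-chromosome analysis, relatedness correction and genomic
control are out of scope.
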