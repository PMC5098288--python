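# Methods

This note documents the models, numerical choices and known limitations of
`selftraingp`, in the order data flows through the pipeline.

## Genotype quality control

Genotypes are allele counts in {0, 1, 2} with missing entries (NaN in
memory, `NA` in the TSV dialect). QC runs in a fixed order:

1. **minor-allele orientation** — a marker whose counted-allele frequency
   (over non-missing entries) exceeds 0.5 is recoded g → 2 − g; a
   frequency of exactly 0.5 is left alone. Heterozygote counts are
   invariant under this flip.
2. **MAF filter** — markers with minor-allele frequency strictly below
   the threshold (default 5%) are removed, as are markers whose entries
   are all missing. Frequencies are computed on *non-missing* entries
   before any imputation, so imputed values can never feed back into the
   filter. A consequence worth knowing: frequencies recomputed *after*
   imputation can fall slightly below the threshold, because imputed
   homozygotes dilute the minor allele.
3. **imputation** — each missing entry at marker j becomes
   `round(2·p_j)` with p_j the minor-allele frequency; ties (2p exactly
   0.5 or 1.5) round *up*, a choice that had to be made because rounding
   alone does not fix tie behaviour. Frequencies default to the dataset
   itself; an external frequency table (e.g. from a national reference
   population) can be supplied instead.

VCF input accepts bi-allelic SNP records only and codes the ALT-allele
count; multi-allelic or non-SNP records are skipped with a logged count.
Marker identity is the ID string alone — no coordinates are interpreted,
because the prediction method uses none.

## The RFI mixed model

Weekly DMI is modelled with fixed YSC (year-season of calving) and ParAge
(parity-by-age) classes, fixed slopes on days-in-milk, milk energy and
metabolic body weight, one random ration-cohort effect and an i.i.d.
residual. Fixed effects use **sum-to-zero contrasts with an explicit
intercept**; any full-rank parameterization yields identical residuals
(tested against dummy coding), and residuals are all that downstream code
consumes.

REML is implemented by **profiling the restricted likelihood over the
single variance ratio γ = σ²ᵣ/σ²ₑ**. Because every record belongs to
exactly one cohort, V = I + γZZ′ is block compound-symmetric and the GLS
pieces reduce to per-cohort sums:

* X′V⁻¹X = X′X − Σₖ δₖ SₖSₖ′ with δₖ = γ/(1 + γmₖ), Sₖ the per-cohort
  column sums of X and mₖ the cohort size;
* log|V| = Σₖ log(1 + γmₖ); σ̂²ₑ = y′Py/(n − p);
* cohort BLUPs ûₖ = γ·sₖ/(1 + γmₖ) with sₖ the cohort sum of fixed-effect
  residuals.

The 1-D profile is maximized by bounded scalar search on γ ∈ [0, 10³]
with absolute tolerance 1e-8; a solution hugging the upper bound is
flagged as non-converged. The implementation agrees with an independent
library REML fit (statsmodels `MixedLM`) to ~1e-3 relative in γ and 1e-5
in restricted log-likelihood on test data, and collapses exactly to OLS
when γ is pinned at 0. `fix_gamma=0` also bypasses the ≥2-cohorts
requirement.

Degenerate designs (confounded levels, constant covariates) are rejected
with a rank check on the QR diagonal naming the offending columns.
Records with factor levels unseen at fit time raise rather than receiving
a silent zero effect. The per-animal phenotype is the plain (unweighted)
mean of that animal's weekly residuals; weighting by week count was
considered and rejected as an undocumented extrapolation. Animals with
different week counts are handled naturally by the per-record model; no
minimum-week filter is applied.

## Base predictor and self-training

The base predictor is ε-insensitive SVR with RBF kernel (scikit-learn
`SVR`, the same libsvm core as R's `e1071::svm` used in the original
analyses). Defaults C = 1, γ = 1/n_markers, ε = 0.1 mirror that
package's documented defaults; tuning is **off by default** (a
reproducible baseline) with an opt-in grid search C ∈ {0.25, 1, 4} ×
γ-scale ∈ {0.25, 1, 4}/n_markers by seeded k-fold cross-validation inside
the labelled training set only, ties breaking toward the first grid point.

Marker columns are standardized by training-set mean and standard
deviation, reapplied at prediction; zero-variance (monomorphic) columns
become all-zero features rather than being dropped, so marker sets stay
aligned across the labelled, unlabelled and test matrices.

Self-training performs exactly one relabel–retrain round: pseudo-labelled
animals enter Step 3 with equal weight, no confidence filtering, and the
identical predictor spec (including tuning mode) is re-applied; the
standardization statistics of f\* are recomputed on the combined set.
With an empty unlabelled set the round reduces to supervised learning and
f\* predicts identically to f. The predictor contract is open — any
object with the fit/predict surface can replace SVR — but only SVR ships.

## Validation designs

Accuracy is the Pearson correlation between predicted and measured
phenotypes on one **fixed test set** (plus MSE). A constant prediction
vector makes the correlation undefined; it is reported as NaN with the
MSE still returned. Replicate summaries carry means and 95% confidence
intervals using Student's t with n−1 degrees of freedom (a normal option
exists); the machinery's empirical coverage is itself under test.

Sampling is without replacement; each replicate of each setting draws
from an independent stream keyed by (CRC32 of the setting label,
replicate index) under the master seed, so any cell is reproducible in
isolation. Samples are sorted after drawing: order is statistically
irrelevant, and a canonical order makes replicates that draw the whole
pool bit-identical (libsvm fits depend on row order at float precision).

In the ratio sweep, f and f\* share the labelled sample and test set
within a replicate, so differences are paired. In the plateau search the
unlabelled set grows by **nested increments** (each step adds animals to
the previous set), which lowers the variance of the stopping rule; the
search stops at the first step whose correlation gain over the previous
step falls below the tolerance (default 1e-4, i.e. 0.01% on the
correlation-as-percentage scale, applied per replicate), or at pool
exhaustion, which is flagged. A tolerance of 0 disables the early stop —
otherwise any strictly negative step would halt the scan — and +∞ stops
after the first increment. The recorded "maximum improvement" is the best
visited correlation minus the supervised baseline; the "optimal ratio" is
the stopping n_unlabelled divided by n_labelled. No step beyond the
stopping step is ever evaluated.

## The simulator

The simulator emulates the *structure* of a feed-efficiency study:
independent bi-allelic loci with frequencies Uniform(maf_range), allele
counts Binomial(2, p), optional uniform missingness, and an additive
trait. Variance bookkeeping is on the per-animal scale: breeding value +
cohort effect + mean weekly residual has unit variance, with fractions
`heritability` (default 0.15, typical for RFI), cohort fraction (default
0.10) and the remainder residual. Weekly residuals are i.i.d. with
variance n_weeks × residual fraction so their per-animal mean carries
exactly the residual fraction. Heritability may be set to 1 as a
degenerate noise-free limit used by exactness tests. Defaults of 19 YSC
and 20 ParAge levels mirror a realistic design-matrix shape; one
lactation of 20 weekly records per animal covers the usual 50–200
days-postpartum window. Birth dates place a configurable fraction of
animals after January 1 of the last birth year, the natural
train/test split.

What the simulator does **not** emulate — and hence what passing tests do
not establish about real cattle data: linkage disequilibrium (an optional
block-LD mode copies adjacent loci with probability ρ, but defaults and
all tests use independence), family/pedigree relatedness, selection,
non-additive genetic effects, genotyping error, and any specific genetic
architecture of RFI (the number and effect-size distribution of causal
loci are unknown; the defaults — 100 QTL with Gaussian effects — are
placeholders). Because simulated animals are exchangeable draws,
self-training here is roughly **neutral**: paired gains centre near zero,
varying by population draw in either direction, while on real data with
herd structure and relatedness the same algorithm has been observed to
help when the labelled set is small and the unlabelled animals share the
target population's environment. The test suite therefore asserts
*non-inferiority* of f\* (mean paired loss no worse than 0.005
correlation) rather than a gain, blocking its 50 replicates over 5
independent populations so the conclusion does not rest on a single
synthetic draw, and reports the measured gain.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen to keep the
whole suite fast while leaving every estimate's Monte-Carlo error well
inside its asserted tolerance: populations of 150–800 animals (2000 for
variance-recovery checks) with 60–2000 markers, 5–50 replicates per
setting, and REML recovery at 80 cohorts × 10 records over 20 seeds. The
full-scale defaults of `ExperimentConfig` (learning curve 20…540 step 20,
sweep 300/400/500 × 200…800, 100 replicates, plateau increment 200)
reproduce the published design dimensions and are practical on a
workstation.
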