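# Methods

This note documents the statistical models, simulator, numerical choices
and limitations of `pheoscan`. Everything stated here is computed by the
package's tests or by `scripts/acceptance.py`; nothing is asserted about
data the package has not seen.

## The phenotype and its scale

Coat pheomelanin intensity is scored on an ordinal 1–6 scale whose levels
are color swatches. The scale is built by placing anchor colors (cream
`#FFFEF9`, tan `#D3A467`, red `#93471A` by default) at equally spaced
positions in [0, 1], interpolating each RGB channel piecewise-linearly,
sampling at n equally spaced positions, and rounding each channel half
away from zero (this rounding convention is load-bearing: channel values
like 190.6 must round up to reproduce the canonical swatch set
byte-for-byte). Observed colors are mapped to the scale by nearest
Euclidean distance in raw RGB, ties to the lower ordinal. No perceptual
color space is used — the scale is a rating aid, not a colorimetric
instrument. Analyses that need a dimensionless phenotype use the z-score
(population SD); d statistics are conventionally reported on that scale.

## Quality control

Filters run in a fixed order: markers with missingness strictly > 5%, then
samples with missingness strictly > 3% across the remaining markers, then
optional relatedness pruning, then MAF (markers with minor-allele
frequency < 0.001 or missingness > 5% removed; MAF exactly at the
threshold is retained). Relatedness is the classical method-of-moments IBD
estimator: observed identity-by-state class counts over polymorphic
markers are compared with their expectations under IBD ∈ {0,1,2} given
allele frequencies, solved sequentially with each probability clipped into
[0,1] (the same constraint scheme PLINK's `--genome` applies), normalized
to the simplex; π̂ = P(IBD=2) + P(IBD=1)/2. No small-sample bias
corrections are applied, so in-sample allele frequencies from very small
panels (≲20 samples) bias π̂ upward by O(1/n) — the pruning threshold of
0.45 is far above this. Pruning is iterative: for each flagged pair the
member with higher missingness is removed (ties: lexicographically larger
sample id), so a clique of k duplicates retains exactly one member.
Missing phenotypes in breeds with phenotyped members can be filled with
the breed's modal six-point value (modal ties resolve to the higher,
i.e. redder, value).

## Mixed-model association scan

Per marker: y = X_c α + x β + u + ε, u ~ N(0, σ²_g K), ε ~ N(0, σ²_e I),
with K = W Wᵀ / p the centered genomic relationship matrix (missing
dosages mean-imputed per marker before centering). With λ = σ²_g/σ²_e the
covariance is σ²_e (λK + I); one eigendecomposition K = U D Uᵀ rotates the
model to diagonal covariance, after which any λ gives a weighted least
squares with weights 1/(λd_i + 1). λ is maximized per marker over the REML
log-likelihood by bounded scalar search on log₁₀λ ∈ [−5, 5] (relative
tolerance 1e-4; if the lower boundary is as good as the interior optimum,
λ collapses to the boundary, i.e. effectively OLS). The marker effect is
tested by Wald t with n − q degrees of freedom (q = intercept + covariates
+ marker). A fast mode estimates λ once under the covariate-only null and
reuses it (labelled approximate); λ can also be pinned (λ = 0 reproduces
per-marker OLS exactly, which the tests verify against statsmodels).

Missing genotypes are mean-imputed in the scan rather than handled by
per-marker complete cases: per-marker case sets would invalidate the
single shared eigendecomposition, and mean imputation is what the
reference mixed-model GWAS tools do. Candidate-locus models (dominance,
epistasis, model search) instead drop samples missing any required locus.

PVE is reported as β̂²·Var(x)/Var(y) on the analysis sample. This is a
convention — PVE has no single standard definition — and is documented as
such rather than claimed to match any particular tool bit-for-bit.

Case-control mode contrasts cream (1–2, coded 0) against red (5–6,
coded 1) and drops mid-range dogs. Genome-wide significance is Bonferroni
α/n_tests with the test count passed explicitly by the caller.

Calibration is verified empirically: under a two-subpopulation polygenic
null (phenotype = breed-structured polygenic term + iid noise, kinship
estimated from background plus tested markers), the REML scan's type-I
error at nominal 0.05 stays within the binomial band over ~1,000 tests
while naive OLS rejects at ~40%. With very few subpopulations and a large
*fixed* breed shift (rather than a kinship-consistent random one) the LMM
retains mild residual inflation (~0.07–0.08 at nominal 0.05 in the same
design) — a known limitation of kinship correction when structure has only
one or two dimensions, not an implementation defect.

## Dominance and epistasis

Dominance at a biallelic locus: d = ȳ_het − (ȳ_hom0 + ȳ_hom2)/2 on the
standardized phenotype (raw scale available; d is scale-equivariant).
Significance: the additive midpoint falls outside the Student-t 95% CI of
the heterozygote mean (sample SD, n_het − 1 df). The CI construction is a
documented choice; with a single heterozygote d is returned but
significance is undefined. All three genotype classes must be non-empty.

Epistasis per locus pair: OLS of Y = β₀ + β₁g_A + β₂g_B + β₃g_Ag_B on
additive dosages, complete cases, both loci polymorphic and not perfectly
collinear. The reported statistic is the squared Wald t of β₃ referred to
χ²(1) — this stat→p mapping reproduces the conventional interaction-test
output of the standard tooling. Pairs with p < 0.05 are flagged with no
multiplicity correction (by design, matching the analysis this package
implements; a Bonferroni flag exists for other uses). β₀ is a plain
intercept: the interaction regression carries no kinship random effect.

## Encodings and model search

Four encodings per locus: additive (g), red-dominant ([g ≥ 1]),
red-recessive ([g = 2]), and the het/hom split ([g = 1], [g = 2]) whose
coefficient ratio β₁/β₂ diagnoses the dominance mode — nearest of 0.5
(additive), 0 (recessive), 1 (dominant). For the search stage's binary
toggle, each locus offers additive versus its *dominance* alternative
(nearest of 0 / 1 only), so the space always has 2^L encoding
combinations even when the split fit itself looks additive; the additive
mode can still win by ranking.

Models are fit by OLS on complete cases; adjusted
R² = 1 − (1−R²)(n−1)/(n−k−1); the Gaussian log-likelihood uses the MLE
variance SSE/n. PRE for term j is (SSE without j − SSE full)/SST, each
reduced design refit from scratch; PRE is non-negative for nested OLS by
construction. Enumeration is the Cartesian product of encoding toggles
and interaction inclusions (2^(L+I), the all-baseline model optionally
excluded, giving the familiar 31 and 4,095 counts at L=5, I=0 and I=7);
candidate models that are rank-deficient on a given sample (e.g. an
interaction column duplicating a rare main effect at small n) are dropped
from the ranking rather than crashing the search. Ranking is by adjusted
R² descending, ties to fewer terms then lexicographic spec — fully
deterministic. Pruning removes all terms with PRE ≤ 10⁻³ simultaneously
(a single reduction step, not stepwise) and refits. The likelihood-ratio
test compares strictly nested fits on the same cases: 2ΔlnL against χ²
with df = term-count difference; its null distribution is verified
uniform by KS over 1,000 replicates.

Interactions multiply the two loci's single-column encoded values, so a
het/hom-split locus cannot enter an interaction (rejected at spec
construction).

## Prediction and validation

Cohorts are split per breed × phenotype stratum, discovery share
round(0.7·m) half-up (singleton strata go to discovery), seeded.
Predictions are the linear predictor with coefficients frozen from
discovery, unclipped by default (optional clip to [1, 6]); samples missing
a required locus are excluded from metrics and counted. Validation R² is
1 − SSE/SST with the frozen coefficients (it can be negative), adjusted
with the training model's term count — the adjustment convention is a
documented choice, and plain R² is always reported alongside. The
within-one-point fraction compares the continuous prediction to the
integer observation with inclusive tolerance |pred − obs| ≤ 1, overall and
per breed group.

## The simulator

The generator emulates the structure of a multi-breed SNP-array panel:

- **Breed structure.** Per-breed allele frequencies follow a
  Balding–Nichols model: Beta(p(1−F)/F, (1−p)(1−F)/F) around ancestral
  frequency p with divergence F_ST; F_ST = 0 returns p exactly. The
  default F_ST = 0.25 sits in the range commonly reported among dog
  breeds (~0.2–0.33). Defaults: 63 breeds, 49 dogs each.
- **Genotypes.** Binomial(2, freq) within breed — Hardy–Weinberg within
  breed, no linkage disequilibrium along chromosomes, no within-breed
  pedigree structure beyond the breed blocks. This is sufficient to
  exercise kinship correction but deliberately omits LD fine-structure,
  so nothing here validates LD-dependent procedures (fine-mapping,
  clumping).
- **Causal loci.** Five markers at ancestral red-allele frequencies
  (0.42, 0.66, 0.05, 0.65, 0.38); the default generative model uses the
  best-supported dominance modes (two strong additive loci, one
  recessive, two dominant) with raw-scale coefficients of roughly
  0.9/0.29/0.41/1.04/0.36 and intercept 1.07.
- **Phenotypes.** latent = intercept + Σ encoded terms + N(0, σ);
  recorded = round half-away-from-zero, clipped to [1, 6] (the continuous
  latent → six-point mapping is a simulator convention; human raters, not
  an equation, produced the real scale). With probability 0.03 (matching
  ~97% repeat-phenotyping concordance) the recorded value shifts by ±1
  and is re-clipped, so a recorded value is always within one point of
  its pre-error value.
- **Noise calibration.** `calibrate_residual_sd` returns σ either from
  the latent-scale identity σ² = Var(genetic)(1−r²)/r² (Var(genetic) by
  large-sample simulation), or — mode `"recorded"` — by bisection so that
  refitting the true model on *recorded* phenotypes attains the target
  R², absorbing the extra variance from discretization, clipping and
  rater error. Presets use the recorded mode with target 0.73, since the
  R² being emulated was itself measured on the recorded 1–6 scale.
- **Seeding.** One integer seed feeds a spawned `SeedSequence` tree;
  every output is bit-reproducible from the config.

The real phenotype distribution is only approximated (the simulated
distribution is unimodal-ish mid-scale; the study population was
deliberately enriched at both extremes), and simulated breeds are
exchangeable — no breed is fixed for a color the way e.g. Samoyeds are.
Passing tests therefore demonstrate the statistical machinery under
realistic effect sizes and structure, not distributional fidelity to any
particular panel.

## Problem sizes used by tests and the acceptance script

Unit tests run at n of tens to thousands; the acceptance script simulates
63 breeds × 34 dogs (2,142) with ~4,000 background markers for the
full-pipeline numbers and 25 closed-loop replicates for encoding
recovery; the test suite's recovery check uses 50 replicates at the same
shape. The scan's per-marker REML over 4,000 markers at this n takes
under a minute on one CPU.

## Known limitations

- Encoding identifiability at rare loci: with a red-allele frequency of
  0.05, the red-homozygote class (~15–30 dogs of ~2,100 expected under
  the default breed structure) carries all the information separating the
  dominant from the additive encoding. The adjusted-R² ranking (equivalent
  to SSE ranking at equal df, i.e. the ML choice) then mis-selects that
  locus's encoding in roughly 15–20% of replicates; closed-loop encoding
  recovery at study scale plateaus near 80–90%, and the coefficient
  estimates remain unbiased well within sampling noise. This is a property
  of the design, not of the selector.
- Coefficient recovery is judged against the across-replicate SD of the
  estimator (the Monte-Carlo estimate of one experiment's standard
  error). Discretization and clipping necessarily introduce a small bias
  (≲0.03 on these effect sizes), well inside that band but detectable
  against the much smaller SD-of-the-mean at 50 replicates.
- The epistasis regression and dominance estimates are marginal: under
  strong breed structure their effective sample size is closer to the
  number of breeds than the number of dogs, and single-dataset d
  estimates at weak loci can even change sign.
- X-chromosome dosages are treated as autosomal throughout (no dosage
  compensation model); no exact/score association tests; no multi-trait
  models; no haplotype or LD simulation.
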