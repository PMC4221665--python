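# Methods

## Trait model and normalization

Each morphological parameter is assigned one of four probability families
with a canonical link:

| family        | support            | link     | fitted by                              |
|---------------|--------------------|----------|----------------------------------------|
| `gamma`       | (0, ∞)             | log      | GLM, Pearson-χ² dispersion             |
| `beta`        | (0, 1)             | logit    | mean–precision beta regression, common precision |
| `binomial_od` | counts of n trials | logit    | quasi-binomial GLM (Pearson dispersion on proportions with trial-count variance weights) |
| `gaussian_cv` | ℝ (residual scale) | identity | ordinary least squares                 |

The default catalog holds 501 parameters partitioned 220 CV / 183 gamma /
37 beta / 61 binomial. Every CV trait is paired one-to-one with a gamma or
beta mean trait (183 + 37 = 220), the only pairing consistent with the
partition. Identifiers are synthetic but stable (`C101_A`, `CCV101_A`, …);
real CalMorph exports can be analyzed by supplying a catalog TSV with the
published identifier-to-family mapping.

**CV uncoupling.** Coefficient-of-variation traits depend strongly on their
paired mean. Before Gaussian modeling, each CV column is replaced by its
residual from a robust locally weighted regression (Lowess) of CV on the
partner mean, smoothing span 0.4 and three robustness iterations (the
convention of R's `lowess()`), fit across all cultures jointly by default
(`reference_only` restricts the fit to wild-type cultures; residuals are
evaluated everywhere by interpolation of the fitted curve).

**Wald Z-scores.** For each strain × parameter, a two-group model
η(E[y]) = β₀ + β₁x is fit against the wild-type reference cultures; the
Wald statistic β̂₁/SE(β̂₁) is the strain's normalized trait value. A strain
measured as a single culture is identifiable because the group-saturated fit
leaves its residual at zero: the dispersion estimate is then carried by the
reference replicates. Parameters whose fit fails for any strain (missing
values, zero variance, non-convergence) are dropped from the matrix with a
logged count. Convergence follows the statsmodels defaults (IRLS, deviance
tolerance 1e-8, 100 iterations). Z-scores for the wild-type replicates
themselves — needed as null-distributed data — are computed leave-one-out:
each replicate is fit as a pseudo-strain of one culture against the rest.

## Mahalanobis selection

Distances use the wild-type replicate center and covariance. With far more
parameters than replicates the sample covariance is singular, so the default
estimator is the diagonal of the sample covariance (per-parameter variances,
floored at 1e-6); linear shrinkage toward the diagonal and the full sample
covariance are available when the replicate panel permits. The documented
scale-invariance of the distance holds exactly only in full-covariance mode;
the property test uses that mode.

"Edge of PC space" is operationalized as the maximum absolute
per-component-standardized score over PC1..PC20, computed among strains not
already selected by distance; the quota defaults are 100 top-distance + 20
edge strains. All ties break by ascending strain identifier.

## Variance, PCA and ellipses

Per-trait variances expose their centering convention explicitly: own mean
(SS/(n−1)), pooled per-subgroup means (SS/Σ(n_g−1); two parental triplicates
give df 4), or an external reference center (SS/n, unbiased for a known
center). The deletion/natural variance-ratio profile uses own-mean centering
per panel (df 109 for a 110-strain panel, df 36 for 37 strains).

PCA decomposes the covariance (not correlation) of the column-centered Z
matrix — Z-scores are already variance-standardized by construction. Signs
are fixed so each component's largest-magnitude loading is positive.

Equiprobability ellipses: a bivariate normal (or equal-weight two-component
mixture, for the two-parental-strain display) is fit by moments; its density
is evaluated on a 200 × 200 grid spanning the data range ± 3 marginal
standard deviations; the contour level is located by sorting grid cells by
density until the enclosed mass reaches the target (default 0.95). The
broadness ratio of two populations is the ratio of their ellipse areas at a
common mass level, computed in closed form as √(det Σ_A / det Σ_B) (the
grid area is exposed for the mixture case and for verification). The
"x-fold broader" statistic is therefore an *area* ratio; per-axis standard
deviation ratios can be read off the covariances where a length ratio is
wanted.

## Detection of heteroclite strains

Per component, the natural strains' spread is σ̂ = √(Σᵢ(sᵢ − c)²/n) with c
the wild-type reference's score — divisor n because the center is external,
making SS/n unbiased. Each deletion strain gets a one-sample two-sided test
of normal distribution, p = 2(1 − Φ(|score − c|/σ̂)), Bonferroni-corrected
over m = n_strains × n_components (440 for 110 strains × PC1–PC4). The
component list defaults to PC1–PC4 and can instead be chosen as the smallest
prefix whose cumulative explained-variance ratio reaches a target (default
0.60). In the orchestrated pipeline the PCA is fit on all non-reference
strains jointly and the reference center is the projection of the zero
Z-vector (the reference's own Z-score is identically zero).

**Known anti-conservatism.** The test plugs σ̂ estimated from ~37 strains
into an extreme normal quantile (|z| > 3.86 at m = 440). The relative error
of σ̂ is ≈ (2n)^(−1/2) ≈ 12%, which at that tail multiplies the nominal
error mass several-fold: the measured family-wise error under the global
null is ≈ 0.16 at nominal 0.05 (1000-replicate simulation, reported by
`scripts/acceptance.py`). The package implements the normal-reference
convention deliberately and reports the measured rate rather than
substituting a finite-sample correction; users needing strict FWER control
should enlarge the natural panel or lower α.

## PC interpretation

A parameter characterizes a component when its Z column correlates with the
score column at |r| > 0.6 and correlation-test p < 1.95×10⁻³ (both
configurable; the p-threshold is taken as given rather than re-derived from
a Bonferroni denominator). Passing parameters are grouped by a second PCA
on the wild-type replicate Z matrix: parameters passing the same rule on a
common null component co-vary without any strain effect and merge
(transitively) into one group, represented by the member with the strongest
primary loading. With few parameters and an isotropic null, PCA eigenvectors
are rotation-degenerate and the grouping is conservative about claiming
independence; grouping is most meaningful when null replicates comfortably
outnumber the passing parameters.

## GO MANOVA and auxiliary statistics

GO terms annotated to ≥ 3 detected genes, among terms annotated to < 100
genes genome-wide, are tested by comparing nested multivariate linear
models: scores ~ background factor s (natural vs BY background) under the
null, plus the GO-membership dummy x under the alternative. The strains
entering each test are the natural strains, the wild-type reference (x = 0,
BY background) and the deletion strains annotated to the GO (x = 1); a flag
includes unannotated deletion strains as x = 0. The test statistic is the
Pillai trace (Wilks' lambda optional) with the standard F approximation —
exact for this one-degree-of-freedom hypothesis — and significance is
Bonferroni-corrected over the tested GOs. The implementation is a direct
least-squares construction of the H and E matrices; statsmodels' MANOVA
serves as an independent cross-check in the test suite, not as the
implementation.

GO similarity is 1 − Jaccard of the annotated gene sets (Dice optional),
clustered with complete linkage. The Mann–Whitney U-test uses the normal
approximation with continuity and tie corrections, switching to exact
enumeration when both samples have n ≤ 8 without ties.

## Synthetic data generator

The generator emulates the study design: 40 wild-type replicate cultures,
36 natural strains × 5 cultures, 110 deletion strains × 1 culture, ≥ 200
cells counted per culture (trials = 200 + Poisson(20)). Per parameter,
culture values are drawn from the catalog family: gamma with shape 50 and a
strain-shifted log mean; beta with precision 100 and a strain-shifted logit
mean; beta-binomial counts with intra-culture correlation ρ = 0.05
(configurable; ρ = 0 recovers pure binomial); CV traits follow a decreasing
trend c/√(m + 0.05) in the realized partner mean (Taylor-law-like) plus
strain shift and Gaussian noise of sd 0.02, giving the Lowess stage real
coupling to remove.

Strain effects on the link scale are drawn once per strain (replicates are
exchangeable within strain): effect = scale · (√ρ_b · u_block + √(1−ρ_b) · ε)
with a shared latent factor per parameter block (size / actin / nucleus /
noise, assigned round-robin; a CV trait inherits its partner's block) and
within-block correlation ρ_b = 0.5. The effect scale is 0.15 for natural
strains and 0.35 for deletion strains — the deletion panel is broader by
construction, at a contrast large enough that the variance-ratio profile
exceeds 1 for > 90% of parameters, as the analysis expects of the real
panels. Planted heteroclite strains add magnitude × deletion-scale per
parameter of the targeted blocks; the ground-truth record stores every
strain's true effect vector, the block map and the planted labels.

What the generator does *not* emulate: imaging noise and segmentation
artifacts, genotype (SNP/linkage) structure of natural isolates, growth-rate
confounding, and the exact published identifier set. Passing tests therefore
validate the statistical machinery under the assumed generative families,
not the biological fidelity of any particular dataset.

## Problem sizes and seeds

The test suite runs the GLM stages on reduced catalogs (tens of parameters)
and reduced strain panels — the per-fit statsmodels cost makes the full
501 × 146 matrix a batch-scale computation — while structure-only checks
(catalog, selection quotas on 4000+ strain Z panels, detection arithmetic)
run at full published scale. Monte-Carlo checks use 200–1000 replicates
with fixed seeds; every simulation API takes an explicit seed and is
deterministic given it.
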