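# Methods

This note documents the statistical machinery implemented in
`funcniche`, the assumptions behind it, the defaults and why they were
chosen, and what the synthetic-data tests do and do not demonstrate.

## Trait construction and standardization

Nine unitless functional traits are computed from ten linear
morphometrics and body mass (see README for the formulas). Two choices
were genuinely open:

* **Log base for Mass.** `Mass = log(M + 1)` with base 10, the common
  morphometric convention; the base is a parameter of
  `compute_traits`, and because PCA operates on z-scores the base has
  no downstream effect (log-base changes are linear rescalings).
* **Head size.** Rendered as the cube root of `HW·HL·HH` — a length
  with the geometric-mean interpretation — rather than the raw
  product; configurable in spirit (the raw product is a monotone
  transform and again z-scores away for any analysis that only uses
  standardized traits, though it would change the raw trait table).

Standardization uses the sample SD (ddof = 1). This choice only scales
every z-score by a constant √(n/(n−1)) factor relative to the
population SD and affects no downstream conclusion; it matches the
default of most statistical software. Centering/scaling constants are
stored so the transform inverts exactly (round-trip verified to 1e-10).

## Functional space

PCA is the eigendecomposition of the trait correlation matrix (z-scored
traits), so eigenvalues sum to the number of traits and "explained %"
is eigenvalue/9. Axes with eigenvalues > 1 are retained (Kaiser rule),
with a 1e-12 guard so an eigenvalue of exactly 1.0 is kept. PCA signs
are arbitrary; each axis is oriented so its largest-|loading| trait
loads positively, making outputs reproducible across LAPACK builds.
For correlation-matrix PCA on ddof-1 z-scores, the Pearson correlation
between trait *j* and axis *k* equals `v_jk·√λ_k` exactly; the package
both uses this identity (loadings) and recomputes the correlations from
the data (`trait_axis_correlations`) as a cross-check. The limb-ratio
trait is a deterministic ratio of two other traits, so the correlation
matrix is close to singular but not singular; a hard singularity
(duplicated trait) raises.

## Convex-hull geometry

Hull volumes come from Qhull. Degenerate point sets (fewer than d+1
points, or affinely dependent) have zero d-volume by convention —
this is the "FRic = 0" convention for undersized groups. Intersections
are computed **exactly**: the facet half-spaces of both hulls are
pooled; the Chebyshev center of the pooled system is found by linear
programming (HiGHS); if the LP is infeasible or the inradius is below
1e-12 of the coordinate scale the hulls are disjoint (volume 0);
otherwise Qhull's half-space intersection enumerates the polytope's
vertices and its hull gives the volume. Monte-Carlo rejection sampling
is used only as an independent oracle in the tests, never in the
analysis path: 4-D hulls of ≤ ~50 points are cheap exactly, and the
exact route avoids MC error in the reported overlaps.

FRic is reported as a percentage of the convex hull of **all**
individuals pooled, the standard functional-space convention; the
denominator is a parameter (`fric(group, pooled)`) so any other
reference set can be used.

## Bootstrap CIs and PERMANOVA

Observed FRic and FOve grow with sample size, so both are recomputed at
a common subsample size (each distinct group size by default, following
the smallest-group logic) by drawing **without replacement** — reading
"randomly selecting n individuals" as subsampling; a classical
with-replacement bootstrap is available behind a flag. A group at or
below the subsample size cannot be strictly subsampled and is skipped
with a logged notice; a pair is resampled only when both members are
eligible. 10,000 replicates and 2.5/97.5 percentiles are the analysis
defaults; the desk-scale reproduction in `scripts/acceptance.py` uses
2,000 replicates, which puts the percentile Monte-Carlo error well
below a percentage point on the default data.

PERMANOVA is one-way, on Euclidean distances among the retained PC
coordinates (the space in which the groups are plotted):
`pseudo-F = (SS_between/(g−1)) / (SS_within/(n−g))` with the sums of
squares computed from pairwise squared distances, and
`p = (1 + #{F* ≥ F}) / (1 + n_perm)` — the add-one convention, so p is
never exactly zero and the smallest attainable p at 999 permutations is
0.001. Permutations are vectorized (batched one-hot contractions), so
calibration studies with thousands of replicates run in seconds. The
implementation is cross-checked against scikit-bio's PERMANOVA on the
same distance matrix.

## Habitat models

* **Screening.** Shapiro–Wilk per variable (α = 0.05); pairwise
  correlations use Spearman when either member failed normality,
  Pearson otherwise. Pairs with |r| ≥ 0.9 and p < .05 collapse to one
  member; the default keep-rules retain soil temperature over surface
  ground temperature and clumping-grass over bare-soil coverage
  (the ecologically prioritized members); pairs without a rule keep the
  variable less correlated with everything else. The pipeline
  additionally guarantees the full GLM stays estimable
  (p ≤ n_transects − 2), collapsing the most collinear survivors if
  necessary.
* **GLM family.** Poisson with log link by default — counts per
  transect — with a negative-binomial alternative (ML dispersion,
  which counts toward k) for overdispersed data. Predictors are
  z-scored before fitting so coefficients are comparable and AICc is
  stable.
* **Selection.** Every predictor subset (2^p, capped at p = 12) is
  fitted; subsets that cannot be fitted at the sample size (AICc needs
  n > k+1; selection fits require n ≥ k+2) are flagged, logged, and
  excluded from the Akaike weights. A single best model is declared
  only when the runner-up trails by ΔAICc > 2; otherwise the table is
  marked ambiguous and model averaging is the recommended summary.
* **Model averaging.** Full (zero-substitution) averaging over all
  converged models by default, MuMIn-style; `delta2` (ΔAICc ≤ 2) and
  `cum95` (95% cumulative weight) scopes are available. Unconditional
  SEs follow Burnham–Anderson:
  `SE = Σ w_i √(SE_i² + (β_i − β̄)²)`.
* **Hierarchical partitioning.** The independent contribution of
  predictor *j* is its improvement in goodness of fit averaged over all
  subsets at each hierarchy level, then across levels — exactly the
  Shapley value of the goodness-of-fit function, so the independent
  contributions sum to the full model's goodness of fit (verified to
  1e-8 against an independently coded ordering-enumeration oracle).
  Goodness of fit is the deviance-explained fraction
  `(D_null − D_model)/D_null` for count families and R² for Gaussian
  responses. The joint contribution is reported as
  `J_j = gof({j}) − I_j` (univariate fit minus independent part); it is
  zero for orthogonal designs and can be negative under suppression.
  Partition fits relax the df margin to n ≥ k+1 so near-saturated
  hierarchies remain computable at small transect counts.
* **Aspect** is treated as a linear covariate in degrees, not a
  circular variable — matching how such data are usually recorded and
  analyzed in this workflow; this is a documented simplification.
* Counts are per-transect totals over survey days (summation assumed).

## Ordination

* **DCA gate.** Detrending only affects axes ≥ 2, so the axis-1
  gradient length needs no detrending machinery. The gate computes
  correspondence-analysis axis 1 (SVD of the standardized residual
  matrix), takes site scores with unit abundance-weighted variance, and
  rescales into species-turnover SD units via the reciprocal-averaging
  species scores expanded by 1/eigenvalue: near-linear data spread
  every "species" (trait) across every site, inflating the within-site
  dispersion of species scores and shrinking the gradient below 1 SD,
  while genuine unimodal turnover yields long gradients. This is
  Hill's σ-unit scaling without decorana's iterative per-segment
  smoothing; against vegan's `decorana` it agrees to ~5% on short and
  medium gradients and always on the RDA/CCA recommendation (the
  segment smoothing only diverges on very long gradients, far beyond
  the 3-SD decision point). Trait matrices are made nonnegative by a
  per-column min-shift before CA; `n_segments` is carried on the
  result for interface completeness. CCA itself is intentionally not
  implemented — the gate selects RDA for every short-gradient dataset
  this package targets — and raises `NotImplementedError`.
* **RDA.** Multivariate least squares of centered (standardized)
  traits on centered environments, PCA of the fitted values; canonical
  eigenvalues are variances (ddof = 1) and percentages are of the total
  trait variance, so constrained + residual = total (verified to
  1e-8). Each individual carries its transect's environment values
  (individual-level RDA, matching how individuals are plotted);
  standardized traits are used for consistency with the PCA scaling.
  Env and trait scores are correlations with the site scores
  (correlation/"type-2" triplot reading: the cosine between arrows
  approximates the correlation between the variables). The overall
  permutation test uses
  `pseudo-F = (V_constrained/q)/(V_residual/(n−q−1))`, permuting rows
  of the environment matrix, add-one p. Triplot arrows are chosen by
  forward selection at permutation p < 0.05.

## The synthetic generator

The generator reproduces the *statistical structure* the analysis
assumes, with defaults fixed to the study design: 11 transects; 40
juveniles, 30 males, 41 females; a 2-SD separation between juvenile and
adult latent trait centroids along an ontogeny contrast (lighter,
smaller-headed, relatively longer-limbed juveniles) plus a smaller sex
contrast (heavier, wider-abdomen females); environment correlations of
0.958 (surface-ground ~ soil temperature) and −0.907 (bare-soil ~
clumping-grass cover).

Design details worth knowing:

* Separation is injected on **latent trait means** and back-transformed
  through the trait formulas (SVL drawn separately: juveniles < 40 mm,
  adults larger; head width recovered from head size and mildly noisy
  shape ratios; limbs/tail/abdomen as ratio × SVL). Because the ratio
  traits are scale-free, group structure in trait space comes *only*
  from the centroid shift: at `trait_centroid_shift = 0` the groups are
  exchangeable and downstream group-difference tests hold their nominal
  level (verified). The trait baselines (e.g. adult mass ≈ 7 g,
  relative hindlimb ≈ 0.6) are plausible for a small high-elevation
  agamid but are not fitted to any dataset; the generator reproduces
  the qualitative PC-sign pattern, not published trait values.
* Coverages are simulated on the **logit scale** and mapped through
  `100·expit`, so [0, 100] bounds hold by construction. The logistic
  map attenuates correlations slightly, so the latent correlation is
  calibrated (Gauss–Hermite quadrature + bisection) to make the
  realized %-scale correlation converge to the configured value.
* Aspect is linear in [0, 360), matching the analysis's (non-circular)
  treatment; counts follow log-link Poisson preferences per group, and
  individuals are assigned to transects with probabilities proportional
  to the expected densities, so the transect count table tallies the
  individual table exactly.

**What passing tests show — and don't.** The synthetic data are
multivariate Gaussian on the latent scale with exactly the assumed
correlation structure, no measurement error, no missing data, no
spatial autocorrelation among transects, and no trait–environment
coupling beyond group-mediated distribution differences. Passing the
suite therefore demonstrates the *estimators and tests* are correct and
calibrated under the assumed model, not that the model describes any
real population; with real data the screening decisions, family choice
(overdispersion), and the circular-aspect simplification deserve
scrutiny.

## Numerical choices and problem sizes

* Hull intersections below an inradius of 1e-12 × coordinate scale
  count as disjoint; FOve is clamped to [0, 1] against numerical fuzz.
* Eigenvalue retention uses a 1e-12 guard at the 1.0 threshold;
  correlation matrices with a minimum eigenvalue below 1e-10 are
  treated as singular.
* Permutation p-values always use the add-one convention.
* The per-stage RNG seeds derive from the global seed XOR a CRC-32 hash
  of the stage name (kept below 2³¹), so any stage can be reproduced in
  isolation.
* Default analysis sizes are 10,000 bootstrap replicates and 999
  permutations. The package's desk-scale reproduction
  (`scripts/acceptance.py`) uses 2,000 bootstrap replicates and 999
  permutations; the test suite's calibration studies use 1,000 null
  PERMANOVA simulations at 199 permutations, 500 null RDA runs at 199
  permutations, 500 GLM-recovery replicates at n = 200, and 1e6-sample
  Monte-Carlo geometry oracles — sizes at which the Monte-Carlo error
  of each check is far below the tolerance being asserted.

## Known limitations

* CCA is absent by design; datasets with DCA gradients ≥ 3 SD need a
  unimodal-response toolchain.
* No zero-inflation, GLMMs, or spatial autocorrelation in the habitat
  models; transects are treated as independent.
* FOve is pairwise; simultaneous ≥ 3-group overlap is out of scope.
* The DCA gate uses global σ-unit rescaling rather than decorana's
  segment-wise smoothing, so lengths on very long gradients (> ~8 SD)
  are not comparable to decorana's — irrelevant to the < 3 SD decision
  it exists to make.
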