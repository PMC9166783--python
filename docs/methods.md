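# Methods

## The analysis model

The pipeline asks three nested questions about a two-arm longitudinal
cohort with a multiplex cytokine panel and behavioural scales:

1. **Covariation.** Is there a linear combination of symptom changes that
   correlates with a linear combination of cytokine changes? We use the
   penalized-matrix-decomposition form of canonical correlation analysis:
   maximise w₁ᵀX₁ᵀX₂w₂ under ‖wᵢ‖₂ = 1 and L1 budgets cᵢ ∈ [1, √pᵢ].
   The L2 constraint is on the weights, not on the canonical-score
   variance, i.e. within-block covariance is treated as diagonal. That is
   the standard sparse-CCA compromise when n is far below p₂: the
   within-block covariance of 35 analytes cannot be stably inverted at
   n ≈ 37–79. The objective is maximised by alternating exact half-steps
   (soft-threshold the gradient, renormalise; the threshold found by
   bisection so the L1 budget binds), started from the leading singular
   pair of X₁ᵀX₂. Consequences worth knowing: with slack budgets the
   solution equals classical CCA only when within-block covariance is the
   identity (the test suite whitens blocks before comparing with the
   closed form), and the objective is monotone only up to the bisection
   tolerance (~1e-7 relative; asserted at 1e-4).

2. **Subgroups.** Treated subjects live on the covariation plane
   (cytokine score, behavioural score). K-means with 50 greedy-spread
   restarts partitions the discovery set; the number of clusters is the
   elbow (maximum second difference) of the Hubert Γ curve, Γ(k) being
   the correlation between pairwise distances and the different-cluster
   indicator. Groups are named best/medium/least by mean behavioural
   improvement, which makes naming invariant to k-means label
   permutations. Validation subjects are mapped by nearest discovery
   centroid rather than re-clustered, so group definitions are comparable
   across sets.

3. **Prediction.** Baseline-only features (optionally including the
   batch-adjusted cytokine panel) predict responder labels — either the
   named subgroups or CARS-total-improvement cutoffs (strict > 2.5 or
   > 2 points). Five families are fit on the discovery set after random
   minority oversampling and point-biserial top-m feature selection
   (m = 10, demographics always retained), and scored on the validation
   set. The contrast of interest is mean AUC across the five families
   with vs without cytokines, with a percentile bootstrap CI over test
   subjects (B = 100; single-class resamples are redrawn).

## Inference choices

* **Permutation scheme.** The discovery p-value permutes the rows of X₂
  and *refits* the sparse CCA at fixed budgets each time. The refit is
  essential: the observed r is selection-biased upward (a best sparse
  combination of 35 analytes against 3 behavioural changes reaches
  r ≈ 0.4–0.5 at n = 79 under pure noise), and a fixed-weight null would
  compare that biased statistic against an unbiased null and reject
  almost always on null data. The price of validity is power: because
  even the null refits track the selection bias, detection power for a
  planted canonical correlation of 0.46 at n = 79 with 35 candidate
  analytes plateaus around 75–90% at α = 0.05 depending on the budget
  (the operating-characteristics suite reports the realized rates), and
  no valid variant we evaluated — fixed sparse budgets, cross-validated
  budgets, or an adaptive max-over-budgets statistic — reaches
  materially higher power at this design size. This is a property of
  the design (n, p₂, effect size), not of the implementation.
* **Validation and control sets** are never refit: discovery weights and
  discovery column standardisation are frozen, and only the correlation
  of the projected scores is re-tested by permuting one score vector.
* **Budgets.** The L1 budgets are not identifiable from theory at this
  n; the pipeline cross-validates c₂ over a small grid (default 1.2,
  1.5, 1.8; c₁ = √3 since all three behavioural changes are expected to
  load) by mean held-out canonical-score correlation, ties toward the
  sparser point, with a low-signal flag when the best held-out r < 0.1.
* **Sensitivity analysis** residualises both validation-score vectors on
  age, sex, BMI and the frozen-weight baseline canonical variables, and
  reports the partial correlation with a t-based p on n − k − 2 df.

## Preprocessing

* **Detection limits.** An analyte is dropped when the fraction of its
  values below the lower limit exceeds θ; θ = 0 by default (any sub-LOD
  value excludes the analyte), configurable because assay practice
  varies between per-value and per-analyte exclusion.
* **Min-max + log.** Within each shipping batch, each analyte is mapped
  to [0, 1] and then log1p-transformed. log1p rather than log because
  the batch minimum maps to 0 where log is undefined; the transform is
  monotone, so rank statistics are unchanged. Baseline and change
  matrices are transformed independently.
* **Change conventions.** ΔCARS = baseline − month 3 (improvement
  positive); Δcytokine = month 3 − baseline (increase positive). Both are
  fixed in `cohort.cars_change` / `cohort.cytokine_change`.
* **Batch adjustment** is the parametric empirical-Bayes location/scale
  model, applied to baseline concentrations only (change scores are
  within-subject differences and are left unadjusted). No biological
  covariates enter the design; a mean-only mode is available. The
  implementation was cross-checked against the Bioconductor reference on
  a fixed fixture (agreement ~1e-7; frozen in the test suite). Note that
  empirical-Bayes shrinkage leaves the sampling noise of the batch means
  behind, so the adjustment is only *nearly* idempotent and residual
  per-column batch differences are O(1/√n).

## The synthetic-cohort generator

The generator emulates the study design, not the immunology. Defaults:
37/42/37 subjects (discovery/validation drug, control placebo), one batch
per set, 48 log-normal analytes (between-subject SD 0.4 on the log
scale) of which 35 sit inside their detection ranges, CARS subscales with
an additive total (offset ≥ 0, baseline total ≥ 30), ADOS/SRS baselines
weakly correlated (r ≈ 0.25) with the latent cytokine score.

Planted structure:

* Each subject has a latent plane position. A 3-component Gaussian
  mixture (proportions 0.215/0.557/0.228; within-cluster SD 0.3) supplies
  the clusters; the mixture is whitened and recoloured by a linear map so
  that the population correlation of the two plane axes is exactly the
  value required for the *observed-block* canonical correlation to equal
  `rho_latent` (default 0.46). Per-variable loadings put 80% of each
  observed change-score variance on its block's plane score; with 3
  variables per block the block-level multiple correlation is 0.961, so
  the plane correlation is rho_latent / 0.923. Requesting rho_latent
  above ~0.92 is infeasible and raises. Because the recolouring is an
  invertible linear map, cluster separability is preserved, and
  `rho_latent = 0` (needed for null simulations) is always feasible.
  The within-cluster SD of 0.3 keeps the planted partition recoverable
  by isotropic k-means after the recolouring shear (mean ARI ≈ 0.95 at
  n = 79); the shear makes clusters anisotropic, which costs k-means
  accuracy even though Bayes separability is unchanged.
* Only the 3 active analytes' log-scale changes load on the cytokine
  plane score (change SD 0.5 log-units); the other analytes change by
  pure noise. The placebo arm uses coupling `placebo_coupling`
  (default 0) and half the mean CARS improvement.
* A baseline "inflammatory signature" (±0.5 log-units by cluster) sits on
  four *non-active* detectable analytes, so baseline cytokines carry
  subgroup information without contaminating the planted change-block
  structure.
* Batch effects are additive location plus multiplicative scale on the
  log concentration scale — exactly the model the empirical-Bayes
  adjustment assumes, so correction is well-posed.

What the generator does **not** emulate: analyte cross-correlation
networks, item-level psychometrics of the scales, dropout beyond an
optional missing-completely-at-random mask, and absolute concentration
levels (no public raw summaries exist to calibrate them). Passing tests
therefore demonstrate structural recovery — active set, correlation
magnitude, cluster count and membership, prediction contrast — not
distributional realism of real plasma panels.

## Operating-characteristics protocol

The simulation suite in `tests/test_acceptance.py` uses 200 permutations
(scaled down from the 5000 used for a single reported analysis) and
replicate counts chosen to bound Monte-Carlo error while keeping the
suite inside a desktop budget: 50 cohorts for detection power and
active-set recovery, 400 null cohorts for the type-I rate (binomial SE
≈ 0.011 at 0.05), 100 cohorts for placebo non-significance and for
cluster recovery, 50 for the prediction contrast. `scripts/acceptance.py`
runs one full analysis at n_perm = 5000 and B = 100.

Two regime choices in that suite deserve a note:

* **True nulls have no clusters.** Setting the planted coupling to zero
  while keeping the shared three-cluster mixture leaves the two blocks
  *dependent* — the cluster label moves both plane axes, so they are
  uncorrelated but not independent, and the permutation test correctly
  detects that dependence at above-nominal rates. That is power, not a
  type-I error. The type-I simulation therefore uses cohorts with zero
  coupling *and* a single-component mixture.
* **The prediction contrast is conditional.** Whether baseline cytokines
  improve subgroup prediction depends on how much cluster information
  the baseline panel carries. The contrast simulation constructs that
  regime explicitly (a ±1 log-unit inflammatory signature by subgroup);
  at the milder default signature (±0.5) the improvement is still
  positive on average (~0.2 mean AUC) but its 100-bootstrap CI at
  n = 42 test subjects excludes zero in only about half the replicates.

## Known limitations

* Detection power of the refit permutation test at the default design is
  below conventional 95% power targets (see "Permutation scheme" above);
  a larger cohort or a pre-registered analyte subset would be needed to
  change that.
* Only the first canonical pair is extracted; no deflation for further
  pairs.
* The "oblique" random-forest family is implemented as an axis-aligned
  random forest (a logged stand-in); sparse LDA is L1-penalised optimal
  scoring, which for two classes is the Lasso on the centered class
  indicator.
* Sub-LOD values are excluded, not imputed; left-censored likelihood
  models are out of scope.
* Classifier hyperparameters are fixed (no nested tuning) — at n = 37
  training subjects nested model selection is noise.
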