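# Methods

## Model

A bulk tumor expression profile is modeled as a linear-scale mixture of
three cellular compartments — cancer, immune and stromal — where the
cancer compartment carries one of K discrete molecular subtypes shared
across the cohort:

    exp(o_ij) ~ exp(E_i^subtype(j)) f_j^cancer
              + exp(E_i^immune)     f_j^immune
              + exp(E_i^stromal)    f_j^stromal

with `o_ij` the observed log expression of gene i in sample j,
`E` per-gene log-scale compartment reference profiles (cohort-level, not
per-sample), `f_j` the per-sample fraction vector on the probability
simplex, and `subtype(j) ∈ {1..K}`.  All logs are natural; mixing is on
the original (linear) scale.  The fit criterion is the summed squared
log-scale reconstruction error,

    SSE = Σ_ij ( o_ij − log(reconstruction_ij) )²,

i.e. a least-squares fit under an (approximately) log-normal error
model.  Optimization uses the sum; model selection uses the mean
(SSE / (genes × samples)), because the selection formula below reads the
error as a *mean* squared error.  The two differ by a constant factor
and are monotonically equivalent for optimization.

Three groups of unknowns are estimated jointly by two nested
block-coordinate loops:

* **inner layer** — at fixed fractions, alternate (a) per-gene profile
  estimation and (b) exact per-sample subtype reassignment;
* **outer layer** — alternate the inner layer with (c) per-sample
  fraction estimation.

Each of (a), (b), (c) can only decrease the objective (see *Numerical
choices*), so the objective trace is non-increasing across accepted
steps; this is asserted in the test suite.

### Initialization

Immune and stromal fractions are initialized from marker genes: the
per-sample mean log expression of immune (resp. stromal) markers is
exponentiated and scaled by a constant `C_immune` (resp. `C_stromal`);
the cancer fraction is the complement.  The two constants are chosen by
an exhaustive 10×10 grid search.  Each axis spans (0, c_max] where
c_max makes the largest implied single-compartment fraction equal 1, and
grid points sit at the ten bin centers; pairs implying
f_immune + f_stromal > 0.99 for any sample are infeasible and skipped
(with bin centers at 0.05·c_max and above, at least the smallest pair is
always feasible).  Each feasible pair is scored by a *single*
non-iterated pass of the two layers — K=1 fit, K-means label
initialization, one profile update, one reassignment, one fraction
update — with reduced solver iterations and K-means restarts: the
purpose is a cheap, consistent ranking, not a converged fit.  The search
is repeated for each candidate K and cached.

A note on identifiability: when the marker scores are exactly
proportional to the true fractions and K = 1, wrong constants can be
compensated exactly by linearly transformed profiles, making the grid
objective flat.  With K ≥ 2 distinct cancer profiles the shared immune
and stromal profiles can no longer absorb the error, and the grid
develops a sharp minimum at the generating constants (verified in the
test suite).

Initial subtype labels come from K-means clustering of the residual
matrix of the K=1 fit (samples as observations, k-means++ with 25
restarts driven by the run seed, labels renumbered by descending cluster
size).

### Model selection

For each K in a range (default 1..10) the model is fit and scored with

    BIC(K) = log(MSE) · n_samples + log(n_samples) · K,

MSE being the mean variant above.  Two readings of the curve are
combined: `k_min`, the argmin (ties to the smallest K), and `k_elbow`,
the interior point maximizing the discrete second difference
BIC(k−1) − 2·BIC(k) + BIC(k+1) (a standard discrete-curvature elbow;
when the argmin is the first point the elbow is defined to coincide with
it).  When the two disagree, their midpoint rounded *down* (parsimony)
is returned.  Diagnostics (`k_min`, `k_elbow`, the full curve) are
always reported.

The log(MSE) term makes the criterion fragile on data that the model can
fit almost exactly: once the error floor is set by optimizer convergence
rather than by noise, its small K-dependence is amplified by the log.
`compute_bic` therefore refuses a non-positive MSE outright, and on
noiseless data the elbow/midpoint combination — not the argmin alone —
is what carries the selection.  See *Known limitations*.

## Numerical choices

* **Per-gene profile updates.** At fixed fractions and labels the
  objective separates across genes into (K+2)-parameter problems.  All
  genes are advanced simultaneously by a damped (Levenberg-style) Newton
  iteration with analytic gradients and Hessians; steps are clipped to a
  per-gene box (observed log range ± `profile_bounds_pad`, default 2)
  and accepted per gene only when they improve that gene's objective —
  per-gene descent therefore holds by construction, and a gene whose
  steps all fail simply keeps its warm start.  Because the landscape is
  non-convex (a sum of exponentials inside a log), two starting points
  are tried per gene and the better kept: the caller's warm start, and
  the linear-scale least-squares solution (its design matrix is shared
  across genes, so it costs one small solve; at zero noise it is exact).
  The default box pad of 2 log units deliberately trades recovery of
  very weakly contributing compartment values (which are barely
  identifiable anyway) for stability; widen it when exact recovery of
  such values matters.
* **Per-sample fraction updates.** In the free coordinates
  (f_immune, f_stromal) with f_cancer the complement, the linear-scale
  mixture is linear, and each sample is a 2-parameter damped-Newton
  problem with closed-form 2×2 solves.  Steps are projected onto the
  feasible triangle {f_immune, f_stromal ≥ ε, sum ≤ 1−ε} (ε = 1e-9) and
  accepted per sample only when they improve; the returned fractions are
  projected onto the simplex exactly.
* **Subtype reassignment** enumerates all K labels per sample and is
  exactly optimal; ties break toward the lowest subtype index.
* **Empty subtypes.** A subtype losing all members during reassignment
  has its cancer profile re-seeded from the worst-reconstructed sample
  (linear-scale subtraction of the non-cancer signal), followed by one
  extra profile pass; the repair is kept only if it does not worsen the
  objective.  During a profile update an empty subtype's column has zero
  gradient and keeps its warm start, flagged in the log.
* **Convergence.** Inner layer: relative objective change < 1e-6 with
  unchanged labels, or 20 iterations.  Outer layer: relative change
  < 1e-5 or 10 iterations (non-convergence at the cap is a logged
  warning, not an error).  Outer iterations after the first warm-start
  the inner layer from the previous labels and profiles rather than
  re-running the K-means initialization: re-initializing stochastically
  every pass would break monotone descent and discard information.
* **Determinism.** A single integer seed drives K-means restarts; there
  is no other stochastic element, so identical inputs and seed give
  bit-identical outputs.

## Synthetic cohorts

The simulator emulates the benchmark structure used for reference-free
deconvolution methods, entirely offline:

* **Reference profiles.** Per-gene log-scale values are drawn as
  Gaussians (mean 3, sd 1.5 — linear-scale median ≈ 20, a plausible
  magnitude and spread for filtered log expression).  K cancer profiles
  share a common latent base; the mixing weight is tuned by bisection
  until the realized mean pairwise Spearman correlation hits the target
  (default 0.87, the moderate similarity typical of cancer-subtype
  references).  Immune and stromal profiles get K near-identical
  subtype variants (minimum pairwise Spearman ≥ target, default 0.98):
  the mixture is built with the variant of each sample's subtype, while
  the reported ground-truth profile is the per-gene average — mirroring
  the fact that the fitted model assumes a single profile per non-cancer
  compartment even when reality is slightly subtype-specific.  With the
  target set to 1.0 the variants coincide and the zero-noise data follow
  the model identity exactly.
* **Markers.** A configurable number of genes per compartment (default
  20) are overexpressed in their compartment by ≥ 2 log units relative
  to every other compartment; the boost is shared across subtype
  variants.
* **Fractions.** Subtype labels follow configurable proportions
  (default 0.5/0.3/0.2); fractions are Dirichlet around subtype-specific
  means (defaults centred at 60% cancer / 25% immune / 15% stromal with
  subtype-dependent balance) with concentration 10, chosen so the
  cancer-fraction spread (sd ≈ 0.15) matches the purity dispersion of
  real solid-tumor cohorts.  An infinite concentration returns the means
  exactly.
* **Noise.** Log-normal: additive N(0, sd²) on the log scale, default
  sd 0.3, study grid {0.2 … 0.6}.  Negative binomial: Gamma-Poisson
  counts with the linear-scale mixture as mean and size
  1/(exp(sd²) − 1), matching the per-gene coefficient of variation of
  the log-normal model at the same sd; observed values are
  log(count + 1).

What the simulator does *not* emulate: real gene-gene correlation
structure, library-size and batch effects, per-gene dispersion
heterogeneity, and compartment profiles anchored to real cell lines or
sorted-cell references — only their correlation structure is matched.
Passing tests therefore demonstrate correctness of the machinery and
robustness under the stated noise laws, not performance on real tumors.

## Comparator strategies and metrics

Two K-means baselines: direct clustering of the bulk matrix, and a
two-step strategy — remove the immune/stromal signal on the linear
scale using reference profiles and per-sample fractions, divide by the
cancer fraction, floor negatives at 1e-6 of the matrix median,
quantile-normalize columns, then K-means.  Reference fractions for the
two-step route come from per-sample non-negative least squares on the
linear scale against the three compartment references (cancer reference
= median across subtype profiles); like all reference-based comparators
run with the true simulation references, this is an idealized upper
bound on its real-data behavior.  When references live on a different
scale than the mixture, they are first rescaled so the medians match.

Recovery metrics: fraction accuracy = mean over compartments of the
across-sample Pearson correlation; clustering accuracy =
best-permutation agreement via optimal (Hungarian) label matching, with
the adjusted Rand index alongside; profile accuracy = mean over
compartments of the across-gene Pearson correlation, cancer profiles
matched by the same label permutation (Spearman reported as a
diagnostic).

## Problem sizes used in the checked examples

The bundled acceptance checks run at desk scale, chosen as the package's
own benchmark sizes: the headline profile-accuracy check uses 3
subtypes, 1500 genes, 100 samples, noise sd drawn uniformly in
0.2–0.5, five seeds; exact-recovery and selection checks use 60 samples
and 200–300 genes at zero noise with the K-range 1..5; the comparator
ordering uses ten replicates at sd 0.5.

## Known limitations

* One subtype per sample; no mixtures of cancer subtypes within a
  sample, and no subtype structure for the non-cancer compartments.
* Cohort-level profiles only — no per-sample individualized cancer
  profiles.
* The objective is non-convex; block descent guarantees monotone
  improvement, not a global optimum.  Recovery degrades gracefully with
  noise but initialization (markers, K-means) matters.
* BIC-based selection of K on *noiseless* or near-noiseless data is
  intrinsically unstable (see *Model selection*): the argmin of the
  curve can drift above the true K because the log of a
  convergence-limited error floor still decreases slowly with K.  The
  elbow/midpoint rule compensates in part.  On data with realistic
  noise the criterion behaves conventionally.
* Values of a compartment profile far below a gene's observed mixture
  range are weakly identifiable and, with the default box pad, are
  reported at the box boundary rather than extrapolated.
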