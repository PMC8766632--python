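# Methods

## Model and likelihood

Each record `t` in cohort `g` carries a feature vector `x_t`, an observed
class `Y_obs in {1, 2}`, and an unobserved true class `Y`. A parametric
discriminative model gives `phi_1(x, alpha) = P(Y = 1 | x)`:

* **logit** — `phi_1 = sigma(alpha . x~)` (default);
* **probit** — `phi_1 = Phi(alpha . x~)`;
* **linear** — `phi_1 = clip(alpha . x~, 1e-6, 1 - 1e-6)`; the clip keeps
  probabilities valid and the log finite.

`x~` appends an intercept column by default. Corruption is class-conditional
and cohort-specific: `eps[j, i, g] = P(Y_obs = j | Y = i, g)`, columns on
the simplex. Marginalizing the true label gives the observation likelihood

    L(alpha, eps) = sum_{g, t} 1/(N_g T_g) log sum_i eps[j_t, i, g] phi_i(x_t, alpha),

the quantity all fitting, cross-validation and bootstrapping work with. The
`1/(N_g T_g)` weights make every cohort contribute equally regardless of
size. Mixed probabilities are floored at `1e-300` before the log so that
degenerate parameter combinations stay finite rather than raising.

### The two matrix conventions

Practitioners usually want the *observed-conditioned* risk
`r[i, j, g] = P(Y = i | Y_obs = j, g)` — "how likely is a record labeled
benign to truly be malignant". The two parameterizations are related by
Bayes' rule through the class priors `pi`:

    r[i, j] = eps[j, i] pi_i / sum_k eps[j, k] pi_k.

The estimator scans `eps` and derives `r` afterwards using the priors
implied by the fitted model (`pi_i(g)` = mean of `phi_i` over cohort `g`).
The reason the *generative* direction is the one optimized is structural: if
the mixture weights are taken conditioned on the observed label, the
per-row "probabilities" do not sum to one across observed classes, and the
objective can be inflated without bound toward the mislabeling box corner —
declaring one class nonexistent and charging every one of its observations
to mislabeling at the upper bound raises the objective for *any* dataset
that is not near-perfectly separable. Numerically the in-sample argmax then
sits at the corner for every bound and budget tried, and no recovery of
known rates is possible. With the generative mixture `P(Y_obs | x)` is a
proper probability, maximum likelihood is consistent for this latent-noise
family, and known flip rates are recovered (see the parameter-recovery
tests). `log_likelihood` and `grad_alpha` accept either convention
explicitly — a `FlipMatrix` mixes generatively, a `MislabelMatrix` evaluates
the observed-conditioned weighting literally; identities such as
uniform-columns -> `-log m` and identity -> plain GLM hold in both.

## Optimization

For fixed `(eps, C)` the inner problem maximizes `L` over `alpha` under
`|alpha_slopes|_1 <= C`. Each penalized coefficient is split into
nonnegative positive/negative parts so the budget becomes one linear
inequality; the smooth problem is solved by SLSQP with the analytic
gradient `dL/dalpha = sum_t w_t (c1 - c2) phi_1'(z_t) x~_t / mixed_t`.
The intercept is unpenalized, so the `C = 0` limit is the base-rate model
(`logit(p_hat)`) rather than a degenerate one.

* `tolerance` (SLSQP ftol) defaults to `1e-12`: objective-change tolerances
  translate to roughly square-root-sized parameter errors, and `1e-12`
  keeps coefficients accurate to ~1e-5 at negligible cost.
* Multi-start: `alpha = 0` plus `n_restarts - 1` seeded uniform draws in
  `[-restart_scale, restart_scale]`, rescaled into the L1 ball. Concavity of
  the mixture objective in `alpha` is not assumed; restart agreement is
  reported (`n_restarts_agreeing`). In practice restarts agree and the
  default of 3 is conservative; the heavy simulation tests use 1.
* The outer scan covers the off-diagonal `eps` entries (two per cohort) on a
  uniform grid inside the user boxes (default step 0.05, boxes `[0, 0.5]`)
  crossed with a geometric C ladder `{0.25, ..., 32}`. Ties within `1e-10`
  prefer the smallest off-diagonal sum, then the smallest C — the
  least-mislabeling, sparsest explanation. Grid points are independent;
  with `n_workers > 1` they are dispatched by joblib with per-point seeds
  derived from the point index, so results are identical for any worker
  count.

The mislabeling boxes bound the off-diagonal (error) entries only; diagonals
follow from column normalization. Bounding whole columns at the customary
`r+ = 0.5` would cap the *correct*-labeling probabilities at 0.5, which is
never the intent.

## Model selection

`cross_validate` repeats (default 500, configurable) a random split,
stratified within cohort, into 75% training / 25% validation; at each grid
point `alpha` is refit on the training part and the validation likelihood is
recorded with the grid's mislabeling matrix. Splitting within cohort (not
within label) reflects that cohorts are the sampling design while labels are
exactly what is in doubt. Selection is the argmax of the mean validation
likelihood with a one-standard-error rule: all grid points whose *paired*
deficit to the best (same splits, so split-to-split variance cancels) is
within one standard error form the tie set, resolved by least mislabeling,
then smallest C. The unpaired SE was tried first and is dominated by
between-split variance, collapsing the tie set to everything and
systematically undershooting the rates. The rates/steepness direction is
weakly identified at small sample sizes — misses overshoot along the ridge
where both flip rates and coefficient magnitudes grow together — so
recovery experiments use T = 4000 and >= 25 repeats.

`aic` offers `2k - 2 LL_total`, with `LL_total` the unnormalized sum of log
mixed probabilities and `k` the count of coefficients above `1e-6` in
magnitude (intercept included) plus mislabeling entries not pinned at a box
bound. The exact information-criterion form for this model is a documented
choice, not a received formula.

## Uncertainty

`bootstrap_fit` resamples rows with replacement *within each cohort*
(preserving every `T_g`), re-runs the full grid co-inference per replicate
(default `B = 100`), and treats the replicate distribution as the posterior:
percentile 95% intervals for coefficients, flip rates and converted risks,
per-individual probability intervals, and the fraction of replicates whose
off-diagonals all sit at the zero grid point — the posterior mass on perfect
labeling. Percentile (not BCa) intervals are used; model selection is not
re-run inside replicates (the grid is shared), keeping cost at
`B x |grid|` fits. Replicates missing an observed class entirely are
redrawn and logged.

## Evaluation

* `auc` is the Mann-Whitney estimator via midranks (ties count 1/2); the
  brute-force pair count serves as the test oracle.
* `auc_ci` defaults to the Hanley-McNeil closed-form standard error
  (`q1 = A/(2-A)`, `q2 = 2A^2/(1+A)`) with a normal quantile, clipped to
  `[0, 1]`; a stratified bootstrap percentile interval is the alternative.
  Measured coverage on binormal scores with true AUC 0.85 (n = 500/500) is
  ~96%.
* `feature_impact` reports, per binary feature, the mean change in `phi_1`
  when the feature is forced 1 versus 0 with all else at observed values;
  `risk_curve` sweeps a continuous feature the same way.
* `mislabel_bias_experiment` flips each observed label with probability
  `eps` (levels up to 0.3), re-runs the co-inference, and reports the
  estimated rates, the 0.5-threshold accuracy against the *original*
  labels, and the Pearson correlation between induced and estimated rates.
  Estimates track the induced rates with a mild downward bias; the
  correlation exceeds 0.9 at T = 1500 (per-replicate grid quantization
  noise dominates at a few hundred rows).

## Synthetic data

The generator draws independent Bernoulli indicators (optionally emitted as
indicator/complement pairs), Gaussian continuous columns min-max rescaled to
`[0, 1]`, true labels from a logit model with known `alpha`, and observed
labels through a known flip matrix; it records every flip event. Defaults
mimic a categorical breast-imaging table: 13 binary attributes as 26
paired columns plus one age-like feature, T = 830 in one cohort,
near-balanced classes (intercept centered at the feature means). What it
deliberately does not emulate: correlated features (beyond the built-in
pair collinearity), linkage structure in genotype columns, covariate shift
between cohorts, or feature-dependent (non-MCAR-like) label noise — so
passing tests demonstrate correctness of the estimator under its own model,
not robustness to those violations. `flip_to_r` / `empirical_r` convert
generative truth into the observed-conditioned convention for comparisons;
`empirical_r` (realized conditional frequencies) is the finite-sample target
the recovery tests use.

## I/O

Categorical tables: each subcategory becomes an indicator *and* its
complement (`col_is_x`, `col_not_x`) so the L1 selection can pick either
polarity of a rule; 4 + 5 + 4 subcategories plus age gives the canonical 27
features of the mammography layout. Rows containing the missing sentinel
are dropped and counted; continuous columns are min-max rescaled so one C
budget is comparable across features. The assessment column is metadata by
default (droppable), and label codes follow the schema's category order.

VCF: sites are merged across cohort files on exact (chrom, pos, ref, alt);
only biallelic single-nucleotide sites with complete genotypes in all
samples survive, with merged-cohort MAF >= 1% (floor configurable).
Genotypes are coded additively in the minor allele (0 hom-major / 1 het /
2 hom-minor); at exact 50% frequency the reference allele counts as major.
No imputation, allele flipping, or liftover is attempted; cohort matching
and ancestry filtering are expected upstream.

## Problem sizes and numerical choices

Simulation tests run at T = 600-4000 with 3-5 features, grid step 0.05,
single C, and one restart — sizes at which every qualitative property
(recovery within one grid step, >= 85% interval coverage, correlation >=
0.8) is stable under the fixed seeds used. Coefficients below `1e-6` count
as zero; grid ties resolve at `1e-10`; simplex checks at `1e-12`. Known
limitations: only two classes are fittable (the types admit more); the
flip-rate/steepness ridge makes rates weakly identified at small T, with
CV selections biased conservative by design; bootstrap percentile intervals
can undercover near parameter bounds.
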