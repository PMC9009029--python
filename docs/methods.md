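# Methods

## The model

`swcrt` simulates and analyzes cross-sectional stepped wedge cluster
randomized trials (SW-CRTs) with a continuous outcome. The outcome of
subject *k* in period *j* of cluster *i* follows the linear mixed model

    Y_ijk = beta_j + X_ij * theta + C_i + CP_ij + e_ijk,

with categorical period effects `beta_j`, treatment indicator `X_ij`,
treatment effect `theta`, cluster effect `C_i ~ N(0, sigma_C^2)`,
cluster-period effect `CP_ij ~ N(0, sigma_CP^2)` and subject error
`e_ijk ~ N(0, sigma_e^2)`, all mutually independent. Each subject is
measured once. This induces the *block-exchangeable* within-cluster
correlation structure, parameterized by

- the within-period intracluster correlation
  `rho1 = (sigma_C^2 + sigma_CP^2) / (sigma_C^2 + sigma_CP^2 + sigma_e^2)`,
- the cluster autocorrelation `r = sigma_C^2 / (sigma_C^2 + sigma_CP^2)`,
- the between-period correlation `rho2 = rho1 * r`.

When `r = 1` the cluster-period effect vanishes and the structure is
*exchangeable*. The inversion used everywhere (generator, Bayesian model,
reporting) is `sigma_C^2 = r * rho1 * sigma_e^2 / (1 - rho1)` and
`sigma_CP^2 = (1 - r) * rho1 * sigma_e^2 / (1 - rho1)`; `rho1 = 1` is
rejected (infinite variance).

## Designs and the study grid

A *standard* stepped wedge with `T` periods has `T - 1` unique sequences;
sequence `q` crosses from control to intervention at period `q + 1`, so
period 1 is all-control and period `T` all-intervention. With `S` clusters
per sequence, `N = S (T - 1)`. Clusters are assigned to sequences in
blocks; under the exchangeable models any assignment is equivalent, a
fixed one keeps output reproducible. Clusters and periods are 1-based.

The default simulation grid crosses `S in {1, 2, 5}`, `T in {5, 9}`,
`m in {10, 100}` subjects per cluster-period, `rho1 in {0.05, 0.1}` and
`r in {0.8, 1}` — 48 configurations spanning 4–40 clusters, cluster sizes
50–900 and 200–36,000 total subjects. Generating values: `theta = 0`,
`sigma_e^2 = 1`, linear period effects `beta_j = j / T` (the analysis
model's categorical period effects contain the linear trend, so the
analysis model remains correctly specified), 1000 replicates per
configuration. Analyses are correctly specified throughout: block datasets
are fitted with the block structure, `r = 1` datasets with the
exchangeable structure (and `r` is then not estimated). Non-null `theta`
is supported as a configuration parameter but is not part of the default
grid.

### What the generator emulates, and what it does not

The generator reproduces the study conditions exactly: balanced standard
designs, equal cluster-period sizes, normal errors at all three levels,
cross-sectional sampling. It does not emulate features of real SW-CRT
data such as unequal cluster sizes, missing cells, transition periods,
correlation decay over time, or non-normal outcomes — so passing tests
demonstrate correctness of the estimators *under the model*, not
robustness to misspecification (deliberately out of scope).

## Sufficient statistics and the REML fit

With balance, the likelihood depends on the data only through the
cluster-period means and the pooled within-cell sum of squares. Writing
`x_i = sqrt(m) * ybar_i` for the scaled cell-mean vector of cluster `i`,
`cov(x_i) = D1 (I - P) + DT P` with `P = 11'/T`,
`D1 = sigma_e^2 + m sigma_CP^2`, `DT = D1 + T m sigma_C^2`; the remaining
`N T (m - 1)` within-cell dimensions are iid with variance `sigma_e^2`.
Every likelihood, GLS and information quantity reduces to scalar weights
on these three eigenspaces, making a fit O(N·T) — this is the collapse
that keeps 1000-replicate studies cheap. Equality with the
individual-level fit is verified against dense-matrix oracles in the test
suite (machine precision for the likelihood; 4+ significant figures for
the optimum against brute-force grid maximization).

Optimization profiles out the fixed effects and `sigma_e^2` analytically
and minimizes the restricted criterion over the variance *ratios*
`gamma_C = sigma_C^2/sigma_e^2`, `gamma_CP = sigma_CP^2/sigma_e^2` on the
log scale (Nelder-Mead, up to 3 dispersed starts), comparing the interior
solution against explicit boundary candidates (each ratio fixed at zero,
and both). A ratio below 1e-8 is declared zero and flagged as a boundary.
When both cluster-level variances are zero the cluster autocorrelation
estimate `r_hat` is undefined; that replicate is flagged and later
excluded from `r_hat` summaries only. Non-convergence is flagged, never
silently dropped. A rank-deficient fixed-effect design (e.g. S=1, T=2,
where treatment coincides with the last-period indicator) raises an
error.

## Small-sample corrections

The Kenward-Roger adjusted covariance of the fixed effects is the
first-order form with the expected (REML) information for the variance
parameters. Because the marginal covariance is linear in
`(sigma_C^2, sigma_CP^2, sigma_e^2)`, the second-derivative terms of the
general formula vanish identically here. For the one-dimensional
treatment contrast the Kenward-Roger scale factor equals 1 and the
Kenward-Roger degrees of freedom reduce to `2 / (a' W a)` with
`a_r = c' Phi B_r Phi c / (c' Phi c)` — exactly the Satterthwaite
moment-matching ddf built from the same information. Consequently
"KR" and "Satterthwaite" inference differ only in the standard error
(adjusted vs unadjusted); both are exposed, and with no random effects
both collapse to exact OLS t-inference with residual degrees of freedom
(verified in tests). At boundary variance estimates the derivatives are
evaluated at the boundary point (no reparameterization) and the result is
flagged, matching common mixed-model software. A singular information
matrix triggers a flagged Satterthwaite fallback.

Interval conventions: the *adjusted* interval is
`theta_hat ± t_{0.975, ddf} * se_adj`. The *unadjusted* REML interval
uses the normal quantile on the model-based SE — the conventional choice
when no ddf is produced; a t-with-residual-df alternative can be obtained
via `small_sample("satterthwaite")`. For the largest design
(S=5, T=9, m=100) the pipeline's default ("auto") mode uses the
Satterthwaite ddf with the unadjusted SE instead of full KR — with 40
clusters the adjustment is negligible, and general-purpose KR
implementations become memory-hungry at 36,000 observations; this is a
selectable mode, not hard-wired.

## Bayesian estimation

The Bayesian model is parameterized by `(theta, beta, sigma_e^2, rho1,
r)` with weakly informative priors: `N(0, 10^4)` on `theta` and each
`beta_j`, half-Cauchy(0, 1) on `sigma_e^2`, `Beta(1.5, 10.5)` on `rho1`
(mode 0.05, right-skewed, little mass above 0.2) and `Beta(5, 2)` on `r`
(mode 0.8). Under the exchangeable structure `r` is fixed at 1 and
removed from sampling. The variance components are derived inside the
model by the same inversion as the generator, so the priors imply
distributions for `sigma_C^2` and `sigma_CP^2`; a prior-predictive KS
check against direct Monte Carlo transformation of prior draws is part
of the acceptance suite.

Sampling is an in-package No-U-Turn sampler (multinomial, biased
progressive sampling, dual-averaging step size with target acceptance
0.95, diagonal mass matrix adapted in a Welford window) with the log
posterior and its analytic gradient compiled with numba. Defaults are
four chains of 1000 warmup + 5000 retained iterations.

A deliberate design choice: the cluster and cluster-period effects are
**marginalized analytically** rather than sampled as latent variables
(centered or non-centered). The marginal is exact for this Gaussian
model, reduces the parameter space to `T + 3` (or `T + 4`) dimensions,
and removes the funnel geometry that latent-effect parameterizations
create — the geometry that divergent transitions diagnose. Divergences
are nevertheless tracked with the standard energy-error criterion
(threshold 1000) over post-warmup iterations, because step-size
pathologies near the `rho1 -> 0` boundary can still occur and must
invalidate the replicate. Chains are initialized uniform(-2, 2) on the
unconstrained scale (Stan-style); `rho1` and `r` are sampled on the
logit scale and `sigma_e^2` on the log scale with Jacobian corrections.

Posterior summaries use the median (robust to the skew of correlation
posteriors near their boundaries) and the 2.5th/97.5th percentiles of the
pooled post-warmup draws as the 95% credible interval. A replicate is
*valid* iff it has zero post-warmup divergences, rank-normalized split
R-hat < 1.01 for every monitored parameter (natural-scale parameters plus
the log posterior), and bulk and tail ESS >= 400 (computed via arviz).

## Performance measures

Bias, MSE, coverage of 95% intervals, average model-based SE (ModSE),
empirical SE (EmpSE) and relative % error in ModSE
(`100 (ModSE/EmpSE - 1)`), each with its Monte Carlo standard error,
following the standard simulation-study formulary (including the
variance-of-variance term in the ModSE MCSE). The identity
`MSE = bias^2 + EmpSE^2 (n-1)/n` is enforced as a test invariant. MCSE
denominators use the retained replicate count of each cell. Coverage for
the Bayesian method treats the equal-tailed credible interval as the
interval under evaluation; relative ModSE error is reported for `theta`
only (REML software provides no SEs for the correlation parameters).
Interval width — for which the study defines no scalar summary — is
reported as mean plus quartiles. Exclusion rules: invalid Bayesian
replicates are dropped from all measures; REML replicates with both
cluster-level variances at zero are dropped from `r_hat` measures only.
Each method's cells use its own retained replicate set (whether the
original analysis aligned the REML set to the Bayesian exclusions is not
documented; using per-method sets is the natural reading).

## Numerical choices and reproducibility

- Seeds: one `SeedSequence(entropy=base_seed, spawn_key=(config,
  replicate))` stream per replicate, split between simulation and
  sampling — streams never overlap across batches or workers, and any
  replicate is reproducible in isolation.
- Variance-ratio boundary threshold 1e-8; log-ratio search window
  roughly [1e-15, 3e3]; Nelder-Mead tolerances 1e-9/1e-11.
- A noise-free dataset (zero residual variance) is handled by clipping
  the profiled `sigma_e^2` away from zero; fixed effects are then exact.
- NUTS warmup split 15% fast / 75% mass window / 10% final step-size
  re-adaptation; max tree depth 10.
- The grid default `n_sim = 1000` reproduces the full study; the
  acceptance script and test suite run reduced replicate counts
  (60–1000, recorded per quantity) chosen to keep the Monte Carlo error
  small relative to the effects being verified, with shortened chains
  (4 x (500 + 1000)) for the Bayesian arms.

## Known limitations

- Only balanced standard designs; no incomplete designs, transition
  periods, cohort sampling, or unequal allocation.
- Only correctly-specified analyses; no misspecification study.
- Continuous outcomes only.
- The NUTS implementation is single-threaded and has a simplified
  (single-window) mass adaptation compared to multi-window schedules;
  for the posteriors here this is ample (diagnostics are checked per
  fit), but extremely short warmups (< 100 iterations) are not
  recommended.
- With the marginalized posterior, divergence rates are generally lower
  than a latent-variable implementation would produce; validity
  percentages are therefore conservative upper bounds when compared to
  latent-parameterization implementations, and the exclusion machinery
  is exercised mainly near the `rho1 -> 0` boundary.
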