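# Methods

## Model and estimands

One row per unit (student), nested in clusters (schools). Each unit has two
potential outcomes generated by a two-arm random-coefficient model: arm
means `beta1 + b_k1` and `beta0 + b_k0` per cluster, with
`(b_k1, b_k0) ~ N(0, Omega)`,
`Omega = [[s1^2, rho*s1*s0], [rho*s1*s0, s0^2]]`, and homoscedastic unit
errors `N(0, sigma_eps^2)` in both arms. The estimand is the population
contrast `Delta = beta1 - beta0`. Two cluster-weighting conventions are
supported: `v_k = 1` targets the unit population (the default everywhere),
`v_k = N/(n_k K)` weights clusters equally.

Identification rests on within-cluster ignorability (treatment independent
of the potential outcomes given the cluster effects) and theoretical
positivity. The empirical propensity is `pi_k = n_k1/n_k`; the unit weight
is `w = t*c/pi_k + (1-t)*(1-c)/(1-pi_k)` with `c = N1/N`, which makes the
weights sum to `n_k` in every two-arm cluster. `c` is always recomputed on
the dataset actually being fit: the trimmed sample for the trimming
estimator, and the augmented sample (pseudo-rows counted) for the augmented
estimator. With single-arm clusters present the global normalization
`sum_k v_k sum_i w_ik = N` cannot hold at `c = N1/N` and is not enforced;
only the per-cluster identity is asserted (and tested).

## Weighted likelihood engine

All estimators reduce to one computational primitive: maximum
pseudo-likelihood for the Gaussian two-arm random-coefficient model in
which unit weights act as residual precisions (`Var(e_ik) = sigma_eps^2 /
w_ik`) and cluster weights multiply each cluster's marginal log-likelihood.
This matches the weighting convention of standard mixed-model software, so
the estimators here are exactly "feed the (augmented) data and weights to a
standard fitter", realized natively.

Numerics: the fixed effects are profiled out by GLS at every
variance-component value, and the residual scale has a closed profile form
(`sigma_eps^2 = quadratic form / sum_k v_k n_k`), leaving a 3-dimensional
search over `(log s0/s_eps, log s1/s_eps, atanh rho)` — unconstrained, so no
boundary handling is needed in the optimizer itself. The search is
Nelder-Mead from a deterministic moment start (pooled within-cluster-arm
variance; between-cluster arm-mean variances; arm-mean correlation over
two-arm clusters), `fatol = 1e-8` on the log-likelihood. Transformed
parameters are capped at ±20; a fit ending on the cap is flagged
`boundary` (this occurs routinely for `rho -> ±1` under heavy violation,
where the arm-specific effects are weakly identified — the fixed effects
remain well determined). Per-cluster linear algebra uses the Woodbury
identity on the 2×2 random-effect block over precomputed weighted
cross-products, so one likelihood evaluation is O(K) after a single O(N)
pass; the engine is validated against a dense multivariate-normal oracle to
1e-8 and against an independent mixed-model implementation on unweighted
data. ML (not REML) is the criterion throughout. Estimation of
`(s0, s1, rho)` is reported but is not a formal inferential target; no
standard errors are attached to variance components.

## Correction models and augmentation

Treatment may depend on the cluster effects, so the unweighted outcome
model is corrected with the cluster treated fraction `Tbar_k`
(Mundlak-style): SATC adds `gamma1*Tbar_k` and `gamma0*Tbar_k` to the two
arms; RSATC uses a single shared `gamma` (one parameter fewer; correct when
the two covariances between treatment and the arm effects coincide). Both
are fit unweighted on the original data. For a cluster observed in one arm
only, the missing-arm prediction uses the fixed part only — the missing
arm's random-effect prediction is zero by shrinkage, and the correlated-arm
BLUP route is deliberately not used in predictions (the fitted-model form
with `Tbar_k`, not the re-centered theoretical reparameterization, is what
is estimated). Hence: all-control clusters share one predicted treated
mean, all-treated clusters share one predicted control mean.

Augmentation appends exactly one pseudo-row per violating cluster carrying
that prediction; propensities, `c`, and weights are then recomputed
treating pseudo-rows as observed, which puts every augmented propensity
strictly inside (0, 1) (`pi^a = 1/(n_k+1)` or `n_k/(n_k+1)`) and restores
the full set of estimating equations. With no violating cluster the
augmentation is skipped entirely, so the augmented estimator reduces *bit
for bit* to plain IPTW — an exact, tested invariant. Cluster weights for
the school-population estimand use observed cluster sizes, never `n_k + 1`.
Clusters of size 1 always violate and receive no special casing: they are
augmented, or dropped by trimming.

## Standard errors

- IPTW variants: cluster-robust sandwich covariance,
  `bread = sum_k v_k X_k' W_k X_k` with `W_k` the inverse fitted marginal
  covariance (including `1/w` residual precisions), and a cluster-blocked
  meat `sum_k v_k^2 (X_k'W_k r_k)(X_k'W_k r_k)'`. The meat is blocked by
  cluster — the only reading under which the robust form is nonzero at the
  solution — and the correlation terms enter as the covariance
  `rho*s1*s0` for dimensional consistency with `Omega`.
- AIPTW variants: nonparametric cluster bootstrap, default `B = 30`,
  resampling clusters with replacement (fresh labels keep repeated clusters
  distinct) and rerunning the *full* pipeline — propensities, `c`,
  correction fit, augmentation, weighted fit — on every resample. Resamples
  without any treatment variation are redrawn (more than 50 consecutive
  redraws is an error). Resample refits warm-start at the full-sample
  solutions, which changes nothing statistically (same objective, same
  convergence tolerance) and roughly halves the cost.
- Intervals are normal-quantile (`±1.96` at 95%); no small-sample t
  correction, appropriate at the 150–200 clusters of the study designs.

## Simulation engine

The generator reproduces the two study designs: K clusters, sizes uniform
on `{lo..hi}`, cluster effects from `Omega`, and treatment assigned by the
sign of a latent probit index
`g = c1 + c2*b_k0 + c3*b_k1 + c4*zeta_k + xi_ik` with standard-normal
`zeta_k` (cluster) and `xi_ik` (unit). The coefficients are calibrated, not
set: given targets `(p, r0, r1)` — treated fraction and the two
treatment–effect correlations — `c1, c2, c3` follow in closed form from
normal moment identities at any latent scale `s = sd(g)` (`p = Phi(c1/s)`;
`cov(T, b_k0) = phi(c1/s)(c2 s0^2 + c3 rho s0 s1)/s` by Stein's identity),
and the remaining scale is fixed by a bracketed 1-D root-find so the
expected fraction of single-arm clusters (Gauss-Hermite quadrature over the
cluster latent, averaged over the size law) hits the violation target. The
calibration is fully deterministic, matches `(p, r0, r1)` exactly and the
violation fraction to the `brentq` tolerance; a Monte Carlo oracle verifies
all four to 0.01 in the tests. Infeasible target combinations (the
correlations can demand more latent variance than the cluster effects
provide, or a violation fraction below the zero-`c4` floor) raise an error
reporting the best reachable value.

Shipped presets: the first design (K=150, sizes 1–19, `beta=(35,40)`,
`s0=s1=8`, `rho=0.8`, `sigma_eps=45`, `p=0.3`, `r0=r1=0.4`) at 26% and 80%
violation, and the second design (K=200, sizes 1–49, `beta=(12,15)`,
`sigma_eps=35`, `p=0.3`, 80% violation) over the `(r0, r1, rho)` grid of
the benchmark tables. One source text for the first design states `p=0.8`
in a table caption against `p=0.3` in the body; the body value is used (the
`p=0.8` variant reproduces none of the published metrics, which was checked
explicitly). Sizes are drawn independently of the cluster effects. Each
replicate uses an independent child stream spawned from the master seed, so
any single replicate is reproducible in isolation.

What the generator does *not* emulate: unit-level confounders (assignment
depends on units only through independent noise, so within-cluster
ignorability holds by construction), non-Gaussian outcomes,
heteroscedasticity across arms, more than two levels of nesting, and any
dependence of cluster size on cluster effects. Passing tests therefore
demonstrate correct behavior under the stated generative model, not
robustness to its violations.

## Monte Carlo harness and problem sizes

Metrics per estimator and parameter: percentage bias
`pb = mean(est - truth)/truth` reported on the fraction scale (0.010 =
1%), mean estimated SE, empirical SD of estimates (denominator R−1), and
empirical coverage of nominal 95% intervals. `Delta` metrics are included
as extra output beyond the benchmark grids, since the contrast is the
estimand. Replicates that fail to fit are dropped (never retried, keeping
the seed-to-result map pure) and counted, with a 2% validity cap per
method.

The shipped acceptance checks run at desk scale: 300 replicates for
point-estimate metrics, 150 for the bootstrap-bearing coverage check
(tolerance widened accordingly), and 1500 for the cheap closed-form-SE
coverage check, where the coverage of a biased estimator converges slowly
and two fits per replicate make extra replicates nearly free. The full
published grids used 1000 replicates; `reproduce_table(..., R=1000)`
reruns at that scale.

## Design choices and limitations

- Estimators consume one explicit weight set stored alongside the data
  rather than recomputing weights inside fitters.
- The trimmed estimator recomputes `pi_k`, `N1`, `N`, `c` on the trimmed
  sample — the sample it targets — so its weights normalize internally.
- The nonparametric contrast averages `(1/K) sum v_k d_k` with plain
  (unweighted) within-cluster arm means, and carries only `Delta`.
- Whether the bootstrap should refit the correction model inside each
  resample is an open design point; the conservative full-pipeline refit is
  implemented.
- Variance-component point estimates under weighting are pseudo-likelihood
  quantities: the treated-arm SD is systematically understated and `rho`
  noisy under heavy violation (visible in the benchmark grids themselves);
  they should not be used for formal inference.
- No covariates beyond (cluster, treatment, outcome) are supported; no
  generalized outcomes; no model-based propensity estimation.
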