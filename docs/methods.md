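# Methods

## Model

Observations at location *i* are exchangeable given that location's
parameters: `Y_{i,1:m_i} | θ_i, φ(u_i, v_i)` iid from a GLM family.  Two
families are implemented behind one interface:

* **negative binomial**, log link: mean `μ = exp(offset + xφ)`, variance
  `μ + θμ²`.  θ is the *reciprocal* of the common "size" convention
  (size r = 1/θ); θ → 0 recovers the Poisson.  This parameterization is
  deliberate and documented because silently mixing the two conventions is
  the classic dispersion bug.  The offset (log exposure) enters additively
  on the linear predictor.
* **gaussian**, identity link: θ is the standard deviation.

The coefficient field φ(u, v) is assumed spatially smooth; the dispersions
θ_i are local nuisance parameters with no smoothness assumption.  Using
neighbouring data to estimate φ at a centre therefore introduces controlled
misspecification, which is tempered by weighting each neighbour's
log-likelihood with a Gaussian kernel of the geographic distance.

## Target density

For a centre *c*, inference runs on the augmented parameter
`ψ = (θ_c, θ̃ over active neighbours, φ)` with unnormalized log-density

    log π(ψ) + log p(Y_c | θ_c, φ) + Σ_{i≠c} W(d_i, η) log p(Y_i | θ̃_i, φ).

Marginalizing the auxiliary dispersions θ̃ yields exactly the posterior of
interest for (θ_c, φ), so the sampler simply discards the θ̃ draws; the
per-location conditional factors of the full semi-modular decomposition are
never materialized.  Zero-weight locations contribute a constant factor and
are dropped from the augmented state entirely — the one operation that
needs the full untruncated support, the truncation diagnostic, states that
precondition explicitly.

Limits: all non-centre weights 0 gives the centre's own single-location
posterior (feedback fully cut); all weights 1 gives the standard pooled
joint posterior.  Both identities are verified as tests.

## Priors

The paper-level model leaves prior forms open, so the package defaults are
weakly informative and strictly proper (propriety is required for the
powered posterior to normalize):

| parameter | prior | default |
| --- | --- | --- |
| each coefficient φ_k | Normal(0, `phi_sd`²) | `phi_sd = 10` |
| θ and each θ̃ | LogNormal(`log_theta_mean`, `log_theta_sd`²) | (0, 1) |

All three hyperparameters are configurable everywhere (estimator arguments,
`prior.*` config keys).

## Kernels and distances

* Gaussian kernel `W(d, η) = exp(−d²/η²)`; truncated variant sets the
  weight to exactly 0 unless it *strictly exceeds* the threshold W*
  (default 0.01).  Truncation bounds the per-iteration likelihood cost at
  `O(m × n(W*))`, with `n(W*)` the active-location count.
* Distances: planar Euclidean, or haversine great-circle distance with
  coordinates as (longitude, latitude) in decimal degrees and Earth radius
  6371 km (mean radius; the radius is configurable).  Distances and the
  bandwidth must share units — the package never converts units.
* The truncation error diagnostic reports the percentage change of the
  **log** powered posterior between the full and truncated kernels over a
  set of draws.  Operationalizing the percentage on the log-density (rather
  than the density or a downstream estimate) is a package choice; the
  diagnostic is exactly 0 at W* = 0 and non-decreasing in W*.

## Sampler

Adaptive random-walk Metropolis on the augmented space:

* **φ block**: joint multivariate-normal proposal.  The proposal covariance
  starts at the inverse expected information of the weighted likelihood
  (plus prior precision) — a one-time matrix solve that puts the walk at
  the right scale immediately — and is replaced during burn-in by the
  empirical draw covariance scaled by 2.38²/p (recomputed every 25
  iterations), with a global scale tuned by Robbins–Monro toward 0.234
  acceptance.
* **dispersions**: θ_c and every θ̃ are updated componentwise on the log
  scale (lognormal prior becomes a normal density in log θ, Jacobian
  included).  Because the θ̃ are conditionally independent given φ, all are
  proposed simultaneously and accepted/rejected per location from one
  vectorized likelihood sweep; step sizes adapt toward 0.44 acceptance.
* Adaptation is frozen at the end of burn-in, so retained draws come from a
  fixed kernel.  Defaults: 10 chains, 3000 retained draws each, 1000
  burn-in.
* **Initialization** (`init="moment"`, default): φ from a weighted least
  squares fit of log(y + ½) − offset on X (y itself for the Gaussian), θ
  from a method-of-moments estimate at the centre, clipped to [0.05, 20].
  Deterministic and cheap; with short burn-in budgets a random walk started
  at φ = 0 cannot reliably traverse to the mode, so the moment start is the
  default rather than zero.  `init="zero"` and explicit `phi_init` /
  `log_theta_init` overrides are available.
* **Reproducibility**: each (location, chain) pair draws from its own
  stream seeded by `(seed, crc32(location id), chain)`; auxiliary locations
  are ordered by sorted id.  Results are therefore bitwise reproducible and
  invariant to location order and to parallel scheduling (`joblib` across
  locations, never within a chain).
* Numerical details: the negative binomial is computed entirely in log
  space via log-gamma (no factorial overflow); inside the sampler the
  row-array log-gamma uses a five-term Stirling expansion for arguments
  ≥ 10 (relative error < 1e-11, one fixed target density) and the exact
  function below.  Proposal-density asymmetries do not arise (all proposals
  are symmetric in the sampled coordinates).

Per-parameter split-R̂ and effective sample size come from `arviz`;
credible intervals are empirical 2.5%/97.5% quantiles with linear
interpolation between order statistics (the rule is fixed so summaries are
bit-stable).  R̂ of exactly constant chains is reported as 1 by convention;
a single chain yields R̂ = NaN with a warning.

## Bandwidth selection

For each candidate η and each fold, a random `holdout_fraction` (default
0.5, one fold) of the rows at every interest location is held out — the
same split for every candidate, so candidates are compared on identical
data.  The model centred at location *i* trains on the full dataset minus
*i*'s held-out rows only, and the elpd of those rows is estimated from the
pooled post-burn-in draws by

    elpd ≈ (1/n_test) Σ_j [ logsumexp_s log p(y_j | ψ^(s)) − log S ],

(per-chain estimates are recorded alongside to expose between-chain
spread).  The selected bandwidth maximizes the across-location mean of the
pooled estimates, averaged over folds; ties break toward the smallest
candidate.  `eval_location_ids` restricts the mean to a subset of interest
locations for scaled-down runs; because the selection rule is defined as a
mean over *all* locations, any use of a subset is flagged in the output.

## Synthetic data

`simulate_lattice` generates the lattice benchmark: locations at integer
coordinates 1..g × 1..g (Euclidean distance in lattice units), coefficient
surfaces

    φ0 = 3,   φ1(u,v) = 0.1 + 0.01·√(u²+v²),
    φ2(u) = 0.05·(sin(π/2 + πu/20) + cos(π/2 + πu/20) + 4),

dispersion θ(u,v) ~ N(0.5, 0.01²) independently per location (non-positive
draws redrawn), covariates X1 = 1, X2 ~ U(0,10), X3 ~ U(2,7) redrawn
independently for every observation, and negative binomial outcomes via the
gamma–Poisson mixture.  Defaults are the full benchmark scale: 40 × 40
locations, m = 100.  Two generator readings deserve a note:

* The φ1 surface is read as the smooth radial trend `0.1 + 0.01·√(u²+v²)`.
  The alternative reading `0.1 + 0.01u² + v²` produces coefficients in the
  hundreds, which would overflow `exp(Xφ)` and contradict the smoothness the
  benchmark is built to exhibit; it is rejected.
* Covariates are drawn per observation (iid), the standard reading of
  uniform covariate sampling.

What the generator does *not* emulate: real surveillance data have
temporal structure, reporting artefacts, unequal and correlated exposures,
and non-lattice geography.  Passing the lattice tests demonstrates correct
inference under the stated model, not robustness to those features.

## Study scale

The headline study (`bgwr.studies.bandwidth_recovery_study`,
`scripts/acceptance.py`) runs the benchmark at 15 × 15 locations with
m = 50, candidates {0.0001, 2, 4, 10, 1000}, 50% holdout, 2 chains × 1500
retained draws (500 burn-in), the elpd mean over a seeded subset of 40
interest locations, and three seed replicates with majority vote.  These
sizes keep a full replicate around five minutes on one CPU while leaving
the elpd curve's interior maximum resolvable.  At this reduced scale the
elpd difference between neighbouring interior candidates (2 vs 4) is small
— a genuinely flat optimum — which is why the study reports the majority
over three replicates rather than a single run.

## Known limitations

* One bandwidth for the whole map and all coefficients; no
  spatially-varying or per-coefficient bandwidths.
* Prediction is only available at fitted sampling locations (a centre that
  is not a sampling location would require sampling the per-location
  conditional factors, which the package deliberately never materializes).
* No Hamiltonian/NUTS sampling and no marginal-likelihood estimation.
* elpd is estimated by held-out cross-validation only (no PSIS-LOO/WAIC).
* Beta regression (another family with a local nuisance parameter) is not
  implemented, but the family interface accommodates it.
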