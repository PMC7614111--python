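# bgwr — Bayesian geographically weighted regression

`bgwr` fits generalized linear models whose regression coefficients vary
smoothly over geographic space, for settings — disease surveillance counts
across countries, environmental rates across monitoring stations — where a
single global regression is misspecified but each location alone has too few
observations for a stable local fit.

## The model

At each sampling location *i* with coordinates *(uᵢ, vᵢ)* we observe
outcomes *Y*ᵢ,₁:ₘ with covariates *X* and an optional exposure offset.  The
default family is the negative binomial with log link,

&nbsp;&nbsp;E(Y) = μ = exp(offset + Xφ(u, v)),&nbsp;&nbsp; Var(Y) = μ + θμ²,

where the coefficient field φ(u, v) is spatially smooth while the local
dispersion θᵢ is similar across locations but *not* smooth (a Gaussian
family with θ the standard deviation is also supported).  Inference for a
centre location *c* targets the **geographically-powered posterior**: each
neighbouring location's likelihood enters raised to a kernel weight

&nbsp;&nbsp;p(ψ | Y) ∝ π(ψ) · p(Y_c | θ_c, φ) · ∏ᵢ≠c p(Yᵢ | θ̃ᵢ, φ)^W(dᵢ, η),
&nbsp;&nbsp;W(d, η) = exp(−d²/η²),

with an auxiliary copy θ̃ᵢ of each neighbour's dispersion so that the
weighting only tempers what the neighbours say about the shared coefficients
φ.  The bandwidth η interpolates between two familiar extremes: η → 0 cuts
all feedback from the neighbours (a per-location fit), η → ∞ recovers the
standard pooled posterior.  A truncated kernel (weights that do not exceed a
threshold W* are set to zero) bounds the number of likelihood terms.

The bandwidth is chosen by held-out cross-validation: for each candidate η,
every location's model is refitted with a share of that location's own
observations held out, the expected log pointwise predictive density (elpd)
of the held-out rows is estimated from the posterior draws, and the η
maximizing the mean elpd across locations wins.

Sampling is adaptive random-walk Metropolis: a joint multivariate-normal
proposal on φ (covariance adapted during burn-in) and componentwise
log-scale updates for every dispersion, vectorized across locations.

## Worked example

```python
import pandas as pd
from bgwr import SimulationSpec, simulate_lattice, BayesianGWR

# 5x5 lattice, 30 negative-binomial observations per location
ds, truth = simulate_lattice(SimulationSpec(grid_u=5, grid_v=5, m=30, seed=7))
X = ds.to_frame(); y = X.pop("y")

model = BayesianGWR(bandwidth=4.0, n_chains=2, n_iterations=1000,
                    burn_in=500, seed=7)
model.fit(X, y)
s = model.summary_
print(s[s.location_id == "3_3"].round(3).to_string(index=False))
```

```
location_id parameter  mean  median  ci_lower  ci_upper  rhat     ess
        3_3     theta 0.559   0.541     0.323     0.886 1.005 440.859
        3_3     phi_1 2.933   2.937     2.693     3.182 1.007 165.975
        3_3     phi_2 0.145   0.146     0.126     0.164 1.004 218.339
        3_3     phi_3 0.220   0.221     0.175     0.268 1.001 140.257
```

The posterior medians and 95% credible intervals at location (3, 3) recover
the simulation truth there — intercept 3.0, covariate effects 0.142 and
0.222, dispersion 0.502 — with every R̂ near 1.  `BandwidthSearchCV` wraps
the cross-validated bandwidth selection with the same estimator interface,
and the `bgwr` command line (`simulate`, `select-bandwidth`, `fit`,
`summarize`, `run`) drives the full workflow from CSV files; for real
surveillance data use `metric="haversine"` (coordinates as longitude and
latitude in degrees, distances and bandwidths in kilometres) and put the log
of the exposure (e.g. number of tests) in the `offset` column.

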