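"""scikit-learn style estimators wrapping the powered-posterior machinery.

:class:`BayesianGWR` fits one independent powered-posterior model per
location (centre = that location) at a fixed geographical bandwidth;
:class:`BandwidthSearchCV` selects the bandwidth by cross-validated elpd and
optionally refits at the winner.  Both follow the sklearn contract
(``get_params``/``set_params``, fitted attributes with trailing underscores,
``fit``/``predict``) so they compose with sklearn tooling; the long-format
input is a DataFrame with columns ``location_id, u, v``, the covariates and
an optional ``offset``, plus the outcome vector ``y``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .dataset import SpatialDataset, dataset_from_frame
from .elpd import CVConfig, estimate_elpd, run_bandwidth_cv, select_bandwidth
from .families import PriorSpec, get_family
from .kernels import EARTH_RADIUS_KM, KernelSpec
from .mcmc import MCMCConfig, fit_all_locations, summarize_chains

__all__ = ["BayesianGWR", "BandwidthSearchCV"]


def _as_dataset(X, y, family, metric) -> SpatialDataset:
    if isinstance(X, SpatialDataset):
        return X
    df = pd.DataFrame(X).copy()
    if y is not None:
        df["y"] = np.asarray(y)
    return dataset_from_frame(df, metric=metric, family=family)


class BayesianGWR(RegressorMixin, BaseEstimator):
    """Geographically weighted GLM with per-location powered posteriors.

    Parameters
    ----------
    bandwidth : float
        Geographical kernel bandwidth (same units as the distance metric).
    kernel : {"truncated_gaussian", "gaussian"}
    threshold : float
        Truncation level W* in [0, 1) for the truncated kernel.
    metric : {"euclidean", "haversine"}
    family : {"negative_binomial", "gaussian"}
    phi_sd, log_theta_mean, log_theta_sd : float
        Prior hyperparameters (normal on coefficients, lognormal on the
        dispersion and each auxiliary dispersion).
    n_chains, n_iterations, burn_in, seed : int
        MCMC settings; ``n_iterations`` counts retained draws per chain.
    fix_theta : float or None
        Clamp the dispersion (Gaussian sd) to a known value.
    init : {"moment", "zero"}
        Starting-point strategy.
    n_jobs : int
        Locations are fitted independently and may run in parallel.

    Attributes
    ----------
    results_ : dict[str, ChainResult]
        Per-location MCMC output.
    summary_ : pandas.DataFrame
        Per-location, per-parameter posterior summaries.
    dataset_ : SpatialDataset
        The training data in grouped form.
    """

    def __init__(
        self,
        bandwidth: float = 4.0,
        kernel: str = "truncated_gaussian",
        threshold: float = 0.01,
        metric: str = "euclidean",
        earth_radius: float = EARTH_RADIUS_KM,
        family: str = "negative_binomial",
        phi_sd: float = 10.0,
        log_theta_mean: float = 0.0,
        log_theta_sd: float = 1.0,
        n_chains: int = 10,
        n_iterations: int = 3000,
        burn_in: int = 1000,
        seed: int = 0,
        fix_theta: float | None = None,
        init: str = "moment",
        n_jobs: int = 1,
    ):
        self.bandwidth = bandwidth
        self.kernel = kernel
        self.threshold = threshold
        self.metric = metric
        self.earth_radius = earth_radius
        self.family = family
        self.phi_sd = phi_sd
        self.log_theta_mean = log_theta_mean
        self.log_theta_sd = log_theta_sd
        self.n_chains = n_chains
        self.n_iterations = n_iterations
        self.burn_in = burn_in
        self.seed = seed
        self.fix_theta = fix_theta
        self.init = init
        self.n_jobs = n_jobs

    # -- config assembly -------------------------------------------------
    def _kernel_spec(self) -> KernelSpec:
        return KernelSpec(
            family=self.kernel,
            bandwidth=self.bandwidth,
            threshold=self.threshold,
            metric=self.metric,
            earth_radius=self.earth_radius,
        )

    def _prior(self) -> PriorSpec:
        return PriorSpec(self.phi_sd, self.log_theta_mean, self.log_theta_sd)

    def _mcmc_config(self) -> MCMCConfig:
        return MCMCConfig(
            n_chains=self.n_chains,
            n_iterations=self.n_iterations,
            burn_in=self.burn_in,
            seed=self.seed,
            fix_theta=self.fix_theta,
            init=self.init,
        )

    def fit(self, X, y=None, location_ids=None):
        ds = _as_dataset(X, y, self.family, self.metric)
        self.dataset_ = ds
        self.results_ = fit_all_locations(
            ds,
            self._kernel_spec(),
            self.family,
            self._prior(),
            self._mcmc_config(),
            location_ids=location_ids,
            n_jobs=self.n_jobs,
        )
        frames = []
        for lid, res in self.results_.items():
            s = summarize_chains(res).reset_index()
            s.insert(0, "location_id", lid)
            frames.append(s)
        self.summary_ = pd.concat(frames, ignore_index=True)
        return self

    def _check_fitted(self):
        if not hasattr(self, "results_"):
            raise AttributeError("estimator is not fitted; call fit first")

    def posterior_mean(self, location_id: str) -> np.ndarray:
        """Posterior mean of (theta, phi...) at a fitted location."""
        self._check_fitted()
        return self.results_[location_id].pooled().mean(axis=0)

    def predict(self, X):
        """Posterior-mean response for rows at fitted locations."""
        self._check_fitted()
        df = pd.DataFrame(X)
        fam = get_family(self.family)
        cov_names = self.dataset_.covariate_names
        out = np.empty(len(df))
        for i, (_, row) in enumerate(df.iterrows()):
            lid = str(row["location_id"])
            if lid not in self.results_:
                raise KeyError(f"location {lid!r} was not seen during fit")
            draws = self.results_[lid].pooled()
            x = row[cov_names].to_numpy(dtype=float)
            off = float(row.get("offset", 0.0))
            eta = off + draws[:, 1:] @ x
            mu, _ = fam.moments(eta, 1.0)  # mean does not involve theta
            out[i] = float(np.mean(mu))
        return out

    def score(self, X, y):
        """Mean elpd of the provided rows under the fitted posteriors."""
        self._check_fitted()
        ds = _as_dataset(X, y, self.family, self.metric)
        vals = []
        for lid in ds.location_ids:
            draws = self.results_[lid].pooled()
            vals.append(
                estimate_elpd(
                    ds.outcomes[lid], ds.covariates[lid], draws, self.family, ds.offsets[lid]
                )
            )
        return float(np.mean(vals))


class BandwidthSearchCV(BaseEstimator):
    """Bandwidth selection by cross-validated mean elpd.

    Holds out ``holdout_fraction`` of each interest location's rows, fits the
    location's model on the remainder (other locations untouched), scores the
    held-out rows, and picks the candidate maximizing the mean elpd across
    locations (folds averaged, ties toward the smallest candidate).

    Attributes: ``best_bandwidth_``, ``curve_``, ``elpd_table_``,
    ``tie_broken_``, and ``best_estimator_`` (when ``refit=True``).
    """

    def __init__(
        self,
        estimator: BayesianGWR | None = None,
        candidates=(0.0001, 2.0, 4.0, 6.0, 8.0, 10.0, 20.0, 40.0, 1000.0),
        holdout_fraction: float = 0.5,
        folds: int = 1,
        eval_location_ids=None,
        seed: int = 0,
        refit: bool = False,
    ):
        self.estimator = estimator
        self.candidates = candidates
        self.holdout_fraction = holdout_fraction
        self.folds = folds
        self.eval_location_ids = eval_location_ids
        self.seed = seed
        self.refit = refit

    def fit(self, X, y=None):
        est = self.estimator if self.estimator is not None else BayesianGWR()
        ds = _as_dataset(X, y, est.family, est.metric)
        cv = CVConfig(
            candidates=tuple(float(c) for c in self.candidates),
            holdout_fraction=self.holdout_fraction,
            folds=self.folds,
            eval_location_ids=(
                tuple(self.eval_location_ids) if self.eval_location_ids is not None else None
            ),
            seed=self.seed,
            mcmc=est._mcmc_config(),
        )
        template = KernelSpec(
            family=est.kernel,
            bandwidth=None,
            threshold=est.threshold,
            metric=est.metric,
            earth_radius=est.earth_radius,
        )
        table = run_bandwidth_cv(ds, template, est.family, est._prior(), cv)
        result = select_bandwidth(table)
        self.elpd_table_ = table
        self.curve_ = result.curve
        self.best_bandwidth_ = result.selected
        self.tie_broken_ = result.tie_broken
        if self.refit:
            self.best_estimator_ = BayesianGWR(**{**est.get_params(), "bandwidth": result.selected})
            self.best_estimator_.fit(ds)
        return self
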