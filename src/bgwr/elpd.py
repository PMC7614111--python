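"""Cross-validated elpd estimation and geographical bandwidth selection.

The predictive quality of a fit centred at location *i* is measured by the
expected log pointwise predictive density (elpd) of held-out observations at
that location, approximated from posterior draws by

    elpd_hat = (1 / n_test) * sum_j log( S^-1 * sum_s p(y_j | theta^(s), phi^(s)) )

with the inner average computed through log-sum-exp for numerical safety.
The bandwidth is chosen by holding out a random share of the observations at
every interest location, fitting each location's model on the remaining data
(held-out rows are removed only at that location), and maximizing the mean
elpd across locations; ties break toward the smallest candidate.  Held-out
splits are drawn once per fold so all candidate bandwidths are compared on
identical splits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .dataset import SpatialDataset
from .families import PriorSpec, get_family
from .kernels import KernelSpec, compute_weight_vector
from .mcmc import MCMCConfig, sample_powered_posterior
from .posterior import PoweredPosteriorProblem

__all__ = [
    "CVConfig",
    "ElpdTable",
    "BandwidthResult",
    "estimate_elpd",
    "elpd_from_log_densities",
    "run_bandwidth_cv",
    "select_bandwidth",
]


@dataclass(frozen=True)
class CVConfig:
    """Bandwidth cross-validation settings.

    ``holdout_fraction`` is the share of each interest location's
    observations placed in the test set; every location must retain at least
    one training and one test observation.  ``eval_location_ids`` restricts
    the across-location mean to a subset (for scaled-down runs); when used,
    the resulting table is flagged, since the selection rule is defined as a
    mean over all sampling locations.
    """

    candidates: tuple[float, ...] = (0.0001, 2.0, 4.0, 6.0, 8.0, 10.0, 20.0, 40.0, 1000.0)
    holdout_fraction: float = 0.5
    folds: int = 1
    eval_location_ids: tuple[str, ...] | None = None
    seed: int = 0
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)

    def __post_init__(self) -> None:
        if not self.candidates:
            raise ValueError("candidates must be nonempty")
        if any(not c > 0 for c in self.candidates):
            raise ValueError("candidate bandwidths must be > 0")
        if not 0.0 < self.holdout_fraction < 1.0:
            raise ValueError("holdout_fraction must lie in (0, 1)")
        if self.folds < 1:
            raise ValueError("folds must be >= 1")


@dataclass
class ElpdTable:
    """Per-(location, bandwidth, fold) elpd estimates and the mean curve."""

    entries: pd.DataFrame  # columns: location_id, eta, fold, chain, elpd
    mean_curve: dict[float, float]
    eval_subset_used: bool = False
    posterior_means: pd.DataFrame | None = None


@dataclass
class BandwidthResult:
    selected: float
    curve: dict[float, float]
    tie_broken: bool = False


def elpd_from_log_densities(log_dens: np.ndarray) -> float:
    """elpd estimate from an (S draws, n_test) matrix of log-densities."""
    log_dens = np.atleast_2d(np.asarray(log_dens, dtype=float))
    S = log_dens.shape[0]
    with np.errstate(divide="ignore"):
        per_point = logsumexp(log_dens, axis=0) - np.log(S)
    if np.any(np.isneginf(per_point)):
        warnings.warn(
            "every draw assigned zero density to at least one test point; elpd is -inf",
            RuntimeWarning,
            stacklevel=2,
        )
    return float(np.mean(per_point))


def _log_pred_matrix(test_y, test_X, test_offset, draws, family) -> np.ndarray:
    """(S, n_test) log predictive densities; draws columns are (theta, phi...)."""
    family = get_family(family)
    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    test_y = np.asarray(test_y, dtype=float)
    test_X = np.atleast_2d(np.asarray(test_X, dtype=float))
    if test_offset is None:
        test_offset = np.zeros(test_y.shape[0])
    theta = draws[:, 0][:, None]  # (S, 1)
    eta = np.asarray(test_offset)[None, :] + draws[:, 1:] @ test_X.T  # (S, n_test)
    return family.log_density(test_y[None, :], eta, theta)


def estimate_elpd(test_y, test_X, draws, family, test_offset=None) -> float:
    """Monte-Carlo elpd of held-out rows under posterior draws.

    Invariant to permutations of draws and of test rows; finite unless every
    draw assigns zero density to some test point.
    """
    test_y = np.asarray(test_y, dtype=float)
    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    if test_y.size == 0:
        raise ValueError("test set must be nonempty")
    if draws.size == 0:
        raise ValueError("draws must be nonempty")
    return elpd_from_log_densities(_log_pred_matrix(test_y, test_X, test_offset, draws, family))


def _holdout_indices(ds: SpatialDataset, ids, fraction: float, rng: np.random.Generator):
    """Per-location (train_idx, test_idx); at least 1 row on each side."""
    split = {}
    for lid in ids:
        m = ds.m(lid)
        n_test = int(round(m * fraction))
        n_test = min(max(n_test, 1), m - 1)
        if m < 2:
            raise ValueError(f"location {lid!r}: holdout infeasible with m={m}")
        perm = rng.permutation(m)
        split[lid] = (np.sort(perm[n_test:]), np.sort(perm[:n_test]))
    return split


def run_bandwidth_cv(
    ds: SpatialDataset,
    spec_template: KernelSpec,
    family,
    prior: PriorSpec,
    cv: CVConfig,
    collect_posterior_means: bool = False,
) -> ElpdTable:
    """Cross-validated elpd for every candidate bandwidth.

    For each fold a random ``holdout_fraction`` of rows is held out at every
    interest location (the same split for all candidates).  For candidate
    ``eta`` and interest location *i*, the model centred at *i* is fitted on
    the full data minus location *i*'s held-out rows, and elpd is estimated
    on those held-out rows from the pooled post-burn-in draws (per-chain
    estimates are recorded alongside).  The mean curve averages pooled
    estimates across locations, then across folds.
    """
    family = get_family(family)
    ids = list(cv.eval_location_ids) if cv.eval_location_ids is not None else ds.location_ids
    subset_used = cv.eval_location_ids is not None
    if subset_used:
        unknown = set(ids) - set(ds.location_ids)
        if unknown:
            raise KeyError(f"eval_location_ids not in dataset: {sorted(unknown)}")
        warnings.warn(
            "elpd mean taken over a subset of locations; the selection rule is "
            "defined as the mean over all sampling locations",
            UserWarning,
            stacklevel=2,
        )

    records = []
    pm_records = []
    for fold in range(cv.folds):
        rng = np.random.default_rng(np.random.SeedSequence((cv.seed, fold)))
        split = _holdout_indices(ds, ids, cv.holdout_fraction, rng)
        for ci, eta in enumerate(cv.candidates):
            spec = spec_template.with_bandwidth(eta)
            for lid in ids:
                train_idx, test_idx = split[lid]
                train_ds = ds.replace_location_rows(lid, train_idx)
                wv = compute_weight_vector(train_ds, lid, spec)
                prob = PoweredPosteriorProblem(train_ds, lid, wv, family, prior)
                res = sample_powered_posterior(prob, cv.mcmc, extra_entropy=(ci, fold))
                test_y = ds.outcomes[lid][test_idx]
                test_X = ds.covariates[lid][test_idx]
                test_off = ds.offsets[lid][test_idx]
                pooled = res.pooled()
                records.append(
                    {
                        "location_id": lid,
                        "eta": eta,
                        "fold": fold,
                        "chain": "pooled",
                        "elpd": estimate_elpd(test_y, test_X, pooled, family, test_off),
                    }
                )
                for c in range(res.n_chains):
                    records.append(
                        {
                            "location_id": lid,
                            "eta": eta,
                            "fold": fold,
                            "chain": c,
                            "elpd": estimate_elpd(test_y, test_X, res.draws[c], family, test_off),
                        }
                    )
                if collect_posterior_means:
                    means = pooled.mean(axis=0)
                    rec = {"location_id": lid, "eta": eta, "fold": fold, "theta": means[0]}
                    for j in range(1, means.shape[0]):
                        rec[f"phi_{j}"] = means[j]
                    pm_records.append(rec)

    entries = pd.DataFrame.from_records(records)
    pooled_rows = entries[entries["chain"] == "pooled"]
    by_fold = pooled_rows.groupby(["eta", "fold"])["elpd"].mean()
    mean_curve = {float(eta): float(v) for eta, v in by_fold.groupby("eta").mean().items()}
    return ElpdTable(
        entries=entries,
        mean_curve=mean_curve,
        eval_subset_used=subset_used,
        posterior_means=pd.DataFrame.from_records(pm_records) if collect_posterior_means else None,
    )


def select_bandwidth(table: ElpdTable) -> BandwidthResult:
    """Argmax of the mean elpd curve; ties break toward the smallest eta."""
    if not table.mean_curve:
        raise ValueError("elpd table is empty")
    best = max(table.mean_curve.values())
    winners = sorted(eta for eta, v in table.mean_curve.items() if v == best)
    return BandwidthResult(
        selected=winners[0],
        curve=dict(table.mean_curve),
        tie_broken=len(winners) > 1,
    )
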