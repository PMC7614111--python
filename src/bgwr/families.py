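"""GLM families (negative binomial with log link, Gaussian) and priors.

The negative binomial is parameterized by its mean ``mu = exp(offset + x.phi)``
and local dispersion ``theta > 0`` so that ``Var(Y) = mu + theta * mu^2``.
Note this is the *reciprocal* of the "size" convention used by many software
packages (size r = 1/theta); with this convention theta -> 0 recovers the
Poisson.  For the Gaussian family ``theta`` is the standard deviation and the
link is the identity.

Priors: independent zero-mean normals on each regression coefficient and a
lognormal on every dispersion (theta and each auxiliary theta-tilde).  Both
are proper, which the powered posterior requires for normalizability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = [
    "GLMFamily",
    "NegativeBinomial",
    "Gaussian",
    "get_family",
    "ParameterState",
    "PriorSpec",
    "nb_log_density",
    "nb_moments",
    "gaussian_log_density",
    "log_prior",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the independent prior.

    phi_sd
        Standard deviation of the N(0, phi_sd^2) prior on each coefficient.
    log_theta_mean, log_theta_sd
        Parameters of the LogNormal prior on theta and each theta-tilde
        (equivalently, of the normal prior on log theta).
    """

    phi_sd: float = 10.0
    log_theta_mean: float = 0.0
    log_theta_sd: float = 1.0

    def __post_init__(self) -> None:
        if not (self.phi_sd > 0 and self.log_theta_sd > 0):
            raise ValueError("prior scales must be > 0")

    def log_phi_prior(self, phi: np.ndarray) -> float:
        phi = np.asarray(phi, dtype=float)
        return float(
            np.sum(-0.5 * _LOG_2PI - math.log(self.phi_sd) - 0.5 * (phi / self.phi_sd) ** 2)
        )

    def log_theta_prior(self, theta) -> float:
        """Lognormal log-density, summed over entries of ``theta``."""
        theta = np.asarray(theta, dtype=float)
        if np.any(theta <= 0):
            raise ValueError("theta must be > 0")
        z = (np.log(theta) - self.log_theta_mean) / self.log_theta_sd
        return float(
            np.sum(
                -0.5 * _LOG_2PI - math.log(self.log_theta_sd) - np.log(theta) - 0.5 * z**2
            )
        )

    def log_logtheta_prior(self, log_theta) -> float:
        """Normal log-density of log(theta) — the lognormal after the log
        change of variables (Jacobian included)."""
        z = (np.asarray(log_theta, dtype=float) - self.log_theta_mean) / self.log_theta_sd
        return float(np.sum(-0.5 * _LOG_2PI - math.log(self.log_theta_sd) - 0.5 * z**2))


@dataclass
class ParameterState:
    """Augmented parameter (theta_center, theta-tilde over active neighbours, phi)."""

    theta_center: float
    phi: np.ndarray
    theta_aux: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        if not self.theta_center > 0:
            raise ValueError("theta_center must be > 0")
        for lid, th in self.theta_aux.items():
            if not th > 0:
                raise ValueError(f"theta_aux[{lid!r}] must be > 0")
        if not np.all(np.isfinite(self.phi)):
            raise ValueError("phi must be finite")


class GLMFamily:
    """Interface shared by the outcome families."""

    name: str
    link: str

    def log_density(self, y: np.ndarray, eta: np.ndarray, theta: float | np.ndarray):
        """Pointwise log-density given linear predictor eta = offset + x.phi."""
        raise NotImplementedError

    def moments(self, eta: np.ndarray, theta: float):
        raise NotImplementedError


class NegativeBinomial(GLMFamily):
    name = "negative_binomial"
    link = "log"

    def log_density(self, y, eta, theta):
        y = np.asarray(y, dtype=float)
        eta = np.asarray(eta, dtype=float)
        theta = np.asarray(theta, dtype=float)
        if np.any(theta <= 0):
            raise ValueError("theta must be > 0")
        if np.any(y < 0) or np.any(y != np.round(y)):
            raise ValueError("negative binomial outcomes must be non-negative integers")
        r = 1.0 / theta
        # log p = lgamma(y+r) - lgamma(r) - lgamma(y+1)
        #         + y*(log theta + eta) - (y+r)*log1p(theta*exp(eta))
        return (
            gammaln(y + r)
            - gammaln(r)
            - gammaln(y + 1.0)
            + y * (np.log(theta) + eta)
            - (y + r) * np.log1p(theta * np.exp(eta))
        )

    def moments(self, eta, theta):
        if np.any(np.asarray(theta) < 0):
            raise ValueError("theta must be >= 0")
        mu = np.exp(np.asarray(eta, dtype=float))
        return mu, mu + theta * mu**2


class Gaussian(GLMFamily):
    name = "gaussian"
    link = "identity"

    def log_density(self, y, eta, theta):
        y = np.asarray(y, dtype=float)
        eta = np.asarray(eta, dtype=float)
        theta = np.asarray(theta, dtype=float)
        if np.any(theta <= 0):
            raise ValueError("theta (standard deviation) must be > 0")
        return -0.5 * _LOG_2PI - np.log(theta) - 0.5 * ((y - eta) / theta) ** 2

    def moments(self, eta, theta):
        eta = np.asarray(eta, dtype=float)
        return eta, np.full_like(eta, float(theta) ** 2)


_FAMILIES = {"negative_binomial": NegativeBinomial(), "gaussian": Gaussian()}


def get_family(name) -> GLMFamily:
    if isinstance(name, GLMFamily):
        return name
    try:
        return _FAMILIES[name]
    except KeyError:
        raise ValueError(f"unknown family {name!r}; expected one of {tuple(_FAMILIES)}") from None


# -- convenience wrappers on single observations -------------------------


def nb_log_density(y, x, phi, theta, offset=0.0):
    """Negative binomial log-pmf at count ``y`` with mean exp(offset + x.phi)."""
    eta = float(offset) + float(np.dot(np.asarray(x, dtype=float), np.asarray(phi, dtype=float)))
    return float(NegativeBinomial().log_density(y, eta, theta))


def nb_moments(x, phi, theta, offset=0.0):
    """(mean, variance) = (mu, mu + theta*mu^2) with mu = exp(offset + x.phi)."""
    eta = float(offset) + float(np.dot(np.asarray(x, dtype=float), np.asarray(phi, dtype=float)))
    mu, var = NegativeBinomial().moments(eta, theta)
    return float(mu), float(var)


def gaussian_log_density(y, x, phi, theta, offset=0.0):
    """Normal log-density with mean offset + x.phi and standard deviation theta."""
    eta = float(offset) + float(np.dot(np.asarray(x, dtype=float), np.asarray(phi, dtype=float)))
    return float(Gaussian().log_density(y, eta, theta))


def log_prior(state: ParameterState, prior: PriorSpec) -> float:
    """Log-density of the independent prior on (theta_center, theta-tilde, phi)."""
    total = prior.log_phi_prior(state.phi)
    total += prior.log_theta_prior(state.theta_center)
    if state.theta_aux:
        total += prior.log_theta_prior(np.array(list(state.theta_aux.values())))
    return total
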