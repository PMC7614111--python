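"""Synthetic spatial datasets: the lattice benchmark and small toys.

The lattice benchmark places locations on a ``grid_u x grid_v`` integer
lattice (coordinates 1..grid_u, 1..grid_v, Euclidean distance in lattice
units) with spatially smooth regression coefficients

    phi0(u, v) = 3
    phi1(u, v) = 0.1 + 0.01 * sqrt(u^2 + v^2)          (smooth radial trend)
    phi2(u)    = 0.05 * (sin(pi/2 + pi u/20) + cos(pi/2 + pi u/20) + 4)

and a local dispersion theta(u, v) ~ N(0.5, 0.01^2) drawn independently per
location — similar in magnitude everywhere, but *not* spatially smooth
(redrawing non-positive values keeps theta > 0).  At each location ``m``
independent outcomes are drawn from a negative binomial with mean
``exp(phi0 + phi1 X2 + phi2 X3)`` where ``X1 = 1``, ``X2 ~ U(0, 10)`` and
``X3 ~ U(2, 7)`` are redrawn independently for every observation.

Negative binomial sampling uses the gamma-Poisson mixture: Y | g ~
Poisson(mu * g), g ~ Gamma(shape 1/theta, scale theta), giving
Var(Y) = mu + theta mu^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import Location, SpatialDataset

__all__ = [
    "SimulationSpec",
    "coefficient_surfaces",
    "simulate_lattice",
    "simulate_gaussian_toy",
    "nb_rvs",
]


@dataclass(frozen=True)
class SimulationSpec:
    grid_u: int = 40
    grid_v: int = 40
    m: int = 100
    theta_mean: float = 0.5
    theta_sd: float = 0.01
    x2_range: tuple[float, float] = (0.0, 10.0)
    x3_range: tuple[float, float] = (2.0, 7.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_u < 1 or self.grid_v < 1 or self.m < 1:
            raise ValueError("grid dims and m must be >= 1")
        if not self.theta_mean > 0:
            raise ValueError("theta_mean must be > 0")
        for lo, hi in (self.x2_range, self.x3_range):
            if not hi > lo:
                raise ValueError("covariate ranges must be non-degenerate")


def coefficient_surfaces(u, v):
    """True (phi0, phi1, phi2) at lattice coordinates (u, v)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    phi0 = np.broadcast_to(3.0, u.shape).copy() if u.ndim else 3.0
    phi1 = 0.1 + 0.01 * np.sqrt(u**2 + v**2)
    angle = math.pi / 2.0 + math.pi * u / 20.0
    phi2 = 0.05 * (np.sin(angle) + np.cos(angle) + 4.0)
    if np.ndim(u) == 0:
        return float(phi0), float(phi1), float(phi2)
    return phi0, phi1, phi2


def nb_rvs(rng: np.random.Generator, mu, theta, size=None):
    """Negative binomial draws, mean mu and variance mu + theta mu^2.

    theta = 0 degenerates to the Poisson.
    """
    mu = np.asarray(mu, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0):
        raise ValueError("theta must be >= 0")
    if size is None:
        size = np.broadcast_shapes(mu.shape, theta.shape)
    mu_b = np.broadcast_to(mu, size)
    th_b = np.broadcast_to(theta, size)
    g = np.ones(size)
    pos = th_b > 0
    if np.any(pos):
        g[pos] = rng.gamma(shape=1.0 / th_b[pos], scale=th_b[pos])
    return np.asarray(rng.poisson(mu_b * g))


def simulate_lattice(spec: SimulationSpec) -> tuple[SpatialDataset, pd.DataFrame]:
    """Simulate the lattice benchmark; returns (dataset, truth table).

    The truth table has one row per location: ``location_id, u, v, phi0,
    phi1, phi2, theta``.  Reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    locations: list[Location] = []
    outcomes, covariates, offsets = {}, {}, {}
    truth_rows = []
    for u in range(1, spec.grid_u + 1):
        for v in range(1, spec.grid_v + 1):
            lid = f"{u}_{v}"
            phi0, phi1, phi2 = coefficient_surfaces(u, v)
            theta = rng.normal(spec.theta_mean, spec.theta_sd)
            while theta <= 0:  # essentially probability zero at the defaults
                theta = rng.normal(spec.theta_mean, spec.theta_sd)
            x2 = rng.uniform(*spec.x2_range, size=spec.m)
            x3 = rng.uniform(*spec.x3_range, size=spec.m)
            mu = np.exp(phi0 + phi1 * x2 + phi2 * x3)
            y = nb_rvs(rng, mu, theta)
            locations.append(Location(lid, float(u), float(v)))
            outcomes[lid] = y.astype(float)
            covariates[lid] = np.column_stack([np.ones(spec.m), x2, x3])
            offsets[lid] = np.zeros(spec.m)
            truth_rows.append(
                {
                    "location_id": lid,
                    "u": u,
                    "v": v,
                    "phi0": phi0,
                    "phi1": phi1,
                    "phi2": phi2,
                    "theta": theta,
                }
            )
    ds = SpatialDataset(
        locations=locations,
        outcomes=outcomes,
        covariates=covariates,
        offsets=offsets,
        metric="euclidean",
        family="negative_binomial",
        covariate_names=["x1", "x2", "x3"],
    )
    return ds, pd.DataFrame(truth_rows)


def simulate_gaussian_toy(
    n_locations: int,
    means,
    sd: float,
    m: int,
    coords=None,
    seed: int = 0,
) -> SpatialDataset:
    """IID normal outcomes per location (intercept-only design).

    A fixture for conjugate closed-form checks: location *i* has ``m`` draws
    from N(means[i], sd^2), covariate matrix a single all-ones column.
    """
    means = np.asarray(means, dtype=float)
    if means.shape[0] != n_locations:
        raise ValueError("means must have one entry per location")
    if coords is None:
        coords = [(float(i), 0.0) for i in range(n_locations)]
    if len(coords) != n_locations:
        raise ValueError("coords must have one entry per location")
    rng = np.random.default_rng(seed)
    locations, outcomes, covariates = [], {}, {}
    for i in range(n_locations):
        lid = f"loc{i}"
        locations.append(Location(lid, float(coords[i][0]), float(coords[i][1])))
        outcomes[lid] = rng.normal(means[i], sd, size=m)
        covariates[lid] = np.ones((m, 1))
    return SpatialDataset(
        locations=locations,
        outcomes=outcomes,
        covariates=covariates,
        metric="euclidean",
        family="gaussian",
        covariate_names=["x1"],
    )
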