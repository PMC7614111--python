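"""Geographic distances and geographically weighted kernels.

The weight given to a neighbouring location's likelihood is a decreasing
function of its distance from the centre: the Gaussian kernel
``W(d, eta) = exp(-d^2 / eta^2)`` with bandwidth ``eta``, or its truncated
variant that sets weights to exactly zero once ``exp(-d^2/eta^2) <= W*``
(strict inequality keeps a weight), bounding the number of locations whose
likelihood must be evaluated.

Distances and the bandwidth must share units; no unit conversion is ever
performed here.  For the haversine metric, coordinates are (longitude,
latitude) in decimal degrees and distances are in the units of
``earth_radius`` (default km, mean Earth radius 6371 km).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dataset import Location, SpatialDataset

__all__ = [
    "KernelSpec",
    "WeightVector",
    "euclidean_distance",
    "haversine_distance",
    "gaussian_weight",
    "truncated_gaussian_weight",
    "compute_weight_vector",
    "EARTH_RADIUS_KM",
]

EARTH_RADIUS_KM = 6371.0

KERNEL_FAMILIES = ("gaussian", "truncated_gaussian")


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family, bandwidth and distance metric.

    ``bandwidth`` may be ``None`` in a template used for bandwidth search;
    every weight computation requires it to be a positive number.
    """

    family: str = "truncated_gaussian"
    bandwidth: float | None = None
    threshold: float = 0.01
    metric: str = "euclidean"
    earth_radius: float = EARTH_RADIUS_KM

    def __post_init__(self) -> None:
        if self.family not in KERNEL_FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.bandwidth is not None and not self.bandwidth > 0:
            raise ValueError("bandwidth must be > 0")
        if not (0.0 <= self.threshold < 1.0):
            raise ValueError("threshold W* must lie in [0, 1)")

    def with_bandwidth(self, eta: float) -> "KernelSpec":
        return KernelSpec(self.family, float(eta), self.threshold, self.metric, self.earth_radius)

    def distance(self, a: Location, b: Location) -> float:
        if self.metric == "haversine":
            return haversine_distance(a, b, self.earth_radius)
        return euclidean_distance(a, b)

    def weight(self, d) -> np.ndarray | float:
        if self.bandwidth is None:
            raise ValueError("KernelSpec has no bandwidth set")
        if self.family == "gaussian":
            return gaussian_weight(d, self.bandwidth)
        return truncated_gaussian_weight(d, self.bandwidth, self.threshold)


@dataclass
class WeightVector:
    """Per-location kernel weights for one geographical centre.

    The centre always has weight exactly 1 (distance zero); ``active_ids``
    is the set of locations with strictly positive weight — the locations
    whose likelihood terms enter the powered posterior.
    """

    center_id: str
    weights: dict[str, float]
    active_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.active_ids:
            self.active_ids = {i for i, w in self.weights.items() if w > 0}
        if self.weights.get(self.center_id) != 1.0:
            raise ValueError("weight at the centre must be exactly 1")
        for i, w in self.weights.items():
            if not (0.0 <= w <= 1.0):
                raise ValueError(f"weight for {i!r} outside [0, 1]")

    @property
    def n_active(self) -> int:
        return len(self.active_ids)


def euclidean_distance(a: Location, b: Location) -> float:
    """Planar distance in coordinate units."""
    return math.hypot(a.u - b.u, a.v - b.v)


def haversine_distance(a: Location, b: Location, earth_radius: float = EARTH_RADIUS_KM) -> float:
    """Great-circle distance; coordinates are (longitude, latitude) degrees."""
    for loc in (a, b):
        if not -90.0 <= loc.v <= 90.0:
            raise ValueError(f"latitude {loc.v} outside [-90, 90] for location {loc.id!r}")
    lon1, lat1, lon2, lat2 = map(math.radians, (a.u, a.v, b.u, b.v))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = math.sin(dlat / 2.0) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2.0) ** 2
    return 2.0 * earth_radius * math.asin(min(1.0, math.sqrt(h)))


def gaussian_weight(d, eta: float):
    """Gaussian kernel ``exp(-d^2/eta^2)``; 1 at d = 0, decreasing in d."""
    if not eta > 0:
        raise ValueError("bandwidth eta must be > 0")
    d = np.asarray(d, dtype=float)
    w = np.exp(-(d**2) / eta**2)
    return float(w) if w.ndim == 0 else w


def truncated_gaussian_weight(d, eta: float, threshold: float):
    """Gaussian kernel truncated to zero wherever it does not exceed W*."""
    if not (0.0 <= threshold < 1.0):
        raise ValueError("threshold W* must lie in [0, 1)")
    w = gaussian_weight(d, eta)
    w = np.asarray(w)
    out = np.where(w > threshold, w, 0.0)
    return float(out) if out.ndim == 0 else out


def compute_weight_vector(ds: SpatialDataset, center_id: str, spec: KernelSpec) -> WeightVector:
    """Kernel weights of every location in ``ds`` relative to one centre."""
    center = ds.location(center_id)  # raises KeyError for unknown ids
    weights: dict[str, float] = {}
    for loc in ds.locations:
        d = 0.0 if loc.id == center_id else spec.distance(center, loc)
        w = float(spec.weight(d))
        weights[loc.id] = 1.0 if loc.id == center_id else w
    return WeightVector(center_id=center_id, weights=weights)
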