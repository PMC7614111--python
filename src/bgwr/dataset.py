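"""Spatial dataset container and delimited-text I/O.

A :class:`SpatialDataset` holds long-format spatial observations: every row is
one observation ``(y, x_1..x_p[, offset])`` attached to a named location with
planar or longitude/latitude coordinates.  Locations carry repeated,
exchangeable observations; the covariate dimension ``p`` is shared across
locations while the number of observations per location may differ.

All exchange formats are plain CSV with a header row (see :func:`read_dataset`
and :func:`write_dataset`).  Credible-interval summaries use empirical
quantiles with linear interpolation between order statistics; this rule is
fixed so that written summaries are reproducible bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Location",
    "SpatialDataset",
    "read_dataset",
    "write_dataset",
    "validate_dataset",
    "write_posterior_summary",
    "write_draws",
    "ci_quantiles",
]

METRICS = ("euclidean", "haversine")
FAMILIES = ("negative_binomial", "gaussian")


@dataclass(frozen=True)
class Location:
    """A named sampling location with coordinates ``(u, v)``.

    For ``metric="haversine"`` the convention is ``u`` = longitude and
    ``v`` = latitude, both in decimal degrees.
    """

    id: str
    u: float
    v: float


@dataclass
class SpatialDataset:
    """Observations grouped by location.

    Parameters
    ----------
    locations
        Ordered locations (order of first appearance in the source table).
    outcomes
        Per-location outcome vectors ``y`` (length ``m_i >= 1``).
    covariates
        Per-location covariate matrices (``m_i`` rows, ``p`` columns). An
        explicit all-ones column is permitted (and conventional) for the
        intercept.
    offsets
        Optional per-location log-exposure vectors; default all zero.
    metric
        ``"euclidean"`` or ``"haversine"``.
    family
        ``"negative_binomial"`` or ``"gaussian"``.
    covariate_names
        Column labels for the covariates, default ``x1..xp``.
    """

    locations: list[Location]
    outcomes: dict[str, np.ndarray]
    covariates: dict[str, np.ndarray]
    offsets: dict[str, np.ndarray] = field(default_factory=dict)
    metric: str = "euclidean"
    family: str = "negative_binomial"
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}; expected one of {METRICS}")
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        for loc in self.locations:
            lid = loc.id
            self.outcomes[lid] = np.asarray(self.outcomes[lid], dtype=float)
            self.covariates[lid] = np.atleast_2d(np.asarray(self.covariates[lid], dtype=float))
            if lid not in self.offsets or self.offsets[lid] is None:
                self.offsets[lid] = np.zeros(self.outcomes[lid].shape[0])
            else:
                self.offsets[lid] = np.asarray(self.offsets[lid], dtype=float)
        if not self.covariate_names and self.locations:
            p = self.covariates[self.locations[0].id].shape[1]
            self.covariate_names = [f"x{k + 1}" for k in range(p)]

    # -- basic accessors -------------------------------------------------
    @property
    def location_ids(self) -> list[str]:
        return [loc.id for loc in self.locations]

    @property
    def n_locations(self) -> int:
        return len(self.locations)

    @property
    def p(self) -> int:
        return self.covariates[self.locations[0].id].shape[1]

    def location(self, location_id: str) -> Location:
        for loc in self.locations:
            if loc.id == location_id:
                return loc
        raise KeyError(f"unknown location id {location_id!r}")

    def m(self, location_id: str) -> int:
        return int(self.outcomes[location_id].shape[0])

    def coords(self) -> np.ndarray:
        """(n_locations, 2) array of (u, v) in listed order."""
        return np.array([[loc.u, loc.v] for loc in self.locations])

    def replace_location_rows(
        self,
        location_id: str,
        keep_idx: np.ndarray,
    ) -> "SpatialDataset":
        """Copy of the dataset with only rows ``keep_idx`` at one location.

        Used by cross-validation: the training set for a model centred at
        location *i* removes held-out rows only at that location.
        """
        if location_id not in self.outcomes:
            raise KeyError(f"unknown location id {location_id!r}")
        keep_idx = np.asarray(keep_idx, dtype=int)
        out = SpatialDataset(
            locations=list(self.locations),
            outcomes=dict(self.outcomes),
            covariates=dict(self.covariates),
            offsets=dict(self.offsets),
            metric=self.metric,
            family=self.family,
            covariate_names=list(self.covariate_names),
        )
        out.outcomes[location_id] = self.outcomes[location_id][keep_idx]
        out.covariates[location_id] = self.covariates[location_id][keep_idx]
        out.offsets[location_id] = self.offsets[location_id][keep_idx]
        return out

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for loc in self.locations:
            lid = loc.id
            df = pd.DataFrame(self.covariates[lid], columns=self.covariate_names)
            df.insert(0, "location_id", lid)
            df.insert(1, "u", loc.u)
            df.insert(2, "v", loc.v)
            df.insert(3, "y", self.outcomes[lid])
            df["offset"] = self.offsets[lid]
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


DEFAULT_SCHEMA = {
    "location_id": "location_id",
    "u": "u",
    "v": "v",
    "y": "y",
    "offset": "offset",
}


def dataset_from_frame(
    df: pd.DataFrame,
    schema: Mapping[str, str] | None = None,
    covariate_columns: Sequence[str] | None = None,
    metric: str = "euclidean",
    family: str = "negative_binomial",
) -> SpatialDataset:
    """Build a validated :class:`SpatialDataset` from a long-format frame."""
    sch = dict(DEFAULT_SCHEMA)
    if schema:
        sch.update(schema)
    for key in ("location_id", "u", "v", "y"):
        if sch[key] not in df.columns:
            raise KeyError(f"missing required column {sch[key]!r} (schema key {key!r})")
    if covariate_columns is None:
        reserved = {sch["location_id"], sch["u"], sch["v"], sch["y"], sch.get("offset")}
        covariate_columns = [c for c in df.columns if c not in reserved]
    if not covariate_columns:
        raise KeyError("no covariate columns found; name at least one (e.g. an all-ones x1)")

    has_offset = sch.get("offset") in df.columns
    locations: list[Location] = []
    outcomes: dict[str, np.ndarray] = {}
    covariates: dict[str, np.ndarray] = {}
    offsets: dict[str, np.ndarray] = {}
    seen: dict[str, tuple[float, float]] = {}
    for lid, grp in df.groupby(sch["location_id"], sort=False):
        lid = str(lid)
        uu = grp[sch["u"]].to_numpy(dtype=float)
        vv = grp[sch["v"]].to_numpy(dtype=float)
        if np.ptp(uu) != 0 or np.ptp(vv) != 0:
            raise ValueError(f"location {lid!r}: inconsistent coordinates across rows")
        seen[lid] = (float(uu[0]), float(vv[0]))
        locations.append(Location(lid, float(uu[0]), float(vv[0])))
        outcomes[lid] = grp[sch["y"]].to_numpy(dtype=float)
        covariates[lid] = grp[list(covariate_columns)].to_numpy(dtype=float)
        offsets[lid] = (
            grp[sch["offset"]].to_numpy(dtype=float) if has_offset else np.zeros(len(grp))
        )
    ds = SpatialDataset(
        locations=locations,
        outcomes=outcomes,
        covariates=covariates,
        offsets=offsets,
        metric=metric,
        family=family,
        covariate_names=[str(c) for c in covariate_columns],
    )
    problems = validate_dataset(ds)
    if problems:
        raise ValueError("invalid dataset: " + "; ".join(problems))
    return ds


def read_dataset(
    path,
    schema: Mapping[str, str] | None = None,
    covariate_columns: Sequence[str] | None = None,
    metric: str = "euclidean",
    family: str = "negative_binomial",
) -> SpatialDataset:
    """Read a CSV table (``location_id,u,v,y,x1..xp[,offset]``) into a dataset.

    Row order within a location is preserved; locations are ordered by first
    appearance.  Raises on schema violations or invalid values (e.g. negative
    counts under the negative binomial family).
    """
    df = pd.read_csv(path)
    return dataset_from_frame(
        df, schema=schema, covariate_columns=covariate_columns, metric=metric, family=family
    )


def write_dataset(ds: SpatialDataset, path) -> None:
    """Write a dataset to CSV so that :func:`read_dataset` round-trips it."""
    ds.to_frame().to_csv(path, index=False)


def validate_dataset(ds: SpatialDataset) -> list[str]:
    """Return a list of invariant violations (empty list iff valid)."""
    problems: list[str] = []
    ids = ds.location_ids
    dup = {i for i in ids if ids.count(i) > 1}
    for d in sorted(dup):
        problems.append(f"location {d!r}: duplicate id")
    p_values = {}
    for loc in ds.locations:
        lid = loc.id
        if not (math.isfinite(loc.u) and math.isfinite(loc.v)):
            problems.append(f"location {lid!r}: non-finite coordinates")
        y = ds.outcomes[lid]
        X = ds.covariates[lid]
        off = ds.offsets[lid]
        if y.shape[0] < 1:
            problems.append(f"location {lid!r}: outcomes must have at least one observation")
        if X.shape[0] != y.shape[0]:
            problems.append(f"location {lid!r}: covariates rows {X.shape[0]} != m {y.shape[0]}")
        if off.shape[0] != y.shape[0]:
            problems.append(f"location {lid!r}: offsets length {off.shape[0]} != m {y.shape[0]}")
        if not np.all(np.isfinite(off)):
            problems.append(f"location {lid!r}: offsets contain non-finite values")
        if not np.all(np.isfinite(X)):
            problems.append(f"location {lid!r}: covariates contain non-finite values")
        if ds.family == "negative_binomial":
            if np.any(y < 0) or np.any(y != np.round(y)):
                problems.append(
                    f"location {lid!r}: outcomes must be non-negative integers under "
                    "the negative_binomial family"
                )
        elif not np.all(np.isfinite(y)):
            problems.append(f"location {lid!r}: outcomes contain non-finite values")
        p_values[lid] = X.shape[1]
    if len(set(p_values.values())) > 1:
        counts = ", ".join(f"{lid}: p={pv}" for lid, pv in sorted(p_values.items()))
        problems.append(f"covariate dimension differs across locations ({counts})")
    return problems


def ci_quantiles(draws: np.ndarray, probs=(0.025, 0.5, 0.975)) -> np.ndarray:
    """Empirical quantiles, linear interpolation between order statistics."""
    return np.quantile(np.asarray(draws, dtype=float), probs, method="linear")


def write_posterior_summary(results: Mapping[str, Mapping[str, np.ndarray]], path) -> None:
    """Write per-location, per-parameter posterior summaries to CSV.

    ``results`` maps ``location_id -> {parameter_name: draws}``.  The output
    has columns ``location_id,parameter,median,ci_lower,ci_upper`` with the
    2.5% and 97.5% empirical quantiles as the 95% credible interval.
    """
    rows = []
    for lid, params in results.items():
        for name, draws in params.items():
            lo, med, hi = ci_quantiles(np.ravel(draws))
            rows.append(
                {
                    "location_id": lid,
                    "parameter": name,
                    "median": med,
                    "ci_lower": lo,
                    "ci_upper": hi,
                }
            )
    pd.DataFrame(rows, columns=["location_id", "parameter", "median", "ci_lower", "ci_upper"]).to_csv(
        path, index=False
    )


def write_draws(results: Mapping[str, "object"], path, covariate_names: Iterable[str] | None = None) -> None:
    """Export raw MCMC draws: ``location_id,chain,iteration,theta,phi_1..phi_p``."""
    frames = []
    for lid, res in results.items():
        draws = res.draws  # (n_chains, S, 1 + p)
        n_chains, S, k = draws.shape
        p = k - 1
        names = list(covariate_names) if covariate_names else [f"phi_{j + 1}" for j in range(p)]
        flat = draws.reshape(n_chains * S, k)
        df = pd.DataFrame(flat, columns=["theta"] + names)
        df.insert(0, "location_id", lid)
        df.insert(1, "chain", np.repeat(np.arange(n_chains), S))
        df.insert(2, "iteration", np.tile(np.arange(S), n_chains))
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
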