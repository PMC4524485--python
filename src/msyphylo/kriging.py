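"""Ordinary kriging of haplogroup frequency surfaces.

Population frequencies observed at sampling locations are interpolated
onto a regular latitude/longitude grid (default 50 columns x 45 rows).
The spatial structure is summarized by an empirical semivariogram binned
on great-circle distance, fitted by weighted least squares with an
exponential (default) or spherical model, and each grid cell's estimate
solves the standard ordinary-kriging system, whose weights are
constrained to sum to one (unbiasedness).  Estimates are clamped to the
admissible frequency range [0, 1] after solving.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import linalg, optimize

EARTH_RADIUS_KM = 6371.0


@dataclass
class FrequencyObservation:
    population: str
    lat: float
    lon: float
    frequency: float
    n: int = 1

    def __post_init__(self) -> None:
        if not (-90 <= self.lat <= 90 and -180 <= self.lon <= 180):
            raise ValueError(f"{self.population}: coordinates out of range")
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError(f"{self.population}: frequency outside [0, 1]")
        if self.n < 1:
            raise ValueError(f"{self.population}: sample size must be >= 1")


@dataclass
class VariogramModel:
    model: str  # "exponential" | "spherical"
    nugget: float
    sill: float
    range_km: float

    def __post_init__(self) -> None:
        if self.nugget < 0 or self.sill < self.nugget or self.range_km <= 0:
            raise ValueError(
                "variogram needs 0 <= nugget <= sill and range > 0"
            )

    def __call__(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        partial = self.sill - self.nugget
        if self.model == "exponential":
            gamma = partial * (1.0 - np.exp(-3.0 * h / self.range_km))
        elif self.model == "spherical":
            x = np.clip(h / self.range_km, 0.0, 1.0)
            gamma = partial * (1.5 * x - 0.5 * x**3)
        else:
            raise ValueError(f"unknown variogram model {self.model!r}")
        return np.where(h > 0, self.nugget + gamma, 0.0)


def haversine_km(
    lat1: np.ndarray, lon1: np.ndarray, lat2: np.ndarray, lon2: np.ndarray
) -> np.ndarray:
    """Great-circle distance in km (vectorized)."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def _pairwise_km(obs: Sequence[FrequencyObservation]) -> np.ndarray:
    lat = np.array([o.lat for o in obs])
    lon = np.array([o.lon for o in obs])
    return haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])


class DegenerateGeometryError(ValueError):
    pass


def empirical_semivariogram(
    obs: Sequence[FrequencyObservation], n_bins: int = 12
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(bin centre km, mean semivariance, pair count) per distance bin."""
    d = _pairwise_km(obs)
    z = np.array([o.frequency for o in obs])
    iu = np.triu_indices(len(obs), k=1)
    h = d[iu]
    gamma = 0.5 * (z[iu[0]] - z[iu[1]]) ** 2
    if h.max() == 0:
        raise DegenerateGeometryError("all observations are colocated")
    edges = np.linspace(0, h.max() * 1.0001, n_bins + 1)
    centres, means, counts = [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (h >= lo) & (h < hi)
        if mask.sum() == 0:
            continue
        centres.append(h[mask].mean())
        means.append(gamma[mask].mean())
        counts.append(int(mask.sum()))
    return np.array(centres), np.array(means), np.array(counts)


def fit_variogram(
    obs: Sequence[FrequencyObservation],
    model: str = "exponential",
    n_bins: int = 12,
    max_lag_fraction: float = 0.5,
) -> VariogramModel:
    """Weighted least-squares fit of the binned semivariogram.

    Bins are weighted by pair count and, following standard practice,
    only lags up to ``max_lag_fraction`` of the maximum distance enter
    the fit (the empirical variogram is unreliable beyond).  Constant
    data yield a degenerate zero-variance model (nugget = sill = 0)
    rather than an error.
    """
    if len(obs) < 5:
        raise ValueError("variogram fitting needs at least 5 observations")
    d = _pairwise_km(obs)
    if len({(o.lat, o.lon) for o in obs}) < 2:
        raise DegenerateGeometryError("all observations are colocated")
    h, gamma, counts = empirical_semivariogram(obs, n_bins=n_bins)
    if np.allclose(gamma, 0.0):
        return VariogramModel(model, 0.0, 0.0, max(float(d.max()), 1.0))

    hmax = float(d.max())
    keep = h <= max_lag_fraction * hmax
    if keep.sum() >= 4:
        h, gamma, counts = h[keep], gamma[keep], counts[keep]
    gmax = float(gamma.max())

    def residuals(theta: np.ndarray) -> np.ndarray:
        nugget, partial, rng = theta
        vm = VariogramModel(model, nugget, nugget + partial, rng)
        return np.sqrt(counts) * (vm(h) - gamma)

    x0 = np.array([min(gamma[0] * 0.5, gmax * 0.1), gmax, hmax / 4.0])
    fit = optimize.least_squares(
        residuals,
        x0,
        bounds=(
            [0.0, 1e-12, 1e-6],
            [gmax * 2 + 1e-9, gmax * 4 + 1e-6, hmax * 3],
        ),
    )
    nugget, partial, rng = fit.x
    return VariogramModel(model, float(nugget), float(nugget + partial), float(rng))


@dataclass
class KrigingGrid:
    """Regular lat/lon grid with per-cell estimates.

    ``estimates[i, j]`` is the value at row i (latitude ``lats[i]``) and
    column j (longitude ``lons[j]``).
    """

    n_cols: int = 50
    n_rows: int = 45
    lat_min: float = -35.0
    lat_max: float = 40.0
    lon_min: float = -20.0
    lon_max: float = 55.0
    estimates: Optional[np.ndarray] = None
    kriging_variance: Optional[np.ndarray] = None
    max_weight_error: float = 0.0

    @classmethod
    def from_observations(
        cls,
        obs: Sequence[FrequencyObservation],
        n_cols: int = 50,
        n_rows: int = 45,
        pad_fraction: float = 0.05,
    ) -> "KrigingGrid":
        lat = np.array([o.lat for o in obs])
        lon = np.array([o.lon for o in obs])
        dlat = max(lat.max() - lat.min(), 1e-6) * pad_fraction
        dlon = max(lon.max() - lon.min(), 1e-6) * pad_fraction
        return cls(
            n_cols=n_cols,
            n_rows=n_rows,
            lat_min=float(lat.min() - dlat),
            lat_max=float(lat.max() + dlat),
            lon_min=float(lon.min() - dlon),
            lon_max=float(lon.max() + dlon),
        )

    @property
    def lats(self) -> np.ndarray:
        return np.linspace(self.lat_min, self.lat_max, self.n_rows)

    @property
    def lons(self) -> np.ndarray:
        return np.linspace(self.lon_min, self.lon_max, self.n_cols)

    def write_tsv(self, path) -> None:
        np.savetxt(path, self.estimates, delimiter="\t", fmt="%.6f")


def krige(
    obs: Sequence[FrequencyObservation],
    grid: KrigingGrid,
    variogram: VariogramModel,
    clamp: bool = True,
) -> KrigingGrid:
    """Ordinary kriging of the observations onto the grid.

    Per cell, weights w solve ``[[Gamma, 1], [1', 0]] [w; mu] =
    [gamma0; 1]`` where Gamma holds semivariances between observations
    and gamma0 between observations and the cell.  The pure-nugget and
    zero-variance limits fall back to the unweighted mean.  A singular
    system triggers a warning and a Tikhonov-regularized solve.
    """
    z = np.array([o.frequency for o in obs])
    n = len(obs)
    d = _pairwise_km(obs)
    gamma_obs = variogram(d)
    lhs = np.zeros((n + 1, n + 1))
    lhs[:n, :n] = gamma_obs
    lhs[:n, n] = 1.0
    lhs[n, :n] = 1.0

    olat = np.array([o.lat for o in obs])
    olon = np.array([o.lon for o in obs])
    glat = np.repeat(grid.lats, grid.n_cols)
    glon = np.tile(grid.lons, grid.n_rows)
    d0 = haversine_km(olat[:, None], olon[:, None], glat[None, :], glon[None, :])
    rhs = np.zeros((n + 1, d0.shape[1]))
    rhs[:n] = variogram(d0)
    rhs[n] = 1.0

    if variogram.sill == 0.0:
        # no spatial variance: every cell is the (exactly unbiased) mean
        w = np.full((n, d0.shape[1]), 1.0 / n)
        mu = np.zeros(d0.shape[1])
        sol = np.vstack([w, mu])
    else:
        try:
            sol = linalg.solve(lhs, rhs)
            if not np.all(np.isfinite(sol)):
                raise linalg.LinAlgError("non-finite solution")
        except (linalg.LinAlgError, ValueError):
            warnings.warn(
                "singular kriging matrix; using regularized solve",
                stacklevel=2,
            )
            reg = lhs + np.eye(n + 1) * 1e-10
            sol = np.linalg.lstsq(reg, rhs, rcond=None)[0]

    weights = sol[:n]
    mu = sol[n]
    est = weights.T @ z
    variance = np.einsum("ij,ij->j", weights, rhs[:n]) + mu
    max_weight_error = float(np.abs(weights.sum(axis=0) - 1.0).max())

    if clamp:
        est = np.clip(est, 0.0, 1.0)

    out = KrigingGrid(
        n_cols=grid.n_cols,
        n_rows=grid.n_rows,
        lat_min=grid.lat_min,
        lat_max=grid.lat_max,
        lon_min=grid.lon_min,
        lon_max=grid.lon_max,
        estimates=est.reshape(grid.n_rows, grid.n_cols),
        kriging_variance=np.maximum(
            variance.reshape(grid.n_rows, grid.n_cols), 0.0
        ),
        max_weight_error=max_weight_error,
    )
    return out


def krige_at_points(
    obs: Sequence[FrequencyObservation],
    lats: Sequence[float],
    lons: Sequence[float],
    variogram: VariogramModel,
    clamp: bool = True,
) -> np.ndarray:
    """Kriging estimates at arbitrary points (used for cross-checks)."""
    z = np.array([o.frequency for o in obs])
    n = len(obs)
    d = _pairwise_km(obs)
    lhs = np.zeros((n + 1, n + 1))
    lhs[:n, :n] = variogram(d)
    lhs[:n, n] = 1.0
    lhs[n, :n] = 1.0
    olat = np.array([o.lat for o in obs])
    olon = np.array([o.lon for o in obs])
    qlat = np.asarray(lats, dtype=float)
    qlon = np.asarray(lons, dtype=float)
    d0 = haversine_km(olat[:, None], olon[:, None], qlat[None, :], qlon[None, :])
    rhs = np.zeros((n + 1, d0.shape[1]))
    rhs[:n] = variogram(d0)
    rhs[n] = 1.0
    if variogram.sill == 0.0:
        est = np.full(d0.shape[1], z.mean())
    else:
        sol = linalg.solve(lhs, rhs)
        est = sol[:n].T @ z
    return np.clip(est, 0.0, 1.0) if clamp else est
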