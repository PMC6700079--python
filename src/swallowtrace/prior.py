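"""Movement-direction prior from ringing recoveries.

Ringed birds recaptured between their European breeding grounds and
sub-Saharan winter quarters carry directional information: the bearing from
the breeding to the winter location. Pooled over recoveries, these bearings
are summarized by a von Mises distribution (the circular analogue of the
normal, mean direction mu and concentration kappa), which is then evaluated
along the bearing from the breeding centroid to every pixel of the
assignment grid and normalized into a prior probability surface f_m for the
Bayesian isotope assignment.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.special import i0e, i1e

from .grid import GridSpec, Raster

KAPPA_CAP = 500.0

#: Breeding-site centroid used for pixel-direction evaluation
#: (Kraghede, Denmark).
DEFAULT_CENTROID = (57.22, 9.97)


def initial_bearing(origin: tuple[float, float], dest: tuple[float, float]) -> float:
    """Initial great-circle bearing from ``origin`` to ``dest``.

    Points are (lat, lon) in degrees; the result is degrees clockwise from
    geographic north in [0, 360). Spherical model.
    """
    lat1, lon1 = map(math.radians, origin)
    lat2, lon2 = map(math.radians, dest)
    if abs(lat1 - lat2) < 1e-15 and abs(lon1 - lon2) < 1e-15:
        raise ValueError("bearing undefined for coincident points")
    dlon = lon2 - lon1
    y = math.sin(dlon) * math.cos(lat2)
    x = math.cos(lat1) * math.sin(lat2) - math.sin(lat1) * math.cos(lat2) * math.cos(dlon)
    return math.degrees(math.atan2(y, x)) % 360.0 % 360.0  # second mod folds 360.0 -> 0.0


def initial_bearing_array(
    origin: tuple[float, float], lats: np.ndarray, lons: np.ndarray
) -> np.ndarray:
    """Vectorized :func:`initial_bearing` from one origin to many points."""
    lat1 = math.radians(origin[0])
    lon1 = math.radians(origin[1])
    lat2 = np.radians(lats)
    lon2 = np.radians(lons)
    dlon = lon2 - lon1
    y = np.sin(dlon) * np.cos(lat2)
    x = math.cos(lat1) * np.sin(lat2) - math.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return np.degrees(np.arctan2(y, x)) % 360.0 % 360.0


@dataclass(frozen=True)
class VonMisesFit:
    """Fitted von Mises parameters: mean direction (degrees in [0, 360)),
    concentration kappa >= 0 and the number of bearings used."""

    mu: float
    kappa: float
    n: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "VonMisesFit":
        return cls(**json.loads(Path(path).read_text()))


def _a1(kappa: float) -> float:
    # A1(k) = I1(k)/I0(k), computed with exponentially scaled Bessels.
    return i1e(kappa) / i0e(kappa)


def fit_von_mises(bearings_deg) -> VonMisesFit:
    """Maximum-likelihood von Mises fit to bearings in degrees.

    mu is the circular mean; kappa solves A1(kappa) = Rbar (mean resultant
    length) by bracketing/Brent. kappa is capped at ``KAPPA_CAP`` when the
    bearings are (nearly) identical, with a warning.
    """
    theta = np.radians(np.asarray(bearings_deg, dtype=float))
    n = theta.size
    if n < 2:
        raise ValueError("need at least 2 bearings")
    C = np.mean(np.cos(theta))
    S = np.mean(np.sin(theta))
    rbar = math.hypot(C, S)
    mu = math.degrees(math.atan2(S, C)) % 360.0 % 360.0
    if rbar < 1e-12:
        return VonMisesFit(mu=mu, kappa=0.0, n=n)
    if _a1(KAPPA_CAP) <= rbar:
        warnings.warn(
            "bearings nearly identical; kappa capped at "
            f"{KAPPA_CAP} (Rbar = {rbar:.6f})",
            stacklevel=2,
        )
        return VonMisesFit(mu=mu, kappa=KAPPA_CAP, n=n)
    kappa = brentq(lambda k: _a1(k) - rbar, 1e-12, KAPPA_CAP)
    return VonMisesFit(mu=mu, kappa=float(kappa), n=n)


def von_mises_density(theta_deg: np.ndarray, mu_deg: float, kappa: float) -> np.ndarray:
    """von Mises density on the circle, angles in degrees (density per radian)."""
    th = np.radians(np.asarray(theta_deg, dtype=float) - mu_deg)
    # i0e scaling keeps this finite up to the kappa cap
    return np.exp(kappa * (np.cos(th) - 1.0)) / (2.0 * math.pi * i0e(kappa))


def direction_nodes(step: float = 2.0, start: float = 1.0) -> np.ndarray:
    """The discrete direction grid 1°, 3°, …, 359° (default step 2°)."""
    return np.arange(start, 360.0, step)


@dataclass
class PriorSurface:
    """Per-pixel prior probability of moult origin f_m (sums to 1)."""

    grid: GridSpec
    values: np.ndarray
    breeding_centroid: tuple[float, float]
    mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.ones(self.grid.shape, dtype=bool)

    def as_raster(self) -> Raster:
        return Raster(grid=self.grid, values=self.values, mask=self.mask)


def build_prior_surface(
    fit: VonMisesFit,
    centroid: tuple[float, float],
    grid: GridSpec,
    direction_grid_step: float = 2.0,
    mask: np.ndarray | None = None,
    snap: bool = True,
) -> PriorSurface:
    """Rasterize a fitted von Mises direction distribution into a prior f_m.

    For each valid pixel the initial bearing from ``centroid`` to the pixel
    center is computed, optionally snapped to the nearest node of the
    discrete direction grid (1°, 3°, …, 359° for step 2), the von Mises
    density evaluated there, and the surface normalized to sum 1 over valid
    pixels. A pixel coinciding with the centroid gets the mean of its valid
    8-neighbours.
    """
    if mask is None:
        mask = np.ones(grid.shape, dtype=bool)
    lat, lon = grid.center_mesh()
    coincident = (np.abs(lat - centroid[0]) < 1e-12) & (np.abs(lon - centroid[1]) < 1e-12)
    safe_lat = np.where(coincident, centroid[0] + grid.resolution, lat)
    bearings = initial_bearing_array(centroid, safe_lat, lon)
    if snap:
        nodes = direction_nodes(direction_grid_step)
        # nearest node on the circle
        diff = np.abs(bearings[..., None] - nodes[None, None, :])
        diff = np.minimum(diff, 360.0 - diff)
        bearings = nodes[np.argmin(diff, axis=-1)]
    # log-space evaluation: the normalizing constant cancels in the pixel
    # normalization, and subtracting the in-mask maximum keeps large kappa
    # from underflowing the whole surface to zero
    logd = fit.kappa * np.cos(np.radians(bearings - fit.mu))
    ref = logd[mask].max() if mask.any() else 0.0
    dens = np.exp(logd - ref)
    if coincident.any():
        dens = _fill_with_neighbor_mean(dens, coincident, mask)
    dens = np.where(mask, dens, 0.0)
    total = dens.sum()
    if total <= 0:
        raise ValueError("prior surface is identically zero on the valid mask")
    return PriorSurface(grid=grid, values=dens / total, breeding_centroid=centroid, mask=mask)


def _fill_with_neighbor_mean(
    values: np.ndarray, where: np.ndarray, mask: np.ndarray
) -> np.ndarray:
    out = values.copy()
    nrows, ncols = values.shape
    for i, j in zip(*np.nonzero(where)):
        acc, cnt = 0.0, 0
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == 0 and dj == 0:
                    continue
                ii, jj = i + di, j + dj
                if 0 <= ii < nrows and 0 <= jj < ncols and mask[ii, jj] and not where[ii, jj]:
                    acc += values[ii, jj]
                    cnt += 1
        if cnt:
            out[i, j] = acc / cnt
    return out


def bearings_from_recoveries(recoveries) -> np.ndarray:
    """Breeding→winter initial bearings (degrees) from RingingRecovery records."""
    return np.array(
        [
            initial_bearing((r.breeding_lat, r.breeding_lon), (r.winter_lat, r.winter_lon))
            for r in recoveries
        ]
    )
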