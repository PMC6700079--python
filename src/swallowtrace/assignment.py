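"""Bayesian multi-isotope assignment of moult origin.

For each feather the observed δ²H/δ¹³C/δ¹⁵N triplet is compared with the
isoscape expectation at every pixel through a multivariate normal likelihood
(missing isotopes marginalized out), combined with the movement prior f_m by
Bayes' rule into a posterior origin surface f_x, reduced to a binary map by
the smallest set of highest-posterior pixels holding 67% of the mass, and
the per-individual binary maps summed into a population surface that is
thresholded (>50/>60/>70% of individuals) into winter masks with spherical
areas.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .grid import GridSpec, Raster
from .prior import PriorSurface
from .synthetic import FeatherSample, IsoscapeSet

LAYERS = ("d2H", "d13C", "d15N")


# ---------------------------------------------------------------------------
# residual covariance (ML, optionally with missing data via EM)


@dataclass
class ResidualCovariance:
    """ML mean/covariance of feather-minus-isoscape residuals (‰, ‰²)."""

    mean: np.ndarray
    cov: np.ndarray
    method: str  # ML-complete | ML-EM-missing | user-supplied
    n: int = 0

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        if self.cov.shape != (3, 3) or not np.allclose(self.cov, self.cov.T, atol=1e-10):
            raise ValueError("covariance must be symmetric 3x3")
        if np.any(np.diag(self.cov) <= 0):
            raise ValueError("covariance diagonal must be positive")
        if np.linalg.eigvalsh(self.cov).min() < -1e-10:
            raise ValueError("covariance must be positive semi-definite")


def _residual_matrix(samples, isoscapes: IsoscapeSet) -> np.ndarray:
    rows = []
    for s in samples:
        if s.true_origin is None:
            raise ValueError(f"sample {s.individual_id} has no known/assumed origin")
        mu = isoscapes.values_at(*s.true_origin)
        rows.append(s.triplet() - mu)
    return np.array(rows)


def estimate_residual_covariance(
    samples,
    isoscapes: IsoscapeSet,
    tol: float = 1e-8,
    max_iter: int = 5000,
    ridge: float = 0.0,
) -> ResidualCovariance:
    """ML multivariate-normal fit to assignment residuals.

    Complete data gives the closed-form ML estimate (n denominator). With
    missing entries the EM algorithm iterates conditional-expectation sweeps
    until the log-likelihood improves by less than ``tol``. A degenerate
    (rank-deficient) estimate raises unless ``ridge`` adds ε·mean(diag) to
    the diagonal.
    """
    R = _residual_matrix(samples, isoscapes)
    n = R.shape[0]
    if n < 4:
        raise ValueError("need at least 4 samples")
    obs = ~np.isnan(R)
    if not obs.any(axis=0).all():
        dropped = [LAYERS[k] for k in range(3) if not obs[:, k].any()]
        warnings.warn(f"isotope(s) {dropped} missing in every sample; dropped", stacklevel=2)
    if obs.all():
        mean = R.mean(axis=0)
        cov = (R - mean).T @ (R - mean) / n
        method = "ML-complete"
    else:
        mean, cov = _em_mvn(R, tol=tol, max_iter=max_iter)
        method = "ML-EM-missing"
    if ridge > 0:
        scale = float(np.mean(np.diag(cov)))
        cov = cov + ridge * (scale if scale > 1e-12 else 1.0) * np.eye(3)
    eig = np.linalg.eigvalsh(cov)
    if eig.min() <= 1e-12 * max(eig.max(), 1.0):
        raise ValueError(
            "residual covariance is (near-)singular; pass ridge > 0 to regularize"
        )
    return ResidualCovariance(mean=mean, cov=cov, method=method, n=n)


def _em_mvn(X: np.ndarray, tol: float, max_iter: int):
    """EM for the ML mean/covariance of an MVN with values missing at random."""
    n, p = X.shape
    obs = ~np.isnan(X)
    mean = np.nanmean(X, axis=0)
    mean = np.where(np.isfinite(mean), mean, 0.0)
    diag = np.nanvar(X, axis=0)
    diag = np.where(np.isfinite(diag) & (diag > 0), diag, 1.0)
    cov = np.diag(diag)
    last_ll = -np.inf
    for _ in range(max_iter):
        Xhat = np.where(obs, X, 0.0)
        C = np.zeros((p, p))
        for i in range(n):
            o = obs[i]
            m = ~o
            if m.any():
                if o.any():
                    Soo = cov[np.ix_(o, o)]
                    Smo = cov[np.ix_(m, o)]
                    sol = np.linalg.solve(Soo, (X[i, o] - mean[o]))
                    Xhat[i, m] = mean[m] + Smo @ sol
                    C_mm = cov[np.ix_(m, m)] - Smo @ np.linalg.solve(Soo, Smo.T)
                else:
                    Xhat[i, m] = mean[m]
                    C_mm = cov[np.ix_(m, m)]
                idx = np.ix_(np.where(m)[0], np.where(m)[0])
                C[idx] += C_mm
        new_mean = Xhat.mean(axis=0)
        D = Xhat - new_mean
        new_cov = (D.T @ D + C) / n
        ll = _mvn_obs_loglik(X, obs, new_mean, new_cov)
        mean, cov = new_mean, new_cov
        if ll - last_ll < tol and np.isfinite(last_ll):
            break
        last_ll = ll
    return mean, 0.5 * (cov + cov.T)


def _mvn_obs_loglik(X, obs, mean, cov) -> float:
    ll = 0.0
    for i in range(X.shape[0]):
        o = obs[i]
        if not o.any():
            continue
        d = X[i, o] - mean[o]
        S = cov[np.ix_(o, o)]
        sign, logdet = np.linalg.slogdet(S)
        ll += -0.5 * (o.sum() * math.log(2 * math.pi) + logdet + d @ np.linalg.solve(S, d))
    return ll


# ---------------------------------------------------------------------------
# likelihood and posterior surfaces


def likelihood_surface(
    sample: FeatherSample, isoscapes: IsoscapeSet, cov: ResidualCovariance
) -> Raster:
    """Multivariate-normal density of the sample's observed isotopes at each
    pixel, with the pixel's isoscape values as mean and the matching
    sub-covariance (missing isotopes marginalized out)."""
    x = sample.triplet()
    o = sample.observed
    if not o.any():
        raise ValueError(f"sample {sample.individual_id} has no observed isotope")
    S = cov.cov[np.ix_(o, o)]
    k = int(o.sum())
    sign, logdet = np.linalg.slogdet(S)
    if sign <= 0 or not np.isfinite(logdet):
        raise ValueError("singular sub-covariance; consider a ridge on the covariance")
    Sinv = np.linalg.inv(S)
    stacked = isoscapes.stacked()[o]  # (k, rows, cols)
    diff = x[o][:, None, None] - stacked
    quad = np.einsum("irc,ij,jrc->rc", diff, Sinv, diff)
    dens = np.exp(-0.5 * quad) / math.sqrt((2 * math.pi) ** k * math.exp(logdet))
    dens = np.where(isoscapes.mask, dens, 0.0)
    return Raster(grid=isoscapes.grid, values=dens, mask=isoscapes.mask)


@dataclass
class PosteriorSurface:
    """Normalized posterior origin probability f_x for one individual."""

    individual_id: str
    grid: GridSpec
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.ones(self.grid.shape, dtype=bool)

    def as_raster(self) -> Raster:
        return Raster(grid=self.grid, values=self.values, mask=self.mask)


def posterior_surface(
    likelihood: Raster, prior: PriorSurface, individual_id: str = ""
) -> PosteriorSurface:
    """Bayes' rule on the grid: posterior ∝ likelihood × prior, sum 1."""
    if likelihood.grid != prior.grid:
        raise ValueError("likelihood and prior grids differ")
    prod = likelihood.values * prior.values
    mask = likelihood.mask & prior.mask
    prod = np.where(mask, prod, 0.0)
    total = prod.sum()
    if total <= 0:
        raise ValueError(
            f"posterior for individual '{individual_id}' is identically zero "
            "(prior and likelihood have disjoint support)"
        )
    return PosteriorSurface(
        individual_id=individual_id, grid=likelihood.grid, values=prod / total, mask=mask
    )


# ---------------------------------------------------------------------------
# binarization, population surface, winter masks


@dataclass
class BinaryOriginMap:
    """Smallest set of highest-posterior pixels holding ≥ q of the mass."""

    individual_id: str
    grid: GridSpec
    values: np.ndarray  # 0/1 ints
    q: float


def binarize_odds(posterior: PosteriorSurface, q: float = 0.67) -> BinaryOriginMap:
    """Code as 1 the pixels of the upper ``q`` posterior mass.

    Pixels are sorted by posterior descending (ties broken by row-major
    index) and included until the cumulative mass first reaches ``q``.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    flat = posterior.values.ravel()
    order = np.argsort(-flat, kind="stable")  # stable → row-major tie-break
    csum = np.cumsum(flat[order])
    k = int(np.searchsorted(csum, q - 1e-12) + 1)
    k = min(k, flat.size)
    out = np.zeros(flat.size, dtype=int)
    out[order[:k]] = 1
    out[flat <= 0] = 0  # never include zero-probability pixels
    return BinaryOriginMap(
        individual_id=posterior.individual_id,
        grid=posterior.grid,
        values=out.reshape(posterior.grid.shape),
        q=q,
    )


@dataclass
class PopulationOriginSurface:
    """Per-pixel count of individuals whose binary map includes the pixel."""

    grid: GridSpec
    counts: np.ndarray
    n_individuals: int


def population_surface(maps: list[BinaryOriginMap]) -> PopulationOriginSurface:
    if not maps:
        raise ValueError("no binary maps given")
    grid = maps[0].grid
    for m in maps[1:]:
        if m.grid != grid:
            raise ValueError("binary maps on different grids")
    counts = np.sum([m.values for m in maps], axis=0).astype(int)
    return PopulationOriginSurface(grid=grid, counts=counts, n_individuals=len(maps))


@dataclass
class WinterMask:
    """Pixels assigned as moult origin for > p of the sample, with area."""

    grid: GridSpec
    mask: np.ndarray
    p: float
    area_km2: float


def threshold_origin(pop: PopulationOriginSurface, p: float) -> WinterMask:
    """Strict threshold: pixel kept iff count / n_individuals > p."""
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    mask = pop.counts / pop.n_individuals > p
    area = float(pop.grid.pixel_areas_km2()[mask].sum())
    return WinterMask(grid=pop.grid, mask=mask, p=p, area_km2=area)


def assign_population(
    samples,
    isoscapes: IsoscapeSet,
    prior: PriorSurface,
    cov: ResidualCovariance,
    q: float = 0.67,
    thresholds=(0.5, 0.6, 0.7),
):
    """Full per-individual → population chain; returns (posteriors, pop, masks)."""
    posteriors = [
        posterior_surface(likelihood_surface(s, isoscapes, cov), prior, s.individual_id)
        for s in samples
    ]
    maps = [binarize_odds(post, q=q) for post in posteriors]
    pop = population_surface(maps)
    masks = {p: threshold_origin(pop, p) for p in thresholds}
    return posteriors, pop, masks
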