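"""Winter NDVI conditions: gap filling, window means, temporal trends.

The winter-condition covariate is the mean NDVI over the delineated winter
mask across the twice-monthly composites dated 1 November of year i−1
through 31 March of year i (the months Danish barn swallows spend south of
the Sahara); the winter is labelled by its January year i. Trends over
years are ordinary least squares with year entered raw (uncentered), with
an optional quadratic term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .grid import GridSpec


@dataclass
class NDVIStack:
    """Twice-monthly NDVI composites: data (T, rows, cols), dates, gaps."""

    grid: GridSpec
    dates: pd.DatetimeIndex
    data: np.ndarray
    missing: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.data.shape != (len(self.dates), *self.grid.shape):
            raise ValueError("data shape must be (n_dates, n_rows, n_cols)")
        if self.missing.shape != self.data.shape:
            raise ValueError("missing mask shape mismatch")

    @property
    def n_composites(self) -> int:
        return len(self.dates)

    def copy(self) -> "NDVIStack":
        return NDVIStack(
            grid=self.grid,
            dates=self.dates.copy(),
            data=self.data.copy(),
            missing=self.missing.copy(),
        )


def gap_fill(stack: NDVIStack) -> NDVIStack:
    """Fill missing cells: linear interpolation along time per pixel, nearest
    observed composite at the boundaries, then the mean of valid 8-neighbours
    within the same composite for anything still missing.

    A stack with no gaps is returned unchanged (bit-exact copy). A pixel
    missing in every composite raises, naming the pixel.
    """
    if not stack.missing.any():
        return stack.copy()
    T = stack.n_composites
    nrows, ncols = stack.grid.shape
    all_missing = stack.missing.all(axis=0)
    if all_missing.any():
        bad = [(int(i), int(j)) for i, j in np.argwhere(all_missing)[:10]]
        raise ValueError(f"pixel(s) missing in all composites: {bad}")
    t = np.arange(T, dtype=float)
    data = stack.data.copy()
    flat = data.reshape(T, -1)
    miss = stack.missing.reshape(T, -1)
    for p in range(flat.shape[1]):
        m = miss[:, p]
        if not m.any():
            continue
        obs = ~m
        # np.interp handles interior gaps linearly and boundary gaps by
        # clamping to the nearest observed value
        flat[m, p] = np.interp(t[m], t[obs], flat[obs, p])
    filled = flat.reshape(T, nrows, ncols)
    # neighbour fallback (only reachable if a pixel had <2 observations and
    # interp degenerated — kept for stacks assembled from partial sources)
    still = ~np.isfinite(filled)
    if still.any():
        for ti, i, j in np.argwhere(still):
            vals = []
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == dj == 0:
                        continue
                    ii, jj = i + di, j + dj
                    if 0 <= ii < nrows and 0 <= jj < ncols and np.isfinite(filled[ti, ii, jj]):
                        vals.append(filled[ti, ii, jj])
            if not vals:
                raise ValueError(f"cannot fill pixel ({i}, {j}) at composite {ti}")
            filled[ti, i, j] = float(np.mean(vals))
    return NDVIStack(
        grid=stack.grid,
        dates=stack.dates.copy(),
        data=filled,
        missing=np.zeros_like(stack.missing),
    )


def winter_window(year: int) -> tuple[pd.Timestamp, pd.Timestamp]:
    """Date span of winter ``year``: 1 Nov (year−1) through 31 Mar (year)."""
    return pd.Timestamp(year - 1, 11, 1), pd.Timestamp(year, 3, 31)


def winter_mean(stack: NDVIStack, mask: np.ndarray, year: int) -> dict:
    """Mean NDVI over masked pixels × composites within winter ``year``.

    Missing cells must have been filled (or are excluded). Returns a series
    row: year, ndvi, n_pixels, n_composites.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stack.grid.shape:
        raise ValueError("mask shape mismatch")
    if not mask.any():
        raise ValueError("empty winter mask")
    lo, hi = winter_window(year)
    in_window = (stack.dates >= lo) & (stack.dates <= hi)
    if not in_window.any():
        raise ValueError(f"no composites between {lo.date()} and {hi.date()}")
    block = stack.data[in_window][:, mask]
    valid = ~stack.missing[in_window][:, mask]
    if not valid.all():
        block = np.where(valid, block, np.nan)
        val = float(np.nanmean(block))
    else:
        val = float(block.mean())
    return dict(
        year=year,
        ndvi=val,
        n_pixels=int(mask.sum()),
        n_composites=int(in_window.sum()),
    )


def winter_series(stack: NDVIStack, mask: np.ndarray, years) -> pd.DataFrame:
    """One :func:`winter_mean` row per requested year."""
    return pd.DataFrame([winter_mean(stack, mask, int(y)) for y in years])


@dataclass
class TrendFit:
    """OLS trend of annual winter NDVI on (raw) year, optionally quadratic."""

    terms: list
    estimates: np.ndarray
    ses: np.ndarray
    pvalues: np.ndarray
    r_squared: float
    durbin_watson: float

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(term=self.terms, estimate=self.estimates, se=self.ses, p=self.pvalues)
        )


def fit_trend(series: pd.DataFrame, quadratic: bool = False) -> TrendFit:
    """OLS of winter NDVI on year (and year² when ``quadratic``).

    Year enters raw/uncentered, so coefficients are on the calendar-year
    scale. For conditioning the fit is computed on centered year and the
    coefficients and their covariance mapped back to the raw basis.
    """
    year = series["year"].to_numpy(dtype=float)
    y = series["ndvi"].to_numpy(dtype=float)
    need = 4 if quadratic else 3
    if len(series) < need:
        raise ValueError(f"need at least {need} years")
    if np.ptp(year) == 0:
        raise ValueError("year is constant; trend undefined")
    c = year.mean()
    xc = year - c
    cols = [np.ones_like(xc), xc] + ([xc**2] if quadratic else [])
    X = np.column_stack(cols)
    fit = sm.OLS(y, X).fit()
    # back-transform centered-basis coefficients to the raw-year basis:
    # raw = T @ centered where T encodes (year - c)^k expansion
    if quadratic:
        T = np.array([[1.0, -c, c**2], [0.0, 1.0, -2 * c], [0.0, 0.0, 1.0]])
    else:
        T = np.array([[1.0, -c], [0.0, 1.0]])
    beta = T @ fit.params
    cov = T @ fit.cov_params() @ T.T
    ses = np.sqrt(np.diag(cov))
    from scipy import stats as sps

    tvals = beta / ses
    pvals = 2 * sps.t.sf(np.abs(tvals), df=fit.df_resid)
    dw = float(sm.stats.stattools.durbin_watson(fit.resid))
    r2 = float(fit.rsquared)
    if not np.isfinite(r2):
        r2 = 0.0  # constant response: no variance to explain
    terms = ["intercept", "year"] + (["year2"] if quadratic else [])
    return TrendFit(
        terms=terms,
        estimates=beta,
        ses=ses,
        pvalues=pvals,
        r_squared=r2,
        durbin_watson=dw,
    )


def stratify_by_biome(mask: np.ndarray, landcover: np.ndarray, class_names: dict | None = None):
    """Partition a winter mask by land-cover class.

    ``landcover`` is an integer raster co-registered with the mask (resample
    beforehand if resolutions differ). Returns {biome: submask}; classes not
    in ``class_names`` are pooled under ``"other"``. Union of the submasks
    equals the input mask.
    """
    mask = np.asarray(mask, dtype=bool)
    landcover = np.asarray(landcover)
    if landcover.shape != mask.shape:
        raise ValueError("landcover must be co-registered with the mask")
    out: dict[str, np.ndarray] = {}
    for code in np.unique(landcover[mask]):
        name = (class_names or {}).get(int(code), None)
        key = name if name is not None else ("other" if class_names else f"class_{int(code)}")
        sub = mask & (landcover == code)
        out[key] = out[key] | sub if key in out else sub
    return out
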