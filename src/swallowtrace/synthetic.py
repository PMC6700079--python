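"""Synthetic inputs with known ground truth.

The pipeline's real inputs — feather isoscapes, EURING ringing recoveries,
twice-monthly NDVI composites and a 30-year longitudinal breeding table for
barn swallows — are not publicly archived. This module generates statistical
stand-ins for each of them from known parameters so that every downstream
stage (prior construction, isotope assignment, NDVI extraction, path
analysis) can be exercised and validated end to end. Real rasters and CSV
tables enter through the same container types.

Every generator is a pure function of its parameters and a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import GridSpec, Raster, EARTH_RADIUS_KM
from .ndvi import NDVIStack

# ---------------------------------------------------------------------------
# study-area defaults: the sub-Saharan assignment extent and the European
# breeding box (5–15°E longitude buffer around Denmark)

WINTER_BOX = GridSpec(lon_min=-17.0, lon_max=42.0, lat_min=-35.0, lat_max=15.0, resolution=0.83)
BREEDING_BOX = dict(lat_min=36.0, lat_max=66.0, lon_min=5.0, lon_max=15.0)
WINTER_BOUNDS = dict(lat_min=-35.0, lat_max=15.0, lon_min=-17.0, lon_max=42.0)


# ---------------------------------------------------------------------------
# isoscapes


@dataclass
class IsoscapeSet:
    """Co-registered expected-feather-isotope rasters (d2H, d13C, d15N)."""

    grid: GridSpec
    d2H: np.ndarray
    d13C: np.ndarray
    d15N: np.ndarray
    mask: np.ndarray

    LAYERS = ("d2H", "d13C", "d15N")

    def layer(self, name: str) -> np.ndarray:
        return getattr(self, name)

    def values_at(self, lat: float, lon: float) -> np.ndarray:
        i, j = self.grid.index_of(lat, lon)
        if not self.mask[i, j]:
            raise ValueError(f"origin ({lat}, {lon}) outside isoscape mask")
        return np.array([self.d2H[i, j], self.d13C[i, j], self.d15N[i, j]])

    def stacked(self) -> np.ndarray:
        """(3, nrows, ncols) array in layer order."""
        return np.stack([self.d2H, self.d13C, self.d15N])

    def as_rasters(self) -> dict[str, Raster]:
        return {
            name: Raster(grid=self.grid, values=self.layer(name), mask=self.mask)
            for name in self.LAYERS
        }


#: planar gradients (intercept, per-degree-lat, per-degree-lon) loosely shaped
#: like African feather isoscapes: d2H most negative in the wet equatorial
#: belt, d13C tracking C3/C4 vegetation, d15N aridity.
DEFAULT_GRADIENTS = {
    "d2H": (-55.0, 1.2, 0.6),
    "d13C": (-16.0, -0.25, 0.05),
    "d15N": (9.0, 0.15, -0.04),
}

DEFAULT_ISO_NOISE_SD = {"d2H": 8.0, "d13C": 1.5, "d15N": 1.2}


def generate_isoscapes(
    grid: GridSpec,
    gradient_spec: dict[str, tuple[float, float, float]] | None = None,
    noise_sd: dict[str, float] | float | None = None,
    seed: int = 0,
    smooth_sigma_px: float = 5.0,
    mask: np.ndarray | None = None,
) -> IsoscapeSet:
    """Planar gradient plus a smooth random field, per isotope layer.

    ``gradient_spec`` maps layer name to (intercept, slope per degree
    latitude, slope per degree longitude); ``noise_sd`` is the marginal SD
    of the smooth field added on top (0 gives the exact plane).
    """
    gradient_spec = gradient_spec or DEFAULT_GRADIENTS
    if noise_sd is None:
        noise_sd = DEFAULT_ISO_NOISE_SD
    if np.isscalar(noise_sd):
        noise_sd = {name: float(noise_sd) for name in IsoscapeSet.LAYERS}
    if any(sd < 0 for sd in noise_sd.values()):
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    lat, lon = grid.center_mesh()
    layers = {}
    for name in IsoscapeSet.LAYERS:
        b0, blat, blon = gradient_spec[name]
        plane = b0 + blat * lat + blon * lon
        sd = noise_sd[name]
        if sd > 0:
            raw = rng.standard_normal(grid.shape)
            smooth = ndimage.gaussian_filter(raw, sigma=smooth_sigma_px, mode="reflect")
            s = smooth.std()
            noise = smooth * (sd / s) if s > 0 else np.zeros_like(smooth)
        else:
            rng.standard_normal(grid.shape)  # keep stream alignment across sd choices
            noise = 0.0
        layers[name] = plane + noise
    if mask is None:
        mask = np.ones(grid.shape, dtype=bool)
    return IsoscapeSet(grid=grid, mask=mask, **layers)


# ---------------------------------------------------------------------------
# ringing recoveries


@dataclass(frozen=True)
class RingingRecovery:
    """One ringed bird: breeding capture and winter recapture (degrees)."""

    breeding_lat: float
    breeding_lon: float
    winter_lat: float
    winter_lon: float
    direction_known: bool = True


def _destination_point(lat: float, lon: float, bearing_deg: float, distance_km: float):
    """Great-circle destination from a start point, bearing and range."""
    delta = distance_km / EARTH_RADIUS_KM
    theta = math.radians(bearing_deg)
    phi1 = math.radians(lat)
    lam1 = math.radians(lon)
    phi2 = math.asin(
        math.sin(phi1) * math.cos(delta) + math.cos(phi1) * math.sin(delta) * math.cos(theta)
    )
    lam2 = lam1 + math.atan2(
        math.sin(theta) * math.sin(delta) * math.cos(phi1),
        math.cos(delta) - math.sin(phi1) * math.sin(phi2),
    )
    return math.degrees(phi2), (math.degrees(lam2) + 540.0) % 360.0 - 180.0


def generate_ringing_recoveries(
    n: int,
    breeding_box: dict | None = None,
    winter_box: dict | None = None,
    mu: float = 190.0,
    kappa: float = 4.0,
    range_km: tuple[float, float] = (6000.0, 9500.0),
    seed: int = 0,
    max_tries: int = 10_000,
) -> list[RingingRecovery]:
    """Simulate breeding→winter recovery pairs with von Mises bearings.

    A breeding point is drawn uniformly in ``breeding_box``, a bearing from
    VM(mu, kappa) (mu in degrees clockwise from north; kappa = 0 gives
    uniform directions), a range uniformly in ``range_km``, and the winter
    point is the great-circle destination; draws landing outside
    ``winter_box`` are rejected. Raises if the rejection loop exhausts
    ``max_tries`` consecutive failures.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    bb = breeding_box or BREEDING_BOX
    wb = winter_box or WINTER_BOUNDS
    for box in (bb, wb):
        if box["lat_min"] >= box["lat_max"] or box["lon_min"] >= box["lon_max"]:
            raise ValueError("degenerate box")
    rng = np.random.default_rng(seed)
    out: list[RingingRecovery] = []
    failures = 0
    while len(out) < n:
        if failures >= max_tries:
            raise RuntimeError(
                f"rejection sampling failed {max_tries} consecutive times; "
                "boxes and bearing distribution are incompatible"
            )
        blat = rng.uniform(bb["lat_min"], bb["lat_max"])
        blon = rng.uniform(bb["lon_min"], bb["lon_max"])
        if kappa == 0:
            bearing = rng.uniform(0.0, 360.0)
        else:
            bearing = math.degrees(rng.vonmises(math.radians(mu), kappa)) % 360.0
        dist = rng.uniform(*range_km)
        wlat, wlon = _destination_point(blat, blon, bearing, dist)
        if wb["lat_min"] <= wlat <= wb["lat_max"] and wb["lon_min"] <= wlon <= wb["lon_max"]:
            out.append(
                RingingRecovery(
                    breeding_lat=blat, breeding_lon=blon, winter_lat=wlat, winter_lon=wlon
                )
            )
            failures = 0
        else:
            failures += 1
    return out


def recoveries_to_frame(recoveries: Sequence[RingingRecovery]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in recoveries])


def recoveries_from_frame(df: pd.DataFrame) -> list[RingingRecovery]:
    cols = ["breeding_lat", "breeding_lon", "winter_lat", "winter_lon"]
    return [
        RingingRecovery(**{c: float(row[c]) for c in cols})
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# feather samples


@dataclass
class FeatherSample:
    """One feather's isotope triplet; NaN marks a missing measurement.

    ``true_origin`` (lat, lon) exists only for synthetic samples.
    """

    individual_id: str
    d2H: float
    d13C: float
    d15N: float
    true_origin: tuple[float, float] | None = None

    def triplet(self) -> np.ndarray:
        return np.array([self.d2H, self.d13C, self.d15N], dtype=float)

    @property
    def observed(self) -> np.ndarray:
        return ~np.isnan(self.triplet())


def generate_feather_samples(
    n: int,
    origin_sampler: Callable[[np.random.Generator], tuple[float, float]],
    isoscapes: IsoscapeSet,
    residual_cov: np.ndarray,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> list[FeatherSample]:
    """Feather triplets = isoscape value at a true origin + MVN residual.

    ``origin_sampler(rng)`` returns a (lat, lon) inside the isoscape mask.
    Each isotope is independently set missing with probability
    ``missing_rate``; a draw losing all three isotopes is redrawn so every
    sample keeps at least one value.
    """
    residual_cov = np.asarray(residual_cov, dtype=float)
    if residual_cov.shape != (3, 3) or not np.allclose(residual_cov, residual_cov.T):
        raise ValueError("residual_cov must be a symmetric 3x3 matrix")
    eig = np.linalg.eigvalsh(residual_cov)
    if eig.min() < -1e-10:
        raise ValueError("residual_cov must be positive semi-definite")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    chol = _psd_factor(residual_cov)
    out = []
    for k in range(n):
        lat, lon = origin_sampler(rng)
        mu = isoscapes.values_at(lat, lon)
        vals = mu + chol @ rng.standard_normal(3)
        if missing_rate > 0:
            while True:
                miss = rng.random(3) < missing_rate
                if not miss.all():
                    break
            vals = np.where(miss, np.nan, vals)
        out.append(
            FeatherSample(
                individual_id=f"bird_{k:04d}",
                d2H=vals[0],
                d13C=vals[1],
                d15N=vals[2],
                true_origin=(lat, lon),
            )
        )
    return out


def _psd_factor(cov: np.ndarray) -> np.ndarray:
    # Cholesky with eigen fallback for singular PSD matrices
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(cov)
        return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def box_origin_sampler(
    lat_min: float, lat_max: float, lon_min: float, lon_max: float
) -> Callable[[np.random.Generator], tuple[float, float]]:
    """Uniform origin sampler over a lat/lon box."""

    def sample(rng: np.random.Generator) -> tuple[float, float]:
        return rng.uniform(lat_min, lat_max), rng.uniform(lon_min, lon_max)

    return sample


def feathers_to_frame(samples: Sequence[FeatherSample]) -> pd.DataFrame:
    rows = []
    for s in samples:
        row = dict(individual_id=s.individual_id, d2H=s.d2H, d13C=s.d13C, d15N=s.d15N)
        if s.true_origin is not None:
            row["true_lat"], row["true_lon"] = s.true_origin
        rows.append(row)
    return pd.DataFrame(rows)


def feathers_from_frame(df: pd.DataFrame) -> list[FeatherSample]:
    out = []
    for _, row in df.iterrows():
        origin = None
        if "true_lat" in df.columns and np.isfinite(row.get("true_lat", np.nan)):
            origin = (float(row["true_lat"]), float(row["true_lon"]))
        out.append(
            FeatherSample(
                individual_id=str(row["individual_id"]),
                d2H=float(row["d2H"]) if pd.notna(row["d2H"]) else np.nan,
                d13C=float(row["d13C"]) if pd.notna(row["d13C"]) else np.nan,
                d15N=float(row["d15N"]) if pd.notna(row["d15N"]) else np.nan,
                true_origin=origin,
            )
        )
    return out


# ---------------------------------------------------------------------------
# NDVI stack


def generate_ndvi_series(
    grid: GridSpec,
    years: tuple[int, int] = (1982, 2013),
    trend_per_year: float = 0.001,
    base: float = 0.45,
    seasonal_amp: float = 0.12,
    noise_sd: float = 0.05,
    gap_fraction: float = 0.05,
    seed: int = 0,
    seasonal_peak_doy: float = 46.0,
    interannual_sd: float = 0.015,
) -> NDVIStack:
    """Twice-monthly NDVI composites with linear trend, one annual sinusoid,
    interannual (climate) variation, white noise and missing cells.

    Composites are dated the 1st and 15th of every month from January of
    ``years[0]`` through December of ``years[1]``. The per-pixel expectation
    at time t (in years since the first composite) is
    ``base + trend_per_year * t + seasonal_amp * cos(2π (doy − peak)/365.25)``
    plus one shared N(0, interannual_sd) offset per calendar year (wet/dry
    years move the whole region together — this is what keeps region-mean
    trends from being trivially significant); draws are clipped to [−1, 1]
    and a fraction ``gap_fraction`` of cells is flagged missing.
    """
    if not 0 <= gap_fraction < 1:
        raise ValueError("gap_fraction must be in [0, 1)")
    if interannual_sd < 0 or noise_sd < 0:
        raise ValueError("noise SDs must be >= 0")
    rng = np.random.default_rng(seed)
    dates = []
    for year in range(years[0], years[1] + 1):
        for month in range(1, 13):
            dates.append(pd.Timestamp(year=year, month=month, day=1))
            dates.append(pd.Timestamp(year=year, month=month, day=15))
    dates = pd.DatetimeIndex(dates)
    t_years = (dates - dates[0]).days.values / 365.25
    doy = dates.dayofyear.values
    seasonal = seasonal_amp * np.cos(2 * math.pi * (doy - seasonal_peak_doy) / 365.25)
    year_offsets = dict(
        zip(
            range(years[0], years[1] + 1),
            rng.normal(0.0, interannual_sd, years[1] - years[0] + 1)
            if interannual_sd > 0
            else np.zeros(years[1] - years[0] + 1),
        )
    )
    annual = np.array([year_offsets[y] for y in dates.year])
    nT = len(dates)
    shape = (nT, *grid.shape)
    signal = (base + trend_per_year * t_years + seasonal + annual)[:, None, None]
    data = signal + (rng.standard_normal(shape) * noise_sd if noise_sd > 0 else 0.0)
    data = np.clip(np.broadcast_to(data, shape), -1.0, 1.0).astype(float)
    missing = rng.random(shape) < gap_fraction if gap_fraction > 0 else np.zeros(shape, bool)
    return NDVIStack(grid=grid, dates=dates, data=data, missing=missing)


# ---------------------------------------------------------------------------
# longitudinal breeding table


@dataclass
class CausalTruth:
    """Generative coefficients for the breeding table's causal diagram.

    Units are raw: breeding date in days from 1 May, tail length in mm,
    NDVI unitless, age in years, clutch/fledglings in counts, mass in g.
    The defaults put the system in the regime the path analysis describes:
    a negative main age effect and a positive age×NDVI interaction on
    breeding date (older birds breed much earlier only after poor winters),
    tail ornaments advancing breeding, breeding date depressing clutch size
    and fledgling numbers, and a weak positive residual correlation of body
    mass with breeding date.
    """

    # breeding date equation (both sexes); the intercept puts a mean-tailed
    # yearling male at day 35 after a poor winter (NDVI 0.6) and a
    # five-year-old at day 21, with the gap closing to 34 vs 31 after a good
    # winter (NDVI 0.675)
    beta0_date: float = 79.0
    beta_ndvi: float = -50.0
    beta_age: float = -25.5
    beta_age_ndvi: float = 36.7
    beta_tail: float = -0.10
    # clutch equation (females only)
    gamma0_clutch: float = 5.8
    gamma_date_clutch: float = -0.030
    gamma_age_clutch: float = 0.005
    gamma_tail_clutch: float = -0.002
    # fledglings equation (females: from clutch; males: from date)
    phi0_fledg_female: float = 1.4
    phi_clutch_fledg: float = 0.50
    phi_age_fledg_female: float = 0.02
    phi_tail_fledg_female: float = 0.002
    phi0_fledg_male: float = 4.8
    phi_date_fledg_male: float = -0.022
    phi_age_fledg_male: float = 0.01
    phi_tail_fledg_male: float = 0.002
    # crossed random-intercept SDs; they enter the breeding-date equation and
    # propagate to clutch/fledglings only through breeding date, keeping the
    # causal diagram over observed variables exact
    sd_ring: float = 2.5
    sd_colony: float = 1.5
    sd_year: float = 3.0
    # residual SDs
    resid_sd_date: float = 7.0
    resid_sd_clutch: float = 0.9
    resid_sd_fledg: float = 1.0
    # body mass: mean, SD, and residual correlation with each reproductive variable
    mass_mean: float = 19.5
    mass_sd: float = 1.3
    mass_corr_date: float = 0.05
    mass_corr_clutch: float = 0.0
    mass_corr_fledg: float = 0.0
    # tail length by sex
    tail_mean_female: float = 90.0
    tail_mean_male: float = 106.0
    tail_sd: float = 6.0

    def __post_init__(self) -> None:
        for name in ("sd_ring", "sd_colony", "sd_year", "resid_sd_date",
                     "resid_sd_clutch", "resid_sd_fledg", "mass_sd", "tail_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("mass_corr_date", "mass_corr_clutch", "mass_corr_fledg"):
            if abs(getattr(self, name)) > 1:
                raise ValueError(f"|{name}| must be <= 1")


MAX_AGE = 8


def generate_breeding_records(
    truth: CausalTruth | None = None,
    n_individuals: int = 700,
    years: tuple[int, int] = (1984, 2013),
    ndvi_by_year: dict[int, float] | None = None,
    age_survival: float = 0.52,
    sexes: tuple[str, ...] = ("female", "male"),
    n_colonies: int = 40,
    seed: int = 0,
    round_counts: bool = True,
) -> pd.DataFrame:
    """Longitudinal bird-year table generated from the causal diagram.

    Each sex gets ``n_individuals`` recruits entering at age 1 in a uniform
    random year; a bird survives to the next breeding season with
    probability ``age_survival`` (capped at age 8 and at the last study
    year), which produces the steeply declining age distribution seen in
    long-term swallow datasets. ``ndvi_by_year[y]`` is the winter-condition
    covariate attached to breeding year ``y``; by default a gentle positive
    trend over 0.60–0.675 with interannual noise.

    Clutch size and fledglings are Gaussian draws rounded to integers and
    floored at 0 (fledglings additionally capped at clutch size for
    females) when ``round_counts`` — downstream equations consume the
    *observed* (rounded) upstream values, so the causal diagram over
    observed variables is exact.
    """
    truth = truth or CausalTruth()
    rng = np.random.default_rng(seed)
    year_lo, year_hi = years
    year_list = list(range(year_lo, year_hi + 1))
    if ndvi_by_year is None:
        t = np.arange(len(year_list))
        vals = 0.60 + 0.075 * t / max(len(year_list) - 1, 1) + rng.normal(0, 0.01, len(year_list))
        ndvi_by_year = dict(zip(year_list, np.clip(vals, -1, 1)))
    missing_years = [y for y in year_list if y not in ndvi_by_year]
    if missing_years:
        raise ValueError(f"ndvi_by_year missing years {missing_years}")
    if not 0 <= age_survival <= 1:
        raise ValueError("age_survival must be a probability")

    u_year = {y: rng.normal(0, truth.sd_year) for y in year_list}
    u_colony = {c: rng.normal(0, truth.sd_colony) for c in range(n_colonies)}

    rows = []
    for sex in sexes:
        tail_mean = truth.tail_mean_female if sex == "female" else truth.tail_mean_male
        for k in range(n_individuals):
            ring = f"{sex[0].upper()}{k:05d}"
            colony = int(rng.integers(n_colonies))
            recruit_year = int(rng.choice(year_list))
            u_ring = rng.normal(0, truth.sd_ring)
            tail_indiv = rng.normal(tail_mean, truth.tail_sd)
            age, year = 1, recruit_year
            while age <= MAX_AGE and year <= year_hi:
                ndvi = float(ndvi_by_year[year])
                tail = tail_indiv + rng.normal(0, 1.0)  # measurement noise
                eps_d = rng.normal(0, truth.resid_sd_date)
                date = (
                    truth.beta0_date
                    + truth.beta_ndvi * ndvi
                    + truth.beta_age * age
                    + truth.beta_age_ndvi * age * ndvi
                    + truth.beta_tail * tail
                    + u_ring + u_colony[colony] + u_year[year]
                    + eps_d
                )
                z_resid = [eps_d / truth.resid_sd_date if truth.resid_sd_date else 0.0]
                clutch = np.nan
                eps_c = 0.0
                if sex == "female":
                    eps_c = rng.normal(0, truth.resid_sd_clutch)
                    clutch_raw = (
                        truth.gamma0_clutch
                        + truth.gamma_date_clutch * date
                        + truth.gamma_age_clutch * age
                        + truth.gamma_tail_clutch * tail
                        + eps_c
                    )
                    clutch = (
                        max(round(clutch_raw), 0) if round_counts else clutch_raw
                    )
                    z_resid.append(eps_c / truth.resid_sd_clutch if truth.resid_sd_clutch else 0.0)
                eps_f = rng.normal(0, truth.resid_sd_fledg)
                if sex == "female":
                    fledg_raw = (
                        truth.phi0_fledg_female
                        + truth.phi_clutch_fledg * clutch
                        + truth.phi_age_fledg_female * age
                        + truth.phi_tail_fledg_female * tail
                        + eps_f
                    )
                else:
                    fledg_raw = (
                        truth.phi0_fledg_male
                        + truth.phi_date_fledg_male * date
                        + truth.phi_age_fledg_male * age
                        + truth.phi_tail_fledg_male * tail
                        + eps_f
                    )
                if round_counts:
                    fledg = max(round(fledg_raw), 0)
                    if sex == "female":
                        fledg = min(fledg, clutch)
                else:
                    fledg = fledg_raw
                z_resid.append(eps_f / truth.resid_sd_fledg if truth.resid_sd_fledg else 0.0)
                # body mass: correlated with the reproductive residuals only
                if sex == "female":
                    w = np.array(
                        [truth.mass_corr_date, truth.mass_corr_clutch, truth.mass_corr_fledg]
                    )
                else:
                    w = np.array([truth.mass_corr_date, truth.mass_corr_fledg])
                    z_resid = [z_resid[0], z_resid[-1]]
                w2 = float(w @ w)
                if w2 > 1:
                    raise ValueError("mass residual correlations jointly exceed unit variance")
                mass_z = float(w @ np.asarray(z_resid)) + math.sqrt(1 - w2) * rng.normal()
                mass = truth.mass_mean + truth.mass_sd * mass_z
                rows.append(
                    dict(
                        ring_id=ring,
                        colony_id=f"col_{colony:02d}",
                        year=year,
                        sex=sex,
                        age=age,
                        tail_length=tail,
                        body_mass=mass,
                        breeding_date=date,
                        clutch_size=clutch,
                        fledglings=fledg,
                        winter_ndvi=ndvi,
                    )
                )
                if rng.random() >= age_survival:
                    break
                age += 1
                year += 1
    return pd.DataFrame(rows)
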