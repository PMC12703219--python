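"""Robust trend machinery for gridded and regional NPP series.

Per-pixel trends are routed by a normality test: series that pass the
D'Agostino–Pearson test (α = 0.05) get a Huber robust regression (ε = 1.35,
outliers = points with final robust weight < 1, more than 50 % outliers →
no trend); series that fail are handled non-parametrically with the
Mann-Kendall test and the Theil–Sen (median-of-pairwise) slope.  Pixels with
less than 50 % of their nominal time axis available report no trend.

Regional integration multiplies per-pixel rates (mg C m⁻² day⁻¹) by spherical
pixel areas and 365 days to Pg C yr⁻¹.  Trend uncertainty against start/end
choices uses a jackknife over all contiguous fixed-length windows of the
annual regional series, each window estimated with the same routed estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats
from sklearn.linear_model import HuberRegressor

__all__ = [
    "PixelSeries",
    "TrendEstimate",
    "TrendConfig",
    "JackknifeSummary",
    "mann_kendall",
    "pixel_trend",
    "area_weights",
    "regional_integral",
    "regional_series",
    "jackknife_windows",
    "float_trend",
    "trend_map",
    "annual_means",
]

EARTH_RADIUS = 6_371_000.0  # m
MG_PER_PG = 1e18


@dataclass
class PixelSeries:
    """One pixel's time series on a nominal axis, with gaps as NaN."""

    time: np.ndarray          # decimal years, strictly increasing
    values: np.ndarray

    @property
    def fraction_available(self) -> float:
        return float(np.mean(np.isfinite(self.values)))


@dataclass
class TrendConfig:
    min_availability: float = 0.5
    normality_alpha: float = 0.05
    normality_min_n: int = 20           # below this, route to Mann-Kendall
    huber_epsilon: float = 1.35
    max_outlier_fraction: float = 0.5


@dataclass
class TrendEstimate:
    """Slope (units yr⁻¹) with the routing metadata that produced it."""

    slope: float
    intercept: float
    method: str                          # 'huber' | 'mann_kendall' | 'none'
    normality_p: float = np.nan
    outlier_fraction: float = np.nan
    p_value: float = np.nan
    stderr: float = np.nan
    n: int = 0

    @property
    def missing(self) -> bool:
        return self.method == "none"


@dataclass
class JackknifeSummary:
    windows: list                        # (start_year, end_year, slope)
    mean_trend: float
    sd_trend: float
    estimates: list = field(default_factory=list)


def mann_kendall(values, time=None):
    """Mann-Kendall trend test with Theil–Sen slope.

    Returns ``(S, p, sen_slope)``.  S is the all-pairs sign statistic; p uses
    the tie-corrected normal approximation with continuity correction
    (p = 1 when the variance degenerates, e.g. a constant series).  The slope
    is the median of all pairwise slopes against ``time`` (indices if omitted).
    """
    x = np.asarray(values, dtype=float)
    if time is None:
        time = np.arange(x.size, dtype=float)
    t = np.asarray(time, dtype=float)
    ok = np.isfinite(x) & np.isfinite(t)
    x, t = x[ok], t[ok]
    n = x.size
    if n < 2:
        return 0, 1.0, np.nan
    diff = np.sign(x[:, None] - x[None, :])
    s = int(np.sum(np.triu(diff.T, 1)))          # sum over j > i of sign(x_j - x_i)
    # tie correction
    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    var_s = (n * (n - 1) * (2 * n + 5)
             - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    if var_s <= 0:
        p = 1.0
    else:
        z = (s - np.sign(s)) / np.sqrt(var_s)
        p = 2.0 * stats.norm.sf(abs(z))
    if np.all(x == x[0]):
        slope = 0.0
    else:
        slope = float(stats.theilslopes(x, t).slope)
    return s, float(p), slope


def _huber_fit(t, x, cfg: TrendConfig):
    # degenerate case: an exact line has zero robust scale, where the IRLS
    # solver stalls at its tolerance — the Huber estimate is then the OLS fit
    b, a = np.polyfit(t, x, 1)
    if np.max(np.abs(x - (a + b * t))) <= 1e-12 * max(np.ptp(x), 1.0):
        return float(b), float(a), 0.0, 0.0 if b != 0 else 1.0, 0.0
    h = HuberRegressor(epsilon=cfg.huber_epsilon, alpha=0.0,
                       max_iter=500, tol=1e-10)
    h.fit(t[:, None] - t.mean(), x)
    outlier_frac = float(np.mean(h.outliers_))
    slope = float(h.coef_[0])
    intercept = float(h.intercept_ - slope * t.mean())
    # slope p-value / se from the OLS formula on the non-outlier residuals
    resid = x - (intercept + slope * t)
    n = x.size
    denom = np.sum((t - t.mean()) ** 2)
    se = np.sqrt(np.sum(resid ** 2) / max(n - 2, 1) / denom) if denom > 0 else np.nan
    if np.isfinite(se) and se > 0:
        p = 2.0 * stats.t.sf(abs(slope / se), df=max(n - 2, 1))
    else:
        p = 0.0 if slope != 0 else 1.0
    return slope, intercept, outlier_frac, p, se


def pixel_trend(series: PixelSeries, cfg: TrendConfig = TrendConfig()) -> TrendEstimate:
    """Availability-filtered, normality-routed trend of one pixel series."""
    t = np.asarray(series.time, dtype=float)
    x = np.asarray(series.values, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("time must be strictly increasing")
    avail = series.fraction_available
    if avail < cfg.min_availability:
        return TrendEstimate(np.nan, np.nan, "none", n=int(np.isfinite(x).sum()))
    ok = np.isfinite(x)
    tv, xv = t[ok], x[ok]
    n = xv.size
    if n < 3:
        return TrendEstimate(np.nan, np.nan, "none", n=n)

    norm_p = np.nan
    use_huber = False
    if n >= cfg.normality_min_n and not np.all(xv == xv[0]):
        norm_p = float(stats.normaltest(xv).pvalue)
        use_huber = norm_p > cfg.normality_alpha

    if use_huber:
        slope, intercept, outlier_frac, p, se = _huber_fit(tv, xv, cfg)
        if outlier_frac > cfg.max_outlier_fraction:
            return TrendEstimate(np.nan, np.nan, "none", normality_p=norm_p,
                                 outlier_fraction=outlier_frac, n=n)
        return TrendEstimate(slope, intercept, "huber", normality_p=norm_p,
                             outlier_fraction=outlier_frac, p_value=p,
                             stderr=se, n=n)

    s, p, slope = mann_kendall(xv, tv)
    intercept = float(np.median(xv) - slope * np.median(tv)) if np.isfinite(slope) else np.nan
    return TrendEstimate(slope, intercept, "mann_kendall", normality_p=norm_p,
                         p_value=p, n=n)


# ---------------------------------------------------------------------------
# geometry and regional integration
# ---------------------------------------------------------------------------

def area_weights(lat_centers, lat_res, lon_res):
    """Spherical pixel areas (m²) per latitude row.

    area = R²·Δλ·(sin φ₂ − sin φ₁) with R = 6,371,000 m; equal for equal
    |latitude|.
    """
    lat = np.asarray(lat_centers, dtype=float)
    phi1 = np.deg2rad(lat - lat_res / 2.0)
    phi2 = np.deg2rad(lat + lat_res / 2.0)
    return EARTH_RADIUS ** 2 * np.deg2rad(lon_res) * (np.sin(phi2) - np.sin(phi1))


def regional_integral(field, lat, lon, lat_res=None, lon_res=None):
    """Area-weighted regional NPP in Pg C yr⁻¹ from mg C m⁻² day⁻¹ pixels.

    Missing pixels are excluded from the sum (treated as zero production,
    not filled).  ``field`` may have leading dimensions (e.g. time).
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if lat_res is None:
        lat_res = float(np.abs(np.diff(lat)).min()) if lat.size > 1 else 1.0
    if lon_res is None:
        lon_res = float(np.abs(np.diff(lon)).min()) if lon.size > 1 else 1.0
    f = np.asarray(field, dtype=float)
    area = area_weights(lat, lat_res, lon_res)[:, None] * np.ones((1, lon.size))
    if not np.isfinite(f).any():
        return np.nan
    contrib = np.where(np.isfinite(f), f, 0.0) * area
    total = contrib.sum(axis=(-2, -1)) * 365.0 / MG_PER_PG
    return float(total) if np.ndim(total) == 0 else total


def annual_means(da: xr.DataArray) -> xr.DataArray:
    """Calendar-year means of a (time, ...) DataArray (NaNs skipped)."""
    return da.groupby("time.year").mean("time", skipna=True)


def regional_series(npp: xr.DataArray, lat_res=None, lon_res=None) -> pd.Series:
    """Annual regional NPP series (Pg C yr⁻¹) from a (time, lat, lon) stack."""
    ann = annual_means(npp)
    vals = regional_integral(ann.values, npp["lat"].values, npp["lon"].values,
                             lat_res, lon_res)
    return pd.Series(np.atleast_1d(vals), index=ann["year"].values, name="npp_pgc")


def jackknife_windows(annual: pd.Series, window_years: int = 20,
                      cfg: TrendConfig = TrendConfig()) -> JackknifeSummary:
    """Trends of every contiguous window of the annual regional series.

    Each window is estimated with the same routed estimator as the pixels
    (window n < 20 routes to Mann-Kendall by construction).  Returns the
    per-window slopes and their mean ± sd.
    """
    years = np.asarray(annual.index, dtype=float)
    vals = np.asarray(annual.values, dtype=float)
    n = years.size
    if n < window_years:
        raise ValueError(f"need >= {window_years} annual values, got {n}")
    windows, estimates = [], []
    for i in range(n - window_years + 1):
        sl = slice(i, i + window_years)
        est = pixel_trend(PixelSeries(years[sl], vals[sl]), cfg)
        estimates.append(est)
        windows.append((int(years[sl][0]), int(years[sl][-1]), est.slope))
    slopes = np.array([w[2] for w in windows], dtype=float)
    ok = np.isfinite(slopes)
    return JackknifeSummary(
        windows=windows,
        mean_trend=float(np.mean(slopes[ok])) if ok.any() else np.nan,
        sd_trend=float(np.std(slopes[ok], ddof=0)) if ok.any() else np.nan,
        estimates=estimates)


def float_trend(times, npp_values, min_years: int = 3) -> TrendEstimate:
    """Float NPP trend: OLS on calendar-year annual means.

    ``times`` are datetimes; years with no profiles are skipped; fewer than
    ``min_years`` annual means gives no trend.
    """
    t = pd.DatetimeIndex(times)
    df = pd.DataFrame({"year": t.year, "npp": np.asarray(npp_values, dtype=float)})
    ann = df.dropna().groupby("year")["npp"].mean()
    if len(ann) < min_years:
        return TrendEstimate(np.nan, np.nan, "none", n=len(ann))
    res = stats.linregress(ann.index.values.astype(float), ann.values)
    return TrendEstimate(float(res.slope), float(res.intercept), "ols",
                         p_value=float(res.pvalue), stderr=float(res.stderr),
                         n=len(ann))


def trend_map(npp: xr.DataArray, cfg: TrendConfig = TrendConfig(),
              cadence: str = "annual") -> xr.Dataset:
    """Per-pixel routed trends of an NPP stack.

    ``cadence='annual'`` (default) first forms calendar-year means per pixel
    (deseasonalised by construction); ``cadence='8day-anomaly'`` removes the
    multi-year climatology of each nominal step and fits the anomalies.
    Returns a Dataset with slope, method code (0 none / 1 huber / 2 MK),
    p-value and outlier fraction.
    """
    if cadence == "annual":
        da = annual_means(npp)
        tcoord = da["year"].values.astype(float)
        dim = "year"
    elif cadence == "8day-anomaly":
        clim = npp.groupby("time.dayofyear").mean("time")
        da = npp.groupby("time.dayofyear") - clim
        tcoord = (da["time"].values - da["time"].values[0]) \
            / np.timedelta64(1, "D") / 365.25
        dim = "time"
    else:
        raise ValueError(f"unknown cadence {cadence!r}")

    vals = da.transpose(dim, "lat", "lon").values
    nt, nlat, nlon = vals.shape
    slope = np.full((nlat, nlon), np.nan)
    method = np.zeros((nlat, nlon), dtype=np.int8)
    pval = np.full((nlat, nlon), np.nan)
    outfrac = np.full((nlat, nlon), np.nan)
    codes = {"none": 0, "huber": 1, "mann_kendall": 2}
    for i in range(nlat):
        for j in range(nlon):
            est = pixel_trend(PixelSeries(tcoord, vals[:, i, j]), cfg)
            slope[i, j] = est.slope
            method[i, j] = codes.get(est.method, 0)
            pval[i, j] = est.p_value
            outfrac[i, j] = est.outlier_fraction
    coords = {"lat": npp["lat"].values, "lon": npp["lon"].values}
    return xr.Dataset(
        {"slope": (("lat", "lon"), slope),
         "method": (("lat", "lon"), method),
         "p_value": (("lat", "lon"), pval),
         "outlier_fraction": (("lat", "lon"), outfrac)},
        coords=coords,
        attrs={"slope_units": "per year",
               "method_codes": "0=none 1=huber 2=mann_kendall"})
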