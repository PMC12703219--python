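"""Earth-System-Model (CMIP6-style) processing and driver decomposition.

Operations: depth integration of phytoplankton carbon to 100 m (the same
interval as the models' depth-integrated NPP), biomass-weighted surface
limitation terms, conservative regridding of rectilinear native grids to 1°,
end-of-century minus end-of-historical Δ fields (optionally Austral summer
only), per-driver linear regressions of ΔNPP against ΔC_phyto / ΔLimFe /
ΔLimIrr, cumulative regional NPP change relative to the 1995–2014 baseline,
and contemporary/future trend extraction that delegates to the same routed
estimator used for the remote-sensing stacks.

Units: `intpp` is handled in mol C m⁻² day⁻¹; an input declared in the CMIP
standard mol C m⁻² s⁻¹ is auto-converted (× 86,400) based on its units
attribute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from . import trends as _trends

__all__ = [
    "DeltaFields",
    "DriverRegression",
    "SECONDS_PER_DAY",
    "CARBON_G_PER_MOL",
    "intpp_to_per_day",
    "integrate_phyc",
    "weight_limitation",
    "regrid_1deg",
    "delta_fields",
    "driver_regression",
    "cumulative_npp_change",
    "esm_regional_series",
    "esm_trend",
]

SECONDS_PER_DAY = 86_400.0
CARBON_G_PER_MOL = 12.0
HIST_PERIOD = (1995, 2014)
FUTURE_PERIOD = (2081, 2100)


@dataclass
class DeltaFields:
    """End-of-future minus end-of-historical means on a common grid."""

    npp: xr.DataArray            # mol C m⁻² day⁻¹
    cphyto: xr.DataArray         # mol C m⁻² (depth-integrated to 100 m)
    limfe: xr.DataArray
    limirr: xr.DataArray
    hist_period: tuple = HIST_PERIOD
    future_period: tuple = FUTURE_PERIOD
    summer_only: bool = False


@dataclass
class DriverRegression:
    driver: str
    slope: float
    r: float
    n: int
    area_weighted: bool = False


def intpp_to_per_day(intpp: xr.DataArray) -> xr.DataArray:
    """Normalise intpp to mol C m⁻² day⁻¹ from its declared units."""
    units = str(intpp.attrs.get("units", "")).lower()
    if "s-1" in units or "/s" in units or "s^-1" in units:
        out = intpp * SECONDS_PER_DAY
        out.attrs = dict(intpp.attrs, units="mol C m-2 day-1",
                         converted_from="mol C m-2 s-1")
        return out
    return intpp


def integrate_phyc(phyc, z=None, depth: float = 100.0):
    """Depth-integrated phytoplankton carbon, mol C m⁻² to ``depth``.

    Trapezoidal; the shallowest level is extended to the surface.  A grid with
    no levels above ``depth`` gives a missing result.  Accepts an xarray
    DataArray with a ``lev`` dimension or plain arrays with ``z``.
    """
    if isinstance(phyc, xr.DataArray):
        z = phyc["lev"].values
        arr = phyc.transpose("lev", ...).values
        moved = True
    else:
        arr = np.asarray(phyc, dtype=float)
        z = np.asarray(z, dtype=float)
        moved = False
        if arr.ndim > 1:
            arr = np.moveaxis(arr, -1, 0) if arr.shape[-1] == z.size else arr
    if np.any(np.diff(z) <= 0):
        raise ValueError("z must be increasing")
    if z.min() > depth:
        return np.nan
    k = int(np.count_nonzero(z <= depth))
    zi = z[:k]
    vi = arr[:k]
    if z[k - 1] < depth and k < z.size:
        # interpolate the partial bottom layer down to `depth`
        v_at = arr[k - 1] + (arr[k] - arr[k - 1]) \
            * (depth - z[k - 1]) / (z[k] - z[k - 1])
        zi = np.concatenate([zi, [depth]])
        vi = np.concatenate([vi, v_at[None]], axis=0)
    if zi[0] > 0:
        zi = np.concatenate([[0.0], zi])
        vi = np.concatenate([vi[:1], vi], axis=0)
    integ = np.trapezoid(vi, zi, axis=0)
    if isinstance(phyc, xr.DataArray):
        dims = [d for d in phyc.dims if d != "lev"]
        coords = {d: phyc[d] for d in dims if d in phyc.coords}
        out = xr.DataArray(integ, dims=dims, coords=coords)
        out.attrs["units"] = "mol C m-2"
        return out
    return integ if np.ndim(integ) else float(integ)


def weight_limitation(lim_per_pft, biomass_per_pft):
    """Biomass-weighted limitation: Σ limᵢ·bᵢ / Σ bᵢ (NaN where Σ b = 0).

    Works on aligned arrays/DataArrays whose leading dimension is the PFT.
    The result is bounded by the component limitations.
    """
    lim = np.asarray(lim_per_pft, dtype=float)
    b = np.asarray(biomass_per_pft, dtype=float)
    if np.any(b < 0):
        raise ValueError("negative biomass")
    tot = b.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(tot > 0, (lim * b).sum(axis=0) / np.where(tot > 0, tot, 1.0),
                       np.nan)
    if isinstance(lim_per_pft, xr.DataArray):
        dims = lim_per_pft.dims[1:]
        coords = {d: lim_per_pft[d] for d in dims if d in lim_per_pft.coords}
        return xr.DataArray(out, dims=dims, coords=coords)
    return out if np.ndim(out) else float(out)


# ---------------------------------------------------------------------------
# conservative regridding (rectilinear only)
# ---------------------------------------------------------------------------

def _edges(centers):
    c = np.asarray(centers, dtype=float)
    if c.size == 1:
        raise ValueError("need at least 2 cells to infer edges")
    mid = (c[:-1] + c[1:]) / 2.0
    return np.concatenate([[c[0] - (mid[0] - c[0])], mid,
                           [c[-1] + (c[-1] - mid[-1])]])


def _overlap_matrix(src_edges, dst_edges, spherical_lat=False):
    """dst×src matrix of overlap measure (sin-lat for meridional axes)."""
    if spherical_lat:
        src = np.sin(np.deg2rad(src_edges))
        dst = np.sin(np.deg2rad(dst_edges))
    else:
        src, dst = src_edges, dst_edges
    lo = np.maximum(dst[:-1, None], src[None, :-1])
    hi = np.minimum(dst[1:, None], src[None, 1:])
    return np.clip(hi - lo, 0.0, None)


def regrid_1deg(field: xr.DataArray, target_res: float = 1.0,
                lat_name: str = "lat", lon_name: str = "lon",
                return_coverage: bool = False):
    """Area-weighted conservative binning of a rectilinear field onto 1°.

    Cell overlap areas on the sphere (Δλ · Δsin φ) weight the source values;
    missing source cells are excluded and the weights renormalised.  The
    target grid spans the source domain, so the covered-area-weighted mean
    (and hence the spatial integral) is conserved exactly for fully valid
    fields; ``return_coverage=True`` additionally returns the covered area
    per target cell (edge cells may be partial).  Curvilinear grids (2-D
    coordinate variables) are rejected.
    """
    if field[lat_name].ndim != 1 or field[lon_name].ndim != 1:
        raise ValueError("curvilinear grids are not supported (rectilinear only)")
    lat_s = field[lat_name].values
    lon_s = field[lon_name].values
    lat_se, lon_se = _edges(lat_s), _edges(lon_s)
    lat_t = np.arange(np.floor(lat_se[0]) + target_res / 2,
                      np.ceil(lat_se[-1]), target_res)
    lon_t = np.arange(np.floor(lon_se[0]) + target_res / 2,
                      np.ceil(lon_se[-1]), target_res)
    lat_te = np.concatenate([lat_t - target_res / 2, [lat_t[-1] + target_res / 2]])
    lon_te = np.concatenate([lon_t - target_res / 2, [lon_t[-1] + target_res / 2]])

    w_lat = _overlap_matrix(lat_se, lat_te, spherical_lat=True)
    w_lon = _overlap_matrix(lon_se, lon_te)

    arr = field.transpose(..., lat_name, lon_name).values
    valid = np.isfinite(arr)
    num = np.einsum("ai,...ij,bj->...ab", w_lat,
                    np.where(valid, arr, 0.0), w_lon)
    den = np.einsum("ai,...ij,bj->...ab", w_lat, valid.astype(float), w_lon)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)

    dims = [d for d in field.dims if d not in (lat_name, lon_name)]
    coords = {d: field[d] for d in dims if d in field.coords}
    coords[lat_name] = lat_t
    coords[lon_name] = lon_t
    res = xr.DataArray(out, dims=dims + [lat_name, lon_name], coords=coords)
    res.attrs = dict(field.attrs)
    if return_coverage:
        cov = xr.DataArray(den if den.ndim == 2 else den.reshape(out.shape),
                           dims=dims + [lat_name, lon_name], coords=coords)
        return res, cov
    return res


# ---------------------------------------------------------------------------
# Δ fields and driver regressions
# ---------------------------------------------------------------------------

def _period_mean(da: xr.DataArray, period, summer_only=False,
                 require_full=True) -> xr.DataArray:
    """Mean over calendar years [y0, y1]; DJF subset attaches December to the
    following year's summer (so Dec y contributes to summer y+1)."""
    y0, y1 = period
    t = pd.DatetimeIndex(da["time"].values)
    have = set(zip(t.year, t.month))
    if summer_only:
        # only complete DJF seasons are averaged, so every season contributes
        # the same within-season phase mix; a first summer whose December
        # precedes the record (e.g. Dec 1994 for a 1995 start) is dropped
        complete = [y for y in range(y0, y1 + 1)
                    if {(y - 1, 12), (y, 1), (y, 2)} <= have]
        if not complete:
            raise ValueError(f"period {period}: no complete DJF season")
        if require_full:
            expected = [y for y in range(y0, y1 + 1)
                        if (y - 1, 12) >= (t[0].year, t[0].month)]
            missing = sorted(set(expected) - set(complete))
            if missing:
                raise ValueError(f"period {period} incomplete; missing DJF "
                                 f"seasons {missing[:6]}"
                                 f"{'...' if len(missing) > 6 else ''}")
        season_year = np.where(t.month == 12, t.year + 1, t.year)
        sel = np.isin(t.month, (12, 1, 2)) & np.isin(season_year, complete)
    else:
        sel = (t.year >= y0) & (t.year <= y1)
        if require_full:
            need = {(y, m) for y in range(y0, y1 + 1) for m in range(1, 13)}
            missing = sorted(need - have)
            if missing:
                raise ValueError(f"period {period} incomplete; missing months "
                                 f"{missing[:6]}{'...' if len(missing) > 6 else ''}")
    return da.isel(time=np.flatnonzero(sel)).mean("time", skipna=True)


def delta_fields(hist_member, future_member, summer_only: bool = False,
                 hist_period=HIST_PERIOD, future_period=FUTURE_PERIOD,
                 regrid: bool = True, target_res: float = 1.0) -> DeltaFields:
    """Δ = mean(2081–2100) − mean(1995–2014) for NPP and the three drivers.

    Limitation terms are biomass-weighted across PFTs at the surface before
    averaging; phytoplankton carbon is depth-integrated to 100 m; all fields
    are conservatively regridded to the target resolution (on by default).
    """
    def prep(member, period):
        npp = _period_mean(intpp_to_per_day(member.intpp), period, summer_only)
        cphy = _period_mean(integrate_phyc(member.phyc), period, summer_only)
        limfe = _period_mean(
            weight_limitation(member.limfe, member.biomass), period, summer_only)
        limirr = _period_mean(
            weight_limitation(member.limirr, member.biomass), period, summer_only)
        return npp, cphy, limfe, limirr

    h = prep(hist_member, hist_period)
    f = prep(future_member, future_period)
    deltas = []
    for hv, fv in zip(h, f):
        d = fv - hv
        if regrid:
            d = regrid_1deg(d, target_res)
        deltas.append(d)
    return DeltaFields(npp=deltas[0], cphyto=deltas[1], limfe=deltas[2],
                       limirr=deltas[3], hist_period=tuple(hist_period),
                       future_period=tuple(future_period),
                       summer_only=summer_only)


def driver_regression(delta: DeltaFields, driver: str,
                      area_weighted: bool = False,
                      min_cells: int = 10) -> DriverRegression:
    """OLS of ΔNPP on one Δdriver across grid cells (optionally area-weighted)."""
    dmap = {"cphyto": delta.cphyto, "limfe": delta.limfe, "limirr": delta.limirr}
    if driver not in dmap:
        raise ValueError(f"driver must be one of {sorted(dmap)}")
    x = np.ravel(np.asarray(dmap[driver], dtype=float))
    y = np.ravel(np.asarray(delta.npp, dtype=float))
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < min_cells:
        raise ValueError(f"only {x.size} valid cells (need >= {min_cells})")
    if np.ptp(x) == 0:
        return DriverRegression(driver, np.nan, np.nan, int(x.size), area_weighted)
    if area_weighted:
        lat2d, _ = np.meshgrid(delta.npp["lat"].values, delta.npp["lon"].values,
                               indexing="ij")
        w = np.cos(np.deg2rad(np.ravel(lat2d)))[ok]
        w = w / w.sum()
        mx, my = np.sum(w * x), np.sum(w * y)
        cov = np.sum(w * (x - mx) * (y - my))
        vx = np.sum(w * (x - mx) ** 2)
        vy = np.sum(w * (y - my) ** 2)
        slope = cov / vx
        r = cov / np.sqrt(vx * vy) if vx > 0 and vy > 0 else np.nan
    else:
        res = stats.linregress(x, y)
        slope, r = float(res.slope), float(res.rvalue)
    return DriverRegression(driver, float(slope), float(r), int(x.size),
                            area_weighted)


# ---------------------------------------------------------------------------
# regional series, cumulative change, trends
# ---------------------------------------------------------------------------

def esm_regional_series(member, lat_res=None, lon_res=None) -> pd.Series:
    """Annual regional NPP (Pg C yr⁻¹) from a member's monthly intpp."""
    intpp = intpp_to_per_day(member.intpp)
    mg = intpp * (CARBON_G_PER_MOL * 1000.0)      # mol C m-2 day-1 → mg C
    mg.attrs["units"] = "mg C m-2 day-1"
    return _trends.regional_series(mg, lat_res, lon_res)


def cumulative_npp_change(annual: pd.Series, baseline=(1995, 2014)) -> pd.Series:
    """Each year's regional NPP minus the baseline-period mean (Pg C)."""
    years = np.asarray(annual.index, dtype=int)
    in_base = (years >= baseline[0]) & (years <= baseline[1])
    missing = sorted(set(range(baseline[0], baseline[1] + 1)) - set(years.tolist()))
    if missing:
        raise ValueError(f"baseline {baseline} incomplete; missing years {missing}")
    base = float(annual.values[in_base].mean())
    return pd.Series(annual.values - base, index=annual.index,
                     name="cumulative_change_pgc")


def ensemble_cumulative_change(series_by_member, baseline=(1995, 2014),
                               at_period=FUTURE_PERIOD):
    """Multi-model mean ± sd of the cumulative change over ``at_period``.

    ``series_by_member`` maps member id → annual regional series covering the
    baseline and the target period.  Models are weighted equally.
    """
    changes = []
    for key, ser in series_by_member.items():
        cum = cumulative_npp_change(ser, baseline)
        years = np.asarray(cum.index, dtype=int)
        sel = (years >= at_period[0]) & (years <= at_period[1])
        if not sel.any():
            raise ValueError(f"member {key} does not cover {at_period}")
        changes.append(float(cum.values[sel].mean()))
    arr = np.asarray(changes)
    return float(arr.mean()), float(arr.std(ddof=1) if arr.size > 1 else 0.0), arr


def esm_trend(annual: pd.Series, period,
              cfg: _trends.TrendConfig = _trends.TrendConfig()):
    """Routed trend of a member's annual regional NPP over a year window."""
    years = np.asarray(annual.index, dtype=float)
    sel = (years >= period[0]) & (years <= period[1])
    if not sel.any():
        raise ValueError(f"series does not cover {period}")
    return _trends.pixel_trend(
        _trends.PixelSeries(years[sel], np.asarray(annual.values)[sel]), cfg)
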