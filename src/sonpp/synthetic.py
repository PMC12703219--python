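"""Synthetic data generators with known ground truth.

Three generators emulate the input classes of the analysis so the whole
pipeline runs offline and every downstream stage can be tested against the
generator's own truth record:

* :func:`gen_rs_fields` — gridded 8-day ocean-colour/physics fields
  (chl, b_bp, a_ph, a_dg, Kd490, η, PAR, SST, MLD, nitracline depth, SSS)
  built as baseline + linear trend + seasonal sine + AR(1) pixel noise;
* :func:`gen_float_dataset` — depth-resolved float profiles with instrument
  artifacts (daytime fluorescence quenching, backscatter spikes and negative
  samples, bad QC flags) on irregular raw depths;
* :func:`gen_esm_ensemble` — monthly Earth-System-Model-like members for a
  historical period and three emission scenarios, where the end-of-century
  change in NPP is constructed as a prescribed linear combination of changes
  in phytoplankton carbon, iron limitation and light limitation plus noise.

What the generators do *not* emulate: multi-sensor merging artefacts, real
Argo telemetry, curvilinear model grids, sea ice.  See docs/methods.md.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import xarray as xr

from .argo import FloatProfile, BBP_700_TO_470, CPHYTO_SLOPE_FACTOR

__all__ = [
    "VariableSpec",
    "SyntheticConfig",
    "TruthRecord",
    "ESMEnsembleMember",
    "default_rs_variables",
    "gen_rs_fields",
    "gen_float_dataset",
    "gen_esm_ensemble",
]

EARTH_RADIUS = 6_371_000.0  # m


@dataclass(frozen=True)
class VariableSpec:
    """Statistical recipe for one gridded variable.

    value(t, pixel) = baseline + trend·(t − t0) + seasonal·sin(2π·doy/365 + phase)
                      + AR(1) noise(ρ, sd), clipped to [clip_min, clip_max].
    Trend in units per year; sd is the stationary noise standard deviation.
    """

    baseline: float
    seasonal_amp: float = 0.0
    trend_per_year: float = 0.0
    rho: float = 0.3
    noise_sd: float = 0.0
    phase: float = 0.0
    clip_min: float | None = None
    clip_max: float | None = None

    def validate(self, name: str) -> None:
        for fname, v in asdict(self).items():
            if v is not None and not np.isfinite(v):
                raise ValueError(f"{name}.{fname} is not finite")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"{name}.rho must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError(f"{name}.noise_sd must be >= 0")


def default_rs_variables() -> dict:
    """Southern-Ocean-plausible defaults for the 11 ocean-colour variables.

    Seasonal phases put the biological maximum in austral summer and the
    mixed-layer maximum in austral winter.
    """
    summer = np.pi / 2        # sin peaks near doy 91 shifted: see phase use
    return {
        "chl":   VariableSpec(0.35, 0.20, 0.0, 0.3, 0.05, summer, 0.01, None),
        "bbp":   VariableSpec(0.0020, 0.0008, 0.0, 0.3, 0.0002, summer, 1e-5, None),
        "aph":   VariableSpec(0.015, 0.006, 0.0, 0.3, 0.002, summer, 1e-4, None),
        "adg":   VariableSpec(0.010, 0.003, 0.0, 0.3, 0.001, summer, 1e-4, None),
        "kd490": VariableSpec(0.06, 0.02, 0.0, 0.3, 0.005, summer, 0.02, None),
        "eta":   VariableSpec(0.78, 0.1, 0.0, 0.3, 0.05, 0.0, 0.0, 2.0),
        "par":   VariableSpec(25.0, 20.0, 0.0, 0.3, 2.0, summer, 0.5, None),
        "sst":   VariableSpec(2.0, 2.5, 0.0, 0.3, 0.3, summer, -2.0, None),
        "mld":   VariableSpec(95.0, 55.0, 0.0, 0.3, 5.0, summer + np.pi, 10.0, None),
        "zno3":  VariableSpec(60.0, 15.0, 0.0, 0.3, 3.0, summer + np.pi, 5.0, None),
        "sss":   VariableSpec(34.0, 0.2, 0.0, 0.3, 0.05, 0.0, 30.0, 37.0),
    }


@dataclass
class SyntheticConfig:
    """Configuration shared by all three generators.

    The defaults define a 0–20°E sector of the Southern Ocean at 1°, 1998–2024
    at 8-day cadence — a desk-scale stand-in for the circumpolar archives.
    """

    lat_range: tuple = (-78.0, -40.0)
    lon_range: tuple = (0.0, 20.0)
    grid_res: float = 1.0
    start_year: int = 1998
    end_year: int = 2024
    cadence: str = "8D"                         # "8D" or "MS"
    variables: dict = field(default_factory=default_rs_variables)

    # float generator -------------------------------------------------------
    float_count: int = 20
    profiles_per_float: int = 25
    float_years: tuple = (2014, 2024)
    quench_factor: float = 0.5                  # multiplicative suppression
    quench_depth: float | None = None           # None → min(0.5·MLD, 20 m)
    spike_rate: float = 2.0                     # spikes per profile (count)
    negative_rate: float = 0.01                 # fraction of b_bp samples
    bad_flag_fraction: float = 0.05
    day_fraction: float = 0.5
    depth_spacing: tuple = (2.0, 8.0)           # m, irregular raw sampling
    max_depth: float = 1000.0
    bbp_deep_baseline: float = 4e-4             # m⁻¹ non-algal background
    float_amp_trend: float = 0.0                # fractional yr⁻¹ on chl & C_phyto
    theta_float: float = 0.010                  # Chl:C of the synthetic floats

    # ESM generator ----------------------------------------------------------
    esm_models: int = 5
    esm_pft_count: int = 3
    esm_res: tuple = (1.25, 1.5)                # (dlat, dlon) native degrees
    esm_alpha: float = 0.01                     # ΔNPP per ΔC_phyto, day⁻¹
    esm_beta: float = 0.01                      # ΔNPP per ΔLimFe, mol C m⁻² day⁻¹
    esm_gamma: float = 0.01                     # ΔNPP per ΔLimIrr
    esm_noise_frac: float = 0.10                # ε sd as fraction of δNPP sd
    esm_monthly_noise: float = 0.0              # sd of monthly weather noise
    esm_hist_years: tuple = (1995, 2014)
    esm_scenario_years: tuple = (2015, 2100)
    esm_cumulative_pgc: dict = field(default_factory=lambda: {
        "ssp245": 0.3, "ssp370": 0.5, "ssp585": 0.5})
    esm_cumulative_spread: float = 0.2          # across-model spread, Pg C
    # the prescribed cumulative changes describe the full circumpolar band;
    # a sector domain carries its proportional share unless this is disabled
    esm_scale_target_by_area: bool = True
    esm_intpp_base: float = 0.010               # mol C m⁻² day⁻¹
    esm_driver_shares: tuple = (0.4, 0.3, 0.3)  # biomass / Fe / light shares

    seed: int = 0

    def validate(self) -> None:
        if self.grid_res <= 0:
            raise ValueError("grid_res must be > 0")
        if not 0.0 < self.quench_factor <= 1.0:
            raise ValueError("quench_factor must be in (0, 1]")
        for nm in ("spike_rate", "negative_rate", "bad_flag_fraction"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be >= 0")
        if self.esm_pft_count < 1:
            raise ValueError("esm_pft_count must be >= 1")
        for nm in ("esm_alpha", "esm_beta", "esm_gamma"):
            if not np.isfinite(getattr(self, nm)):
                raise ValueError(f"{nm} must be finite")
        for name, spec in self.variables.items():
            spec.validate(name)

    def replace(self, **kw) -> "SyntheticConfig":
        return replace(self, **kw)


@dataclass
class TruthRecord:
    """Ground truth carried alongside every generated dataset."""

    kind: str
    imposed_trends: dict = field(default_factory=dict)
    regional_npp_trend_pgc: float | None = None
    float_truth: list = field(default_factory=list)
    esm_coeffs: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def to_json(self) -> str:
        """JSON sidecar: scalars and per-profile summaries (arrays summarised)."""
        def _clean(obj):
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            if isinstance(obj, np.ndarray):
                return {"n": int(obj.size), "mean": float(np.nanmean(obj))} \
                    if obj.size > 24 else [float(v) for v in obj.ravel()]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if isinstance(obj, np.datetime64):
                return str(obj)
            return obj
        return json.dumps(_clean({
            "kind": self.kind,
            "imposed_trends": self.imposed_trends,
            "regional_npp_trend_pgc": self.regional_npp_trend_pgc,
            "float_truth": self.float_truth,
            "esm_coeffs": self.esm_coeffs,
            "extras": self.extras,
        }), sort_keys=True)


# ---------------------------------------------------------------------------
# gridded remote-sensing-like fields
# ---------------------------------------------------------------------------

def _grid_axes(cfg: SyntheticConfig):
    lat = np.arange(cfg.lat_range[0] + cfg.grid_res / 2, cfg.lat_range[1],
                    cfg.grid_res)
    lon = np.arange(cfg.lon_range[0] + cfg.grid_res / 2, cfg.lon_range[1],
                    cfg.grid_res)
    return lat, lon


def _time_axis(cfg: SyntheticConfig):
    """8-day (46 per year, same days every year) or month-start cadence."""
    if cfg.cadence == "8D":
        doys = np.arange(1, 366, 8)
        times = []
        for year in range(cfg.start_year, cfg.end_year + 1):
            base = np.datetime64(f"{year}-01-01")
            times.extend(base + np.timedelta64(1, "D") * (doys - 1))
        return pd.DatetimeIndex(times)
    if cfg.cadence == "MS":
        return pd.date_range(f"{cfg.start_year}-01-01", f"{cfg.end_year}-12-01",
                             freq="MS")
    raise ValueError(f"unknown cadence {cfg.cadence!r}")


def _years_since_start(times: pd.DatetimeIndex) -> np.ndarray:
    t0 = times[0]
    return (times - t0).days.to_numpy() / 365.25


def _ar1(rng, rho, sd, shape):
    """Stationary AR(1) noise: e_t = ρ e_{t−1} + √(1−ρ²)·sd·w_t."""
    nt = shape[0]
    w = rng.standard_normal(shape)
    e = np.empty(shape)
    e[0] = sd * w[0]
    scale = np.sqrt(1.0 - rho ** 2) * sd
    for t in range(1, nt):
        e[t] = rho * e[t - 1] + scale * w[t]
    return e


def gen_rs_fields(cfg: SyntheticConfig, seed: int | None = None):
    """Generate the gridded ocean-colour/physics dataset and its truth record.

    Returns ``(xr.Dataset, TruthRecord)`` with dims (time, lat, lon) and the
    imposed per-variable linear trends recorded.  If a variable named ``npp``
    is present its exact noiseless regional trend (Pg C yr⁻¹ per year) is also
    recorded (imposed trends are spatially uniform, so it is the area-weighted
    sum of the per-pixel trend).
    """
    cfg.validate()
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    lat, lon = _grid_axes(cfg)
    times = _time_axis(cfg)
    doy = times.dayofyear.to_numpy()
    tyr = _years_since_start(times)
    shape = (len(times), len(lat), len(lon))

    data = {}
    for name, spec in cfg.variables.items():
        base = (spec.baseline
                + spec.trend_per_year * tyr
                + spec.seasonal_amp * np.sin(2 * np.pi * doy / 365.0 + spec.phase))
        fld = base[:, None, None] + _ar1(rng, spec.rho, spec.noise_sd, shape) \
            if spec.noise_sd > 0 else np.broadcast_to(
                base[:, None, None], shape).copy()
        if spec.clip_min is not None or spec.clip_max is not None:
            fld = np.clip(fld, spec.clip_min, spec.clip_max)
        data[name] = (("time", "lat", "lon"), fld)

    ds = xr.Dataset(data, coords={"time": times, "lat": lat, "lon": lon})
    ds.attrs["title"] = "synthetic ocean-colour fields"
    ds.attrs["seed"] = int(seed)
    units = {"chl": "mg m-3", "bbp": "m-1", "aph": "m-1", "adg": "m-1",
             "kd490": "m-1", "eta": "1", "par": "mol photons m-2 day-1",
             "sst": "degC", "mld": "m", "zno3": "m", "sss": "1",
             "npp": "mg C m-2 day-1"}
    for v in ds.data_vars:
        ds[v].attrs["units"] = units.get(v, "1")

    truth = TruthRecord(
        kind="rs_fields",
        imposed_trends={k: v.trend_per_year for k, v in cfg.variables.items()})
    if "npp" in cfg.variables:
        # uniform imposed trend: exact regional trend is trend × cap area × 365
        area = _cell_areas(lat, lon, cfg.grid_res)
        total_area = float(area.sum()) * len(lon)
        truth.regional_npp_trend_pgc = (
            cfg.variables["npp"].trend_per_year * total_area * 365.0 / 1e18)
        truth.extras["regional_area_m2"] = total_area
    return ds, truth


def _cell_areas(lat, lon, res):
    """Per-latitude-row pixel areas, m² (see trend_analysis.area_weights)."""
    phi1 = np.deg2rad(lat - res / 2)
    phi2 = np.deg2rad(lat + res / 2)
    return EARTH_RADIUS ** 2 * np.deg2rad(res) * (np.sin(phi2) - np.sin(phi1))


# ---------------------------------------------------------------------------
# float profiles
# ---------------------------------------------------------------------------

def _true_chl_profile(z, chl0, mld, dcm_depth, dcm_width, dcm_amp):
    """Mixed-layer plateau plus Gaussian deep maximum, decaying below."""
    plateau = np.where(z <= mld, chl0, chl0 * np.exp(-(z - mld) / 50.0))
    dcm = dcm_amp * np.exp(-((z - dcm_depth) / dcm_width) ** 2)
    return plateau + dcm


def gen_float_dataset(cfg: SyntheticConfig, seed: int | None = None):
    """Generate float profiles with instrument artifacts plus the truth.

    Raw fluorescence is 2 × true chlorophyll (the slope-factor convention that
    the processing chain divides out); daytime profiles are quenched
    (multiplied by ``quench_factor``) above the quench depth; b_bp(700) is the
    non-algal baseline plus true C_phyto divided through the processing
    chain's conversion, with isolated spikes and occasional negatives; QC
    flags are drawn from {1,2,5,8} with a configured bad fraction of {3,4}.
    """
    cfg.validate()
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    if cfg.profiles_per_float == 0 or cfg.float_count == 0:
        warnings.warn("float generator configured for zero profiles")
        return [], TruthRecord(kind="floats")

    y0, y1 = cfg.float_years
    t_start = np.datetime64(f"{y0}-01-01")
    span_days = (np.datetime64(f"{y1}-12-31") - t_start) / np.timedelta64(1, "D")

    profiles, truth_list = [], []
    for fi in range(cfg.float_count):
        fid = f"SYN{fi:04d}"
        f_lat = rng.uniform(cfg.lat_range[0] + 2, cfg.lat_range[1] - 2)
        f_lon = rng.uniform(*cfg.lon_range)
        chl0_f = float(np.exp(rng.normal(np.log(0.4), 0.3)))
        day_offsets = np.sort(rng.uniform(0, span_days, cfg.profiles_per_float))
        for pi in range(cfg.profiles_per_float):
            time = t_start + np.timedelta64(int(day_offsets[pi] * 86400), "s")
            t_years = day_offsets[pi] / 365.25
            amp = max(1.0 + cfg.float_amp_trend * t_years, 0.05)

            steps = rng.uniform(*cfg.depth_spacing,
                                int(cfg.max_depth / cfg.depth_spacing[0]) + 2)
            z = np.cumsum(steps)
            z = np.concatenate([[rng.uniform(1.0, 3.0)], z + 3.0])
            z = z[z <= cfg.max_depth]

            mld = float(rng.uniform(30.0, 120.0))
            dcm_depth = mld + rng.uniform(15.0, 45.0)
            chl_true = amp * _true_chl_profile(
                z, chl0_f, mld, dcm_depth, rng.uniform(10.0, 20.0),
                rng.uniform(0.3, 0.7) * chl0_f)
            cphyto_true = chl_true / cfg.theta_float

            t_surf, t_deep = rng.uniform(3.0, 6.0), rng.uniform(0.5, 2.0)
            s_surf, s_deep = rng.uniform(33.7, 34.0), rng.uniform(34.3, 34.6)
            blend = 1.0 / (1.0 + np.exp(-(z - mld) / 1.0))   # sharp 2-layer step
            temp = t_surf + (t_deep - t_surf) * blend
            sal = s_surf + (s_deep - s_surf) * blend

            par0 = rng.uniform(15.0, 45.0)
            kd = 0.04 + 0.03 * chl0_f
            par = par0 * np.exp(-kd * z)

            is_day = bool(rng.uniform() < cfg.day_fraction)
            fchl = 2.0 * chl_true
            qdepth = cfg.quench_depth if cfg.quench_depth is not None \
                else min(0.5 * mld, 20.0)
            if is_day and cfg.quench_factor < 1.0:
                fchl = np.where(z < qdepth, fchl * cfg.quench_factor, fchl)

            bbp = cfg.bbp_deep_baseline + cphyto_true / (
                CPHYTO_SLOPE_FACTOR * BBP_700_TO_470)
            n_spikes = int(round(cfg.spike_rate))
            spike_idx = np.array([], dtype=int)
            if n_spikes > 0 and z.size > 2 * n_spikes:
                spike_idx = rng.choice(np.arange(1, z.size - 1), n_spikes,
                                       replace=False)
                bbp = bbp.copy()
                bbp[spike_idx] += rng.uniform(5.0, 15.0, n_spikes) * bbp[spike_idx]
            neg_idx = np.flatnonzero(rng.uniform(size=z.size) < cfg.negative_rate)
            if neg_idx.size:
                bbp[neg_idx] = -np.abs(bbp[neg_idx]) * 0.1

            qc = {}
            for name in ("temp", "sal", "fchl", "bbp700", "par"):
                flags = rng.choice([1, 2, 5, 8], size=z.size,
                                   p=[0.85, 0.09, 0.03, 0.03])
                bad = rng.uniform(size=z.size) < cfg.bad_flag_fraction
                flags[bad] = rng.choice([3, 4], size=int(bad.sum()))
                qc[name] = flags
            # corrupt flagged-bad samples so QC selection matters
            fchl_obs = fchl.copy()
            fchl_obs[np.isin(qc["fchl"], (3, 4))] *= rng.uniform(3.0, 8.0)
            bbp_obs = bbp.copy()
            bbp_obs[np.isin(qc["bbp700"], (3, 4))] *= rng.uniform(3.0, 8.0)

            profiles.append(FloatProfile(
                float_id=fid, time=time, lat=f_lat, lon=f_lon, z=z,
                temp=temp, sal=sal, fchl=fchl_obs, bbp700=bbp_obs, par=par,
                qc=qc, is_day=is_day))
            truth_list.append({
                "float_id": fid, "time": time, "lat": f_lat, "lon": f_lon,
                "z": z, "chl": chl_true, "cphyto": cphyto_true, "par": par,
                "temp": temp, "mld": mld, "quench_depth": qdepth,
                "is_day": is_day, "spike_indices": spike_idx,
                "amp": amp,
            })

    truth = TruthRecord(kind="floats", float_truth=truth_list,
                        extras={"amp_trend_per_year": cfg.float_amp_trend,
                                "theta": cfg.theta_float,
                                "bbp_deep_baseline": cfg.bbp_deep_baseline})
    return profiles, truth


# ---------------------------------------------------------------------------
# ESM-like ensemble
# ---------------------------------------------------------------------------

@dataclass
class ESMEnsembleMember:
    """Monthly NPP/biomass/limitation fields for one model–scenario pair.

    ``intpp`` covers the member's full year span; the driver fields (phyc,
    per-PFT biomass and limitation terms) are archived only for the analysis
    period the member contributes to (historical 1995–2014, scenario
    2081–2100 by default) — the decadal-change operations need no more.
    """

    model_id: str
    scenario: str
    intpp: xr.DataArray                 # (time, lat, lon) mol C m-2 day-1
    phyc: xr.DataArray                  # (time2, lev, lat, lon) mol C m-3
    biomass: xr.DataArray               # (pft, time2, lat, lon) mol C m-3
    limfe: xr.DataArray                 # (pft, time2, lat, lon) in [0, 1]
    limirr: xr.DataArray
    native_res: tuple = (1.25, 1.5)


def _esm_axes(cfg):
    dlat, dlon = cfg.esm_res
    lat = np.arange(cfg.lat_range[0] + dlat / 2, cfg.lat_range[1], dlat)
    lon = np.arange(cfg.lon_range[0] + dlon / 2, cfg.lon_range[1], dlon)
    return lat, lon


def _month_axis(y0, y1):
    return pd.date_range(f"{y0}-01-01", f"{y1}-12-01", freq="MS")


def _month_centers_years(times):
    return times.year.to_numpy() + (times.month.to_numpy() - 0.5) / 12.0


def _ramp(times, hist_end=2014, future_mid=2091.0):
    """Linear ramp: 0 through the historical period, 1 at the 2081–2100 mean.

    ``future_mid`` is the mean of the monthly time centers over 2081–2100
    (2090.5 + ½ year), so the period-mean of the ramp is exactly 1 and the
    constructed Δ fields are recovered exactly in the noise-free case.
    """
    tc = _month_centers_years(times)
    return np.clip((tc - (hist_end + 0.5)) / (future_mid - (hist_end + 0.5)),
                   0.0, None)


def gen_esm_ensemble(cfg: SyntheticConfig, seed: int | None = None):
    """Generate the ESM-like ensemble and its truth record.

    For each model, one historical member plus one member per scenario.  The
    end-of-century change field is constructed per cell as

        ΔNPP = α·ΔC_phyto + β·ΔLimFe + γ·ΔLimIrr + ε,

    with spatially orthogonal driver patterns, and scaled so the regional
    cumulative NPP change (Pg C by 2081–2100 vs 1995–2014) equals the
    prescribed per-model target.  Per-PFT surface biomass fractions sum to 1.
    """
    cfg.validate()
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    lat, lon = _esm_axes(cfg)
    nlat, nlon = len(lat), len(lon)
    # orthogonal, zero-mean spatial patterns: a sin/cos quadrature pair over
    # the lon index plus a latitude mode.  The lat/lon separation keeps the
    # third pattern exactly uncorrelated with the first two under any
    # latitude-dependent area weighting, including after conservative
    # regridding (which acts on lat and lon independently).
    lon_frac = (np.arange(nlon) + 0.5) / nlon
    p1 = np.broadcast_to(np.sin(2 * np.pi * lon_frac), (nlat, nlon))
    p2 = np.broadcast_to(np.cos(2 * np.pi * lon_frac), (nlat, nlon))

    dlat, dlon = cfg.esm_res
    phi1 = np.deg2rad(lat - dlat / 2)
    phi2 = np.deg2rad(lat + dlat / 2)
    row_area = EARTH_RADIUS ** 2 * np.deg2rad(dlon) * (np.sin(phi2) - np.sin(phi1))
    area2d = np.broadcast_to(row_area[:, None], (nlat, nlon))
    total_area = float(area2d.sum())

    lat_frac = (np.arange(nlat) + 0.5) / nlat
    p3_raw = np.sin(2 * np.pi * lat_frac)
    p3_raw = p3_raw - (p3_raw * row_area).sum() / row_area.sum()
    p3 = np.broadcast_to(p3_raw[:, None], (nlat, nlon))

    hist_times = _month_axis(*cfg.esm_hist_years)
    scen_times = _month_axis(*cfg.esm_scenario_years)
    month = scen_times.month.to_numpy()
    seasonal = 1.0 + 0.6 * np.sin(2 * np.pi * month / 12.0 + np.pi / 2)
    seasonal_h = 1.0 + 0.6 * np.sin(2 * np.pi * hist_times.month.to_numpy()
                                    / 12.0 + np.pi / 2)
    ramp = _ramp(scen_times, cfg.esm_hist_years[1])

    lev = np.array([0., 10., 20., 30., 40., 50., 60., 70., 80., 90., 100.,
                    150., 200.])
    sA, sB, sC = cfg.esm_driver_shares

    members, truth_models = [], {}
    for mi in range(cfg.esm_models):
        model_id = f"SYN-ESM-{mi:02d}"
        level = cfg.esm_intpp_base * rng.uniform(0.6, 1.6)
        base2d = level * (1.0 + 0.3 * rng.standard_normal((nlat, nlon)) * 0.0
                          + 0.3 * np.cos(np.deg2rad(lat))[:, None]
                          * np.cos(2 * np.pi * lon_frac)[None, :])
        base2d = np.maximum(base2d, 0.1 * level)

        # per-PFT surface biomass fractions, fixed per cell, summing to 1
        g = rng.gamma(2.0, 1.0, size=(cfg.esm_pft_count, nlat, nlon))
        frac = g / g.sum(axis=0, keepdims=True)
        phyc_surf = level * 30.0                       # mol C m⁻³ scale
        lim0_fe = rng.uniform(0.3, 0.6, size=(cfg.esm_pft_count, 1, 1)) \
            * np.ones((1, nlat, nlon))
        lim0_irr = rng.uniform(0.4, 0.7, size=(cfg.esm_pft_count, 1, 1)) \
            * np.ones((1, nlat, nlon))

        hist_intpp = base2d[None] * seasonal_h[:, None, None]
        if cfg.esm_monthly_noise > 0:
            hist_intpp = hist_intpp + rng.normal(
                0, cfg.esm_monthly_noise * level, hist_intpp.shape)

        hist_phyc = _phyc_field(phyc_surf, lev, hist_times, lat, lon)
        hist_member = ESMEnsembleMember(
            model_id=model_id, scenario="historical",
            intpp=_da(hist_intpp, hist_times, lat, lon, "mol C m-2 day-1"),
            phyc=hist_phyc,
            biomass=_da_pft(np.broadcast_to(
                frac[:, None] * phyc_surf,
                (cfg.esm_pft_count, len(hist_times), nlat, nlon)),
                hist_times, lat, lon),
            limfe=_da_pft(np.broadcast_to(
                lim0_fe[:, None], (cfg.esm_pft_count, len(hist_times), nlat, nlon)),
                hist_times, lat, lon),
            limirr=_da_pft(np.broadcast_to(
                lim0_irr[:, None], (cfg.esm_pft_count, len(hist_times), nlat, nlon)),
                hist_times, lat, lon),
            native_res=cfg.esm_res)
        members.append(hist_member)
        truth_models[model_id] = {"base_level": level}

        lon_fraction = (cfg.lon_range[1] - cfg.lon_range[0]) / 360.0 \
            if cfg.esm_scale_target_by_area else 1.0
        for scenario, target in cfg.esm_cumulative_pgc.items():
            # per-model prescribed cumulative change, spread across the ensemble
            offset = 0.0 if cfg.esm_models == 1 else \
                cfg.esm_cumulative_spread * (2 * mi / (cfg.esm_models - 1) - 1)
            target_m = (target + offset) * lon_fraction
            # mean ΔNPP (mol C m⁻² day⁻¹) needed for the regional Pg C target
            mean_d = target_m * 1e15 / (12.0 * 365.0 * total_area)
            dC = (sA * mean_d / cfg.esm_alpha) * (1 + 0.5 * p1) \
                if cfg.esm_alpha != 0 else np.zeros((nlat, nlon))
            dF = (sB * mean_d / cfg.esm_beta) * (1 + 0.5 * p2) \
                if cfg.esm_beta != 0 else np.zeros((nlat, nlon))
            dI = (sC * mean_d / cfg.esm_gamma) * (1 + 0.5 * p3) \
                if cfg.esm_gamma != 0 else np.zeros((nlat, nlon))
            signal = (cfg.esm_alpha * dC + cfg.esm_beta * dF
                      + cfg.esm_gamma * dI)
            # keep the regional total exact: draw zero-mean noise
            eps_sd = cfg.esm_noise_frac * float(np.std(signal))
            eps = rng.normal(0.0, eps_sd, (nlat, nlon)) if eps_sd > 0 else \
                np.zeros((nlat, nlon))
            eps -= (eps * area2d).sum() / total_area
            dnpp = signal + eps
            missing_shares = sum(s for s, c in
                                 zip((sA, sB, sC),
                                     (cfg.esm_alpha, cfg.esm_beta, cfg.esm_gamma))
                                 if c == 0)
            if missing_shares:
                dnpp = dnpp + missing_shares * mean_d

            intpp = base2d[None] * seasonal[:, None, None] \
                + dnpp[None] * ramp[:, None, None]
            if cfg.esm_monthly_noise > 0:
                intpp = intpp + rng.normal(
                    0, cfg.esm_monthly_noise * level, intpp.shape)

            fut_mask = (scen_times.year >= 2081) & (scen_times.year <= 2100)
            fut_times = scen_times[fut_mask]
            ramp_f = ramp[fut_mask]
            phyc = _phyc_field(phyc_surf, lev, fut_times, lat, lon,
                               delta=dC / 100.0, ramp=ramp_f)
            limfe_f = lim0_fe[:, None] + dF[None, None] * ramp_f[None, :, None, None]
            limirr_f = lim0_irr[:, None] + dI[None, None] * ramp_f[None, :, None, None]
            lim_clipped = bool(np.any((limfe_f < 0) | (limfe_f > 1)
                                      | (limirr_f < 0) | (limirr_f > 1)))
            if lim_clipped:
                warnings.warn(
                    f"{model_id}/{scenario}: limitation deltas hit the [0,1] "
                    "bounds; the clipped fields no longer follow the exact "
                    "linear construction")

            members.append(ESMEnsembleMember(
                model_id=model_id, scenario=scenario,
                intpp=_da(intpp, scen_times, lat, lon, "mol C m-2 day-1"),
                phyc=phyc,
                biomass=_da_pft(np.broadcast_to(
                    frac[:, None] * phyc_surf,
                    (cfg.esm_pft_count, len(fut_times), nlat, nlon)),
                    fut_times, lat, lon),
                limfe=_da_pft(np.clip(limfe_f, 0, 1), fut_times, lat, lon),
                limirr=_da_pft(np.clip(limirr_f, 0, 1), fut_times, lat, lon),
                native_res=cfg.esm_res))
            truth_models[model_id][scenario] = {
                "cumulative_pgc": target_m,
                "limit_clipped": lim_clipped,
                "delta_cphyto": dC, "delta_limfe": dF, "delta_limirr": dI,
                "delta_npp": dnpp, "noise_sd": eps_sd,
                # the ramp is linear from hist_end: exact regional trend
                "regional_trend_pgc_per_yr": target_m / (2091.0 - (cfg.esm_hist_years[1] + 0.5)),
            }

    truth = TruthRecord(
        kind="esm",
        esm_coeffs={"alpha": cfg.esm_alpha, "beta": cfg.esm_beta,
                    "gamma": cfg.esm_gamma,
                    "noise_frac": cfg.esm_noise_frac},
        extras={"models": truth_models, "total_area_m2": total_area})
    return members, truth


def _phyc_field(phyc_surf, lev, times, lat, lon, delta=None, ramp=None):
    """Phytoplankton carbon profile: uniform to 100 m then linear decay."""
    shape_surface = np.ones((len(times), len(lat), len(lon))) * phyc_surf
    if delta is not None and ramp is not None:
        shape_surface = shape_surface + delta[None] * ramp[:, None, None]
    vert = np.where(lev <= 100.0, 1.0, np.maximum(1.0 - (lev - 100.0) / 100.0, 0.0))
    arr = shape_surface[:, None] * vert[None, :, None, None]
    return xr.DataArray(
        arr, dims=("time", "lev", "lat", "lon"),
        coords={"time": times, "lev": lev, "lat": lat, "lon": lon},
        attrs={"units": "mol C m-3"})


def _da(arr, times, lat, lon, units):
    return xr.DataArray(arr, dims=("time", "lat", "lon"),
                        coords={"time": times, "lat": lat, "lon": lon},
                        attrs={"units": units})


def _da_pft(arr, times, lat, lon):
    return xr.DataArray(np.asarray(arr), dims=("pft", "time", "lat", "lon"),
                        coords={"time": times, "lat": lat, "lon": lon})
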