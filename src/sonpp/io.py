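"""Readers, writers, configuration and the end-to-end pipeline manifest.

Gridded data are CF-style NetCDF (classic format via scipy); float profiles
are a flat CSV (one row per sample) with an Argo-like per-float NetCDF reader
as an adapter; configuration and manifests are JSON.  Every numeric output
carries the hash of the configuration and of the serialized algorithm
coefficient set, so results are reproducible from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from . import argo as _argo
from . import esm as _esm
from . import npp as _npp
from . import synthetic as _synth
from . import trends as _trends

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "read_grid",
    "write_grid",
    "write_profiles_csv",
    "read_profiles_csv",
    "read_argo_netcdf",
    "run_pipeline",
    "config_hash",
]

log = logging.getLogger(__name__)

NETCDF_ENGINE = "scipy"

#: variable-name mapping accepted on read (external name → internal name)
VARIABLE_ALIASES = {
    "chlor_a": "chl", "CHL": "chl", "bbp443": "bbp", "bbp_443": "bbp",
    "kd_490": "kd490", "Kd_490": "kd490", "PAR": "par", "SST": "sst",
    "analysed_sst": "sst", "MLD": "mld", "so": "sss", "SSS": "sss",
    "intpp": "intpp", "phyc": "phyc",
}


class ConfigError(ValueError):
    """Invalid pipeline configuration (validation failure, exit code 2)."""


_ALLOWED_KEYS = {
    "region_lat", "out_dir", "algorithms", "coefficients", "seed",
    "synthetic", "trend", "stages", "window_years", "esm_scenarios",
}


@dataclass
class PipelineConfig:
    """Validated configuration for the end-to-end pipeline."""

    region_lat: float = -40.0
    out_dir: str = "sonpp_out"
    algorithms: tuple = _npp.ALGORITHMS
    coefficients: _npp.AlgorithmCoefficients = field(
        default_factory=_npp.AlgorithmCoefficients)
    seed: int = 0
    synthetic: _synth.SyntheticConfig = field(
        default_factory=_synth.SyntheticConfig)
    trend: _trends.TrendConfig = field(default_factory=_trends.TrendConfig)
    stages: tuple = ("simulate", "npp", "argo", "trends", "esm", "report")
    window_years: int = 20
    esm_scenarios: tuple = ("ssp245", "ssp370", "ssp585")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - _ALLOWED_KEYS
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        kw = dict(d)
        if "algorithms" in kw:
            bad = [a for a in kw["algorithms"] if a not in _npp.ALGORITHMS]
            if bad:
                raise ConfigError(
                    f"unknown algorithm(s) {bad}; valid: {list(_npp.ALGORITHMS)}")
            kw["algorithms"] = tuple(kw["algorithms"])
        if "coefficients" in kw and isinstance(kw["coefficients"], dict):
            try:
                kw["coefficients"] = _npp.AlgorithmCoefficients(
                    **{k: tuple(v) if isinstance(v, list) else v
                       for k, v in kw["coefficients"].items()})
            except TypeError as e:
                raise ConfigError(f"bad coefficients: {e}") from e
        if "synthetic" in kw and isinstance(kw["synthetic"], dict):
            sd = dict(kw["synthetic"])
            if "variables" in sd:
                sd["variables"] = {
                    k: _synth.VariableSpec(**v) for k, v in sd["variables"].items()}
            for tk in ("lat_range", "lon_range", "float_years"):
                if tk in sd:
                    sd[tk] = tuple(sd[tk])
            try:
                kw["synthetic"] = _synth.SyntheticConfig(**sd)
            except TypeError as e:
                raise ConfigError(f"bad synthetic config: {e}") from e
        if "trend" in kw and isinstance(kw["trend"], dict):
            kw["trend"] = _trends.TrendConfig(**kw["trend"])
        if "stages" in kw:
            kw["stages"] = tuple(kw["stages"])
        if "esm_scenarios" in kw:
            kw["esm_scenarios"] = tuple(kw["esm_scenarios"])
        cfg = cls(**kw)
        cfg.validate()
        return cfg

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def validate(self) -> None:
        if not -90 <= self.region_lat <= 0:
            raise ConfigError("region_lat must be in [-90, 0]")
        try:
            self.synthetic.validate()
        except ValueError as e:
            raise ConfigError(str(e)) from e
        bad = [a for a in self.algorithms if a not in _npp.ALGORITHMS]
        if bad:
            raise ConfigError(f"unknown algorithm(s) {bad}")
        bad_stage = [s for s in self.stages if s not in
                     ("simulate", "npp", "argo", "trends", "esm", "report")]
        if bad_stage:
            raise ConfigError(f"unknown stage(s) {bad_stage}")

    def canonical(self) -> str:
        """Scientific configuration only — output paths are excluded so two
        runs of the same analysis hash identically wherever they land."""
        def enc(o):
            if isinstance(o, _npp.AlgorithmCoefficients):
                return json.loads(o.to_json())
            if hasattr(o, "__dict__"):
                return {k: enc(v) for k, v in o.__dict__.items()
                        if k != "out_dir"}
            if isinstance(o, dict):
                return {k: enc(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [enc(v) for v in o]
            return o
        return json.dumps(enc(self), sort_keys=True, default=str)


def config_hash(cfg: PipelineConfig) -> str:
    return hashlib.sha256(cfg.canonical().encode()).hexdigest()[:16]


def demo_config(out_dir: str = "sonpp_demo", seed: int = 0) -> PipelineConfig:
    """Packaged demo: a small sector so the full pipeline runs in minutes."""
    synth = _synth.SyntheticConfig(
        lat_range=(-65.0, -45.0), lon_range=(0.0, 6.0),
        start_year=2000, end_year=2023,
        float_count=6, profiles_per_float=6, float_years=(2014, 2023),
        esm_models=2)
    return PipelineConfig(out_dir=out_dir, seed=seed, synthetic=synth)


@dataclass
class RunManifest:
    config_hash: str
    coefficient_hash: str
    seed: int
    stages: dict = field(default_factory=dict)   # stage → record counts etc.
    outputs: dict = field(default_factory=dict)  # path → sha256
    timings: dict = field(default_factory=dict)  # stage → seconds
    warnings: list = field(default_factory=list)

    def identity(self) -> dict:
        """Everything except timings — must be identical across reruns."""
        return {"config_hash": self.config_hash,
                "coefficient_hash": self.coefficient_hash,
                "seed": self.seed, "stages": self.stages,
                "outputs": self.outputs, "warnings": self.warnings}

    def to_json(self) -> str:
        return json.dumps({**self.identity(), "timings": self.timings},
                          indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# NetCDF / CSV round trips
# ---------------------------------------------------------------------------

def write_grid(ds: xr.Dataset | xr.DataArray, path, manifest: RunManifest | None = None):
    """Write a gridded dataset as CF-style NetCDF (classic format)."""
    if isinstance(ds, xr.DataArray):
        ds = ds.to_dataset(name=ds.name or "field")
    ds = ds.copy()
    ds.attrs.setdefault("Conventions", "CF-1.8")
    if manifest is not None:
        ds.attrs["config_hash"] = manifest.config_hash
        ds.attrs["coefficient_hash"] = manifest.coefficient_hash
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ds.to_netcdf(path, engine=NETCDF_ENGINE)
    if manifest is not None:
        manifest.outputs[str(path)] = _file_hash(path)
    return path


def read_grid(path, rename: dict | None = None) -> xr.Dataset:
    """Read a CF NetCDF grid, applying the variable-name mapping table.

    Raises a schema error naming the missing coordinate if lat/lon/time are
    absent.  Any `intpp` declared per second is auto-converted to per day and
    flagged in its attributes.
    """
    ds = xr.open_dataset(path, engine=NETCDF_ENGINE).load()
    mapping = {**VARIABLE_ALIASES, **(rename or {})}
    present = {k: v for k, v in mapping.items() if k in ds and v not in ds}
    ds = ds.rename(present)
    for coord in ("lat", "lon"):
        if coord not in ds.coords and coord not in ds:
            raise ValueError(f"schema error: missing coordinate variable {coord!r}")
    if "intpp" in ds:
        ds["intpp"] = _esm.intpp_to_per_day(ds["intpp"])
    return ds


_PROFILE_COLS = ["float_id", "time", "lat", "lon", "is_day", "z", "temp",
                 "sal", "fchl", "bbp700", "par", "qc_temp", "qc_sal",
                 "qc_fchl", "qc_bbp700", "qc_par"]


def write_profiles_csv(profiles, path, manifest: RunManifest | None = None):
    """Flat CSV, one row per (profile, depth) sample; RFC 4180, UTF-8."""
    rows = []
    for i, p in enumerate(profiles):
        n = len(p.z)
        rows.append(pd.DataFrame({
            "profile_index": i, "float_id": p.float_id,
            "time": np.repeat(np.datetime64(p.time, "s"), n),
            "lat": p.lat, "lon": p.lon, "is_day": p.is_day,
            "z": p.z, "temp": p.temp, "sal": p.sal, "fchl": p.fchl,
            "bbp700": p.bbp700, "par": p.par,
            **{f"qc_{k}": v for k, v in p.qc.items()},
        }))
    df = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["profile_index"] + _PROFILE_COLS)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    if manifest is not None:
        manifest.outputs[str(path)] = _file_hash(path)
    return path


def read_profiles_csv(path):
    """Inverse of :func:`write_profiles_csv`."""
    df = pd.read_csv(path, parse_dates=["time"])
    profiles = []
    for _, grp in df.groupby("profile_index", sort=True):
        qc = {k[3:]: grp[k].to_numpy(dtype=int)
              for k in grp.columns if k.startswith("qc_")}
        profiles.append(_argo.FloatProfile(
            float_id=str(grp["float_id"].iloc[0]),
            time=np.datetime64(grp["time"].iloc[0]),
            lat=float(grp["lat"].iloc[0]), lon=float(grp["lon"].iloc[0]),
            z=grp["z"].to_numpy(dtype=float),
            temp=grp["temp"].to_numpy(dtype=float),
            sal=grp["sal"].to_numpy(dtype=float),
            fchl=grp["fchl"].to_numpy(dtype=float),
            bbp700=grp["bbp700"].to_numpy(dtype=float),
            par=grp["par"].to_numpy(dtype=float),
            qc=qc, is_day=bool(grp["is_day"].iloc[0])))
    return profiles


_ARGO_VARS = {"PRES": "z", "TEMP": "temp", "PSAL": "sal", "CHLA": "fchl",
              "BBP700": "bbp700", "DOWNWELLING_PAR": "par"}


def read_argo_netcdf(path, float_id=None):
    """Adapter for Argo-like per-float NetCDF (PRES/TEMP/PSAL/CHLA/BBP700/
    DOWNWELLING_PAR plus *_QC), one profile per N_PROF row."""
    ds = xr.open_dataset(path, engine=NETCDF_ENGINE).load()
    missing = [v for v in _ARGO_VARS if v not in ds]
    if missing:
        raise ValueError(f"schema error: missing variable(s) {missing}")
    n_prof = ds.sizes.get("N_PROF", 1)
    out = []
    for i in range(n_prof):
        row = ds.isel(N_PROF=i) if "N_PROF" in ds.dims else ds
        fields = {new: np.asarray(row[old].values, dtype=float)
                  for old, new in _ARGO_VARS.items()}
        qc = {}
        for old, new in _ARGO_VARS.items():
            if new == "z":
                continue
            qname = old + "_QC"
            if qname in row:
                raw = np.asarray(row[qname].values)
                qc[new] = np.array([int(c) for c in raw.astype(str)]) \
                    if raw.dtype.kind in "SU" else raw.astype(int)
        order = np.argsort(fields["z"])
        t = row["JULD"].values if "JULD" in row else np.datetime64("2000-01-01")
        out.append(_argo.FloatProfile(
            float_id=float_id or str(getattr(row, "PLATFORM_NUMBER", "argo")),
            time=np.datetime64(np.ravel(t)[0] if np.ndim(t) else t, "s"),
            lat=float(np.ravel(row["LATITUDE"].values)[0]) if "LATITUDE" in row else np.nan,
            lon=float(np.ravel(row["LONGITUDE"].values)[0]) if "LONGITUDE" in row else np.nan,
            z=fields["z"][order],
            temp=fields["temp"][order], sal=fields["sal"][order],
            fchl=fields["fchl"][order], bbp700=fields["bbp700"][order],
            par=fields["par"][order],
            qc={k: v[order] for k, v in qc.items()}))
    return out


def _file_hash(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(cfg: PipelineConfig) -> RunManifest:
    """Run simulate → npp → argo → trends → esm → report as configured.

    Deterministic given the seed; any stage failure aborts downstream stages
    and the manifest records partial completion.  Outputs land in
    ``cfg.out_dir`` (NetCDF grids, CSV tables, JSON manifest).
    """
    cfg.validate()
    manifest = RunManifest(
        config_hash=config_hash(cfg),
        coefficient_hash=hashlib.sha256(
            cfg.coefficients.to_json().encode()).hexdigest()[:16],
        seed=cfg.seed)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    state: dict = {}
    scfg = cfg.synthetic.replace(seed=cfg.seed)

    def stage(name, fn):
        if name not in cfg.stages:
            return
        t0 = _time.perf_counter()
        fn()
        manifest.timings[name] = round(_time.perf_counter() - t0, 3)

    def _simulate():
        ds, truth = _synth.gen_rs_fields(scfg)
        state["rs"] = ds
        write_grid(ds, out / "rs_fields.nc", manifest)
        (out / "rs_truth.json").write_text(truth.to_json())
        manifest.outputs[str(out / "rs_truth.json")] = _file_hash(out / "rs_truth.json")
        profiles, ftruth = _synth.gen_float_dataset(scfg)
        state["profiles"], state["ftruth"] = profiles, ftruth
        write_profiles_csv(profiles, out / "float_profiles.csv", manifest)
        manifest.stages["simulate"] = {
            "grid_pixels": int(ds["chl"].size), "profiles": len(profiles)}

    def _npp_stage():
        results = {}
        for alg in cfg.algorithms:
            da = _npp.compute_npp(state["rs"], alg, cfg.coefficients)
            results[alg] = da
            write_grid(da.to_dataset(name="npp"), out / f"npp_{alg}.nc", manifest)
        state["npp"] = results
        manifest.stages["npp"] = {a: int(np.isfinite(v.values).sum())
                                  for a, v in results.items()}

    def _argo_stage():
        processed = _argo.process_profiles(state["profiles"])
        state["processed"] = processed
        rows = []
        for p in processed:
            env = _npp.DepthEnvironment(
                z=p.z, chl=p.chl, cphyto=p.cphyto, par=p.par, temp=p.temp)
            doy = int(pd.Timestamp(p.time).dayofyear)
            _, res = _npp.cbpm_depth_resolved(env, p.lat, doy, cfg.coefficients)
            rows.append({"float_id": p.float_id, "time": p.time, "lat": p.lat,
                         "lon": p.lon, "mld": p.mld, "npp_cbpm": res.npp,
                         "audit": "|".join(p.audit)})
        df = pd.DataFrame(rows)
        df.to_csv(out / "float_npp.csv", index=False)
        manifest.outputs[str(out / "float_npp.csv")] = _file_hash(out / "float_npp.csv")
        state["float_npp"] = df
        manifest.stages["argo"] = {"processed": len(processed),
                                   "input": len(state["profiles"])}

    def _trends_stage():
        rows = []
        jk = {}
        for alg, da in state["npp"].items():
            ser = _trends.regional_series(da)
            summary = _trends.jackknife_windows(ser, cfg.window_years, cfg.trend)
            jk[alg] = summary
            rows.append({"algorithm": alg,
                         "mean_trend_pgc_yr": summary.mean_trend,
                         "sd_trend_pgc_yr": summary.sd_trend,
                         "windows": len(summary.windows)})
        pd.DataFrame(rows).to_csv(out / "regional_trends.csv", index=False)
        manifest.outputs[str(out / "regional_trends.csv")] = \
            _file_hash(out / "regional_trends.csv")
        state["jackknife"] = jk
        if "float_npp" in state and len(state["float_npp"]):
            df = state["float_npp"]
            ft = _trends.float_trend(df["time"], df["npp_cbpm"])
            state["float_trend"] = ft
            manifest.stages.setdefault("trends", {})["float_trend_mg_m2_yr"] = \
                None if ft.missing else round(ft.slope, 6)
        manifest.stages.setdefault("trends", {})["algorithms"] = len(rows)

    def _esm_stage():
        members, etruth = _synth.gen_esm_ensemble(scfg)
        state["esm_members"], state["esm_truth"] = members, etruth
        hist = {m.model_id: m for m in members if m.scenario == "historical"}
        rows = []
        for scen in cfg.esm_scenarios:
            series = {}
            for m in members:
                if m.scenario != scen:
                    continue
                h = hist[m.model_id]
                sh = _esm.esm_regional_series(h)
                sf = _esm.esm_regional_series(m)
                series[m.model_id] = pd.concat([sh, sf])
            if not series:
                continue
            mean, sd, _ = _esm.ensemble_cumulative_change(series)
            rows.append({"scenario": scen, "cumulative_pgc_mean": mean,
                         "cumulative_pgc_sd": sd, "models": len(series)})
        pd.DataFrame(rows).to_csv(out / "esm_cumulative.csv", index=False)
        manifest.outputs[str(out / "esm_cumulative.csv")] = \
            _file_hash(out / "esm_cumulative.csv")
        manifest.stages["esm"] = {"members": len(members),
                                  "scenarios": len(rows)}

    def _report():
        rep = {"stages": manifest.stages}
        if "jackknife" in state:
            rep["regional_trends_pgc_yr"] = {
                a: {"mean": s.mean_trend, "sd": s.sd_trend}
                for a, s in state["jackknife"].items()}
        (out / "report.json").write_text(json.dumps(rep, indent=2, sort_keys=True))
        manifest.outputs[str(out / "report.json")] = _file_hash(out / "report.json")

    try:
        stage("simulate", _simulate)
        stage("npp", _npp_stage)
        stage("argo", _argo_stage)
        stage("trends", _trends_stage)
        stage("esm", _esm_stage)
        stage("report", _report)
    except Exception as e:               # partial completion recorded
        manifest.warnings.append(f"stage failure: {e}")
        (out / "manifest.json").write_text(manifest.to_json())
        raise
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
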