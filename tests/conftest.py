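"""Shared fixtures: synthetic datasets generated once per session."""

import numpy as np
import pandas as pd
import pytest

from sonpp import argo, npp, synthetic


@pytest.fixture(scope="session")
def float_dataset():
    """120 synthetic profiles with all artifacts at default rates, plus truth."""
    cfg = synthetic.SyntheticConfig(float_count=10, profiles_per_float=12)
    profiles, truth = synthetic.gen_float_dataset(cfg, seed=2)
    return cfg, profiles, truth


@pytest.fixture(scope="session")
def processed_floats(float_dataset):
    _, profiles, truth = float_dataset
    processed = argo.process_profiles(profiles)
    truth_map = {(t["float_id"], str(t["time"])): t for t in truth.float_truth}
    return processed, truth_map


@pytest.fixture(scope="session")
def clean_float_dataset():
    """Artifact-free profiles (no quenching, spikes, negatives or bad flags)."""
    cfg = synthetic.SyntheticConfig(
        float_count=6, profiles_per_float=6, quench_factor=1.0,
        spike_rate=0.0, negative_rate=0.0, bad_flag_fraction=0.0)
    profiles, truth = synthetic.gen_float_dataset(cfg, seed=7)
    return cfg, profiles, truth


@pytest.fixture(scope="session")
def esm_small():
    """One-model ensemble, 60° sector, noise-free Δ construction."""
    cfg = synthetic.SyntheticConfig(
        lon_range=(0.0, 60.0), esm_models=1, esm_noise_frac=0.0)
    members, truth = synthetic.gen_esm_ensemble(cfg, seed=4)
    return cfg, members, truth


def cbpm_truth_npp(tr, z_max=200.0):
    """Integrated CbPM NPP on a truth (artifact-free) profile."""
    env = npp.DepthEnvironment(z=tr["z"], chl=tr["chl"], cphyto=tr["cphyto"],
                               par=tr["par"], temp=tr["temp"])
    doy = int(pd.Timestamp(tr["time"]).dayofyear)
    _, res = npp.cbpm_depth_resolved(env, tr["lat"], doy, z_max=z_max)
    return res.npp


def cbpm_processed_npp(p, z_max=200.0):
    env = npp.DepthEnvironment(z=p.z, chl=p.chl, cphyto=p.cphyto,
                               par=p.par, temp=p.temp)
    doy = int(pd.Timestamp(p.time).dayofyear)
    _, res = npp.cbpm_depth_resolved(env, p.lat, doy, z_max=z_max)
    return res.npp


def recovery_ratios(processed, truth_map, min_truth=1.0):
    """Processed/truth integrated NPP ratios, skipping zero-light profiles."""
    ratios = []
    for p in processed:
        tr = truth_map[(p.float_id, str(np.datetime64(p.time, "s")))]
        t = cbpm_truth_npp(tr)
        if t > min_truth:
            ratios.append(cbpm_processed_npp(p) / t)
    return np.asarray(ratios)
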