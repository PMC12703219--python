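"""NPP algorithm tests: closed forms, limits, and family-wide properties."""

import math

import numpy as np
import pytest
import xarray as xr

from sonpp import npp
from sonpp.npp import (AlgorithmCoefficients, DepthEnvironment, SurfacePixel,
                       absorption_npp, bbp_spectral, cbpm_depth_resolved,
                       cbpm_surface, day_length, euphotic_depth,
                       median_ml_light, pb_opt, reconstruct_profile, vgpm)

C = AlgorithmCoefficients()


def reference_pixel(**kw):
    base = dict(chl=0.5, par=30.0, sst=5.0, lat=-50.0, doy=15, bbp=0.002,
                eta=0.78, aph=0.015, adg=0.01, kd490=0.05, mld=40.0,
                zno3=60.0, sss=34.0)
    base.update(kw)
    return SurfacePixel(**base)


# ---------------------------------------------------------------------------
# photophysiology utilities
# ---------------------------------------------------------------------------

class TestDayLength:
    def test_equator_is_half_day(self):
        for doy in (1, 80, 172, 300):
            assert day_length(0.0, doy) == pytest.approx(12.0, abs=0.2)

    def test_austral_polar_day_and_night(self):
        assert day_length(-70.0, 355) == pytest.approx(24.0)
        assert day_length(-70.0, 172) == pytest.approx(0.0)

    def test_against_independent_formula(self):
        # Forsythe et al. (1995) CBM day-length model, evaluated independently
        lat, doy = -50.0, 172
        theta = 0.2163108 + 2 * math.atan(
            0.9671396 * math.tan(0.00860 * (doy - 186)))
        phi = math.asin(0.39795 * math.cos(theta))
        p = 0.0  # sunrise/sunset at centre of sun's disk
        expected = 24 - (24 / math.pi) * math.acos(
            (math.sin(p * math.pi / 180) + math.sin(lat * math.pi / 180) * math.sin(phi))
            / (math.cos(lat * math.pi / 180) * math.cos(phi)))
        assert day_length(lat, doy) == pytest.approx(expected, abs=0.3)

    def test_bounded(self):
        rng = np.random.default_rng(0)
        lats = rng.uniform(-90, 90, 200)
        doys = rng.integers(1, 367, 200)
        dl = day_length(lats, doys)
        assert np.all((dl >= 0.0) & (dl <= 24.0))


class TestEuphoticDepth:
    def test_monotone_nonincreasing_in_chl(self):
        chl = np.linspace(0.01, 10.0, 500)
        zeu = euphotic_depth(chl)
        assert np.all(np.diff(zeu) <= 1e-12)

    def test_hand_value_chl_one(self):
        # direct evaluation of the configured Morel case-I closed form
        ctot = 40.2 * 1.0 ** 0.507
        expected = 568.2 * ctot ** -0.746
        if expected > 102.0:
            expected = 200.0 * ctot ** -0.293
        assert euphotic_depth(1.0) == pytest.approx(expected, rel=1e-12)

    def test_branch_discontinuity_bounded(self):
        # the two-branch form has a small jump where Z_eu crosses 102 m;
        # left/right limits must agree within 15 %
        chl = np.linspace(0.01, 1.0, 20001)
        zeu = euphotic_depth(chl)
        i = int(np.argmax(np.abs(np.diff(zeu))))
        assert abs(zeu[i + 1] / zeu[i] - 1.0) < 0.15

    def test_nonpositive_chl_missing(self):
        assert np.isnan(euphotic_depth(0.0))
        assert np.isnan(euphotic_depth(-1.0))


class TestPbOpt:
    def test_eppley_at_zero(self):
        assert pb_opt(0.0, "eppley") == pytest.approx(1.54 * 10 ** -0.07, rel=1e-12)

    def test_eppley_increasing(self):
        assert pb_opt(10.0, "eppley") < pb_opt(20.0, "eppley")
        t = np.linspace(-2, 30, 100)
        assert np.all(np.diff(pb_opt(t, "eppley")) > 0)

    def test_behrenfeld_clamps(self):
        assert pb_opt(-2.0, "behrenfeld") == C.behrenfeld_lo_value
        assert pb_opt(30.0, "behrenfeld") == C.behrenfeld_hi_value

    def test_positive_over_domain(self):
        t = np.linspace(-2, 30, 200)
        assert np.all(pb_opt(t, "behrenfeld") > 0)
        assert np.all(pb_opt(t, "eppley") > 0)


class TestBbpSpectral:
    def test_identity_same_wavelength(self):
        assert bbp_spectral(0.002, 443, 443, 0.78) == 0.002

    def test_eta_zero_unchanged(self):
        assert bbp_spectral(0.002, 700, 470, 0.0) == 0.002

    def test_700_to_470_factor(self):
        factor = (470.0 / 700.0) ** (-0.78)
        assert factor == pytest.approx(1.365, abs=0.001)
        assert bbp_spectral(1.0, 700, 470, 0.78) == pytest.approx(factor)


class TestMedianMlLight:
    def test_surface_limit(self):
        assert median_ml_light(40.0, 0.1, 1e-12, 16.0) == pytest.approx(40.0 / 16.0)

    def test_hand_value(self):
        # (40/16)·exp(−0.1·50/2) = 2.5·e^−2.5
        assert median_ml_light(40.0, 0.1, 50.0, 16.0) == pytest.approx(
            2.5 * math.exp(-2.5), rel=1e-12)

    def test_zero_daylength(self):
        assert median_ml_light(40.0, 0.1, 50.0, 0.0) == 0.0

    def test_exponential_in_kd(self):
        a = median_ml_light(40.0, 0.1, 50.0, 16.0)
        b = median_ml_light(40.0, 0.2, 50.0, 16.0)
        assert math.log(b / a) == pytest.approx(-0.1 * 50.0 / 2.0, rel=1e-9)


# ---------------------------------------------------------------------------
# VGPM
# ---------------------------------------------------------------------------

class TestVgpm:
    def test_zero_biomass(self):
        assert vgpm(reference_pixel(chl=0.0), "eppley").npp == 0.0

    def test_light_saturation_limit(self):
        px = reference_pixel(par=1e6)
        res = vgpm(px, "eppley")
        d = res.diagnostics
        ceiling = C.vgpm_scale * d["pb_opt"] * px.chl * d["z_eu"] * d["daylength"]
        assert res.npp == pytest.approx(ceiling, rel=1e-3)

    def test_reference_pixel_independent_evaluation(self):
        # the same closed form evaluated with plain arithmetic
        px = reference_pixel()
        pbo = 1.54 * 10 ** (0.0275 * 5.0 - 0.07)
        ctot = 38.0 * 0.5 ** 0.425
        zeu = 568.2 * ctot ** -0.746
        if zeu > 102.0:
            zeu = 200.0 * ctot ** -0.293
        decl = math.radians(23.45) * math.sin(2 * math.pi * (284 + 15) / 365.0)
        cos_h0 = min(1.0, max(-1.0, -math.tan(math.radians(-50.0)) * math.tan(decl)))
        dl = 24.0 / math.pi * math.acos(cos_h0)
        expected = 0.66125 * pbo * (30.0 / (30.0 + 4.1)) * 0.5 * zeu * dl
        assert vgpm(px, "eppley").npp == pytest.approx(expected, rel=1e-10)

    def test_missing_input_flagged(self):
        res = vgpm(reference_pixel(sst=np.nan), "eppley")
        assert res.missing


# ---------------------------------------------------------------------------
# CbPM
# ---------------------------------------------------------------------------

class TestCbpmSurface:
    def test_dark_is_zero(self):
        res = cbpm_surface(reference_pixel(par=0.0))
        assert res.npp == 0.0

    def test_joint_saturation_reaches_mu_max(self):
        # θ at θ_max for the ambient light, light term saturated
        px = reference_pixel(par=500.0, kd490=0.01, mld=1.0)
        dl = day_length(px.lat, px.doy)
        ig = median_ml_light(px.par, px.kd490, px.mld, dl)
        theta_max = C.theta_lo + (C.theta_hi - C.theta_lo) * math.exp(-C.k_theta * ig)
        cphy = C.cphyto_slope * (px.bbp - C.cphyto_dark)
        px.chl = theta_max * cphy
        res = cbpm_surface(px)
        assert res.diagnostics["mu"] == pytest.approx(C.mu_max, rel=1e-3)

    def test_reference_pixel_independent_evaluation(self):
        px = reference_pixel(chl=0.4)
        cphy = 13000.0 * (0.002 - 0.00035)
        decl = math.radians(23.45) * math.sin(2 * math.pi * (284 + 15) / 365.0)
        dl = 24.0 / math.pi * math.acos(
            min(1.0, max(-1.0, -math.tan(math.radians(-50.0)) * math.tan(decl))))
        ig = (30.0 / dl) * math.exp(-0.05 * 40.0 / 2.0)
        theta = 0.4 / cphy
        theta_max = 0.022 + (0.045 - 0.022) * math.exp(-3.0 * ig)
        accl = min(1.0, max(0.0, (theta - 0.0003) / (theta_max - 0.0003)))
        mu = 2.0 * accl * (1.0 - math.exp(-5.0 * ig))
        ctot = 38.0 * 0.4 ** 0.425
        zeu = 568.2 * ctot ** -0.746
        if zeu > 102.0:
            zeu = 200.0 * ctot ** -0.293
        assert cbpm_surface(px).npp == pytest.approx(mu * cphy * zeu, rel=1e-10)

    def test_nonpositive_carbon_flagged_zero(self):
        res = cbpm_surface(reference_pixel(bbp=0.0001))
        assert res.npp == 0.0


class TestCbpmDepthResolved:
    def test_constant_integrand_exact(self):
        # uniform μ, C: integral = μ·C·z_max exactly on a uniform grid
        z = np.arange(0.0, 201.0)
        coeffs = C.with_updates(theta_lo=0.01, theta_hi=0.01)  # θ_max flat
        cphy = np.full(z.size, 30.0)
        chl = 0.01 * cphy           # θ == θ_max → acclimation term = 1
        par = np.full(z.size, 1e5)  # saturating everywhere
        env = DepthEnvironment(z=z, chl=chl, cphyto=cphy, par=par,
                               temp=np.full(z.size, 2.0))
        npp_z, res = cbpm_depth_resolved(env, -50.0, 15, coeffs, z_max=200.0)
        assert res.npp == pytest.approx(coeffs.mu_max * 30.0 * 200.0, rel=1e-6)

    def test_dark_integral_zero(self):
        z = np.arange(0.0, 201.0)
        env = DepthEnvironment(z=z, chl=np.full(z.size, 0.3),
                               cphyto=np.full(z.size, 30.0),
                               par=np.zeros(z.size), temp=np.full(z.size, 2.0))
        _, res = cbpm_depth_resolved(env, -50.0, 15, z_max=200.0)
        assert res.npp == 0.0

    def test_refinement_oracle(self, clean_float_dataset):
        # coarse standard-grid integral vs 0.1 m quadrature within 1 %
        _, profiles, truth = clean_float_dataset
        tr = truth.float_truth[0]
        z_fine = np.arange(0.1, 200.01, 0.1)
        kd = -np.log(tr["par"][5] / tr["par"][0]) / (tr["z"][5] - tr["z"][0])

        def interp(v):
            return np.interp(z_fine, tr["z"], v)

        env_f = DepthEnvironment(z=z_fine, chl=interp(tr["chl"]),
                                 cphyto=interp(tr["cphyto"]),
                                 par=tr["par"][0] * np.exp(-kd * (z_fine - tr["z"][0])),
                                 temp=interp(tr["temp"]))
        env_c = DepthEnvironment(z=tr["z"], chl=tr["chl"], cphyto=tr["cphyto"],
                                 par=tr["par"], temp=tr["temp"])
        doy = 15
        _, fine = cbpm_depth_resolved(env_f, tr["lat"], doy, z_max=200.0)
        _, coarse = cbpm_depth_resolved(env_c, tr["lat"], doy, z_max=200.0)
        assert coarse.npp == pytest.approx(fine.npp, rel=0.01)

    def test_non_monotone_depths_rejected(self):
        z = np.array([0.0, 10.0, 5.0])
        env = DepthEnvironment(z=z, chl=np.ones(3), cphyto=np.ones(3),
                               par=np.ones(3), temp=np.ones(3))
        with pytest.raises(ValueError):
            cbpm_depth_resolved(env, -50.0, 15, z_max=5.0)


# ---------------------------------------------------------------------------
# absorption family
# ---------------------------------------------------------------------------

class TestAbsorption:
    def test_zero_absorption(self):
        for variant in ("abpm", "cafe"):
            assert absorption_npp(reference_pixel(aph=0.0), variant).npp == 0.0

    def test_constant_yield_closed_form(self):
        # φ(E) → φ_max: NPP = (mg/mol C)·φ_max·a_ph·PAR/Kd490 analytically
        px = reference_pixel()
        coeffs = C.with_updates(e_k=1e12)   # saturation so high φ ≈ φ_max
        res = absorption_npp(px, "abpm", coeffs, dz=1.0)
        expected = npp.CARBON_MG_PER_MOL * coeffs.phi_max * px.aph * px.par / px.kd490
        assert res.npp == pytest.approx(expected, rel=5e-3)

    def test_refinement_oracle_both_variants(self):
        px = reference_pixel()
        for variant in ("abpm", "cafe"):
            coarse = absorption_npp(px, variant, dz=1.0).npp
            fine = absorption_npp(px, variant, dz=0.05).npp
            assert coarse == pytest.approx(fine, rel=5e-3)

    def test_bounded_by_closed_form(self):
        px = reference_pixel()
        bound = npp.CARBON_MG_PER_MOL * C.phi_max * px.aph * px.par / px.kd490
        for variant in ("abpm", "cafe"):
            assert absorption_npp(px, variant).npp <= bound * (1 + 1e-9)


# ---------------------------------------------------------------------------
# family-wide properties on the gridded driver
# ---------------------------------------------------------------------------

def random_pixel_dataset(rng, n_lat=20, n_lon=20):
    shape = (1, n_lat, n_lon)
    coords = {"time": np.array(["2010-01-15"], dtype="datetime64[ns]"),
              "lat": np.linspace(-75, -41, n_lat),
              "lon": np.linspace(0.5, 19.5, n_lon)}
    def v(lo, hi):
        return (("time", "lat", "lon"), rng.uniform(lo, hi, shape))
    return xr.Dataset({
        "chl": v(0.01, 5.0), "bbp": v(0.0006, 0.01), "aph": v(0.001, 0.1),
        "adg": v(0.001, 0.05), "kd490": v(0.02, 0.5), "eta": v(0.0, 1.5),
        "par": v(0.5, 60.0), "sst": v(-1.8, 15.0), "mld": v(10.0, 300.0),
        "zno3": v(10.0, 200.0), "sss": v(33.0, 35.0)}, coords=coords)


class TestFamilyProperties:
    def test_nonnegative_and_monotone_in_par(self):
        rng = np.random.default_rng(11)
        ds = random_pixel_dataset(rng, 25, 20)
        ds_hi = ds.copy()
        ds_hi["par"] = ds["par"] * 1.5
        for alg in npp.ALGORITHMS:
            lo = npp.compute_npp(ds, alg).values
            hi = npp.compute_npp(ds_hi, alg).values
            assert np.all(lo >= -1e-9), alg
            assert np.all(hi >= lo - 1e-6 - 1e-9 * np.abs(lo)), alg

    def test_zero_biomass_zero_npp(self):
        rng = np.random.default_rng(3)
        ds = random_pixel_dataset(rng, 5, 5)
        ds["chl"] = ds["chl"] * 0.0
        for alg in ("vgpm-e", "vgpm-b"):
            assert float(np.nanmax(npp.compute_npp(ds, alg).values)) == 0.0
        ds2 = random_pixel_dataset(rng, 5, 5)
        ds2["bbp"] = ds2["bbp"] * 0.0
        for alg in ("cbpm-b", "cbpm-w"):
            assert float(np.nanmax(npp.compute_npp(ds2, alg).values)) == 0.0
        ds3 = random_pixel_dataset(rng, 5, 5)
        ds3["aph"] = ds3["aph"] * 0.0
        for alg in ("abpm", "cafe"):
            assert float(np.nanmax(npp.compute_npp(ds3, alg).values)) == 0.0

    def test_quadrature_convergence_westberry(self):
        px = reference_pixel(chl=0.4)
        for dz in (1.0,):
            env1 = reconstruct_profile(px, dz=1.0)
            env2 = reconstruct_profile(px, dz=0.5)
            _, r1 = cbpm_depth_resolved(env1, px.lat, px.doy, z_max=200.0)
            _, r2 = cbpm_depth_resolved(env2, px.lat, px.doy, z_max=200.0)
            assert r1.npp == pytest.approx(r2.npp, rel=0.01)

    def test_coefficients_round_trip_bitwise(self):
        c2 = AlgorithmCoefficients.from_json(C.to_json())
        assert c2 == C
        px = reference_pixel()
        assert vgpm(px, "eppley", c2).npp == vgpm(px, "eppley", C).npp
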