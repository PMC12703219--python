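"""ESM processing: integration, weighting, regridding, Δ fields, drivers."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from sonpp import esm, synthetic
from sonpp.esm import (DeltaFields, cumulative_npp_change, delta_fields,
                       driver_regression, ensemble_cumulative_change,
                       esm_regional_series, esm_trend, integrate_phyc,
                       intpp_to_per_day, regrid_1deg, weight_limitation)


class TestIntegratePhyc:
    def test_constant_profile(self):
        z = np.arange(0.0, 201.0, 10.0)
        v = np.full(z.size, 0.5)
        assert integrate_phyc(v, z) == pytest.approx(50.0, rel=1e-12)

    def test_linear_closed_form(self):
        z = np.arange(0.0, 201.0, 5.0)
        a, b = 0.2, -0.001
        v = a + b * z
        assert integrate_phyc(v, z) == pytest.approx(
            a * 100 + b * 100 ** 2 / 2, rel=1e-12)

    def test_partial_bottom_layer_interpolated(self):
        z = np.array([0.0, 40.0, 80.0, 120.0])
        v = np.array([1.0, 1.0, 1.0, 1.0])
        assert integrate_phyc(v, z) == pytest.approx(100.0, rel=1e-12)

    def test_fine_grid_oracle(self, esm_small):
        _, members, _ = esm_small
        m = members[0]
        col = m.phyc.isel(time=0, lat=3, lon=4).values
        z = m.phyc["lev"].values
        zf = np.arange(0.0, 100.001, 0.1)
        fine = np.trapezoid(np.interp(zf, z, col), zf)
        assert integrate_phyc(col, z) == pytest.approx(fine, rel=0.01)

    def test_no_levels_above_depth(self):
        assert np.isnan(integrate_phyc(np.array([1.0, 1.0]),
                                       np.array([150.0, 200.0])))


class TestWeightLimitation:
    def test_uniform_limitation_invariance(self):
        b = np.array([[1.0], [5.0], [0.3]])
        lim = np.full((3, 1), 0.5)
        assert weight_limitation(lim, b)[0] == pytest.approx(0.5, rel=1e-12)

    def test_three_to_one_mix(self):
        lim = np.array([[0.4], [0.8]])
        b = np.array([[3.0], [1.0]])
        assert weight_limitation(lim, b)[0] == pytest.approx(0.5, rel=1e-12)

    def test_single_pft_identity(self):
        lim = np.array([[0.37]])
        assert weight_limitation(lim, np.array([[2.0]]))[0] == pytest.approx(0.37)

    def test_zero_biomass_missing(self):
        out = weight_limitation(np.array([[0.4], [0.8]]), np.zeros((2, 1)))
        assert np.isnan(out[0])

    def test_negative_biomass_rejected(self):
        with pytest.raises(ValueError):
            weight_limitation(np.array([[0.5]]), np.array([[-1.0]]))

    def test_bounded_by_components_over_ensemble(self, esm_small):
        _, members, _ = esm_small
        for m in members[:4]:
            w = weight_limitation(m.limfe, m.biomass)
            lo = m.limfe.min("pft").values
            hi = m.limfe.max("pft").values
            assert np.all(w.values >= lo - 1e-12)
            assert np.all(w.values <= hi + 1e-12)


class TestRegrid:
    def test_constant_field_exact(self):
        lat = np.arange(-77.375, -40, 1.25)
        lon = np.arange(0.75, 30, 1.5)
        f = xr.DataArray(np.full((lat.size, lon.size), 3.3),
                         dims=("lat", "lon"), coords={"lat": lat, "lon": lon})
        g = regrid_1deg(f)
        np.testing.assert_allclose(g.values, 3.3, rtol=1e-12)

    def test_mean_preserved_random_fields(self):
        # covered-area-weighted mean before == after for 100 random fields
        rng = np.random.default_rng(6)
        lat = np.arange(-77.375, -40, 1.25)
        lon = np.arange(0.75, 30, 1.5)
        wlat_s = np.sin(np.deg2rad(lat + 0.625)) - np.sin(np.deg2rad(lat - 0.625))
        for _ in range(100):
            f = xr.DataArray(rng.uniform(0, 1, (lat.size, lon.size)),
                             dims=("lat", "lon"),
                             coords={"lat": lat, "lon": lon})
            g, cov = regrid_1deg(f, return_coverage=True)
            ms = np.average(f.values, weights=np.broadcast_to(
                wlat_s[:, None] * 1.5, f.shape))
            mt = np.average(g.values, weights=cov.values)
            assert mt == pytest.approx(ms, rel=1e-3)

    def test_checkerboard_against_brute_force_overlap(self):
        lat = np.arange(-50.75, -46, 1.5)
        lon = np.arange(0.75, 6, 1.5)
        vals = np.indices((lat.size, lon.size)).sum(axis=0) % 2
        f = xr.DataArray(vals.astype(float), dims=("lat", "lon"),
                         coords={"lat": lat, "lon": lon})
        g = regrid_1deg(f)

        # brute force: overlap areas Δλ · Δsinφ computed cell by cell
        def edges(c, res):
            return np.concatenate([c - res / 2, [c[-1] + res / 2]])
        lat_se, lon_se = edges(lat, 1.5), edges(lon, 1.5)
        lat_te, lon_te = edges(g["lat"].values, 1.0), edges(g["lon"].values, 1.0)
        expected = np.zeros(g.shape)
        for a in range(g.shape[0]):
            for b in range(g.shape[1]):
                num = den = 0.0
                for i in range(lat.size):
                    dphi = (min(lat_se[i + 1], lat_te[a + 1])
                            - max(lat_se[i], lat_te[a]))
                    if dphi <= 0:
                        continue
                    dsin = (np.sin(np.deg2rad(max(lat_se[i], lat_te[a]) + dphi))
                            - np.sin(np.deg2rad(max(lat_se[i], lat_te[a]))))
                    for j in range(lon.size):
                        dlam = (min(lon_se[j + 1], lon_te[b + 1])
                                - max(lon_se[j], lon_te[b]))
                        if dlam <= 0:
                            continue
                        num += vals[i, j] * dsin * dlam
                        den += dsin * dlam
                expected[a, b] = num / den
        np.testing.assert_allclose(g.values, expected, rtol=1e-10)

    def test_curvilinear_rejected(self):
        lat2d = np.zeros((3, 3))
        f = xr.DataArray(np.zeros((3, 3)), dims=("y", "x"),
                         coords={"lat": (("y", "x"), lat2d),
                                 "lon": (("y", "x"), lat2d)})
        with pytest.raises(ValueError, match="curvilinear|rectilinear"):
            regrid_1deg(f)


class TestDeltaFields:
    def test_identical_periods_zero(self, esm_small):
        _, members, _ = esm_small
        hist = members[0]
        d = delta_fields(hist, hist, hist_period=(1995, 2014),
                         future_period=(1995, 2014), regrid=False)
        np.testing.assert_allclose(d.npp.values, 0.0, atol=1e-15)

    def test_uniform_offset_recovered(self, esm_small):
        _, members, _ = esm_small
        hist = members[0]
        import copy
        fut = copy.copy(hist)
        fut.intpp = hist.intpp + 2.0
        d = delta_fields(hist, fut, hist_period=(1995, 2014),
                         future_period=(1995, 2014), regrid=False)
        np.testing.assert_allclose(d.npp.values, 2.0, rtol=1e-12)

    def test_generator_truth_recovered_exactly(self, esm_small):
        _, members, truth = esm_small
        hist = members[0]
        fut = next(m for m in members
                   if m.scenario == "ssp370" and m.model_id == hist.model_id)
        tm = truth.extras["models"][hist.model_id]["ssp370"]
        d = delta_fields(hist, fut, regrid=False)
        np.testing.assert_allclose(d.npp.values, tm["delta_npp"], atol=1e-12)
        np.testing.assert_allclose(d.cphyto.values, tm["delta_cphyto"],
                                   atol=1e-10)
        np.testing.assert_allclose(d.limfe.values, tm["delta_limfe"],
                                   atol=1e-12)

    def test_summer_subset_close_to_annual(self, esm_small):
        # the Δ ramp is linear in time: the DJF mean sits within ~1 % of 1
        _, members, truth = esm_small
        hist = members[0]
        fut = next(m for m in members
                   if m.scenario == "ssp370" and m.model_id == hist.model_id)
        tm = truth.extras["models"][hist.model_id]["ssp370"]
        d = delta_fields(hist, fut, summer_only=True, regrid=False)
        np.testing.assert_allclose(d.npp.values, tm["delta_npp"], rtol=0.01)

    def test_incomplete_period_lists_missing_months(self, esm_small):
        _, members, _ = esm_small
        hist = members[0]
        import copy
        trunc = copy.copy(hist)
        trunc.intpp = hist.intpp.isel(time=slice(0, 100))
        with pytest.raises(ValueError, match="missing months"):
            delta_fields(trunc, members[1], hist_period=(1995, 2014))


class TestDriverRegression:
    def _delta_from(self, x, y, lat=None):
        lat = lat if lat is not None else -60.5 + np.arange(x.shape[0])
        lon = np.arange(x.shape[1]) + 0.5
        mk = lambda v: xr.DataArray(v, dims=("lat", "lon"),
                                    coords={"lat": lat, "lon": lon})
        return DeltaFields(npp=mk(y), cphyto=mk(x), limfe=mk(x * 0),
                           limirr=mk(x * 0))

    def test_exact_linear_relation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(10, 50))
        d = self._delta_from(x, 2.0 * x)
        reg = driver_regression(d, "cphyto")
        assert reg.slope == pytest.approx(2.0, rel=1e-12)
        assert reg.r == pytest.approx(1.0, abs=1e-12)

    def test_null_correlation_small(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(50, 100))
            y = rng.normal(size=(50, 100))
            d = self._delta_from(x, y, lat=np.arange(-64.5, -15, 1.0))
            reg = driver_regression(d, "cphyto")
            hits += abs(reg.r) < 0.05
        assert hits >= 18     # |r| < 0.05 in ≥ 95 % of seeds at n = 5000

    def test_constant_driver_flagged(self):
        x = np.zeros((10, 50))
        d = self._delta_from(x, np.random.default_rng(1).normal(size=(10, 50)))
        reg = driver_regression(d, "cphyto")
        assert np.isnan(reg.slope)

    def test_generator_coefficients_recovered(self, esm_small):
        cfg, members, truth = esm_small
        hist = members[0]
        fut = next(m for m in members
                   if m.scenario == "ssp370" and m.model_id == hist.model_id)
        d = delta_fields(hist, fut)
        for driver, expected in (("cphyto", cfg.esm_alpha),
                                 ("limfe", cfg.esm_beta),
                                 ("limirr", cfg.esm_gamma)):
            for weighted in (False, True):
                reg = driver_regression(d, driver, area_weighted=weighted)
                assert reg.slope == pytest.approx(expected, rel=0.05), \
                    (driver, weighted)


class TestCumulativeChange:
    def test_baseline_series_all_zero(self):
        years = np.arange(1995, 2030)
        ser = pd.Series(np.full(years.size, 7.0), index=years)
        np.testing.assert_allclose(cumulative_npp_change(ser).values, 0.0)

    def test_step_change(self):
        years = np.arange(1995, 2101)
        vals = np.where(years >= 2050, 7.5, 7.0)
        cum = cumulative_npp_change(pd.Series(vals, index=years))
        assert np.all(cum.loc[2050:].values == pytest.approx(0.5))
        assert np.all(cum.loc[:2049].values == pytest.approx(0.0))

    def test_ensemble_hand_calculation(self):
        years = np.arange(1995, 2101)
        series = {}
        for k, change in enumerate([0.3, 0.4, 0.5, 0.6, 0.7]):
            vals = np.where(years >= 2081, 5.0 + change, 5.0)
            series[f"m{k}"] = pd.Series(vals, index=years)
        mean, sd, arr = ensemble_cumulative_change(series)
        assert mean == pytest.approx(0.5, rel=1e-12)
        assert sd == pytest.approx(np.std([0.3, 0.4, 0.5, 0.6, 0.7], ddof=1),
                                   rel=1e-12)
        assert sd == pytest.approx(0.158, abs=0.001)

    def test_incomplete_baseline_raises(self):
        ser = pd.Series(np.arange(50.0), index=np.arange(2000, 2050))
        with pytest.raises(ValueError, match="baseline"):
            cumulative_npp_change(ser)

    def test_prescribed_cumulative_recovered(self, esm_small):
        _, members, truth = esm_small
        hist = members[0]
        fut = next(m for m in members
                   if m.scenario == "ssp370" and m.model_id == hist.model_id)
        ser = pd.concat([esm_regional_series(hist), esm_regional_series(fut)])
        cum = cumulative_npp_change(ser)
        target = truth.extras["models"][hist.model_id]["ssp370"]["cumulative_pgc"]
        assert cum.loc[2081:2100].mean() == pytest.approx(target, abs=1e-6)


class TestEsmTrends:
    def test_noiseless_future_trend_exact(self, esm_small):
        _, members, truth = esm_small
        hist = members[0]
        fut = next(m for m in members
                   if m.scenario == "ssp370" and m.model_id == hist.model_id)
        ser = esm_regional_series(fut)
        est = esm_trend(ser, (2051, 2100))
        tm = truth.extras["models"][hist.model_id]["ssp370"]
        assert est.slope == pytest.approx(tm["regional_trend_pgc_per_yr"],
                                          rel=1e-6)

    def test_flat_series_zero_slope(self):
        years = np.arange(1998, 2025)
        est = esm_trend(pd.Series(np.full(27, 5.0), index=years), (1998, 2024))
        assert est.slope == 0.0

    def test_unit_safety_seconds_vs_days(self, esm_small):
        _, members, _ = esm_small
        m = members[0]
        per_s = m.intpp / esm.SECONDS_PER_DAY
        per_s.attrs["units"] = "mol m-2 s-1"
        converted = intpp_to_per_day(per_s)
        np.testing.assert_allclose(converted.values, m.intpp.values, rtol=1e-9)
        assert converted.attrs.get("converted_from")
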