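# sonpp — Southern Ocean net primary production: algorithms, floats, models

Net primary production (NPP) in the Southern Ocean (south of 40°S) sustains
the region's food webs and primes the biological carbon pump, but estimates of
its ongoing change disagree: satellite ocean-colour algorithms and
biogeochemical (BGC-) Argo floats tend to show regional declines, while CMIP6
Earth System Models project increases. `sonpp` is a tested, reusable pipeline
for making that three-way comparison — and, because the real archives are
multi-terabyte, it ships a synthetic-data module that emulates every input
class with known ground truth, so the entire analysis runs offline and every
stage is verifiable against the truth it was generated from.

## What's inside

**Six ocean-colour NPP algorithms** (`sonpp.npp`), in three families:

* *VGPM* (chlorophyll-based): NPP = 0.66125 · P<sup>B</sup><sub>opt</sub>(SST) ·
  PAR/(PAR + 4.1) · Chl · Z<sub>eu</sub> · daylength, with the polynomial
  (Behrenfeld) or exponential Eppley (1.54·10<sup>0.0275T−0.07</sup>)
  temperature response;
* *CbPM* (carbon-based): phytoplankton carbon C<sub>phyto</sub> from particulate
  backscattering, growth rate μ = μ<sub>max</sub> · f(θ, θ<sub>max</sub>(I<sub>g</sub>)) ·
  (1 − e<sup>−k·I<sub>g</sub></sup>) from the Chl:C photoacclimation state θ,
  surface (NPP = μ·C<sub>phyto</sub>·Z<sub>eu</sub>) and depth-resolved
  (mixed-layer reconstruction, ∫μ(z)·C<sub>phyto</sub>(z) dz) variants;
* *absorption-based* (AbPM, CAFE): NPP = 12 g mol⁻¹ · ∫φ(E(z))·a<sub>ph</sub>·PAR·e<sup>−K<sub>d</sub>z</sup> dz
  with a light-dependent quantum yield φ.

**A BGC-Argo processing chain** (`sonpp.argo`): QC flag selection {1,2,5,8},
vertical regridding to a 1 m (upper 300 m) / 10 m (to 1000 m) grid with
shape-preserving Hermite interpolation and no extrapolation, daytime
fluorescence-quenching correction (mixed-layer maximum extrapolation),
fluorescence→Chl (slope factor 2), backscatter cleaning and 11-point
running-median despiking, b<sub>bp</sub>(700)→C<sub>phyto</sub> (non-algal baseline removal,
spectral slope −0.78 to 470 nm, slope factor 12128), mixed-layer depth from a
0.03 kg m⁻³ density criterion, and upper-ocean integration.

**Robust trend machinery** (`sonpp.trends`): per-pixel routing by the
D'Agostino–Pearson normality test — Huber regression (ε = 1.35, >50 %
outliers → no trend) for normal series, Mann-Kendall + Theil–Sen otherwise;
<50 % availability excluded; spherical area weighting
(R²·Δλ·Δsin φ); regional integrals in Pg C yr⁻¹; moving 20-year jackknife
windows; OLS on annual means for float records.

**CMIP6-style processing** (`sonpp.esm`): phytoplankton carbon integrated to
100 m, biomass-weighted per-PFT iron/light limitation terms, conservative 1°
regridding, Δ(2081–2100 minus 1995–2014) fields with an Austral-summer (DJF)
option, ΔNPP-vs-driver regressions, cumulative NPP change against the
1995–2014 baseline, and trend extraction with the same routed estimator used
for the satellite stacks.

**Synthetic generators** (`sonpp.synthetic`) for all three input classes, each
returning a `TruthRecord` (imposed trends, artifact bookkeeping, prescribed
driver coefficients α, β, γ) against which every downstream stage is tested.

## Worked example

```python
import numpy as np
from sonpp import synthetic, npp, trends

# a 30°-wide sector, 1998–2024 at 8-day cadence, with a declining
# chlorophyll trend imposed on otherwise Southern-Ocean-like fields
spec = synthetic.VariableSpec(baseline=0.35, seasonal_amp=0.2,
                              trend_per_year=-0.004, rho=0.3, noise_sd=0.05,
                              phase=np.pi/2, clip_min=0.01)
cfg = synthetic.SyntheticConfig(lon_range=(0.0, 30.0))
cfg.variables["chl"] = spec
ds, truth = synthetic.gen_rs_fields(cfg, seed=1)

da = npp.compute_npp(ds, "vgpm-e")                 # mg C m-2 day-1 per pixel
series = trends.regional_series(da) * 12           # sector → circumpolar scale
print(series.round(3).head())

jk = trends.jackknife_windows(series, window_years=20)
print(len(jk.windows), "windows")
print(f"trend {jk.mean_trend:.4f} +/- {jk.sd_trend:.4f} Pg C yr-1 per year")
```

prints

```
1998    6.864
1999    6.822
2000    6.774
2001    6.728
2002    6.680
Name: npp_pgc, dtype: float64
8 windows
trend -0.0483 +/- 0.0006 Pg C yr-1 per year
```

— annual Eppley-VGPM NPP of ~6.9 Pg C for the synthetic Southern Ocean, a
27-year series giving exactly 8 twenty-year jackknife windows, and a
recovered decline of 0.048 Pg C yr⁻¹ per year driven by the imposed
chlorophyll trend (the truth record carries the exact imposed value for
comparison).

The same stages are scriptable from the shell:

```bash
sonpp report --seed 0 --out demo_out      # simulate → npp → argo → trends → esm
sonpp npp --grid fields.nc --algorithm cbpm-w --out npp_out
```

## Layout

```
src/sonpp/synthetic.py   generators + TruthRecord
src/sonpp/npp.py         the six NPP algorithms and photophysiology utilities
src/sonpp/argo.py        float processing chain
src/sonpp/trends.py      routed trend estimation, areas, jackknife
src/sonpp/esm.py         ESM integration, regridding, Δ fields, drivers
src/sonpp/io.py          NetCDF/CSV round trips, config, pipeline manifest
src/sonpp/cli.py         `sonpp` command-line interface
docs/methods.md          models, parameter choices, limitations
```
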