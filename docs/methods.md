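# Methods

This note documents the models implemented in `sonpp`, the parameter choices
made where the design was genuinely open, what the synthetic generators do and
do not emulate, and the numerical conventions. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Scope and framing

The package compares Southern Ocean (south of 40°S) NPP levels and trends
across three observing/modelling systems: satellite-style ocean-colour
algorithms, BGC-Argo-style float profiles, and CMIP6-style Earth System Model
(ESM) output, including a decomposition of projected NPP change into
phytoplankton-biomass, iron-limitation and light-limitation contributions.
The real archives behind such a comparison (multi-sensor ocean-colour climate
data records, the Argo GDAC, ESGF) are multi-terabyte; `sonpp` therefore
treats *synthetic data with known ground truth* as a first-class input.
Passing tests demonstrate that the pipeline's machinery is correct and
self-consistent — they do not validate any satellite algorithm against sea
truth, and no quantity computed here reproduces a published trend magnitude.

## NPP algorithms

The six algorithms follow the structure of the standard families; the exact
constants live in `AlgorithmCoefficients`, are serialised into every output,
and are swappable without code change.

**VGPM.** NPP = s · P^B_opt(T) · PAR/(PAR + k_E) · Chl · Z_eu · DL with
s = 0.66125 (dimensionless), k_E = 4.1 mol photons m⁻² day⁻¹, DL the
photoperiod in hours from solar-declination geometry (clamped for polar
day/night). Two temperature responses: the 7th-order polynomial in SST with
fixed clamp values outside [−1, 28.5] °C, and the Eppley exponential
1.54·10^(0.0275 T − 0.07) mg C (mg Chl)⁻¹ h⁻¹. Z_eu is the Morel case-I
two-branch closed form on column-integrated chlorophyll; the branch switch
near Z_eu = 102 m introduces a small discontinuity (< 15 %, checked by test).
For floats the same law is read volumetrically, npp(z) ∝ Chl(z)·E(z)/(E(z)+k),
because the profile supplies depth-resolved chlorophyll, temperature and PAR.

**CbPM.** C_phyto = 13000·(b_bp(443) − 0.00035) mg C m⁻³ (satellite route;
the float route below uses the 12128 slope at 470 nm). The photoacclimation
state is θ = Chl/C_phyto, with an acclimated maximum
θ_max(I) = 0.022 + 0.023·e^(−3 I) and growth
μ = 2 · clamp((θ − 0.0003)/(θ_max − 0.0003), 0, 1) · (1 − e^(−5 I)) day⁻¹,
where I is hourly growth irradiance (median mixed-layer light
(PAR/DL)·e^(−Kd·MLD/2) for the surface variant, local light for the
depth-resolved variant). Surface NPP = μ·C_phyto·Z_eu. The depth-resolved
(mixed-layer reconstruction) variant builds a profile from surface fields:
uniform Chl and C_phyto in the mixed layer; below the deeper of MLD and the
nitracline, θ relaxes linearly in optical depth (over one optical depth)
toward θ_max(E(z)) — nutrients become available below the nitracline, so the
relaxation is switched off above it; C_phyto is held to Z_eu and attenuated
with a 100 m e-folding below. Integration is trapezoidal to 200 m.

**Absorption family.** The absorbed photon flux is
AQ(z) = a_ph·PAR·e^(−Kd490·z), *spectrally integrated*: the synthetic inputs
carry a single diffuse-attenuation coefficient, so no per-wavelength
radiative transfer is attempted — a documented approximation relative to the
multispectral originals. NPP = 12 g mol⁻¹ · ∫ φ(E(z))·AQ(z) dz (reported in
mg C m⁻² day⁻¹), with φ(E) = φ_max·E_k/(E_k+E) (AbPM, hyperbolic) or
φ_max·(E_k/E)(1 − e^(−E/E_k)) (CAFE, cumulative-one-hit) and, for CAFE, E_k
acclimated to the median mixed-layer light. Defaults φ_max = 0.035 mol C
(mol photons)⁻¹, E_k = 0.4 mol photons m⁻² h⁻¹. The quadrature extends to
the depth where light falls to 10⁻⁴ of surface (9.2/Kd), so the analytic
bound 12·φ_max·a_ph·PAR/Kd490 is approached within 0.5 % when φ is constant.

With these defaults the six algorithms span roughly 7–34 Pg C yr⁻¹ on the
default synthetic fields (VGPM family lowest). The spread is wider than the
two-fold range typical of real intercomparisons; since the analysis concerns
trends and internal consistency rather than absolute calibration, the
constants were fixed once from the cited families' standard values and not
tuned to compress that spread.

## Float processing chain

Order of operations (audited per profile): QC → regrid → (fluorescence:
quenching correction → ÷2 → despike) and (backscatter: clean → despike →
C_phyto) → MLD → NPP inputs.

* **QC**: flags {1, 2, 5, 8} retained per variable; flagged samples masked;
  profiles with no valid samples dropped.
* **Regridding**: monotone piecewise-cubic Hermite (PCHIP) onto 1 m (1–300 m)
  / 10 m (310–1000 m); no extrapolation outside the sampled range.
* **Raw-resolution backscatter despiking**: single-sample instrument spikes
  exist only on the native depth axis; the Hermite regrid smears a one-sample
  spike over the two adjacent raw intervals (4–16 m at 2–8 m spacing), wider
  than an 11-point window on the 1 m grid can remove. b_bp is therefore
  despiked with the 11-point running median at native resolution *before*
  regridding, and again (with all other variables) on the standard grid.
  This choice is what makes the end-to-end recovery test pass and mirrors
  how float backscatter is despiked in practice.
* **Quenching**: daytime profiles only — the fluorescence maximum within the
  mixed layer replaces all shallower values (night profiles pass through).
  The synthetic day/night flag is used when present; a solar-elevation
  fallback is provided.
* **Fluorescence→Chl**: division by the slope factor 2, applied after the
  quenching correction (the correction operates on the raw fluorescence
  signal whose quenching it repairs).
* **Backscatter cleaning**: negatives masked; a profile is "noisy" when its
  median absolute successive difference exceeds 5× the profile-set median of
  that metric, and "anomalously deep" when its median b_bp below 700 m
  exceeds 3× the set's deep median. Both thresholds are package choices —
  the criteria are qualitative in the source literature.
* **C_phyto**: non-algal baseline = per-profile median b_bp at 850–1000 m
  (deep particles are overwhelmingly non-algal), floored at zero; spectral
  shift 700→470 nm with slope magnitude 0.78 ((470/700)^−0.78 ≈ 1.365);
  slope factor 12128, no intercept (an intercept is available as config).
  Profiles without deep samples fall back to the set's deep median, flagged.
* **MLD**: shallowest depth where potential density exceeds its 10 m value
  by 0.03 kg m⁻³. Density comes from a documented linear equation of state,
  σ = −0.05·(T − 2) + 0.78·(S − 34) kg m⁻³ (slopes appropriate for cold
  Southern Ocean water; only density *differences* enter the criterion).
  The `eos` argument accepts a TEOS-10 callable where that library is
  available. Reference depth 10 m is a package choice. A homogeneous
  profile returns the deepest valid level, flagged "no threshold crossing".
* **Integration**: trapezoidal from the surface (shallowest sample extended
  to z = 0) to z_max; internal gaps linearly interpolated; more than 50 %
  missing within range → missing. A molar-ratio mode divides two integrals
  after unit conversion (used for upper-100 m dissolved Mn:Fe ratios).

## Trend machinery

Per-pixel series (default: calendar-year annual means, which deseasonalise by
construction; an 8-day-anomaly mode that removes the multi-year climatology
per nominal step is provided) are routed:

1. < 50 % availability → no trend.
2. n ≥ 20 and D'Agostino–Pearson p > 0.05 → Huber regression (scikit-learn,
   ε = 1.35, no regularisation). Outliers are points with final robust
   weight < 1 (|scaled residual| > ε); more than 50 % outliers → no trend.
   On an exactly linear series the IRLS scale degenerates, so the estimator
   short-circuits to the (identical) OLS solution.
3. Otherwise → Mann-Kendall (tie-corrected variance, continuity-corrected
   normal approximation; p = 1 for degenerate variance) with the Theil–Sen
   slope. Series shorter than 20 always take this route (the normality test
   is unreliable at small n).

Slopes are reported regardless of significance; p-values are retained.
Pixel areas are R²·Δλ·(sin φ₂ − sin φ₁); regional integrals sum
value·area·365 over valid pixels into Pg C yr⁻¹ (1 Pg = 10¹⁸ mg). Basin
trends therefore carry Pg C yr⁻¹ per year (= 10⁶ Gg C yr⁻¹ per year), while
per-pixel maps are in mg C m⁻² day⁻¹ per year; the package reports both and
this is the only unit conversion between them. Jackknife uncertainty: the
same routed estimator applied to every contiguous 20-year window of the
annual regional series, reported as mean ± sd over windows. Float trends are
OLS on calendar-year annual means (≥ 3 years required).

## ESM processing

`intpp` is normalised to mol C m⁻² day⁻¹, with automatic ×86,400 conversion
when the units attribute declares per-second (the CMIP standard).
Phytoplankton carbon is trapezoid-integrated to 100 m (partial bottom layer
interpolated; shallowest level extended to the surface). Limitation terms,
archived per phytoplankton functional type (PFT) at the surface, are weighted
by each PFT's share of total surface biomass; the result is bounded by the
component limitations and is missing where total biomass is zero.

Conservative regridding supports rectilinear grids only (curvilinear input is
an explicit error): overlap weights are Δλ in longitude and Δsin φ in
latitude, missing source cells are excluded with weight renormalisation, the
target 1° grid spans the source domain, and the covered-area-weighted mean is
conserved (coverage per target cell is available for exact bookkeeping).

Δ fields are 2081–2100 means minus 1995–2014 means per cell, computed on
monthly data with full-coverage validation. The Austral-summer option
averages only *complete* DJF seasons (December attached to the following
year's summer); a first summer whose December precedes the record is dropped
— using incomplete seasons would leak the seasonal cycle into the Δ field.
Driver regressions are OLS of ΔNPP on one Δdriver across 1° cells, pooled in
space by default (an area-weighted variant is provided; both are labelled in
the output). Cumulative change subtracts the 1995–2014 baseline mean from
each year's regional NPP; ensemble statistics weight models equally.

## Synthetic generators

**Gridded fields** (11 ocean-colour/physics variables): per variable,
baseline + trend·t + seasonal·sin(2π·doy/365 + phase) + AR(1) noise
(e_t = ρ e_{t−1} + √(1−ρ²)·σ·w_t, stationary sd σ, default ρ = 0.3 because
real pixel series are autocorrelated), clipped to physical bounds. Default
values are Southern-Ocean plausible (chl 0.35 ± 0.20 mg m⁻³ seasonal,
kd490 0.06 m⁻¹, PAR 25 ± 20 mol m⁻² day⁻¹, SST 2 ± 2.5 °C, MLD 40–150 m with
the winter maximum, nitracline ~60 m) with the biological maximum in austral
summer. The default domain is a 0–20°E sector at 1°, 1998–2024 at 8-day
cadence (46 steps/year, the same days every year) — a desk-scale stand-in for
the circumpolar band; regional quantities from a sector scale by the
longitude fraction because the statistics are longitudinally homogeneous.
The truth record carries every imposed trend, and for a variable named `npp`
the exact noiseless regional trend (imposed trend × total area × 365).

**Float profiles**: irregular raw depths (2–8 m spacing, so regridding is
non-trivial), true Chl(z) = mixed-layer plateau + Gaussian deep maximum with
exponential decay below, C_phyto = Chl/θ with θ = 0.010, a sharp two-layer
T/S structure defining a known MLD (30–120 m), exponential PAR(z) interpreted
as the daily dose (so polar-winter profiles still carry a light field;
profiles with zero photoperiod produce zero NPP in both the processed and
truth chains and are excluded from ratio comparisons). Artifacts: raw
fluorescence = 2 × true Chl, multiplied by `quench_factor` (default 0.5)
above the quench depth (min(0.5·MLD, 20 m)) on daytime profiles — the form
the mixed-layer-maximum correction can repair; an exact integer number of
isolated b_bp spikes per profile (default 2, indices recorded); occasional
negative b_bp samples; bad QC flags ({3,4}, default 5 %) whose values are
corrupted so QC selection is consequential. b_bp(700) is constructed as the
deep baseline plus C_phyto divided through the processing chain's conversion,
so the artifact-free chain recovers C_phyto exactly (up to interpolation).
A multiplicative amplitude ramp (`float_amp_trend`) imposes a fractional NPP
trend: CbPM NPP scales linearly with a joint Chl/C_phyto rescaling because θ
is unchanged.

**ESM ensemble**: per model, one historical member (1995–2014) plus one
member per scenario (2015–2100), monthly, on a native 1.25° × 1.5° grid so 1°
regridding is non-identity. NPP change is constructed per cell as
ΔNPP = α·ΔC_phyto + β·ΔLimFe + γ·ΔLimIrr + ε with defaults
α = 0.01 day⁻¹, β = γ = 0.01 mol C m⁻² day⁻¹ per unit limitation, driver
shares 0.4/0.3/0.3, and ε Gaussian with sd = 10 % of the signal sd, projected
to zero regional mean so the prescribed regional total stays exact. The
spatial driver patterns are a sin/cos quadrature pair over the longitude
index plus a latitude mode — mutually orthogonal by construction, and the
lat/lon separation keeps them uncorrelated under any latitude-dependent area
weighting, including after conservative regridding, so single-driver
regressions recover α, β, γ without cross-contamination. Future fields ramp
linearly from 2014.5, reaching 1 at the 2081–2100 mean time, so period means
recover the prescribed Δ exactly in the noise-free case. Prescribed
cumulative changes default to 0.3/0.5/0.5 Pg C (SSP2-45/3-70/5-85) for the
full circumpolar band and are scaled by the domain's longitude fraction by
default (disable with `esm_scale_target_by_area=False`); without scaling, a
narrow sector would demand limitation changes that hit the [0,1] bounds and
break the linear construction (the generator warns and records when clipping
occurs). Per-PFT surface biomass fractions are Dirichlet-like and sum to 1
exactly; limitation baselines (0.3–0.7) keep the perturbed fields inside
[0,1] at default settings. Driver fields (phyc, biomass, limitations) are
archived only within the two analysis periods to keep memory flat.

Not emulated: multi-sensor merging artefacts, real Argo telemetry formats,
sea ice, curvilinear ocean grids, spectrally resolved optics, and any
covariance between variables beyond the constructions above. Consequently
the tests show machinery correctness and recovery under the stated artifact
model — not fidelity to real observations.

## Numerical choices and problem sizes

* Trapezoidal quadrature throughout; depth-resolved algorithm results change
  < 1 % when dz halves from 1 m to 0.5 m (tested). Grid sweeps of the
  depth-resolved CbPM use dz = 5 m for throughput; the absorption family
  integrates to the 10⁻⁴ light level.
* Mann-Kendall uses the exact O(n²) pair matrix (n ≤ a few hundred here);
  Theil–Sen comes from `scipy.stats.theilslopes`.
* Seeds: every generator takes (config, seed) and is bit-reproducible;
  derived seeds stay below 2³¹.
* Test and acceptance problem sizes (20×20×27-year trend grids, ~120-profile
  float sets, single-model 140°-sector ESM ensembles with ≥5000 regression
  cells) were chosen so the full suite runs in about a minute and the
  acceptance script in about two on one CPU; they are the smallest sizes at
  which the statistical checks have comfortable power.
* The pipeline manifest hashes the scientific configuration (output paths
  excluded) and the serialized coefficient set; reruns of the same seed give
  identical manifests apart from timings.

## Known limitations

* The absorption family is spectrally integrated; per-wavelength attenuation
  would change absolute magnitudes (not the family's qualitative behaviour).
* The linear equation of state is adequate for the 0.03 kg m⁻³ threshold in
  cold water but is not TEOS-10; inject `gsw`-based σ₀ via the `eos` argument
  for real profiles.
* Algorithm constants are internally consistent defaults, not a calibration;
  absolute NPP levels across the six algorithms span more than the ~two-fold
  range seen in real intercomparisons.
* `trend_map` loops pixels in Python; it is meant for the desk-scale grids
  generated here, not for 4 km circumpolar products.
* Only rectilinear ESM grids are supported; curvilinear grids need an
  external remapping step first.
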