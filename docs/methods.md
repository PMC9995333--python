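# Methods

This note documents the models and procedures `floatpump` implements, the
parameters that matter, the numerical choices made where the design was
genuinely open, what the synthetic-data generator does and does not emulate,
and the known limitations. It states no empirical result that the test
suite and `scripts/acceptance.py` do not themselves compute.

## Scope and data model

The package analyses a single profiling float mission: per-profile 1-m
gridded temperature, salinity, chlorophyll fluorescence, particulate
backscattering at 470/700 nm, beam attenuation at 660 nm, oxygen and
four-channel downwelling irradiance, plus hourly transmissometer attenuance
records from each parking-depth drift and a per-profile scalar daily
surface PAR. Masked samples are NaN and are never deleted. Flux series are
pandas tables with the fixed schema
`bin_start, bin_end, median, q25, q75, n_obs, pathway` — one row per 10-day
bin, empty bins kept with `n_obs = 0`. I/O is plain CSV/JSON.

## Shared numerics

* **Binning** — left-closed/right-open 10-day bins anchored at the first
  profile of each quasi-Lagrangian window; quartiles by linear
  interpolation between order statistics (numpy default, "type 7"). The
  anchoring makes per-window series reproducible regardless of the mission
  start.
* **Monte Carlo** — every uncertain coefficient is `(mean, sd)` and drawn
  as an independent normal; 5000 iterations; summaries are the median and
  quartiles of the evaluated draws. Draws of physically nonnegative
  quantities (sinking speeds, respiration) are *not* truncated at zero, so
  flux summaries can straddle zero; the ESP estimator instead rejects and
  counts draws that break its own algebra (see below). Fixed seeds make
  every summary bit-reproducible; each pipeline stage draws from its own
  seed stream, so disabling one estimator never changes another.
* **Seawater state** — implemented directly from the published fits:
  one-atmosphere EOS-80 density (check value rho(35, 5 °C) = 1027.67547),
  García–Gordon (1992) Benson–Krause oxygen solubility (check value
  274.610 µmol kg⁻¹ at 10 °C/35), Flament (2002) spiciness (surface
  referenced, π(0 °C, 35) = 0), and the NOAA solar-position algorithm.
  Spiciness enters only through *anomalies* at a −0.05 threshold, for which
  the Flament and TEOS-10 variants are interchangeable in practice.

## Per-profile derivations

* **Regridding**: linear interpolation to 1 m, no extrapolation, raw gaps
  wider than 25 m stay masked.
* **MLD_bio**: maximum vertical decrease of chlorophyll, searched over
  10–400 m after a 3-point running-median despike and a 5-m running mean;
  gradient by central differences. A contiguous plateau of maximal
  gradients collapses to its centre (a smeared sharp interface is centred);
  distinct tied maxima break shallow. Gradients below 10⁻⁴ mg m⁻³ m⁻¹
  (vertically uniform chlorophyll) are undefined. The despike matters:
  single-point large-particle spikes otherwise masquerade as the steepest
  gradient. The smoothing length, gradient estimator and search range are
  unspecified in the source methods and are exposed in `Constants`.
* **Density MLD** (used only to gate the quenching correction): shallowest
  depth exceeding the 5-m sigma by 0.01 kg m⁻³; an uncrossed threshold
  returns the deepest depth with a `fully_mixed` flag.
* **iPAR**: at each depth, a cubic spline through the four irradiance
  channels pinned to zero at 1000 nm, evaluated at 1-nm steps, clipped at
  zero, converted to quanta (λ/hcN_A) and integrated over 400–700 nm.
  Pure energy integration is available as a config switch
  (`ipar_quantum = False`).
* **NPQ correction**: daytime profiles only (solar elevation > 5°); the
  chlorophyll maximum above the density MLD is extended to the surface
  provided it sits shallower than the 15 µmol photons m⁻² s⁻¹ isolume.
  The correction never decreases chlorophyll and never alters it below the
  correction depth.
* **Carbon conversions**: POC = 3.12·10⁴ b_bp700 + 3.04 mg C m⁻³ and
  C_phyto = 12.128·10³ b_bp470 + 0.59, exact affine maps; uncertainty is
  attached downstream by the Monte Carlo engine.

## Optical spike decomposition and spike fluxes

The baseline is a morphological opening (running minimum then running
maximum, 11-point window ≈ 11 m); the spike pool is the nonnegative
residual, the blank is the median baseline over the deepest 50 m (≥ 450 m
when sampled), and the small pool is baseline − blank floored at zero.
Within half a window of the profile ends the opening is unreliable on
sloped signals, so the baseline is pinned to the signal there (no spikes
detected in the top/bottom 5 m). The three pools reconstruct the signal
exactly wherever the baseline does not dip below the blank. Spike fluxes
use the 10-day bin mean (and sd) of spike concentrations in the 100-m
stratum below MLD_bio; only b_bl700 feeds the POC flux, and the conversion
intercept is deliberately not used (the spike pool is a fraction of total
backscattering).

## Optical sediment trap

Cleaning follows the stated rules: phases < 24 h rejected, first 3 hourly
samples dropped (stabilisation), optical spikes (rise ≥ 0.002 m² m⁻²
followed within 3 samples by a return below the pre-rise level + 0.002)
removed, then a 5-point running median with edge-replicated padding (a
plain truncated-window median smears a boundary step into a spurious steep
segment). Segmentation is recursive: fit one line; while any |residual|
exceeds `fit_tol` (default 5·10⁻⁴ m² m⁻², exposed in config), split at the
breakpoint minimising the two-segment squared error (prefix-sum closed
form) and recurse. The optimal breakpoint, rather than the worst-residual
point, is used because the latter strands discontinuities inside
minimum-length segments. Interior segments have ≥ 3 points; the two
record-edge segments may be shorter (1–2 points), since a jump within two
samples of the edge is otherwise unresolvable and contaminates the
length-weighted slope. Jumps are differences of the *fitted* lines at the
right segment's first sample; only positive jumps count toward the pulsed
flux. Continuous flux = duration-weighted mean slope × 24; pulsed flux =
Σ positive jumps / phase duration. Negative continuous means are retained
(a clamp switch exists, default off).

Known limitation: two jumps separated by a single sample cannot both be
isolated under the 3-point interior minimum; under the default synthetic
conditions this caps ensemble pulsed recovery at roughly 93–95% (measured
by the acceptance script), and jumps smaller than ~2·`fit_tol` are
indistinguishable from slope.

## Mixed layer pump

Signed exchange stocks between consecutive profiles use the displayed
piecewise integral with the earlier profile's POC and the 100-m floor;
trapezoidal integration on the 1-m grid with interpolated endpoints. The
flux series is the 20-day centred moving sum over 20 days, evaluated daily
and averaged per 10-day bin. Every stock is affine in the two bbp-to-POC
coefficients, so the Monte Carlo over the conversion is propagated exactly
through the affine form (no re-integration per draw). The annual integral
is the plain sum of stocks over a window, in g C m⁻². Bins whose 20-day
neighbourhood contains an event gap longer than the window are flagged low
confidence.

## Eddy subduction pump

Anomalies are value minus a ±10-bin centred running median on 5-m-gridded
profiles, searched between MLD_bio and 500 m (≥ 30 valid bins required).
A feature requires AOU′ < −5 µmol kg⁻¹, spice′ < −0.05 and POC′ > 0 *at the
same bin* (run-overlap coincidence is available as a config option); only
the shallowest contiguous candidate is kept. The vertical extent takes the
shallower of the AOU′/spice′ negative-run tops and the deeper of their
bottoms; z_ev and POC_ev are medians over the extent. Note that against a
steep background gradient the running-median background absorbs part of a
layer's contrast, so measured anomalies understate in-situ contrasts by up
to a factor ~2 for 30-m layers — thresholds are therefore conservative.

The flux uses the respiration clock with R treated as **volumetric**
(0.33 ± 0.16 mg C m⁻³ d⁻¹) so that Δt = (POC_surf − POC_ev)/R is in days,
and the velocity written as w_sub = (z_ev − MLD)/Δt so it is positive
downward. POC_surf and MLD carry the mean and sd over the profiles of the
containing 10-day bin. Draws with R ≤ 0, Δt ≤ 0 or w_sub ≤ 0 are rejected
and counted (the flux is a gross export; nothing negative is emitted);
a rejection rate above 50% flags the estimate unreliable. Positive-spice
detection (π′ > 0.05) exists behind a flag, default off.

## Particle size

`Ā = var(detrended)/mean · (V/Q)/α(τ)`, `D̄ = 2√(Ā/π)`; the variance is of
the 5-point running-median-detrended signal, the mean of the raw signal,
exactly as the estimator is defined. Sensor presets: transmissometer
(t_res 0.1 s, t_samp 1 s, V 12.5 ml, Q = 2) and backscattering sensor
(0.06 s, 1 s, 0.62 ml, Q = 0.02); all volumes in m³ internally, diameters
reported in µm. Samples are taken in depth order within 0–50 m. The three
channel estimates are pooled (not averaged first) into 10-day bins. The
median detrend deflates the variance of uncorrelated noise by a measurable
few percent, so recovered diameters run slightly low; the acceptance script
quantifies this against a mechanistic Poisson/residence-time simulation.

## Photophysiology and phenology

NPQ(z) = (corrected − quenched)/quenched, zero below the correction depth;
α_NPQ is the OLS slope of NPQ against iPAR over 15–75 µmol photons m⁻² s⁻¹
(≥ 3 pairs, fits with r² < 0.8 rejected). All depths with valid pairs in
the window are pooled. Kd(490) is minus the mean derivative over 0–50 m of
a degree-4 polynomial fit to log irradiance (exact for pure exponentials);
Kd(PAR) via the Morel-2007 polynomial
`0.0665 + 0.874 Kd490 − 0.00121/Kd490`; I_ML by the displayed exponential
with the satellite-style daily PAR scalar (no satellite I/O is
implemented). Phytoplankton stock P integrates C_phyto over 0–500 m where
small-pool chlorophyll (chl − chl_l − 0.3 mg m⁻³) is positive. Phenology
interpolates P to 5-day steps, smooths with a 7-point (30-day) running
mean, and takes r by centred differences: apex = max P, climax = max r at
or before the apex, onset = the *last* negative-to-positive crossing of r
before the climax (robust to winter noise; the first-crossing variant is a
config flag).

## Synthetic missions and what passing tests show

The generator builds closed-form fields: a cosine seasonal mixing-layer
cycle (winter 300 m, summer 50 m) with AR(1) sub-seasonal excursions
(sd 12 m, φ 0.7); a Gaussian bloom (peak +1.5 mg chl m⁻³ at mission day
100, width 30 d) on a slowly declining base, homogeneous over the mixing
layer with a sharp 4-m ramp at its base (so MLD_bio is unambiguous by
construction; an offset decouples it from the density MLD for robustness
tests); backscattering tied to chlorophyll; oxygen at saturation in the
mixed layer with AOU rising below; spectral irradiance decaying with
chlorophyll-coupled attenuation; a known quenching law
chl/(1 + α·iPAR) with α = 0.005 on daytime profiles; Poisson large-particle
spikes below the mixing layer; hourly parking attenuance with a
bloom-coupled slope, lognormal jumps (median 3·10⁻³ m² m⁻², ~0.5 d⁻¹),
Gaussian noise (sd 10⁻⁴) and removable optical spikes; and a catalog of
subduction lenses injected as density-compensated T/S perturbations with
AOU and POC contrasts (defaults −25 µmol kg⁻¹, −0.1, +20 mg C m⁻³ — large
enough that the *measured* anomaly clears the thresholds despite the
running-median attenuation, as real subducted surface water would).
Upper-50-m optical noise carries exactly the variance the true particle
diameter implies through α(τ) (Gaussian approximation); the dedicated size
oracle instead simulates particles mechanistically.

Ground truth (mixing-layer path, analytic exchange stocks from the
closed-form fields, per-phase trap slopes and jump sums, the injected
feature catalog, the quenching slope, dense noise-free stock series) is
recorded once in `SyntheticTruth`, and recovery tests read only it.

What the generator does *not* emulate: hydrodynamics and mesoscale velocity
fields, water-mass changes along the trajectory, depth-varying or
time-varying sinking speeds, sensor drift and calibration error,
non-normal measurement noise, and irradiance spectral shapes beyond four
channels. Passing tests therefore demonstrate the estimators' correctness
and internal consistency under the assumed statistical structure — not the
validity of those assumptions for any real mission.

## Pipeline

`run_pipeline` derives all profiles, decomposes the optical pools, and runs
the six flux estimators over quasi-Lagrangian windows (defaults:
2016-09-24–2017-05-22, 2017-10-10–2018-06-07, 2018-11-05–2019-05-01;
missions outside all windows fall back to a single whole-mission window).
All constants are logged at run time; diagnostics record rejected parking
phases, skipped profiles and Monte Carlo rejection counts. Problem sizes
throughout the tests and the acceptance script — 365-day missions at 2-day
cadence, 500-m profiles at 1 m, 5000 Monte Carlo iterations, 20 event-free
specificity missions of 60 days — are the package's chosen study
conditions and run end-to-end in well under a minute each.

## Known limitations

* The OST→carbon calibration is a North Atlantic relationship; no
  Southern-Ocean-specific alternative exists, and the conversion is
  configuration, not science, here.
* ESP fluxes are gross export; upward (obduction) fluxes and feature
  tracking across profiles are out of scope.
* The oxygen air-calibration procedure is reduced to a single configurable
  gain factor (default 1.0557).
* MLD_bio in stratified summer water tracks the base of the euphotic zone
  rather than active mixing; the estimators inherit that interpretation.
* The quenching-slope recovery on synthetic missions runs ~25% low because
  the correction anchors at the chlorophyll maximum above the mixed layer,
  which is itself slightly quenched; the same bias plausibly affects real
  retrievals.
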