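# floatpump

Multi-pathway **biological carbon pump** analysis from a single profiling
float's bio-optical time series — for biogeochemists working with
BGC-Argo-style data who want the gravitational pump and the particle
injection pumps quantified concurrently, with honest uncertainties, from one
platform.

The ocean exports organic carbon from its sunlit surface by several
mechanisms at once:

* **Gravitational pump** — sinking aggregates. Quantified two ways:
  1. *Optical spikes*: chlorophyll and particulate backscattering profiles
     are partitioned into refractory blank, small-particle baseline and
     large-particle spike pools (morphological opening); the spike
     concentrations in the 100-m stratum below the mixing layer times bulk
     sinking speeds give
     `F_chl_spike = <Chl_l> · w_chl` and
     `F_poc_spike = <b_bl700> · Q_bbp/POC · w_bbl`
     with `w_chl = 98 ± 64` and `w_bbl = 74 ± 45 m d⁻¹`.
  2. *Optical sediment trap (OST)*: while the float drifts at ~300 m,
     particles settle on the upward-facing transmissometer window. The
     attenuance record ATN = −ln(transmittance) is segmented into linear
     pieces and discontinuities: the length-weighted mean slope is the
     continuous flux of slow sinkers, the summed positive jumps per day the
     pulsed flux of fast sinkers, both converted to carbon by
     `F_OST = <F_ATN> · 2133(±173) + 1.4(±5.6)` mg C m⁻² d⁻¹.
* **Mixed layer pump (MLP)** — when the mixing layer (depth `MLD_bio`, the
  maximum vertical chlorophyll gradient) shoals, particle-laden water is
  detrained below the 100-m productive floor:
  `∫POC = ±∫ POC(z,t) dz` between consecutive mixing-layer depths, summed
  with a 20-day centred moving sum.
* **Eddy subduction pump (ESP)** — submesoscale circulation injects ~10–40-m
  lenses of surface water to depth. Detected as coincident anomalies against
  a ±10-bin running median on 5-m profiles: `AOU′ < −5 µmol kg⁻¹`,
  `spice′ < −0.05`, `POC′ > 0`. Each feature is dated by a respiration
  clock, `Δt = (POC_surf − POC_ev)/R` with `R = 0.33 ± 0.16 mg C m⁻³ d⁻¹`,
  and exported as `F_ESP = POC_surf · (z_ev − MLD)/Δt`.

Supporting estimators: area-weighted mean particle diameter from the
variance-to-mean ratio of beam attenuation / backscattering
(`Ā = var/mean · V/Q · 1/α(τ)`, `D̄ = 2√(Ā/π)`), the NPQ-based iron-stress
index `α_NPQ` (initial slope of non-photochemical quenching against
instantaneous PAR), mixed-layer light `I_ML = PAR_SAT e^(−0.5 Kd(PAR) MLD)`,
and bloom phenology (onset / climax / apex from the accumulation rate
`r = (1/P) dP/dt` of depth-integrated phytoplankton carbon).

Every flux is summarised per 10-day bin as the median and interquartile
range of 5000 Monte Carlo draws over the calibrated coefficients and the
spatio-temporal spread.

A first-class synthetic mission generator (`floatpump.synthetic`) emulates
the statistical structure the analysis assumes — seasonal mixing-layer
cycle, bloom, sub-mixing-layer spikes, injectable subduction lenses, parking
attenuance with jumps — and records the ground truth for every injected
quantity, so every estimator is exercised end-to-end against known answers.

## Worked example

```bash
python examples/full_mission.py
```

prints (seed 1):

```
mission: 183 profiles, 182 parking phases
  F_ESP              peak 10-d median    279.7 mg C m-2 d-1 over 3 bins
  F_MLP              peak 10-d median    280.8 mg C m-2 d-1 over 24 bins
  F_OST_continuous   peak 10-d median     22.1 mg C m-2 d-1 over 24 bins
  F_OST_pulsed       peak 10-d median      9.7 mg C m-2 d-1 over 24 bins
  F_chl_spike        peak 10-d median      1.0 mg C m-2 d-1 over 24 bins
  F_poc_spike        peak 10-d median     77.1 mg C m-2 d-1 over 24 bins
annual integrals (g C m-2):
  window_1 F_chl_spike           0.12
  window_1 F_poc_spike           6.55
  window_1 F_OST_continuous      2.59
  window_1 F_OST_pulsed          1.22
  window_1 F_MLP                11.97
ESP features detected: 3 (injected: 3)
```

Six concurrent flux series: the spike and trap fluxes peak with the bloom,
the MLP exports during the deep-to-shallow mixing transition, and all three
injected subduction events are found. The `examples/` directory has one
short script per capability (particle size, spike decomposition, trap
segmentation, MLP, ESP, phenology/iron stress).

A thin CLI wraps the same pipeline:

```bash
floatpump synth --out mission/ --seed 1
floatpump run --in mission/ --out report/ --seed 1
```

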