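# Methods

This note documents the models implemented in `rodgain`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical policies used by the fitting stages.

## Units

Fixed package-wide: currents in pA, time in s, flash strengths in R*/rod
(mean photoisomerizations per rod), backgrounds in R*/rod/s, space in µm.
Integrated responses are in pC, gains in pC per R*/rod (or spikes per
R*/rod in spike mode). Converters live only at I/O boundaries.

## The synthetic generator

Each trial is built as

    current(t) = Σ_photons  gain(t_photon) · w(t − t_photon)  +  noise(t)

* **Photon absorptions.** Poisson across the rod pool at the per-rod
  background rate; flash absorptions are Poisson with mean
  `strength × n_rods` at the flash time. Absorptions are binned at the
  sampling interval (default 1 kHz); `generate_absorptions` also exposes
  per-rod arrival times for statistical checks.
* **Single-photon waveform.** An alpha function
  `a · (t/t_p) · exp(1 − t/t_p)` peaking at `t_p` (default 0.1 s) with
  amplitude `a` (default 1 pA); its integral is `a · t_p · e` in closed
  form. The real single-photon response shape is more structured, but only
  the peak time and amplitude matter to the downstream estimators, so the
  simplest smooth unimodal form is used.
* **Continuous noise.** White Gaussian (SD configurable; optional Butterworth
  low-pass via `noise_cutoff_hz`). The dark-noise spectrum of the real
  pathway is not modelled.
* **Gain laws.**
  - `none`: unity gain (used to verify Poisson-noise scaling: baseline
    variance affine in background).
  - `weber`: G = G_D / (1 + I_B/I_0) applied instantaneously to the current
    background. Defaults G_D = 1, I_0 = 0.08 R*/rod/s.
  - `per_photon`: every pooled absorption multiplies the gain state by
    (1 − α). Two recovery laws are provided. *Exponential* (default): the
    state relaxes to 1 with time constant `tau_recovery` (default 0.4 s,
    matching the measured recovery kinetics at light offset); its exact
    steady-state mean gain is 1/(1 + αλ) with λ = μ·τ_rec·C, because the
    multiplicative jump process closes in expectation. *Boxcar*: each
    photon's suppression expires after exactly `tau_recovery`; the
    steady-state mean gain is then exactly the pool-model value exp(−λα).
    The boxcar mode is the exact trial-level realization of the closed-form
    pool model; the exponential mode is the more physiological relaxation.
    Both are tested against their respective closed forms.
* **Sign convention.** On responses are inward currents; traces are emitted
  positive-up so estimators never re-flip signs.
* **Spike mode.** `to_spike_counts` bins a rectified, scaled copy of the
  current into 10 ms Poisson spike counts; gain ratios measured from spike
  counts and currents agree within Monte-Carlo error (tested).
* **Reproducibility.** One root seed; per-trial child generators derived by
  `numpy.random.SeedSequence.spawn` in a fixed trial order. Identical
  config + seed ⇒ bit-identical trace sets.

### Protocol suites

* `flash_series`: probe flashes on steady backgrounds. Because gain spans
  decades, flash strengths are passed per background (`flash_strengths`), as
  a config list rather than a hard-coded schedule.
* `step_series`: a background step with probe flashes at delays after the
  step onset and offset (default grid {0.1, 0.2, 0.4, 0.8, 1.6, 2.0} s),
  plus step-only trials used for subtraction. Flash strengths can differ
  across the step to keep responses comparable (two-point pre-calibration).
* `bar_adaptation`: probes at a bright-bar center (adapted) and a dark-bar
  center (unadapted), in a uniform baseline phase and a bar-grating
  adapting phase. The local effective background at each probe location is
  the grating pooled through the adaptation aperture (below); probe trials
  are then simulated at that effective background. This reduced model skips
  explicit 2-D rod mosaics but preserves exactly the quantity the analysis
  measures (local gain before/after adaptation).
* `dual_wavelength`: rod + cone mixtures. The cone component has fixed gain
  and faster kinetics (alpha function, default t_p = 35 ms); long-wavelength
  flashes drive it at full strength, short-wavelength flashes at a 1/600
  leak (the rod/L-cone spectral sensitivity ratio is a simulator parameter,
  not a fitted quantity). Ground-truth cone components are stored alongside
  each trace for recovery tests.

### What passing tests do and do not show

The generator realizes exactly the statistical structure the estimators
assume: Poisson photon noise, linear superposition of stereotyped
single-photon responses, Gaussian continuous noise, and the stated gain
laws. Parameter recovery on these data validates the estimator
implementations and their noise handling; it cannot validate the biological
assumptions themselves (response nonlinearities, correlated noise, synaptic
saturation, spike-generation dynamics are all absent by construction).

## Estimators

* **Response window**: contiguous run of samples where the trial-averaged
  response exceeds 20% of its post-flash maximum; with several disjoint
  supra-criterion runs, the run containing the global peak is kept.
  Fixed-window analysis is available and agrees with the adaptive window on
  well-formed responses (tested at 15%).
* **Gain**: baseline-subtracted integral of the windowed current divided by
  flash strength. Baseline default: 0.5 s ending 50 ms before the flash.
* **Template projections**: the template is the raw mean windowed response
  (not unit-normalized — the threshold is invariant under template
  rescaling, so normalization is cosmetic). The noise projection ν is *not*
  divided by flash strength: it is a property of the cell's noise alone.
* **Threshold**: θ = σ_ν / mean(γ), the flash strength at which the
  expected projected signal equals the projected-noise SD.

## Weber fits and slopes

Fitting is done on log gain (equal relative weighting across decades of
gain). Initialization: G_D from the maximum gain, I_0 from the background
nearest half-max, with a log-spaced fallback grid of I_0 starts.
A `min_background` mask excludes very dim backgrounds where a separate
history-dependent dark-gain mechanism operates; it is off by default and
exposed in config. Default slope regions: three bands of equal log-width
0.8 decades centered one decade below, on, and one decade above I_0 (the
band width is a free choice exposed in `default_regions`).

## Exponential kinetics

Gain-change-versus-delay series are fit with
`gain(t) = asymptote + amplitude · exp(−t/τ)` by least squares with
multiplicative-error weighting (residuals divided by the observed gain),
matching data whose per-delay errors scale with gain. Because a local
optimizer on 6 noisy points frequently diverges to τ → ∞, the fit is
global: τ is profiled on a 200-point log grid spanning
[first delay / 20, 2 × delay span] — the inner problem in (asymptote,
amplitude) is weighted-linear — then refined by bounded scalar
minimization. Noiseless series are recovered to ~1e-9 relative error; the
standard error of τ comes from the weighted-LS covariance at the optimum.

Synthetic kinetics series model the gain *change* relative to the post-step
steady state, which decays to zero as a single exponential (this is the
quantity a log-scale plot of gain change shows as a straight line). With
the default probe grid and 10% multiplicative noise, the mean fitted τ over
a handful of cells recovers the generating value to ~1%.

The slow (~100 s) baseline relaxation seen in real recordings is treated
purely as a nuisance: it is not modelled, and tests verify that adding such
a drift (with small trial-to-trial amplitude jitter) changes fitted time
constants by <5%, because the step-only subtraction and per-trial baseline
windows cancel it.

Per-cell fits are summarized across cells (mean ± SE); no pooled fit is
performed.

## Spatial transfer

Gain change per location = adapting-phase gain / baseline-phase gain.
Reported measures:

* `transfer` — raw ratio (unadapted change)/(adapted change); 1 means
  complete transfer, >1 incomplete (the unadapted location was less
  desensitized).
* `transfer_index` — (1 − unadapted change)/(1 − adapted change), mapping
  complete transfer to 1 and no transfer to 0, for population plots.

The geometric prediction pools the square-wave grating through an aperture
and applies the Weber law to the pooled local intensity. The default
aperture is a uniform 1-D window of width equal to the pool diameter: a
window spanning exactly one grating period averages to the exact mean
everywhere, so bars of half the pool diameter produce exactly complete
transfer — the idealized geometric argument. A chord-weighted disk section
and a Gaussian kernel (σ = diameter/4) are available via `kernel=`; the
disk weighting is not phase-flat at bar width = diameter/2 and predicts
slightly incomplete transfer there. The bright-bar coverage of the uniform
window is computed in closed form (no quadrature); disk/Gaussian kernels
use dense numeric integration, cross-checked against an independent
integration oracle in the tests.

## Rod/cone separation

The matched short-wavelength (rod-only) response is scaled by least squares
on a late, rod-dominated segment (default 0.2–0.6 s after the flash: late
enough that the fast cone component has decayed, early enough that the rod
response persists) and subtracted from the long-wavelength response. A
late-segment correlation below 0.5 triggers a mismatch warning. Pathway
slopes are computed on gains normalized to the lowest background.

## Problem sizes

Monte-Carlo checks in the tests use 10³–10⁶ draws chosen so that each
assertion's 3-SE band is a few times tighter than the effect it checks;
trace-level simulations use 40–150 trials per condition with 100–400-rod
pools — comparable to real experiments and sufficient for the stated
tolerances.

## Known limitations

* No biophysical phototransduction cascade, synaptic vesicle pool, or
  spiking neuron model; spike mode is a rectified-Poisson read-out.
* The Weber and per-photon gain laws act instantaneously on photon
  amplitudes; there is no separate temporal-filter stage for adaptation.
* The bar-adaptation simulation models pooling implicitly through the local
  effective background rather than an explicit rod mosaic.
* The dark-gain reduction at the very dimmest backgrounds (a distinct
  history-dependent mechanism) is not modelled; the Weber fit provides a
  mask to exclude that regime when fitting real data.
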