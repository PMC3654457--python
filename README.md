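# rodgain

Simulation and analysis of retinal gain control near absolute visual
threshold.

At the lowest light levels vision uses, photons arrive so sparsely that a
single rod photoreceptor absorbs one only every few minutes. Yet retinal
ganglion cells adjust their gain reliably and within a fraction of a second
when the background light changes. `rodgain` packages the computational side
of studying this problem: a stochastic generator of rod-pathway
flash-response experiments with known ground truth, the matching estimators
(gain, noise, ideal-observer detection threshold), curve fits for adaptation
(Weber law, exponential kinetics), spatial adaptation-transfer analysis, and
a closed-form Poisson model of gain control operating on a pool of rods.

## The models

**Weber-law gain.** The gain G of the dim-flash response (integrated
current per unit flash strength, pC per R*/rod) depends on background
I_B (R*/rod/s) as

    G(I_B) = G_D / (1 + I_B / I_0)

where G_D is the dark-adapted gain and I_0 the half-desensitizing
background. `rodgain.weber.fit_weber` fits this in log-gain space;
`loglog_slope` measures the local exponent of gain, noise, or threshold
versus background.

**Detection threshold.** Flash responses are projected on a template (the
mean windowed response). With γ the per-trial projection per unit flash
strength and ν the projection of pre-flash noise, the ideal-observer
threshold is the flash strength giving signal-to-noise ratio 1:

    θ = σ_ν / mean(γ)      (R*/rod)

**Poisson photon-pool model.** A neural element pooling C rods over an
integration time τ at background μ collects k ~ Poisson(λ), λ = μτC photons.
If each photon multiplies the gain applied to later photons by (1 − α), the
expected pooled gain is

    Γ(λ, α) = Σ_k P(k; λ) (1 − α)^k = exp(−λα)

`rodgain.pool` provides Γ, its inversions (the α needed for a target gain,
the convergence C needed for a target photon-catch probability), and the
simulator implements the same law trial by trial.

## Worked example

How strongly must one absorbed photon suppress gain for a pool of rods to
halve its gain at a background of 0.08 R*/rod/s?

```
$ rodgain model alpha --rods 800 --background 0.08
lambda = 6.4; alpha = 0.108304 (10.8% per photon)
$ rodgain model alpha --rods 200 --background 0.08
lambda = 1.6; alpha = 0.433217 (43.3% per photon)
```

An 800-rod pool needs only an 11% per-photon reduction; a 200-rod pool
would need 43%.

Simulating a flash-series experiment and recovering the Weber parameters:

```python
from rodgain.simulate import SimulationConfig, WeberGain, simulate_protocol_suite
from rodgain.metrics import metrics_table
from rodgain.weber import fit_weber

cfg = SimulationConfig(n_rods=200, continuous_noise_sd=0.3,
                       gain_law=WeberGain(G_D=1.0, I_0=0.08))
bgs = [0.01, 0.04, 0.08, 0.16, 0.64, 2.56]
strengths = [0.05 * (1 + b / 0.08) for b in bgs]   # keep responses comparable
traces = simulate_protocol_suite("flash_series", cfg,
    {"backgrounds": bgs, "flash_strengths": strengths}, n_trials=40, seed=7)
table = metrics_table(traces)
fit = fit_weber(table.background, table.gain)
print(f"G_D = {fit.G_D:.1f} pC/(R*/rod), I_0 = {fit.I_0:.4f} R*/rod/s")
```

prints

```
G_D = 47.8 pC/(R*/rod), I_0 = 0.0833 R*/rod/s
```

The fitted half-desensitizing background (0.083 R*/rod/s) recovers the
ground-truth 0.08 within Monte-Carlo error; the gain column falls roughly
two-fold per two-fold background increase above I_0, and the threshold
column rises with a log–log slope below 1 — the same qualitative structure
the estimators are designed to measure on recorded data.

The same stages are available from the shell: `rodgain simulate`,
`rodgain analyze gain|weber|kinetics|transfer|pathways`,
`rodgain model convergence|alpha|gain`, and `rodgain run-all` (full
pipeline with a checksummed run manifest).

## Layout

- `rodgain.simulate` — stochastic trial generator (Poisson absorptions,
  single-photon waveforms, gain laws, protocol suites)
- `rodgain.metrics` — response windows, gain, template projections, noise,
  detection threshold
- `rodgain.weber` — Weber fits, region slopes, fluctuation-driven prediction
- `rodgain.pool` — closed-form Poisson photon-pool model
- `rodgain.kinetics` — step-protocol isolation and exponential fits
- `rodgain.spatial` — bar-adaptation transfer, pooling kernels, rod/cone
  separation
- `rodgain.io`, `rodgain.pipeline`, `rodgain.cli` — HDF5/CSV/config I/O,
  end-to-end orchestration, command-line interface

See `docs/methods.md` for the modelling assumptions, parameter defaults,
and numerical choices.
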