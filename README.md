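# fiberglide

Simulation and analysis toolkit for **gliding motility assays mounted on
optical fiber tips** — a microscope-free biosensing scheme in which
kinesin-propelled microtubules glide off the polished tip of a multimode
fiber while an avalanche photodiode (APD) watches the fiber-coupled
fluorescence decay.

## The science

In a gliding assay, kinesin-1 motors fixed to a surface propel
fluorophore-labelled microtubules across it. Mounted on a fiber tip, only
filaments on the light-guiding core contribute to the collected emission,
so as filaments glide off the tip the signal decays. An analyte that binds
the microtubules slows them (roadblock effect) or cross-links them into
bundles that never leave the tip — both change the decay and can be read
out without any microscope.

The package implements three connected pieces:

1. **Monte-Carlo tip simulator.** Each filament is reduced to its leading
   tip performing a worm-like-chain walk: per 10 ms step the heading gets
   a zero-mean normal increment with `Var(Δθ) = v_f·Δt/L_p`, and the tip
   advances `v_f·Δt`. Tips crossing the motility-zone edge detach with
   probability 0.8 or are steered along the boundary; detached tips
   diffuse above the tip and re-land at 0.01/s while over the zone.
   Bundled tips never leave the core.

2. **Decay model and speed law.** The core population follows the
   moderated exponential `I_rel(t) = (1 − Z)·e^(−Λt) + Z`, where the
   plateau `Z` absorbs cladding returns and re-landing. The decay constant
   converts to gliding speed through `V = Λ·r·H`, with `r` the core radius
   and `H` a calibration constant obtained by regressing independently
   measured speeds on `Λ·r` (through the origin).

3. **Acquisition and detection.** The APD model reproduces the instrument
   schedule — 100 ms shutter openings sampled every 10 ms (nine usable
   samples), one opening per fluorophore per 2.6 s, 22 openings and
   22 × 9 = 198 samples averaged per 58 s window — with Poisson photon
   noise and scalar background subtraction. A two-channel experiment
   (control vs measurement fluorophore) is compared per window with a
   two-sample Kolmogorov–Smirnov test on the normalised raw samples;
   detection time is the first window from which `p < α` is sustained to
   the end of the record, and a bundling flag fires when the decay model
   no longer explains the measurement curve (low fit R² or plateau near 1).

See `docs/methods.md` for model details, parameter defaults and the
statistical trade-offs of the two-channel comparison.

## Worked example

Simulate a two-channel experiment in which the measurement population is
slowed from 800 to 500 nm/s (as by a small analyte at saturating
concentration), and call the analyte:

```yaml
# experiment.yaml
seed: 42
n_tips: 500
duration: 300.0
channels:
  A: {gliding_speed: 800.0}   # control population
  B: {gliding_speed: 500.0}   # analyte-slowed population
calibration: {H: 0.90, r: 100.0}
```

```sh
fiberglide detect --simulate experiment.yaml --report report.json
# verdict=detected detection_time=261.0
```

The report contains, per channel, the decay fit and, across channels, the
per-window KS p-values and the model-based speed difference:

```
p_values:          0.36  0.0011  3e-07  0.16  0.00022
lambda A: 0.00914 /s     lambda B: 0.00291 /s
delta_v:  561 ± 406 nm/s
bundling flag: False
```

Reading this: the two relative-intensity curves are indistinguishable in
the first window (both normalised to 1 there, p = 0.36), diverge strongly
as the faster control population leaves the core (p down to 3×10⁻⁷), and
the sustained-significance rule calls the analyte from the 261 s window.
The fitted decay constants differ by a factor ~3 and convert, through
`V = Λ·r·H`, to a speed difference of (561 ± 406) nm/s — consistent with
the true 300 nm/s gap within its (large, five-window) uncertainty. The
bundling flag stays down because the slowed curve still decays in
agreement with the model; rerunning with
`B: {gliding_speed: 500.0, bundled_fraction: 0.9}` raises it and makes
detection both earlier and far more significant.

The same library surface is available programmatically
(`fiberglide.simulate_population`, `fit_decay`, `calibrate_H`,
`run_detection`, `fiberglide.workflows.lambda_speed_sweep`, …), and the
other subcommands — `simulate`, `synth`, `fit`, `calibrate` — expose the
individual pipeline stages on CSV/YAML files.

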