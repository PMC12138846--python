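# Methods

`fiberglide` models a gliding motility assay mounted on the polished tip of
a multimode optical fiber and the signal chain that turns the fiber-coupled
fluorescence into an analyte call. This note records the model, the
parameters that matter, the numerical choices, and the limits of what the
synthetic experiments can show.

## Tip-population model

Only the leading tip of each microtubule is simulated: in a gliding assay
the tip encounters the next surface-bound kinesin motor and the filament
body follows the tip's path. A tip gliding at speed `v_f` (nm/s) updates
its heading every `Δt` (default 10 ms) by a zero-mean normal draw with

    Var(Δθ) = v_f · Δt / L_p

which is the discrete worm-like-chain result: heading decorrelates over one
persistence length `L_p` (default 100 µm) of arc. The tip then advances
`v_f·Δt` along the new heading.

The kinesin-coated surface is a disc: a light-guiding core (radius 100 µm,
a 200 µm-diameter fiber) plus a cladding annulus (default width 10 µm, not
a measured value). Only tips on the core contribute to the guided
fluorescence. A tip crossing the outer cladding edge detaches with
probability 0.8; otherwise it is steered along the boundary, onto whichever
tangent direction has a positive component along its incoming heading
(exact radial incidence resolves counter-clockwise). Detached tips perform
a 2-D random walk (per-axis step variance `2DΔt`, default D = 1 µm²/s — a
plausible value for µm-scale filaments, not a measured one) in a halo
extending to 4 × the cladding radius; crossing that outer boundary is
absorbing ("lost"). While a diffusing tip is over the motility zone it
re-lands as a per-step Bernoulli trial with probability `0.01/s · Δt`,
with a freshly uniform heading.

Bundled tips (fraction `bundled_fraction`) model filaments cross-linked by
a multivalent analyte: they never detach and are steered at the **core**
edge, so they stay on the light-guiding core indefinitely. Confining them
to the core (rather than the full motility zone) is deliberate: bundles
are held on the tip and keep contributing to the guided signal, so a
90%-bundled population produces a curve that plateaus near 0.9 — the
non-decaying signature the flag looks for. Letting bundled tips wander
onto the (dark) cladding instead produces a clean decay to a ~0.5 plateau,
which is not the bundling phenotype.

The per-tip operations (`step_gliding`, `apply_edge_rule`,
`step_diffusion`) are the readable reference implementation;
`TipEnsemble` applies identical rules to whole arrays and is what
`simulate_population` runs. Identical seeds give bit-identical output.

## Decay model and speed law

The core population, and hence the relative intensity, follows the
moderated exponential

    I_rel(t) = (1 − Z)·e^(−Λt) + Z,     Z ∈ [0, 1)

where Λ is the decay constant and the plateau Z absorbs two return fluxes:
cladding tips turning back onto the core, and detached tips re-landing.
The fit is bounded nonlinear least squares (trust-region reflective) on
data normalised to the first point; Λ is initialised from the log-slope of
the first half of the curve and Z from the last observed value. Standard
errors come from the Jacobian-based covariance at the optimum. A
three-parameter variant with a free amplitude is available behind
`free_i0` for curves whose first point is unreliable.

Gliding speed follows from `V = Λ·r·H` with `r` the core radius and `H` a
dimensionless calibration constant. `H` has no closed geometric form here;
it is recovered by regressing independently known speeds (simulation
ground truth; in the laboratory, tracking software) against `Λ·r`, through
the origin because the law has no intercept.

**Calibration is pipeline-matched.** The sweep (`lambda_speed_sweep`,
default 200–800 nm/s, 20 populations of 300 tips per speed, records
covering 4 decay times at every speed) fits Λ through the *same*
measurement chain used for unknown samples — synthesize, background-
subtract, window-average, normalise, fit — so protocol biases cancel in H.
Fitting raw count series instead leaves a systematic speed-dependent
residual: the 0.01/s re-landing process contributes a speed-independent
timescale that contaminates the fitted decay mode more strongly at low
speeds, drifting the per-speed H by ~10%; through the matched pipeline the
per-speed spread is ~4% and the origin-forced regression R² ≈ 0.999.
A single closed-loop measurement at 1000 tips carries ~5% statistical
scatter (finite-population demographics), so the 15% closed-loop budget
corresponds to ~3 standard deviations.

## Acquisition model

The shutter opens for 100 ms; the APD records counts every 10 ms, and nine
samples per opening are usable (the opening is not instantaneous — the 9
is adopted as stated, not derived from a rise-time model). Each
fluorophore is visited every 2.6 s; with two channels the filter wheels
alternate strictly A,B,A,B so the shutter itself opens every 1.3 s.
Counts are averaged over 58 s windows: 22 openings × 9 samples = 198
samples per window per channel, with the 95 % CI half-width `1.96·sd/√198`.

Because 2.6 does not divide 58 (58/2.6 = 22.3), openings at exactly 2.6 s
spacing would alternate between 22 and 23 per window. The schedule
therefore quantises the effective period to `window/⌊window/period⌋`
(58/22 ≈ 2.636 s) so every window holds exactly the instrument's stated
bookkeeping. Trailing partial windows are dropped, never extrapolated.

Photon counts are Poisson with mean
`counts_per_microtubule · N_core(t) + background`. The background is
estimated as the scalar mean of a separately recorded 2-minute
no-microtubule trace (per channel, no drift model) and subtracted
per-sample, clipping at zero since counts are nonnegative.
Photobleaching is not modelled.

Two photon regimes are used, and the distinction matters:

- **Single-channel speed measurement (PhotonModel defaults):** 1 count per
  microtubule per sample on a 50-count background — a bright,
  well-photobleached fiber. Here clipping after background subtraction is
  negligible and decay curves are clean.
- **Dual-fluorophore detection (ExperimentConfig default):** 0.08 counts
  per microtubule per sample on a 360-count background — weaker dyes and
  filter losses, autofluorescence-dominated.

The second regime is not merely cosmetic. The per-window two-sample KS
test compares the ~198 normalised raw samples of the two channels, and
three nuisance effects can masquerade as signal: (i) *demographic noise* —
two finite populations of N tips differ by ~√N even at identical speeds,
a mean offset of `cpm·√(2N q(1−q))` counts that grows with per-filament
brightness; (ii) *normalisation noise* — each channel is scaled by its
noisy first-window mean (SE ≈ σ/√198); (iii) a *count-lattice artifact* —
integer counts divided by two slightly different constants misalign the
Poisson atoms of the two empirical distributions, contributing a
deterministic ECDF gap ≈ 0.4/σ. The detection defaults sit where photon
noise dominates all three (measured per-window false-rejection ≈ 0.08
against the nominal 0.05, and a whole-experiment false-detection rate of
roughly 0.1–0.2 under the sustained rule; a bright two-channel null
instead "detects" a speed difference in most replicates purely from
demographic noise).
Conversely, the dim regime's clipping bias is why it is *not* used for
absolute speed measurement. This trade-off is intrinsic to comparing raw
per-window samples between two independent finite populations; the real
instrument compares two populations on one fiber, where shared optical
fluctuations add yet another correlated component that this model omits.

## Detection procedure

Per aligned 58 s window the two channels' normalised raw samples are
compared with the asymptotic two-sample KS test, alongside whether the two
95 % CIs are disjoint. The detection time is the earliest window center
from which `p < α` holds through the end of the record
(sustained-significance rule; a lone significant window is not a call).
No multiple-testing correction is applied across windows by default — the
sustained rule plays that role — but a Bonferroni option
(`alpha/n_windows`) is available. Records of ~5 windows (300 s) are used
for the synthetic two-population experiments; on longer records the two
*relative* curves re-converge at their shared plateau and a pure-slowdown
difference becomes transient.

Statistical power differs sharply between the two analyte modes. A pure
slowdown from 800 to 500 nm/s separates the two *relative* curves by only
~0.11 at its transient peak (~150 s) before they re-converge, which in the
dim detection regime is ~0.2–0.3 per-sample standard deviations — single
runs at 500 tips per channel detect it only ~50–70 % of the time, and
detection times scatter across the record. Bundling, by contrast, pins the
measurement curve near 1 while the control decays, a separation an order
of magnitude larger; it is detected essentially always, earlier, and at
extreme significance. The weak-slowdown mode being the hard one is a
property of the method, not of the implementation.

Bundling is flagged from the measurement channel's decay fit: flag =
(R² < 0.8) OR (Ẑ > 0.8), both thresholds tunable; the erratic score is
the residual variance normalised by the squared dynamic range. A
90 %-bundled population plateaus near 0.9 and triggers the flag, and its
divergence from the control is detected earlier than a matched
pure-slowdown population — the qualitative ordering seen between
bundling-type and slowdown-type analytes.

The speed difference between channels is `ΔV = (Λ_A − Λ_B)·r·H` with the
two Λ standard errors combined in quadrature.

## What the synthetic experiments do and do not show

The generator reproduces the population phenomenology (exponential-like
core decay moderated by returns, speed-proportional decay constants,
non-decaying bundled signals) and the acquisition arithmetic exactly as
scheduled. It does not emulate: 3-D diffusion of detached filaments (the
halo is a 2-D projection with an absorbing ring), filament length
distributions or motor-density fluctuations, optical drift or focus
changes shared between channels, photobleaching, or analyte dose-response.
Passing tests therefore validate the computational chain and its internal
statistics, not instrument-specific constants: in particular H depends on
the simulator's geometry and kinetics and must be re-calibrated for any
real fiber.

## Numerical choices and degenerate inputs

- Heading wrap to (−π, π]; boundary-steering tie at exact radial incidence
  goes counter-clockwise.
- Landing is per-step Bernoulli `rate·Δt` (exact small-Δt rate reading);
  re-landing headings are uniform, positions preserved.
- Fit bounds Λ ≥ 0, Z ∈ [0, 0.999]; `xtol = ftol = 1e-14`; non-convergence
  raises an error carrying the best iterate.
- A constant curve fits to Λ·T ≈ 0 (no measurable decay over the record)
  or Z at its upper bound, with near-zero residuals.
- Curves need ≥ 4 points; normalisation requires a positive first value;
  calibration with all-zero Λ is rejected as degenerate.
- Window/opening assignment uses a 10⁻⁶ s tolerance against float drift.
- All stochastic stages draw from `numpy` Generators seeded through
  `SeedSequence.spawn`, so every workflow is reproducible from one root
  seed, and derived seeds stay below 2³¹.

## Problem sizes

Defaults were chosen as the package's standard study conditions:
calibration sweeps use 20 × 300 tips per speed (per-speed Λ SE ≈ 2 %),
closed-loop measurements 1000 tips, detection experiments 500 tips per
channel over 300 s records. Simulating one 500-tip channel for 300 s at
10 ms steps takes a few seconds on one core.
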