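# Methods

This note documents the models behind each analysis stage, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter when reproducing results.

## Synthetic data

### Labelling statistics

Each hexamer carries `Poisson(λ)` dyes right-truncated to `[0, max_dyes]`
(default `max_dyes = 6`, the number of engineered labelling sites per
hexamer; default `λ = 3.5`, a typical red-channel labelling efficiency; the
blue-channel regime is `λ ≈ 2.5`).  Truncation matters quantitatively: at
λ = 3.5 the realised mean dyes per hexamer is 3.21, not 3.5.  A degree-of-
labelling measurement by step counting estimates this realised mean, and the
stoichiometry conversion divides by the *measured* DOL — so copy numbers come
out centred on integers even though the generator's λ parameter is larger.
`simulate.truncated_poisson_mean` exposes the correction.

### Photobleaching clock

Each dye receives an exponential bleaching budget with mean `bleach_tau`,
measured in seconds of *cumulative illuminated (and bound) time*, not wall
time.  A dye's per-frame emission is the fraction of that frame's exposure
falling before its budget runs out, so bleaching within a frame produces a
partial step.  Because the clock only advances during exposure windows,
intermittent excitation (e.g. 400 ms of every 8 s, duty cycle 0.05) extends
the wall-clock fluorophore lifetime by the inverse duty cycle — exactly 20×
for that schedule — which is the mechanism that makes slow dissociation
measurable at all.

### Noise model

Rendered movies use: electronic offset + Gaussian read noise + Poisson shot
noise applied to (background + pixel-integrated Gaussian PSFs).  PSFs are
isotropic 2-D Gaussians (default σ = 1.3 px) integrated per pixel with
error-function differences, so photon counts are conserved to the Gaussian
truncation of the rendering window (±5σ, < 0.5% loss).  No EM-gain excess
noise factor is modelled; this keeps photon statistics closed-form for the
oracle tests and is a deliberate simplification of EMCCD physics.

Trajectory-level simulation (`simulate_trajectory`) produces *background-
subtracted* traces and therefore adds only Gaussian noise of sd
`read_noise_sd`; with noise parameters at zero the trace equals
(dyes × photons_per_dye_per_frame) exactly, which the exactness tests rely
on.  Shot noise on the focus signal itself is not added at trajectory level —
a simplification relative to the movie path; recovery tests that need
realistic photon noise go through the full movie renderer.

### Kinetic classes

* `stable`: bound from `bind_time` until an exponential `unbind_time`.
* `transient-telegraph`: a two-state renewal process — unbound waits
  `Exp(1/k_on)` (k_on in events/min), bound dwells `Exp(mean_dwell)`.  The
  expected number of binding events per minute is the renewal rate
  `1/(1/k_on + mean_dwell/60)`, which the tests use as the exact oracle; it
  approaches `k_on` in the short-dwell limit.
* Fork scenarios translate an anchored emitter at `fork_speed` px/s, with
  transient binders appearing at the instantaneous fork position; a fork
  reaching the field edge is truncated with a warning.

What the generator does **not** emulate: optical aberrations and drift,
EM-gain stochastics, chromatic offset between channels, DNA polymer dynamics
(forks move deterministically), and dye photophysics beyond one-step
irreversible bleaching (no blinking).  A green test therefore establishes
correctness of the analysis under these idealisations, not robustness to
every instrumental artefact.

## Change-point step detection

Traces are segmented into piecewise-constant levels under Gaussian noise.
The selection criterion is the BIC
`n·log(RSS/n) + (2k + 1)·log n` for k change points (one parameter per
segment mean, one per change-point location, one shared variance), with RSS
floored at `1e-12·n` so noiseless staircases remain comparable.

The search proposes candidate change points by binary segmentation of the
squared error — exhaustively for traces of ≤ 150 frames — and then selects
the subset that *globally* minimises the BIC by dynamic programming over
candidate boundaries (minimum-RSS placement for each k, then BIC over k;
ties prefer fewer change points).  Greedy binary segmentation alone was
found to miss pairs of change points that are only jointly favourable on
~6% of random staircases; exact subset selection restores agreement with
brute-force enumeration, which the test suite verifies directly.  For long
traces the candidate set comes from an over-fitted binary segmentation
(default 24 seeds ± 2 frames), making the cost O(n log n + m³) with m
candidates.

Down-steps (bleaching) are transitions to a lower level; upward transitions
(blinking or arrivals) count as change points but not as bleaching steps.
`min_segment` defaults to 3 frames.

## Degree of labelling

Zero-step molecules are excluded by default: an unlabelled hexamer is
invisible, so observed samples are detection-conditioned.  Two estimators are
reported side by side, because which the field uses is often unstated:

* plain Poisson MLE — the sample mean of step counts;
* zero-truncated MLE — solves `λ/(1 − e^(−λ)) = mean` by bisection
  (tolerance 1e-8), appropriate when the zero class is censored.

Neither corrects for the labelling-site cap; with λ ≈ 3.5 and six sites the
plain estimate is biased low by ≈ 0.2, within the tolerance used for λ
recovery.  Single-fluorophore intensity is calibrated from per-molecule
last-step drops (preferred; the final step is a single dye by construction)
or from raw single-molecule intensities; a normality test flags multimodal
calibration samples at p < 0.01.

## Stoichiometry

`copies = initial_intensity / (single_fluor_intensity_mean × DOL)`, with the
initial intensity the mean of the first 3 frames (configurable).  Populations
are resolved by a 1-D Gaussian-mixture EM with 20 restarts from jittered
quantile initialisations, an sd floor of 0.01 copies, and a recorded
log-likelihood trace asserted non-decreasing (the EM invariant).  k is
user-chosen; a BIC-based selector exists but is not the default, matching
field practice of choosing k from the histogram.

Two constrained variants reflect integer stoichiometry: means tied to
`m·μ₁`, and additionally widths tied to `σ₁·√m` (`sd_mode="scaled"`), the
scaling implied when per-hexamer labelling fluctuations add independently.
The scaled-constrained model is the one used for the loading scenario,
because with Poisson labelling spread (per-population sd ≈ 0.5 copies at
λ = 3.5) neighbouring integer populations overlap strongly and the
*unconstrained* 3-component maximum-likelihood fit is not identifiable at
n ≈ 600: its global optimum (confirmed against an independent EM
implementation) places means near 0.7/1.5/2.7 regardless of the true
1/2/3 structure.  The constrained model estimates two shape parameters
instead of six and recovers the population structure reliably.

## Colocalisation

Foci within 2 px (Euclidean, 0-based pixel-centre coordinates) are paired
one-to-one greedily by ascending distance, ties broken by lowest index.
Fractions use channel A (the DNA channel, by convention) as denominator.
Chance coincidence follows `C = (A_R/A_FOV)·n` with `A_R` defaulting to the
matching disc `π·r²`; the Monte-Carlo agreement of this closed form with the
matcher on uniform random foci is a standing test.  Published chance values
for specific experiments cannot be reproduced without knowing the `A_R`,
`A_FOV` and `n` actually used; the package exposes the formula and its
inputs rather than guessing.

## Kinetics

* **Ensemble lifetimes** are fitted on the frame-wise mean intensity of
  aligned trajectories (`A·e^(−t/τ)`, optional offset), the way
  single-molecule ensembles are usually analysed; a per-dwell exponential
  MLE is available when departure times are resolvable.  Initial guesses:
  A from the first value, τ from the 1/e crossing by linear interpolation.
  Standard errors come from the fit covariance, or from a seeded bootstrap
  over molecules (`n_boot`), which is what the chase comparison uses.
* **Competing rates**: `1/τ_obs = 1/τ_off + 1/τ_b`;
  `bleach_corrected_lifetime` inverts it and refuses τ_b ≤ τ_obs.
* **Bleach extrapolation** across excitation conditions assumes bleaching
  probability proportional to time-averaged dose (irradiance × duty cycle):
  `τ_target = τ_ref · dose_ref/dose_target`.  This linear-in-dose model is a
  declared assumption.
* **FRAP**: `I(t) = a·e^(−t/τ_b) + I₀(1 − e^(−t/τ))`, all parameters bounded
  positive; a is the photobleaching amplitude, τ_b the photobleaching time,
  I₀ the steady-state copy number, τ the exchange time.  Fits are performed
  on summed/averaged recovery curves (the standard analysis) and per focus.
  The synthetic FRAP scenario samples 0–600 s at 2 s — roughly twice the
  slowest generating time constant (τ_b = 300 s) — because a shorter window
  leaves τ_b unidentifiable at the scenario's noise level (mean error above
  10% for any fitting strategy at a 240-s window).
* **Binding events**: threshold = 0.5 × (λ × single-fluorophore intensity),
  i.e. half a fully-labelled molecule; an event is a maximal run of
  ≥ `min_duration` frames above threshold (default 1 frame; hysteresis with
  a separate exit threshold is available but off).  Frequency is events per
  minute of trajectory duration; the bound fraction is the fraction of
  frames above threshold.  Channel-specific calibrations are mandatory
  inputs, since λ differs between dye preparations.
* **Chase comparison**: the observed signal-loss lifetime of a chased,
  stable binder should be statistically indistinguishable from the
  bleach-only control; exchange shortens it.  The test is a two-sided z-test
  on the bootstrap-SE'd ensemble lifetimes.  Group sizes matter: a large
  control group (hundreds of molecules) with a small chase group
  concentrates the comparison's variance where the bootstrap measures it.

## Determinism

All randomness flows from integer seeds through `numpy.random.default_rng`
seed sequences (`[seed, emitter_id]` per emitter), so identical configuration
and seed give bit-identical movies, trajectories and reports.  Pipeline run
reports embed the tool version, a SHA-256 hash of the canonical configuration
and the seed; only the timestamp differs between repeated runs.

## Known limitations

- No drift or registration correction; two-channel colocalisation assumes
  registered frames.
- Overlapping-PSF emitters (< ~2 px apart) are merged by detection.
- The change-point engine assumes homoscedastic Gaussian noise; EMCCD
  gain-dependent variance is not modelled in the likelihood.
- Dwell-time statistics assume single-exponential kinetics throughout; no
  multi-exponential model selection is provided.
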