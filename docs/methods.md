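# Methods

This document describes the algorithms and conventions implemented by
`gazecells`, including the known biases of the detection pipeline as
measured against the generator's ground truth.

## Units and conventions

* **Time** — seconds from session start at all interfaces; behavioral
  sampling at 300 Hz.
* **Position** — millimetres, right-handed world frame with the arena floor
  at z = 0 and z pointing up; arena sites given as (x, y) floor
  coordinates.
* **Angles** — degrees at all public interfaces; radians only inside
  geometry internals and for interneuron response phases (which are
  genuinely circular quantities).
* **Orientation** — unit quaternions in (w, x, y, z) order; head frame has
  x forward (beak), y left, z up.
* **CSV dialect** — UTF-8, comma-separated, `.` decimal point, header row
  mandatory; every file written by the package begins with a provenance
  comment line `# gazecells <version> config_hash=<12-hex> seed=<int>`.
* **Eyes and laterality** — eye index 0 = left, 1 = right; "contralateral"
  is defined relative to the recorded hemisphere
  (`contralateral_eye("left") == 1`).

## Synthetic behavior

A session alternates visual-search fixations, head saccades, dashes
(translations between sites) and feeding bouts, driven by a lit-target
detection task. Saccade angular-velocity profiles are raised-cosine
(Hann) pulses, `v(t) = (A/D)(1 − cos 2πt/D)`, so a saccade of amplitude
`A` and duration `D` has peak velocity `2A/D` (a main-sequence
relationship by construction). Durations are drawn from a normal
distribution (mean 76 ms, sd 21 ms) truncated symmetrically to
[30, 122] ms so the realized mean stays exactly at the configured mean.
Inter-saccade intervals during search are reciprocals of a clipped-gamma
instantaneous rate (mean 3.8 Hz, sd 1.4 Hz). The generator records ground
truth for every sample (state) and every event (saccade endpoints, peak
times, amplitudes, gaze targets), which the tests use as oracles.

## Segmentation

Kinematic features (linear/angular speed, site proximity) are low-pass
filtered (4th-order zero-phase Butterworth, 50 Hz). A Gaussian-observation
HMM with one state per (behavioral kind, site) pair and dwell-calibrated
self-transitions is decoded with Viterbi; observation means are refined by
Viterbi training on a subsample. Saccade endpoints are then refined with
the 400 °/s angular-velocity criterion with sub-sample crossing
interpolation.

### Duration estimation and its bias

A velocity-threshold crossing span systematically underestimates pulse
duration (the pulse spends its tails below threshold), and the low-pass
filter smears the pulse. `invert_pulse_duration` therefore inverts a
tabulated forward model: unit-peak raised-cosine pulses of known duration
are passed through the identical measurement pipeline (frame differencing,
midpoint centering, filtering) and their crossing spans recorded; the
observed (span, peak speed) pair is mapped back to duration. On clean
pulses the inversion is exact to < 1 ms; on full sessions the residual
per-saccade bias is about +0.5 ms (neighbouring-saccade overlap and
measurement noise widen suprathreshold runs slightly).

The angular-*acceleration* criterion is deliberately **not** used for
endpoint refinement: after filtering, fixation jitter exceeds the
5000 °/s² criterion on ~12 % of fixation samples, so acceleration
crossings would randomly extend saccade endpoints.

### Known detector biases (measured against ground truth)

* Detected mean saccade duration: +0.2–0.5 ms versus ground truth
  (≈ 0.5 % relative).
* Detected search-saccade rate: the 400 °/s threshold misses the slowest
  ~3 % of generated saccades; each miss merges two inter-saccade intervals
  into one longer one, depressing mean(1/interval) by ≈ 0.05–0.1 Hz below
  the generative 3.8 Hz. The detected rate matches an ideal
  velocity-thresholded oracle to ~0.02 Hz, so this bias is intrinsic to
  the detection criterion, not to its implementation.

### Cleanup rules

Three merge rules repair characteristic HMM confusions, applied once, in
order: (1) saccade directly before a feed → feed; (2) saccade directly
after a dash → dash; (3) feed directly after a dash → dash. They are not
iterated to a fixed point: iterating would also swallow genuine saccades
that follow a feeding bout. A consequence is that a saccade directly after
a dash can legitimately remain when rule 3 merges an intervening feed into
the dash after rule 2 has already run.

## Spiking model

Excitatory cells combine a spatial place field with biphasic saccade-locked
gaze kernels: an early (predictive) Gaussian at +17 ms and a late (visual)
Gaussian at +187 ms after peak saccade velocity, each scaled by the angular
closeness `exp(−α²/2τ²)` (τ = 45°) of the relevant fixation's gaze to the
cell's preferred site, and split between eyes by a contralateral weight.
Interneurons carry a saccade-locked windowed sinusoid whose phase at
+187 ms distinguishes peak from trough subtypes. Spike trains are sampled
by thinning a piecewise-constant 300 Hz rate; kernels are evaluated at bin
midpoints so realized spike mass centers on the kernel (evaluating at bin
left edges shifts all responses +1.67 ms).

## Analyses

* **Tuning** — information rate `I = Σ p (λ/λ̄) log₂(λ/λ̄)` over discrete
  states or map bins; significance from circular time-shift shuffles
  (observed > 99th percentile of 200 shuffles). Maps are occupancy-
  normalized 40×40 grids smoothed with an edge-renormalized 2-D Hamming
  window.
* **Gaze GLM** — per saccade, spike counts in [−0.1, +0.3] s around peak
  velocity regressed on eight Gaussian closeness bases (four contralateral
  and four ipsilateral sites, τ = 45°) with an L1 penalty (λ = 0.005,
  FISTA, intercept unpenalized). Laterality is the normalized difference
  `(c − i)/(c + i)` of the coefficients at the preferred site. With λ = 0
  the fit matches an unpenalized Poisson regression oracle.
* **Temporal** — PSTHs on 3.33-ms bins smoothed with a truncated
  renormalized Gaussian (σ = 30 ms); early/late rates are means in ±50 ms
  windows around +17 and +187 ms. Latency recovery uses *isolated*
  saccades (no neighbour within 0.45 s): at a ~3.8 Hz saccade rate the
  neighbours' kernels overlap the analysis window and drag the apparent
  early peak several ms early.
* **Cell types** — four waveform/rate features, two-component Gaussian
  mixture on standardized features (lower-rate component = excitatory;
  > 3 Mahalanobis units from both → unclassified; < 500 spikes →
  excluded); interneuron subtypes from the Hilbert phase of the
  saccade-aligned PSTH at +187 ms, clustered with circular k-means (k = 2).

## Determinism

All randomness flows through `numpy.random.Generator` objects seeded from
explicit integers; independent streams are derived with
`numpy.random.SeedSequence([seed, stream])`. Rerunning any command with the
same configuration and seed reproduces outputs bit-identically.
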