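# Methods

This note documents the models, conventions and numerical choices behind
`mtvalidate`: a pipeline that quantifies how well a matrix of piezoresistive
skin-strain tapes ("Motion Tape") tracks low back kinematics measured by a
marker-based optical motion capture system.

## Measurement model

### Sensor physics

The tape is a kinesiology tape coated with a graphene-nanosheet /
ethyl-cellulose piezoresistive film. Its resistance follows the gauge
relation

    ΔR / R₀ = K · ε

where `ε` is skin strain (tension positive, compression negative), `R₀` the
zero-strain baseline resistance and `K` the gauge factor. The analysis uses
the dimensionless strain proxy `ε̂ = (R − R₀)/R₀` with `K` absorbed: the
per-trial normalization (below) removes any constant scale, so the gauge
factor only matters when absolute strain is wanted (`compute_strain`
optionally divides by it).

The synthetic sensor model adds, in order:

1. **saturation** — the effective strain is clipped at
   `±saturation_strain`, emulating the film's limited range (visible as the
   flattened strain curves at deep flexion/extension);
2. **rebound** — after each compression-release event (strain crossing back
   up through `−rebound_trigger_strain`), an additive transient
   `rebound_amplitude · exp(−Δt / rebound_tau_s)` models the delayed
   mechanical relaxation of the conductive ink matrix, which momentarily
   *raises* resistance just when the kinematic signal is returning to
   neutral;
3. **fatigue** — the baseline grows by `fatigue_drift_per_trial · j` for
   trial index `j`, emulating progressive baseline rise over a session;
4. **noise and spikes** — white Gaussian resistance noise (`noise_sd`, Ω)
   plus rare positive outliers of `spike_magnitude_mad` robust-scale units
   (contact-loss transients spike resistance high; a negative-going model
   could drive simulated resistance below zero, which the simulator treats
   as an error).

Resistance is quantized to integer counts of **0.1 Ω** and hex-encoded in
the raw-log dialect (3 comment header lines carrying sensor id, trial id
and start timestamp; then `timestamp_iso8601,hex_resistance` rows).

Default physics (`SensorPhysics()`): R₀ = 1 kΩ, K = 25, noise 1 Ω RMS,
spike probability 0.005/sample at 10 robust SDs, saturation at 2.5 %
strain, fatigue 0.2 %/trial, rebound amplitude 0.4 % strain with τ = 1 s.
`SensorPhysics.ideal()` disables every artifact and is used wherever a test
needs the exact forward model.

### Spine model and marker set

Three rigid segments are tracked: **upper lumbar** (left/right markers
lateral to L1 + L3 spinous), **lower lumbar** (lateral-to-L4 pair + L5
spinous) and **pelvis** (PSIS, ASIS, posterior-pelvis, iliac-crest pairs).
Each frame: origin at the midpoint of the mediolateral pair (pelvis: PSIS
midpoint); ML axis from the left to the right marker; SI axis the component
of the origin-to-midline-reference vector orthogonal to ML (pelvis: toward
the iliac-crest midpoint); PA = ML × SI. With X = subject-right, Y = up,
this puts Z posterior.

Relative orientations `R_lowᵀ R_up` (upper lumbar angle) and
`R_pelᵀ R_low` (lower lumbar angle) are decomposed as **Euler XYZ**
(`R = Rx · Ry · Rz`, θy on the (−90°, 90°) branch, gimbal proximity flagged
at |θy| > 89°). Component roles: **x** flexion/extension (about ML), **y**
axial rotation (about SI), **z** lateral bend (about PA).

Sign conventions are a fixed, documented choice (any consistent convention
preserves correlation magnitudes): extension, right lateral bend and left
rotation are positive; forward flexion, left lateral bend and right
rotation are negative and belong to the **flip set** whose normalized
kinematic trace is negated so that the primary movement direction always
reads positive. Each movement's scalar reference angle is the Euler
component of its primary plane.

### Synthetic movements and geometry

Each protocol entry produces one raised-cosine excursion per repetition
(`A/2 · (1 − cos 2πt/T)`, peak = amplitude fraction × end range), with 1 s
of rest before, between and after repetitions, 4 s per repetition. The
profile is C¹, starts and ends at 0°, and its peaks are an analytic
protocol property (deliberately not jittered, so peak heights are invariant
across seeds). Default protocol: lateral bending (standing) and seated
rotation 3 repetitions to end range per side; extension 3 × ~50 % of end
range; flexion 2 × 50 % + 1 × 100 %. End ranges are nominal healthy-adult
values (flexion 50°, extension 25°, lateral bend 25°, rotation 35°) since
measured end ranges are not available.

The marker forward model keeps the pelvis fixed and rotates the lower
lumbar segment against the pelvis and the upper against the lower by
configurable shares of the reference angle (default 50/50), about the
movement's signed axis, pivoting at the L5 and L3 spinous processes. Marker
motion is exactly rigid; nominal geometry uses 40 mm vertebral spacing,
lateral markers 40 mm off midline, and is arranged so every segment frame
is the identity at neutral — making the generator the exact inverse of the
kinematics module on noiseless data. `marker_noise_mm` is the RMS
*displacement magnitude* of isotropic Gaussian jitter (per-coordinate
σ = value/√3), matching how motion capture residuals are usually reported.

Motion capture runs at 179 Hz; the sensor stream at 50 Hz (the acquisition
rate is a package default — plausible for the Bluetooth link and chosen to
exercise the resampling path) and starts 0.5 s after the mocap clock by
default so alignment is non-trivial.

## Processing pipeline

1. **Decode** — hex counts → Ω; time vector linear from the header start
   timestamp to the last sample.
2. **Hampel filter** — sliding window (half-width 5 samples), sample
   replaced by the window median when it deviates more than
   `3 × 1.4826 × MAD`; truncated windows at the edges; applied per trial.
3. **Stream QC** — per-stream statistic = trial-mean resistance, grouped by
   (movement, sensor) across participants. A stream is flagged when it
   deviates more than `threshold_sd` (default 10) population SDs from the
   **leave-one-out** mean of its group. Leave-one-out matters: with the
   candidate included, the largest attainable deviation is √(n−1) pooled
   SDs (3 for n = 10), so a 10 SD rule could never fire; excluding the
   candidate both lets gross failures be caught and keeps a failure from
   dragging healthy streams over the threshold. Groups with fewer than 3
   streams are never flagged (a one-sample SD is meaningless) and produce a
   warning.
4. **Strain** — `ε̂ = (R − R₀)/R₀`, with `R₀` the mean of the trial's first
   0.5 s (robust to startup noise; `first_sample` mode available).
5. **Kinematics** — marker TSV → gap interpolation (per-coordinate cubic,
   gaps ≤ 10 frames, boundary gaps refused) → segment frames → Euler
   angles. Marker trajectories are low-pass filtered first (zero-phase
   4th-order Butterworth, 6 Hz cutoff, `None` disables). The filter is on
   by default because the L4–L5 lever arm is only ~40 mm, so unfiltered
   sub-millimeter marker noise alone costs ~0.5°/frame in the lower-segment
   orientation, while voluntary trunk movement lives below ~0.5 Hz; at
   6 Hz the residual signal distortion is ~3 × 10⁻³ ° on a full 50°
   excursion. Exactness checks of the geometric inversion therefore run
   with the filter disabled.
6. **Align / resample** — both streams on a common absolute clock via their
   start timestamps, cropped to the overlap, strain linearly interpolated
   onto the kinematic time base (no kinematic bandwidth discarded;
   interpolating beyond one sensor sample period is refused).
7. **Normalize** — strain: minus the mean of the first 0.25 s (movement
   starts at zero strain), divided by max |ε̂| so +1 is peak tension and −1
   peak compression; angle: divided by max |θ|, negated for flip-set
   movements. `x / max|x|` is the only normalization that guarantees both
   endpoints ±1 are reachable while keeping the downstream coefficient
   invariant to positive rescaling. Zero-variance series are flagged
   degenerate and excluded. Normalization is idempotent (an
   already-normalized pair is returned unchanged).
8. **Validity** — zero-phase-shift cross-correlation coefficient
   `r₀ = Σxy / √(Σx² Σy²)` (coefficient normalization, no demeaning —
   matching MATLAB-style `xcorr(..., 'coeff')` at lag 0 on zero-shifted
   input; a demeaned Pearson variant sits behind `demean=True`; the full
   lag profile is available but only lag 0 enters the validity table).
   Sensors 1–4 are compared against the upper lumbar angle, sensors 5–6
   against the lower lumbar angle. `r₀ > 0` is interpreted as tape tension
   with increasing reference angle, `r₀ < 0` as compression. Per
   (movement, sensor) cell, the median and range across participants are
   reported; missing values (QC-flagged or degenerate) are counted, never
   imputed. Each trial is one series with all repetitions concatenated.

## Default gain map (tension/compression pattern)

The simulator's gain map encodes the qualitative pattern the sensor matrix
exhibits (sensors 1/2 upper row, 3/4 middle, 5/6 lower; odd = left):
flexion stretches all tapes; extension compresses all; lateral bending
stretches the contralateral column and compresses the ipsilateral one;
rotation stretches both upper tapes and the ipsilateral middle/lower tapes
with mild contralateral compression. Gain magnitudes (1–3 % strain at full
end range) are plausible for skin strain over the lumbar spine.

## What the generator does and does not emulate

It reproduces the study's structure (10 participants × 6 movements × 6
sensors = 360 streams, 179 Hz kinematics, timestamp offset, Table-style
repetition protocol) and the tape's artifact phenomenology (saturation,
fatigue, rebound, spikes). It does **not** model soft-tissue artifact,
participant-specific movement strategies (which in the real data flip the
sign of some cells), electromyography, anthropometric variation, or the
observed 13.9 % spontaneous stream-failure rate — QC is exercised with
planted failures instead. Passing tests therefore demonstrate the
*pipeline* is correct and well-behaved under controlled physics, not that
the physical sensor achieves any particular validity on real skin.

## Numerical choices and edge cases

- Degenerate guards: zero-energy series give a missing `r₀`; identically
  zero normalization inputs flag the pair degenerate; SD = 0 QC groups flag
  only genuinely deviating streams.
- Euler decomposition validates orthonormality and determinant to 1e-6 and
  clamps `sin θy` into [−1, 1]; gimbal proximity (|θy| > 89°) is flagged,
  not fatal.
- A left/right marker swap is caught by checking the ML axis against its
  expected lab direction (the swap flips the frame 180° about SI).
- Hampel ties: a zero-MAD window flags any sample deviating from the
  window median (threshold 0), which is what removes isolated spikes on
  quantized plateaus.
- Problem sizes in the test-suite and acceptance script (3–10 synthetic
  participants, 1000-sample oracle series, 10⁴ rotations) were chosen as
  the smallest cohorts at which medians across participants and the
  360-stream accounting of the study design are meaningful.

## Known limitations

- The axis-role and sign conventions are one consistent choice among
  several; comparing against other software requires mapping conventions
  (correlation magnitudes are unaffected, signs may flip).
- The leave-one-out QC rule assumes at most a minority of streams per
  group fail grossly; two identical gross failures in the same small group
  could mask each other. Conversely, in very small cohorts the
  leave-one-out SD is estimated from few streams and the rule over-flags
  noisy-but-healthy streams (≈12 % at 3 participants with default physics,
  decaying to 0 % at the study's 10); the rule is meant for cohorts of
  roughly 5 participants or more.
- Linear interpolation of the 50 Hz strain stream bounds the resampling
  error at `h²ω²/8` of amplitude (≈2 × 10⁻³ for 1 Hz content), negligible
  against sensor noise but present.
- The rebound model is the simplest transient reproducing the described
  artifact (additive exponential, threshold-triggered); the true
  viscoelastic recovery of the ink matrix is likely amplitude- and
  rate-dependent.
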