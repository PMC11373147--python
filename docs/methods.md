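# Methods

This note documents the models, conventions and deliberate design choices
behind `flightload`, in the order data flows through the package.

## Synthetic session generator

The generator emulates the three recording streams of a head-mounted VR
flight-simulator workload study — eye tracker at 120 Hz, 32-channel EEG at
128 Hz, stick deflections at 120 Hz — for a configurable participants ×
conditions design (default 12 × 5, 60 s sessions).  Streams run on
independent clocks sharing t = 0; nothing is cross-resampled.  Each
condition carries a latent difficulty scalar d ∈ [0, 1] (defaults 0.1,
0.3, 0.5, 0.7, 0.9), and every planted effect is linear in d.  The first
5 s of every stream is a quiet resting baseline, matching the
resting-start protocol the pupil normalization assumes.

Planted difficulty links (defaults in `EffectProfile`; directions are
enforced by constructor validation):

| channel | mechanism | default |
|---|---|---|
| pupil | slow (0.05–0.35 Hz) unit-RMS fluctuation scaled by `pd_drift_gain·d` mm plus a level shift, on a ~3.5 mm baseline, with 1.2 Hz hippus and white measurement noise on top | 0.15 mm |
| fixations | plateau duration ~ N(base + slope·d, (0.15·base)²), truncated at 120 ms | 0.60 s, −0.35 s |
| gaze dispersion | fraction of fixation targets drawn from a tight cluster (σ ≈ 0.46°) around the tracked target vs. uniform scanning over ±12°: base − `gaze_dispersion_slope`·d | 0.25, slope −0.55 |
| EEG | per-band filtered white noise (4th-order Butterworth, zero-phase) with electrode-group amplitude scaling: frontal theta ×(1 + 1.0·d), parietal alpha ×(1 − 0.4·d), frontal beta ×(1 − 0.3·d); base band amplitudes 4/5/3/1.5 µV RMS (θ/α/β/γ) over a 1 µV broadband floor | — |
| stick | deterministic burst count (0.10 + 0.08·d per s), sin² pulses of 0.3–0.6 s, amplitude 6·(1 + 1.5·d) deg (±15 % jitter, clipped at 0.95·δ_max = 19°) over 0.02° hold noise | — |

Gaze plateaus get iid angular jitter of ~0.02° per sample (≈4 deg/s
sample-to-sample — far below the 30 deg/s I-VT threshold); saccades sweep
between centres in 1–8 inter-sample intervals sized so every interval
exceeds the threshold, and consecutive centres are kept ≥ 1.2° apart.
These two margins make the planted fixation count recoverable by the
detector to ±1.

Participant heterogeneity is a log-normal multiplier per effect channel,
`exp(participant_sd · z_p)` with z drawn once per participant (stable
across conditions, keyed by seed and participant index only).  The default
`participant_sd = 0.2` attenuates pooled Pearson correlations relative to
the within-participant (rmcorr) ones, which is the phenomenon the
repeated-measures analysis exists to handle.

Blinks arrive at Poisson times (0.15/s after the baseline window) with
100–400 ms invalid gaps during which the pupil reads 0.  Gaps are planted
*inside* fixation plateaus, a few samples clear of the edges.  Real blinks
often co-occur with saccades; placing them inside plateaus is a deliberate
simplification that keeps the planted fixation structure well defined
while still forcing the interpolation and invalid-skipping code paths to
run.  Consequently, passing tests show the pipeline handles gaps
correctly, not that it would survive blink-saccade interactions in real
recordings.

What the generator does not emulate: oculomotor main-sequence dynamics,
pupil foreshortening with gaze angle, EEG artifacts (EMG, ocular), 1/f
spectral background, tracker-specific noise spectra, or any correlation
between streams beyond the shared difficulty and participant factors.
Recovery results on synthetic data therefore validate the computational
chain and its statistical conventions, not field performance.

## Ocular metrics

**Pupil cleaning.**  Invalid frames are replaced by a natural cubic spline
through the valid samples, evaluated on the original grid; gaps touching
either series edge take the nearest valid value, because cubic
extrapolation of pupil data is unstable.  Fewer than 4 valid samples is a
hard error naming the offending session.

**Normalization.**  The baseline is the *maximum* cleaned diameter over
the first 5 s, per eye and per session; %PD is percent change against it.
Left and right eyes are processed and reported separately throughout.

**Wavelet analysis.**  `haar_mra` produces additive multiresolution
components (each reconstructed on the original grid) via PyWavelets.
`StdDevPD` is the N−1 standard deviation of the level-7 approximation
component — the 0–0.469 Hz band at 120 Hz.  Boundary handling: exact
power-of-two lengths use periodization (the transform is then orthonormal
and coefficient energy equals signal energy); other lengths use symmetric
extension, which avoids edge ringing in a 7-level decomposition of
arbitrary-length sessions at the cost of exact energy bookkeeping.  A
flag computes the statistic on the downsampled approximation coefficients
instead of the reconstructed component; the component variant is the
default because the procedure is a multiresolution analysis and the
statistic should live on the original time support.

**I-VT.**  Angular velocity is the angle between consecutive gaze
directions over the time increment, computed between consecutive *valid*
samples only — a blink inside a steady fixation therefore does not split
the event, while a blink spanning a genuine large saccade still yields a
supra-threshold velocity across the gap.  Runs of sub-threshold intervals
merge into single fixation events; no minimum-duration filter is applied.
Zero fixations gives rate 0 and a NaN mean duration (excluded from
correlations).

**NNI.**  Gaze directions project to the unit-forward plane (x/z, y/z).
The default point pattern is fixation centroids (following the
spatial-statistics literature the index comes from); raw valid samples are
selectable.  The reference area defaults to the bounding box of the
projected points and can be passed explicitly.  The expected mean
nearest-neighbour distance under uniformity is the Clark–Evans
`0.5 √(area/n)`; no boundary correction is applied, which biases the index
a few percent high for uniform patterns (visible in the 2000-point test
tolerance of ±0.05).

## EEG metrics

Band powers use 256-sample Hann windows hopped by 16 samples; each window
is Fourier transformed and converted to a one-sided PSD with Hann power
compensation (units µV²/Hz), then averaged over each band's bins.  Bands
are half-open `[low, high)` so adjacent bands never share a bin, and the
deliberate 12–16 Hz gap between alpha and beta is honoured, not filled.
A sampling rate other than 128 Hz is rejected rather than silently
re-binned.

Montage powers are aggregated by the arithmetic mean across electrodes
before the ratio (this makes the indices invariant to montage size; sum
aggregation would not be).  The session index is the mean of per-window
indices rather than the ratio of session-mean powers — it tracks the
per-window definition and is robust to nonstationarity; zero-denominator
windows are dropped with a logged count.  Input is assumed already
band-limited by the headset's onboard 0.2–45 Hz chain; an optional
zero-phase Butterworth band-pass is provided for other sources.

## Inceptor metrics

The activity indicator for an increment is: deflection change below the
noise threshold (0.5 % of the total displacement range 2·δ_max, per
increment) *and* deflection below δ_max ⇒ inactive; otherwise active.
Duty cycle defaults to the time-fraction reading — each active increment
contributes its own Δt, divided by the total measured time — so the result
is a true percentage of time bounded by 100 even on irregular grids; the
literal indicator-count variant (identical on uniform grids) is selectable
via `method="count"`.  Aggressiveness is the RMS of per-increment
deflection rates.  PIW is the plain product of the two.

## Engagement simulator

Point-mass aircraft, forward-Euler at a default 10 ms step, constant
speeds; the pursuer's velocity direction rotates under the commanded
acceleration (applied normal to velocity), the magnitude clamped at
`max_accel` (default 100 m/s², ≈10 g — physically motivated and it
stabilizes the explicit integrator near close approach, where the LOS
rate diverges).  λ̇ in the APN law is by default the rotation rate of the
LOS unit vector between steps (the quantity proportional-navigation
theory calls the LOS rate); a range-rate reading is flag-selectable since
the symbol is sometimes used for the closing distance.  V_c = V_p − V_e
on speeds; negative (opening) values flow through the law unchanged.

The radar returns the evader state recorded at t − latency when the
target was within 1.2 km at that instant, else nothing, in which case the
pursuer flies straight.  The deviation and aspect angles use the
two-argument arctangent of lateral over forward separation (the
single-argument form is quadrant-ambiguous and undefined for equal
forward positions), wrapped to (−180°, 180°]; the reward evaluator
compares angle magnitudes against its thresholds with strict
inequalities.  d_min/d_max/μ_max/η_max and the reward weights have no
claimed defaults — they are scenario parameters.

The unaware evader flies constant speed with a sinusoidal altitude
profile (amplitude 50 m, period 20 s, configurable; the reference profile
specifies only the shape).  The fleeing evader heads directly away from
the pursuer in the lateral plane at `max(V_p + margin, gain·|λ̇|)` — the
proportionality constant is unspecified in the source material and is
exposed as `evader_los_gain`.

Guidance property checks use 20–25 s runs at a 20 ms step: APN-vs-unguided
on geometries with the target at ±60° bearing within radar coverage and a
±30° initial heading error; latency pairing (400 vs 800 ms) on closing
tail-chases, where the stale-observation offset dominates the closest
approach and the degradation is monotone.  In non-closing crossing
geometries the closest approach is set by geometry, not guidance, and the
latency comparison is uninformative — that scenario family is therefore
not used for the pairing property.

## Statistics

Pearson r via the product-moment formula with pairwise NaN removal,
df = n − 2, two-sided p; zero variance yields a NaN-flagged result.
rmcorr is the ANCOVA estimator: `y ~ C(subject) + x` by OLS, r_rm =
sign(slope)·√(SS_x / (SS_x + SS_err)), df = N_obs − k_subjects − 1, p from
the F-test of the slope.  On the balanced designs used here Type-III and
Type-I sums of squares for the slope coincide; Type III is requested
explicitly.  Subjects with fewer than two complete observations are
dropped with a warning.  No outlier exclusion is automatic anywhere; no
multiple-testing correction is applied (p-values are descriptive).

## Problem sizes and tolerances

Default synthetic sessions are 60 s (7 200 gaze samples, 7 680 EEG
samples per channel), giving ~100–180 fixations and ~460 EEG windows per
session; the full 12 × 5 study runs in well under a minute.  Oracle
equivalences are asserted at 1e-8–1e-12; Monte-Carlo limits use
pre-stated tolerances (StdDevPD sinusoid ±5 %, aggressiveness ±2 %,
uniform-NNI ±0.05).  Convergence of the engagement integrator is checked
by step halving (< 1 % change in closest approach).

## Known limitations

* The synthetic study validates sign patterns and conventions, not
  real-data effect sizes; published correlation magnitudes from any real
  cohort are not reproducible from generated data and are not targeted.
* NNI lacks a boundary correction and depends on the area convention;
  both are configurable but defaults matter when comparing across
  sessions of very different dispersion.
* The engagement model is kinematic only: no aerodynamic forces, no
  attitude dynamics, no missile flyout; the reward function is an
  evaluator, not a trained policy.
* EEG indices assume the montage electrodes exist in the input; there is
  no artifact rejection or re-referencing.
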