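# Methods

This note documents the models, parameter choices and numerical
decisions behind `lapkit`, in the order data flows through the package.

## Synthetic sessions

The generator emulates a head-fixed licking session as seen by the
acquisition chain, with every planted parameter recorded in the
bundle's `truth` record.

**Licking.** Bouts are lists of (start time, n cycles); each cycle is a
raised-cosine jaw deflection of one lapping period (default rate 7 Hz,
the species-typical lapping rhythm). Amplitude is 40 px, i.e. ~2 mm at
the default 100 px / 5 mm calibration — a realistic jaw excursion. The
tongue is confidently tracked (likelihood 0.95) only during the middle
40% of each cycle and otherwise reports likelihood 0.02 with an
aberrant position, reproducing how markerless trackers behave on an
occluded body part. One lick-port contact is planted at maximal
protrusion of every cycle. When no bout schedule is given, bouts are
drawn at random (4–12 licks, a few seconds apart), emulating
self-paced licking. Tracker jitter (default 0.5 px Gaussian) is added
to jaw coordinates.

**Photometry.** The 465 nm channel is a resting baseline (100 a.u.)
plus the calcium response: one kernel copy per contact with the sample
of maximal response placed at contact + delay (default 1.2 s). The
default kernel is a symmetric Gaussian (sd 0.4 s, amplitude 2 a.u.),
chosen so the planted contact-to-peak delay equals the expected
correlation-peak lag exactly; an asymmetric double-exponential
(τ_rise 0.1 s, τ_decay 0.8 s) is provided, but its expected
correlation-peak lag must be measured, not assumed, because asymmetry
shifts the mass of the curve. These kernels are stand-ins for indicator
dynamics, not fitted kinetics, and the noise/artifact magnitudes below
are plumbing placeholders, not measured values.

Both channels are multiplied by a shared exponential bleach (default
τ 600 s; ∞ disables) and by (1 + motion_amp · gain · m(t)) with a
shared unit-variance smooth motion trace m(t) (white noise, Gaussian
smoothed with σ 0.3 s), then receive independent Gaussian noise
(default sd 0.02 a.u. per raw sample). Raw photometry is emitted at
1200 Hz rather than a hardware-scale 12 kHz: the analysis only ever
sees the 120 Hz grid, and the raw:video ratio is preserved.

**Motion gain.** The 405 nm motion gain defaults to 1.0 (common-mode).
This is deliberate: when bleaching and motion are *both* present with a
between-channel gain mismatch g ≠ 1, the 465 nm signal is no longer an
affine function of the 405 nm signal and a single-coefficient
regression provably leaves the fraction |1 − g| of the motion in ΔF/F —
no parameter tuning can recover it. With common-mode motion the two
channels are exactly proportional up to noise, and the OLS stage
cancels bleach and motion together. The mismatch is exposed as
`motion_gain_405` for robustness studies; sessions generated with
g ≠ 1 are a known hard case for single-regressor isosbestic correction.

**Randomness.** One seed sequence per session is split into named
substreams (bouts, motion, noise465, noise405, jitter), so toggling one
artifact never perturbs the others, and identical (config, seed) give
bit-identical sessions and serialized directories.

**Evoked-response presets.** Two phenotypes are modeled for
optogenetics: a rhythmic-capable premotor preset ("irt") — short pulses
evoke one opening that lasts the pulse; pulses beyond ~300 ms evoke an
initial opening followed by licking-like cycles at the lapping rate
(cycles are initiated while the light is on, so the last one may
complete just after light-off); trains entrain one opening per pulse —
and a hold-open preset ("peri5") that keeps the jaw open for the whole
pulse with a small non-rhythmic quiver.

**What passing tests do not show.** The generator's lick cycles are
perfectly periodic within a bout, its artifacts are smooth and
stationary, pose errors are Gaussian, and the calcium kernel is
time-invariant. Real sessions have variable cycle periods, abrupt
motion transients, heavy-tailed tracker failures and state-dependent
indicator dynamics; recovery on synthetic sessions validates the
implementation, not the biology.

## Photometry

Pipeline order is fixed and recorded in the ΔF/F provenance:
resample → lowpass(both channels) → fit → ΔF/F.

* **Resampling** is linear interpolation onto the 120 Hz grid
  (length = ⌊duration × rate⌋ + 1). The subsequent 20 Hz low-pass
  bounds aliasing at this scale; no polyphase decimation is needed.
* **Filtering** is a Butterworth low-pass, order 2, cutoff 20 Hz,
  applied forward–backward (`sosfiltfilt`, reflect padding of ~3
  settling lengths), giving zero phase and an effective squared
  magnitude response. Note that the *digital* (bilinear-transform)
  response 1/(1 + (tan(πf/fs)/tan(πfc/fs))^4) is the correct analytic
  reference: near Nyquist it attenuates far more than the analog
  1/(1 + (f/fc)^4) approximation (at 50 Hz on a 120 Hz grid: 5.7e-4
  versus 2.5e-2). The first/last 0.5 s are flagged edge-affected.
* **Baseline fit.** "Fitting the 405 nm signal onto the 465 nm signal"
  is read as OLS regression F0 = a + b·C405 — the standard isosbestic
  correction in which F0 is a fitted version of the control channel.
  A slope-only `mean_ratio` variant (F0 = C405 · mean F/mean C) is
  selectable. The `auto` mode used by the pipeline helpers falls back
  to `mean_ratio` when the 405 nm channel carries essentially no
  variation (relative peak-to-peak ≤ 1e-8), where a regression would
  amplify numerical ripple; an exactly constant control is a hard error
  under explicit OLS.
* **ΔF/F** requires strictly positive F0 at every sample and reports
  the first offending index otherwise.

## Kinematics

* Calibration divides by the pixel length of the 5 mm scale bar;
  Savitzky–Golay defaults are window 11 frames (~92 ms), order 3 —
  short enough to preserve 7 Hz cycles, long enough to suppress
  frame-to-frame jitter. Smoothing applies to coordinates, never to
  likelihood.
* Quiescent baselines average all still segments of 1–3 s
  (|Δy| < 0.05 mm/frame); pre-stimulus baselines average the 50–100 ms
  window before each stimulus onset. A trace that is never still raises
  an error advising threshold review rather than silently normalizing.
* Tongue gating replaces frames with likelihood < 0.05 by the resting
  baseline (by default the position just before the first confident
  protrusion); gating is idempotent, and a fully gated trace is flagged
  `tongue_never_detected`, not rejected.
* Lick onsets are peaks of the first difference of the jaw trajectory
  with prominence max(0.3 × max|Δy|, 3 × median|Δy|) and a 50 ms
  refractory. The signal-relative term is the operative one: licks
  dominate the derivative whenever present, while a median-only rule
  calibrates to tracker noise on the lick-free majority of a session
  and over-triggers by an order of magnitude at realistic jitter. The
  median term remains as a noise floor. Onset timestamps sit at the
  midpoint of the difference interval.
* Bouts are maximal runs with inter-lick intervals < 0.5 s (n ≥ 2);
  isolated onsets are reported as unitary licking events. Bout
  frequency defaults to (n − 1)/span — the reciprocal mean inter-lick
  interval, which returns the generative rate on periodic licking —
  with the literal n/span variant selectable (it overestimates a
  periodic rate by n/(n − 1)).

## Lagged correlation and the shuffle null

* Correlation is Pearson, computed on the truncated (non-wrapped)
  overlap for every shift in ±10 s at 120 Hz (2401 lags); per-lag
  overlap lengths are stored, and lags with a constant segment get
  r = 0 with a flag. The implementation vectorizes the cross terms with
  an FFT correlation and the marginal moments with prefix sums; it
  matches a naive per-lag Pearson oracle to 1e-10 and is clipped to
  [−1, 1] against round-off.
* Maxima tie-break: smallest |lag| first, then the negative lag, with a
  float tolerance so a symmetric ± pair resolves to the negative
  member.
* The null rotates the contact regressor circularly by a uniform offset
  in [max_lag, duration − max_lag] — preserving the value multiset and
  autocorrelation exactly — and averages 20 recomputed curves per
  session by default.
* The paired test compares per-animal maxima of the mean real curve and
  the mean null curve (two-tailed paired t-test; degenerate-variance
  differences are an error, as is n < 2).
* **Calibration caveat.** Averaging many rotated-surrogate curves makes
  the null mean curve systematically flatter than the real per-animal
  mean curve, so under the null its maximum is smaller and the paired
  max-comparison rejects far above the nominal rate (measured ~24% at
  α = 0.05 with 20 surrogates). With one surrogate per session the real
  and null summaries are exchangeable under the null and the test is
  calibrated (measured 2.5% over 200 replicates). The test suite checks
  calibration in the exchangeable configuration; the 20-surrogate
  default is appropriate for estimating the null curve's *shape*, and
  its maximum should be read as a conservative floor, not a calibrated
  null quantile.

## Evoked-response classification

Trials span [−0.5 s, stimulus + 1.5 s] around each onset (a pulse train
is one trial spanning the whole train), are baseline-normalized on the
−100..−50 ms window, and are classified on |displacement| within the
stimulus window extended by 100 ms (movements lag the light; a cycle
initiated at light-off completes just after). Movement peaks use
prominence 0.25 × peak displacement and a 50 ms refractory, making the
classification invariant to amplitude scaling. Classes: *rhythmic* — ≥ 3
peaks with cycle-period CV < 0.5, frequency (peaks − 1)/(t_last −
t_first); *sustained* — ≥ 80% of the window beyond half-max with < 3
peaks; else *transient*. The thresholds are package decisions calibrated
on the generator presets; no quantitative criterion is standard in the
literature. Stimulus-train duty cycles are derived as width × rate from
the authoritative pulse width.

## Tracing quantification

Inputs are validated against closed vocabularies (class, hemisphere)
and a user-supplied atlas acronym list (a small hindbrain-centred
default ships with the package). Percentages are computed per animal
and pooled as an unweighted mean ± SEM across animals, so animals with
different labeling totals weigh equally; a pooled-count mode is
selectable. The display cutoff (default 0.3%) only flags regions for
exclusion from bar graphs — totals and tables always retain them.
Seeding efficiency is the mean of per-animal inputs/starter ratios,
which differs from the pooled-count ratio whenever starter counts vary
across animals. SEM is reported as absent (not zero) for a single
animal.

## Problem sizes and determinism in the test suite

The suite validates the full latency-recovery pipeline on 4 synthetic
animals × 4 two-minute sessions; statistical properties use 10–200
replicates of 20–120 s sessions, sizes at which the checked effects are
measured with comfortable margins while the whole suite stays fast. All
stochastic tests run on fixed seeds, and hypothesis-based property
tests are derandomized. The acceptance script derives every session
seed from its `--seed` argument.

## Known limitations

* The isosbestic correction is a single affine map per session; slow
  gain drift between channels or wavelength-dependent motion (see
  `motion_gain_405`) leaves residual artifacts by construction.
* Onset detection analyzes the vertical coordinate only, as in the
  underlying experimental design; 2-D kinematics are out of scope.
* The evoked-response thresholds (3 peaks, CV 0.5, 80% occupancy) are
  heuristics; borderline phenotypes near 300–400 ms pulses can fall on
  either side of the transient/rhythmic boundary.
* The shuffle null preserves the regressor's autocorrelation but not
  any slow nonstationarity of the calcium trace; strongly drifting
  sessions should be detrended upstream or excluded.
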