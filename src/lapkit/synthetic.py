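"""Synthetic lapping-session generator with known ground truth.

Emulates a head-fixed licking session as seen by the acquisition chain:

* **Photometry** — demodulated 465 nm (calcium-dependent) and 405 nm
  (isosbestic) channels at 1200 Hz.  Lick-port contacts are convolved
  with a slow indicator kernel whose peak trails each contact by a
  configurable latency (default 1.2 s); both channels share an
  exponential bleaching factor and a multiplicative low-frequency motion
  artifact (channel-specific gain), plus independent Gaussian noise.
* **Pose** — jaw and tongue (x, y, likelihood) at the 120 Hz video rate.
  Each lick cycle is a raised-cosine jaw deflection at the lapping rate
  (default 7 Hz); the tongue is confidently tracked only while
  protruded, and a lick-port contact is planted at maximal protrusion of
  every cycle.
* **Stimuli** — optional optogenetic pulse trains, with preset evoked
  jaw responses (a rhythmically licking medullary phenotype and a
  sustained jaw-opening phenotype).

Every planted parameter is recorded in the bundle's ``truth`` record so
downstream stages have a recoverable target.  Sessions are reproducible
bit-for-bit from (config, seed): one seed sequence is split into named
substreams (bouts, motion, noise465, noise405, jitter) so that toggling
one artifact never perturbs the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .core import EventSeries, PoseTrack, TimeSeries
from .opto import StimTrain

__all__ = [
    "CalciumKernel",
    "GeneratorConfig",
    "PhotometrySession",
    "SessionBundle",
    "calcium_response",
    "motion_trace",
    "apply_artifacts",
    "generate_pose",
    "generate_session",
    "generate_evoked_track",
    "generate_annotation_table",
]

# --- plumbing constants (arbitrary but documented in the methods note) ---
BASELINE_465 = 100.0  # a.u., resting 465 nm level
BASELINE_405 = 80.0  # a.u., resting 405 nm level
MOTION_SMOOTH_S = 0.3  # Gaussian smoothing of the motion artifact
JAW_BASE_PX = 200.0
JAW_AMP_PX = 40.0  # ≈2 mm at the default 100 px / 5 mm calibration
TONGUE_BASE_PX = 260.0
TONGUE_AMP_PX = 60.0
TONGUE_PROTRUSION_PHASE = (0.3, 0.7)  # cycle-phase window of visibility
LIKELIHOOD_HIGH = 0.95
LIKELIHOOD_LOW = 0.02
KERNEL_TRUNCATION = 1e-4  # kernel support truncated below this × amplitude


@dataclass(frozen=True)
class CalciumKernel:
    """Indicator impulse response used by the forward model.

    ``gaussian`` — symmetric Gaussian of standard deviation ``width_s``;
    its peak coincides with its centre, so the planted contact-to-peak
    latency equals the expected correlation-peak lag exactly.
    ``double_exp`` — (1 − e^{−t/τ_rise}) e^{−t/τ_decay}; asymmetric, so
    the expected correlation-peak lag must be measured, not assumed.

    These are stand-ins for indicator dynamics, not fitted kinetics.
    """

    shape: str = "gaussian"
    width_s: float = 0.4
    tau_rise_s: float = 0.1
    tau_decay_s: float = 0.8
    amplitude: float = 2.0

    def __post_init__(self) -> None:
        if self.shape not in ("gaussian", "double_exp"):
            raise ValueError(f"unknown kernel shape {self.shape!r}")
        if self.amplitude < 0:
            raise ValueError("kernel amplitude must be nonnegative")
        if self.shape == "gaussian" and not self.width_s > 0:
            raise ValueError("gaussian width must be positive")
        if self.shape == "double_exp" and not 0 < self.tau_rise_s < self.tau_decay_s:
            raise ValueError("double_exp needs 0 < tau_rise < tau_decay")

    def sample(self, rate_hz: float) -> tuple[np.ndarray, int]:
        """Sample the kernel at ``rate_hz``.

        Returns (values, peak_index): values are truncated where they fall
        below ``KERNEL_TRUNCATION`` × peak, and peak_index marks the
        sample of maximal response (the centre, for the Gaussian).
        """
        dt = 1.0 / rate_hz
        if self.shape == "gaussian":
            half = int(math.ceil(self.width_s * math.sqrt(-2 * math.log(KERNEL_TRUNCATION)) / dt))
            t = np.arange(-half, half + 1) * dt
            vals = self.amplitude * np.exp(-0.5 * (t / self.width_s) ** 2)
            return vals, half
        # double exponential: support [0, T] with T set by the decay tail
        t_end = -self.tau_decay_s * math.log(KERNEL_TRUNCATION)
        t = np.arange(0.0, t_end, dt)
        raw = (1.0 - np.exp(-t / self.tau_rise_s)) * np.exp(-t / self.tau_decay_s)
        vals = self.amplitude * raw / raw.max()
        return vals, int(np.argmax(vals))


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic session.

    Defaults mirror the acquisition constants of the experimental
    protocol (120 Hz video, ~7 Hz lapping, 1.2 s contact-to-peak
    latency, 5 mm scale bar); photometry is emitted at 1200 Hz — a
    scaled-down raw rate with the raw:video ratio preserved, since the
    analysis only ever sees the 120 Hz grid.  Noise and artifact
    magnitudes are plumbing placeholders, not measured values.
    """

    duration_s: float = 120.0
    raw_rate_hz: float = 1200.0
    video_rate_hz: float = 120.0
    lapping_rate_hz: float = 7.0
    bout_structure: Sequence[tuple[float, int]] | None = None
    contact_to_peak_delay_s: float = 1.2
    kernel: CalciumKernel = field(default_factory=CalciumKernel)
    bleach_tau_s: float = 600.0  # math.inf disables bleaching
    motion_amp: float = 0.05  # relative multiplicative motion amplitude
    #: motion gain on the 405 nm channel relative to 465 nm.  At the default
    #: 1.0 motion is common-mode and a single-regressor isosbestic fit can
    #: cancel it fully even while bleaching; any other value leaves a
    #: provable fraction |1 − gain| of the motion in ΔF/F whenever bleaching
    #: is also present (two shared components, one fitted coefficient).
    motion_gain_405: float = 1.0
    noise_sd: float = 0.02  # a.u., per raw sample and channel
    pose_noise_px: float = 0.5  # tracker jitter on jaw coordinates
    scale_bar_px: float = 100.0  # pixels spanned by the 5 mm scale bar
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise ValueError("duration must be positive")
        for name in ("raw_rate_hz", "video_rate_hz", "lapping_rate_hz"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        ratio = self.raw_rate_hz / self.video_rate_hz
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("video_rate_hz must divide raw_rate_hz")
        if self.noise_sd < 0 or self.motion_amp < 0 or self.pose_noise_px < 0:
            raise ValueError("noise and artifact amplitudes must be nonnegative")
        if not self.scale_bar_px > 0:
            raise ValueError("scale_bar_px must be positive")
        if self.bout_structure is not None:
            period = 1.0 / self.lapping_rate_hz
            for start, n in self.bout_structure:
                if start < 0 or start + n * period > self.duration_s:
                    raise ValueError(
                        f"bout at {start} s with {n} licks extends outside "
                        f"[0, {self.duration_s}] s"
                    )

    def substreams(self) -> dict[str, np.random.Generator]:
        """Named independent random substreams for this session."""
        names = ("bouts", "motion", "noise465", "noise405", "jitter")
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {name: np.random.default_rng(child) for name, child in zip(names, children)}


@dataclass(frozen=True)
class PhotometrySession:
    """Paired 465/405 raw traces plus contact events for one session."""

    f465: TimeSeries
    c405: TimeSeries
    contacts: EventSeries
    session_id: str = ""
    animal_id: str = ""


@dataclass(frozen=True)
class SessionBundle:
    """One complete synthetic session and its planted ground truth."""

    photometry: PhotometrySession
    jaw: PoseTrack
    tongue: PoseTrack
    stim: StimTrain | None
    truth: dict
    config: GeneratorConfig


def calcium_response(
    contacts: EventSeries,
    kernel: CalciumKernel,
    delay_s: float,
    rate_hz: float,
    duration_s: float,
) -> TimeSeries:
    """Superpose one kernel copy per contact, peak at contact + delay.

    The response is linear in the contact train.  For the symmetric
    Gaussian kernel the copy is centred at contact + delay; for the
    asymmetric kernel the sample of maximal response is aligned there.
    """
    if not rate_hz > 0:
        raise ValueError("rate must be positive")
    n = int(math.floor(duration_s * rate_hz)) + 1
    out = np.zeros(n)
    t = contacts.times_s
    if t.size and (t.min() < 0 or t.max() > duration_s):
        raise ValueError("contact outside the session duration")
    kvals, kpeak = kernel.sample(rate_hz)
    for tc in t:
        center = int(round((tc + delay_s) * rate_hz))
        i0 = center - kpeak
        i1 = i0 + kvals.size
        s0, s1 = max(i0, 0), min(i1, n)
        if s1 <= s0:
            continue
        out[s0:s1] += kvals[s0 - i0 : s1 - i0]
    return TimeSeries(out, rate_hz=rate_hz)


def motion_trace(
    config: GeneratorConfig,
    n_samples: int,
    rate_hz: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """The unit-variance smooth motion artifact for this config's seed.

    Reproduces exactly the trace that :func:`apply_artifacts` injects,
    so analyses can be validated against the planted artifact.
    """
    rng = rng if rng is not None else config.substreams()["motion"]
    white = rng.standard_normal(n_samples)
    m = gaussian_filter1d(white, MOTION_SMOOTH_S * rate_hz)
    sd = m.std()
    return m / sd if sd > 0 else m


def apply_artifacts(
    sig465: TimeSeries,
    sig405: TimeSeries,
    config: GeneratorConfig,
    rngs: dict[str, np.random.Generator] | None = None,
) -> tuple[TimeSeries, TimeSeries]:
    """Impose shared bleaching and motion plus independent noise.

    Both channels are multiplied by the same exponential bleaching factor
    and by (1 + motion_amp · gain · m(t)) with a shared smooth motion
    trace m(t) (unit variance) and channel-specific gain; independent
    Gaussian noise of sd ``noise_sd`` is then added per channel.
    Reproducible bit-for-bit for a fixed config/seed.
    """
    if not sig465.same_grid(sig405):
        raise ValueError("channels must share the same time grid")
    rngs = rngs or config.substreams()
    t = sig465.times
    if math.isinf(config.bleach_tau_s):
        bleach = np.ones_like(t)
    else:
        bleach = np.exp(-t / config.bleach_tau_s)
    if config.motion_amp > 0:
        m = motion_trace(config, t.size, sig465.rate_hz, rngs["motion"])
    else:
        m = np.zeros_like(t)
    f465 = sig465.values * bleach * (1.0 + config.motion_amp * m)
    f405 = sig405.values * bleach * (1.0 + config.motion_amp * config.motion_gain_405 * m)
    if config.noise_sd > 0:
        f465 = f465 + rngs["noise465"].normal(0.0, config.noise_sd, t.size)
        f405 = f405 + rngs["noise405"].normal(0.0, config.noise_sd, t.size)
    return sig465.with_values(f465), sig405.with_values(f405)


def _auto_bouts(config: GeneratorConfig, rng: np.random.Generator) -> list[tuple[float, int]]:
    """Random bout schedule: starts ~every 8 s, 4–12 licks per bout."""
    period = 1.0 / config.lapping_rate_hz
    bouts: list[tuple[float, int]] = []
    t = 2.0 + float(rng.exponential(2.0))
    while True:
        n = int(rng.integers(4, 13))
        if t + n * period > config.duration_s - 1.0:
            break
        bouts.append((t, n))
        t += n * period + 2.0 + float(rng.exponential(4.0))
    return bouts


def generate_pose(
    config: GeneratorConfig,
    rngs: dict[str, np.random.Generator] | None = None,
) -> tuple[PoseTrack, PoseTrack, EventSeries, list[tuple[float, int]]]:
    """Jaw and tongue tracks plus planted contact events.

    Within each bout, the jaw performs one raised-cosine downward
    deflection per lick cycle (pixel y grows downward, so opening
    increases y); the tongue is visible (likelihood ≥ 0.9) during the
    middle of each cycle and untracked (likelihood < 0.05, position
    aberrant) otherwise.  One contact event is planted at maximal
    protrusion of every cycle.  Returns (jaw, tongue, contacts, bouts).
    """
    rngs = rngs or config.substreams()
    bouts = (
        list(config.bout_structure)
        if config.bout_structure is not None
        else _auto_bouts(config, rngs["bouts"])
    )
    period = 1.0 / config.lapping_rate_hz
    for start, n in bouts:
        if start < 0 or start + n * period > config.duration_s:
            raise ValueError(f"bout at {start} s with {n} licks extends past the session")
    rate = config.video_rate_hz
    n_frames = int(math.floor(config.duration_s * rate)) + 1
    tt = np.arange(n_frames) / rate
    jaw_y = np.full(n_frames, JAW_BASE_PX)
    tongue_y = np.empty(n_frames)
    tongue_lk = np.full(n_frames, LIKELIHOOD_LOW)
    # aberrant tracker output where the tongue is invisible
    tongue_y[:] = TONGUE_BASE_PX + rngs["jitter"].uniform(-50.0, 50.0, n_frames)
    contacts: list[float] = []
    p0, p1 = TONGUE_PROTRUSION_PHASE
    for start, n in bouts:
        for j in range(n):
            c0 = start + j * period
            phase = (tt - c0) / period
            in_cycle = (phase >= 0) & (phase < 1)
            jaw_y[in_cycle] += JAW_AMP_PX * 0.5 * (1 - np.cos(2 * np.pi * phase[in_cycle]))
            prot = (phase >= p0) & (phase < p1)
            prot_phase = (phase[prot] - p0) / (p1 - p0)
            tongue_y[prot] = TONGUE_BASE_PX + TONGUE_AMP_PX * np.sin(np.pi * prot_phase)
            tongue_lk[prot] = LIKELIHOOD_HIGH
            contacts.append(c0 + 0.5 * period)
    if config.pose_noise_px > 0:
        jaw_y = jaw_y + rngs["jitter"].normal(0.0, config.pose_noise_px, n_frames)
    jaw = PoseTrack(
        body_part="jaw",
        x=np.full(n_frames, 100.0),
        y=jaw_y,
        likelihood=np.full(n_frames, LIKELIHOOD_HIGH),
        rate_hz=rate,
    )
    tongue = PoseTrack(
        body_part="tongue",
        x=np.full(n_frames, 120.0),
        y=tongue_y,
        likelihood=tongue_lk,
        rate_hz=rate,
    )
    return jaw, tongue, EventSeries(np.array(sorted(contacts)), kind="contact"), bouts


def generate_session(
    config: GeneratorConfig,
    stim: StimTrain | None = None,
    session_id: str = "",
    animal_id: str = "",
) -> SessionBundle:
    """Assemble a full synthetic session: pose + contacts + photometry.

    The 465 nm channel is a resting baseline plus the calcium response to
    the planted contacts; the 405 nm channel is calcium-blind; both then
    receive the shared artifacts.  Deterministic given (config, seed).
    """
    rngs = config.substreams()
    jaw, tongue, contacts, bouts = generate_pose(config, rngs)
    ca = calcium_response(
        contacts,
        config.kernel,
        config.contact_to_peak_delay_s,
        config.raw_rate_hz,
        config.duration_s,
    )
    f465 = ca.with_values(BASELINE_465 + ca.values)
    c405 = ca.with_values(np.full(len(ca), BASELINE_405))
    f465, c405 = apply_artifacts(f465, c405, config, rngs)
    truth = {
        "contact_to_peak_delay_s": float(config.contact_to_peak_delay_s),
        "lapping_rate_hz": float(config.lapping_rate_hz),
        "bouts": [[float(s), int(n)] for s, n in bouts],
        "contact_times_s": [float(t) for t in contacts.times_s],
        "n_licks": int(len(contacts)),
        "seed": int(config.seed),
    }
    photo = PhotometrySession(
        f465=f465, c405=c405, contacts=contacts,
        session_id=session_id, animal_id=animal_id,
    )
    return SessionBundle(photometry=photo, jaw=jaw, tongue=tongue,
                         stim=stim, truth=truth, config=config)


def generate_evoked_track(
    stim: StimTrain,
    preset: str,
    duration_s: float,
    stim_start_s: float = 1.0,
    rate_hz: float = 120.0,
    lapping_rate_hz: float = 7.0,
    amp_px: float = JAW_AMP_PX,
    noise_px: float = 0.0,
    seed: int = 0,
) -> tuple[PoseTrack, StimTrain]:
    """Synthetic jaw response to a photostimulation protocol.

    Presets model the two experimental phenotypes:

    * ``"irt"`` (medullary premotor population) — short single pulses
      evoke one mouth opening lasting the pulse; pulses beyond ~300 ms
      evoke an initial opening followed by rhythmic licking-like cycles
      at ``lapping_rate_hz``; pulse trains entrain one opening per pulse.
    * ``"peri5"`` (peritrigeminal population) — the jaw opens and is held
      open for the whole pulse with a small non-rhythmic quiver,
      whatever the pulse length.

    Returns the jaw track (pixel units) and the stimulus train shifted to
    ``stim_start_s`` on the session clock.
    """
    if preset not in ("irt", "peri5"):
        raise ValueError(f"unknown preset {preset!r}")
    train = StimTrain(onsets_s=stim.onsets_s + stim_start_s, width_s=stim.width_s,
                      rate_hz=stim.rate_hz)
    n = int(math.floor(duration_s * rate_hz)) + 1
    tt = np.arange(n) / rate_hz
    y = np.full(n, JAW_BASE_PX)

    def deflection(t0: float, dur: float, amp: float) -> None:
        phase = (tt - t0) / dur
        m = (phase >= 0) & (phase < 1)
        y[m] += amp * 0.5 * (1 - np.cos(2 * np.pi * phase[m]))

    def plateau(t0: float, dur: float, amp: float, rise: float = 0.03, fall: float = 0.05) -> None:
        up = (tt >= t0) & (tt < t0 + rise)
        y[up] += amp * 0.5 * (1 - np.cos(np.pi * (tt[up] - t0) / rise))
        hold = (tt >= t0 + rise) & (tt < t0 + dur)
        y[hold] += amp
        down = (tt >= t0 + dur) & (tt < t0 + dur + fall)
        y[down] += amp * 0.5 * (1 + np.cos(np.pi * (tt[down] - t0 - dur) / fall))

    if train.rate_hz > 0:
        # 1:1 entrainment: one cycle per pulse
        dur = min(0.15, 0.9 / train.rate_hz)
        for onset in train.onsets_s:
            deflection(onset, dur, amp_px)
    elif preset == "irt":
        w = train.width_s
        onset = float(train.onsets_s[0])
        if w <= 0.3:
            plateau(onset, w, amp_px)
        else:
            # initial opening, then rhythmic repetition for the rest of the pulse
            period = 1.0 / lapping_rate_hz
            deflection(onset, 0.15, amp_px)
            # cycles are initiated while the light is on; the last one may
            # complete just after light-off, as the evoked movement does
            t0 = onset + 0.15
            while t0 + 0.5 * period <= onset + w + 1e-9:
                deflection(t0, period, amp_px)
                t0 += period
    else:  # peri5: held open, non-rhythmic quiver
        w = train.width_s
        onset = float(train.onsets_s[0])
        plateau(onset, w, amp_px)
        rng = np.random.default_rng(seed)
        hold = (tt >= onset + 0.03) & (tt < onset + w)
        quiver = gaussian_filter1d(rng.standard_normal(n), 0.01 * rate_hz + 1.0)
        sd = quiver[hold].std() or 1.0
        y[hold] += 0.05 * amp_px * quiver[hold] / sd
    if noise_px > 0:
        y = y + np.random.default_rng(seed + 1).normal(0.0, noise_px, n)
    jaw = PoseTrack(
        body_part="jaw",
        x=np.full(n, 100.0),
        y=y,
        likelihood=np.full(n, LIKELIHOOD_HIGH),
        rate_hz=rate_hz,
    )
    return jaw, train


def generate_annotation_table(
    region_probs: dict[str, float],
    n_animals: int = 3,
    inputs_per_animal: int = 100,
    starters_per_animal: int = 5,
    ipsi_fraction: float = 0.556,
    seed: int = 0,
):
    """Synthetic rabies-tracing annotation table with known region mix.

    Draws ``inputs_per_animal`` input neurons per animal from the given
    region distribution, assigns hemispheres with the given ipsilateral
    probability, and adds ``starters_per_animal`` starter cells in the
    first-listed region (the injection site).  Returns a tidy DataFrame
    with columns (animal_id, cell_id, class, region_acronym, hemisphere).
    """
    import pandas as pd

    regions = list(region_probs)
    probs = np.array([region_probs[r] for r in regions], dtype=float)
    probs /= probs.sum()
    rng = np.random.default_rng(seed)
    rows = []
    for a in range(n_animals):
        animal = f"animal{a + 1}"
        cell = 0
        for _ in range(starters_per_animal):
            rows.append((animal, f"c{cell:05d}", "starter", regions[0], "ipsi"))
            cell += 1
        drawn = rng.choice(len(regions), size=inputs_per_animal, p=probs)
        hemi = rng.random(inputs_per_animal) < ipsi_fraction
        for r_idx, is_ipsi in zip(drawn, hemi):
            rows.append((animal, f"c{cell:05d}", "input", regions[r_idx],
                         "ipsi" if is_ipsi else "contra"))
            cell += 1
    return pd.DataFrame(
        rows, columns=["animal_id", "cell_id", "class", "region_acronym", "hemisphere"]
    )
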