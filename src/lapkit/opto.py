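"""Optogenetic stimulation protocols and evoked-movement classification.

Stimulus protocols are single continuous pulses (50–1000 ms) or trains of
100 ms pulses at 4–7 Hz.  Jaw/tongue responses aligned to each stimulus
are classified as:

* ``transient`` — a single movement that ends with (or shortly after) the
  pulse;
* ``sustained`` — the jaw is held beyond half-maximal displacement for
  most of the stimulus with no rhythmic structure;
* ``rhythmic`` — ≥ 3 movement peaks with regular cycle periods; the cycle
  frequency is reported (licking-like responses run near 7 Hz).

Classification is invariant to amplitude scaling of the trace: all peak
thresholds are relative to the trial's displacement range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .core import EventSeries, PoseTrack

__all__ = [
    "StimTrain",
    "Trial",
    "EvokedResponse",
    "build_stim_protocol",
    "extract_trials",
    "classify_evoked_response",
]

#: minimum number of movement peaks to call a response rhythmic
RHYTHMIC_MIN_PEAKS = 3
#: maximum coefficient of variation of cycle periods for rhythmicity
RHYTHMIC_MAX_CV = 0.5
#: fraction of the stimulus window above half-max displacement → sustained
SUSTAINED_OCCUPANCY = 0.8
#: peak prominence as a fraction of the trial's peak displacement
PEAK_PROMINENCE_FRAC = 0.25
#: movements lag the light; count peaks up to this long after stimulus end
WINDOW_EXTENSION_S = 0.1


@dataclass(frozen=True)
class StimTrain:
    """A photostimulation protocol: pulse onsets, width and train rate.

    ``rate_hz`` is 0 for a single continuous pulse.  ``duty`` is the
    derived width × rate (0 for single pulses); note that duty follows
    from the pulse width, which is treated as the authoritative protocol
    parameter.
    """

    onsets_s: np.ndarray
    width_s: float
    rate_hz: float = 0.0
    duty: float = field(init=False)

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets_s, dtype=float)
        if onsets.size > 1 and not np.all(np.diff(onsets) > 0):
            raise ValueError("pulse onsets must be strictly increasing")
        if not self.width_s > 0:
            raise ValueError("pulse width must be positive")
        if self.rate_hz > 0 and self.width_s >= 1.0 / self.rate_hz:
            raise ValueError(
                f"pulse width {self.width_s} s must be shorter than the "
                f"period {1.0 / self.rate_hz:.4f} s at {self.rate_hz} Hz"
            )
        object.__setattr__(self, "onsets_s", onsets)
        object.__setattr__(self, "duty", self.width_s * self.rate_hz)

    def __len__(self) -> int:
        return self.onsets_s.size

    @property
    def span_s(self) -> float:
        """Time from the first pulse onset to the end of the last pulse."""
        if self.onsets_s.size == 0:
            return 0.0
        return float(self.onsets_s[-1] + self.width_s - self.onsets_s[0])

    def as_events(self, start_s: float = 0.0) -> EventSeries:
        return EventSeries(self.onsets_s + start_s, kind="stim_onset")


@dataclass(frozen=True)
class Trial:
    """A stimulus-aligned window of a pose trajectory.

    ``t_s`` is trial time relative to stimulus onset; ``y`` is the
    baseline-normalized displacement (zeroed on the 50–100 ms pre-stimulus
    window).  ``stim_span_s`` is the stimulus duration within the trial
    (first onset to last pulse offset).
    """

    t_s: np.ndarray
    y: np.ndarray
    rate_hz: float
    stim_span_s: float
    onset_s: float
    truncated: bool = False


@dataclass(frozen=True)
class EvokedResponse:
    """Classified evoked movement for one trial."""

    cls: str  # transient | sustained | rhythmic
    onset_latency_s: float
    amplitude_mm: float
    cycle_count: int
    frequency_hz: float | None = None

    def __post_init__(self) -> None:
        if self.cls not in ("transient", "sustained", "rhythmic"):
            raise ValueError(f"unknown response class {self.cls!r}")
        if (self.frequency_hz is not None) != (self.cls == "rhythmic"):
            raise ValueError("frequency is defined iff the response is rhythmic")
        if self.cls == "rhythmic" and self.cycle_count < RHYTHMIC_MIN_PEAKS:
            raise ValueError("rhythmic responses require at least 3 cycles")


def build_stim_protocol(
    pulse_width_s: float,
    rate_hz: float,
    train_duration_s: float | None = None,
) -> StimTrain:
    """Build a stimulus train: pulses of ``pulse_width_s`` at ``rate_hz``
    for ``train_duration_s`` (onsets at k/rate), or a single continuous
    pulse when ``rate_hz`` is 0."""
    if not pulse_width_s > 0:
        raise ValueError("pulse width must be positive")
    if rate_hz == 0:
        return StimTrain(onsets_s=np.array([0.0]), width_s=pulse_width_s, rate_hz=0.0)
    if pulse_width_s >= 1.0 / rate_hz:
        raise ValueError(
            f"pulse width {pulse_width_s} s does not fit the {1.0 / rate_hz:.4f} s "
            f"period of a {rate_hz} Hz train"
        )
    if train_duration_s is None or train_duration_s <= 0:
        raise ValueError("a pulse train needs a positive duration")
    n = math.ceil(train_duration_s * rate_hz)
    onsets = np.arange(n) / rate_hz
    return StimTrain(onsets_s=onsets, width_s=pulse_width_s, rate_hz=rate_hz)


def extract_trials(
    track: PoseTrack,
    stim: StimTrain,
    pre_s: float = 0.5,
    post_s: float = 1.5,
    train_as_one: bool = True,
) -> list[Trial]:
    """Cut stimulus-aligned trials out of a session trajectory.

    Each trial spans [−pre_s, stim_span + post_s] around a stimulus onset
    and is baseline-normalized to the mean displacement 50–100 ms before
    onset.  With ``train_as_one`` a pulse train is one trial spanning the
    whole train.  Trials without a full pre-window are dropped (logged on
    the track's flags); a trial overlapping the next stimulus is truncated
    at the next onset and flagged.
    """
    rate = track.rate_hz
    if train_as_one and stim.rate_hz > 0:
        trial_onsets = [float(stim.onsets_s[0])]
        spans = [stim.span_s]
    else:
        trial_onsets = [float(t) for t in stim.onsets_s]
        spans = [stim.width_s] * len(trial_onsets)
    trials: list[Trial] = []
    dropped: list[float] = []
    for i, (onset, span) in enumerate(zip(trial_onsets, spans)):
        i0 = int(round((onset - pre_s - track.t0_s) * rate))
        i1 = int(round((onset + span + post_s - track.t0_s) * rate))
        truncated = False
        if i + 1 < len(trial_onsets):
            nxt = int(round((trial_onsets[i + 1] - track.t0_s) * rate))
            if i1 > nxt:
                i1 = nxt
                truncated = True
        if i0 < 0 or i1 > len(track):
            dropped.append(onset)
            continue
        b0 = int(round((onset - 0.100 - track.t0_s) * rate))
        b1 = int(round((onset - 0.050 - track.t0_s) * rate))
        baseline = float(np.mean(track.y[b0:b1]))
        seg = track.y[i0:i1] - baseline
        t = (np.arange(i0, i1) / rate + track.t0_s) - onset
        trials.append(Trial(t_s=t, y=seg, rate_hz=rate, stim_span_s=span,
                            onset_s=onset, truncated=truncated))
    if dropped:
        track.flags.setdefault("dropped_trials", []).extend(dropped)
    if not trials:
        raise ValueError("no stimulus onset leaves a complete pre-window inside the session")
    return trials


def classify_evoked_response(
    trial: Trial,
    stim_window_s: float | None = None,
) -> EvokedResponse:
    """Classify one baseline-normalized trial as transient, sustained or
    rhythmic.

    Movement peaks inside the stimulus window are found with a prominence
    of ``PEAK_PROMINENCE_FRAC`` × peak displacement.  ``rhythmic`` needs
    ≥ 3 peaks whose cycle periods have CV < 0.5; its frequency is
    (n_peaks − 1)/(t_last − t_first).  ``sustained`` needs displacement
    beyond half-max for > 80% of the window with < 3 peaks.  Anything
    else is ``transient``.
    """
    window = trial.stim_span_s if stim_window_s is None else stim_window_s
    if window <= 0 or window > trial.t_s[-1] + 1.0 / trial.rate_hz:
        raise ValueError(
            f"stimulus window {window} s falls outside the trial "
            f"(ends at {trial.t_s[-1]:.3f} s)"
        )
    in_win = (trial.t_s >= 0) & (trial.t_s <= window + WINDOW_EXTENSION_S)
    y = trial.y[in_win]
    t = trial.t_s[in_win]
    # displacement magnitude: evoked movement may deflect either way
    disp = np.abs(y)
    amp = float(disp.max(initial=0.0))
    if amp == 0:
        return EvokedResponse(cls="transient", onset_latency_s=float("nan"),
                              amplitude_mm=0.0, cycle_count=0)
    refractory = max(int(round(0.05 * trial.rate_hz)), 1)
    peaks, _ = signal.find_peaks(disp, prominence=PEAK_PROMINENCE_FRAC * amp,
                                 distance=refractory)
    n_peaks = peaks.size
    onset_idx = np.flatnonzero(disp >= 0.5 * amp)
    latency = float(t[onset_idx[0]]) if onset_idx.size else float("nan")
    if n_peaks >= RHYTHMIC_MIN_PEAKS:
        periods = np.diff(t[peaks])
        cv = float(periods.std() / periods.mean())
        if cv < RHYTHMIC_MAX_CV:
            freq = (n_peaks - 1) / float(t[peaks[-1]] - t[peaks[0]])
            return EvokedResponse(cls="rhythmic", onset_latency_s=latency,
                                  amplitude_mm=amp, cycle_count=n_peaks,
                                  frequency_hz=freq)
    occupancy = float(np.mean(disp >= 0.5 * amp))
    if occupancy > SUSTAINED_OCCUPANCY and n_peaks < RHYTHMIC_MIN_PEAKS:
        return EvokedResponse(cls="sustained", onset_latency_s=latency,
                              amplitude_mm=amp, cycle_count=n_peaks)
    return EvokedResponse(cls="transient", onset_latency_s=latency,
                          amplitude_mm=amp, cycle_count=max(n_peaks, 1))
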