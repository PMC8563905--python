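"""Pose-track post-processing: calibration, baselines, licks, bouts.

Raw markerless-tracker output (x, y, likelihood per frame at 120 Hz) is
converted to millimetres against a 5 mm scale bar, Savitzky–Golay
smoothed, baseline-normalized (pre-stimulus or quiescent-period modes),
and — for the tongue — gated on tracker likelihood, since the tongue is
only visible during protrusion.  Lick onsets are the peaks of the first
derivative of the jaw trajectory; runs of onsets with short inter-lick
intervals form bouts, whose frequency is estimated from the bout span.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy import signal

from .core import EventSeries, PoseTrack

__all__ = [
    "LickBout",
    "calibrate_and_smooth",
    "normalize_baseline",
    "find_quiescent_segments",
    "gate_tongue",
    "detect_lick_onsets",
    "segment_bouts",
    "lick_frequency",
]

SCALE_BAR_MM = 5.0
DEFAULT_SG_WINDOW = 11
DEFAULT_SG_ORDER = 3
#: |dy/dt| threshold (mm per frame) below which a frame counts as still
QUIESCENT_MOTION_MM_PER_FRAME = 0.05
#: quiescent segments must last 1–3 s
QUIESCENT_SPAN_S = (1.0, 3.0)
TONGUE_LIKELIHOOD_THRESHOLD = 0.05
#: refractory period between detected lick onsets
ONSET_REFRACTORY_S = 0.05


@dataclass(frozen=True)
class LickBout:
    """A run of ≥ 2 lick onsets with consecutive gaps below the bout threshold."""

    onsets: EventSeries
    n: int
    span_s: float

    @property
    def start_s(self) -> float:
        return float(self.onsets.times_s[0])


def calibrate_and_smooth(
    track: PoseTrack,
    scale_bar_px: float,
    window: int = DEFAULT_SG_WINDOW,
    poly_order: int = DEFAULT_SG_ORDER,
) -> PoseTrack:
    """Convert pixel coordinates to mm and Savitzky–Golay smooth x and y.

    ``scale_bar_px`` is the pixel length of the 5 mm scale bar in the video
    frame.  The likelihood channel is passed through untouched.
    """
    if not scale_bar_px > 0:
        raise ValueError("scale_bar_px must be positive")
    if window % 2 == 0:
        raise ValueError(f"Savitzky–Golay window must be odd, got {window}")
    if window <= poly_order:
        raise ValueError("window must exceed polynomial order")
    if window >= len(track):
        raise ValueError(f"window {window} must be shorter than track ({len(track)} frames)")
    mm_per_px = SCALE_BAR_MM / scale_bar_px
    x = signal.savgol_filter(track.x * mm_per_px, window, poly_order)
    y = signal.savgol_filter(track.y * mm_per_px, window, poly_order)
    return replace(track, x=x, y=y, units="mm")


def find_quiescent_segments(
    track: PoseTrack,
    motion_threshold: float = QUIESCENT_MOTION_MM_PER_FRAME,
    span_s: tuple[float, float] = QUIESCENT_SPAN_S,
) -> list[tuple[int, int]]:
    """Frame index ranges [i0, i1) where |Δy| stays below ``motion_threshold``
    for between ``span_s[0]`` and ``span_s[1]`` seconds.

    Longer still periods are tiled into maximal-length admissible segments.
    """
    still = np.abs(np.diff(track.y, prepend=track.y[:1])) < motion_threshold
    min_len = int(round(span_s[0] * track.rate_hz))
    max_len = int(round(span_s[1] * track.rate_hz))
    segments: list[tuple[int, int]] = []
    i = 0
    n = len(track)
    while i < n:
        if not still[i]:
            i += 1
            continue
        j = i
        while j < n and still[j]:
            j += 1
        run = j - i
        while run >= min_len:
            take = min(run, max_len)
            segments.append((i, i + take))
            i += take
            run -= take
        i = j
    return segments


def normalize_baseline(
    track: PoseTrack,
    mode: Literal["prestim", "quiescent"],
    stim_onsets: EventSeries | None = None,
    motion_threshold: float = QUIESCENT_MOTION_MM_PER_FRAME,
) -> PoseTrack:
    """Subtract the resting jaw position from the y trajectory.

    ``prestim``: baseline is the mean y in the 50–100 ms window before
    each stimulus onset (per-trial windows pooled into one session
    baseline; trial extraction re-applies the per-trial window).
    ``quiescent``: baseline is the mean y over all still segments of
    1–3 s (see :func:`find_quiescent_segments`).
    """
    y = track.y
    if mode == "prestim":
        if stim_onsets is None or len(stim_onsets) == 0:
            raise ValueError("prestim normalization requires stimulus onsets")
        samples = []
        for t in stim_onsets.times_s:
            i0 = int(round((t - 0.100 - track.t0_s) * track.rate_hz))
            i1 = int(round((t - 0.050 - track.t0_s) * track.rate_hz))
            if i0 < 0 or i1 > len(track) or i1 <= i0:
                continue
            samples.append(y[i0:i1])
        if not samples:
            raise ValueError("no stimulus has a complete 50–100 ms pre-window")
        baseline = float(np.mean(np.concatenate(samples)))
    elif mode == "quiescent":
        segments = find_quiescent_segments(track, motion_threshold)
        if not segments:
            raise ValueError(
                "no quiescent segment of 1–3 s found; review the motion threshold "
                f"(currently {motion_threshold} per frame)"
            )
        baseline = float(np.mean(np.concatenate([y[i0:i1] for i0, i1 in segments])))
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    out = replace(track, y=y - baseline)
    out.flags["baseline"] = baseline
    out.flags["baseline_mode"] = mode
    return out


def gate_tongue(
    track: PoseTrack,
    threshold: float = TONGUE_LIKELIHOOD_THRESHOLD,
    baseline: float | None = None,
) -> PoseTrack:
    """Replace low-confidence tongue positions with the resting baseline.

    The tongue is tracked only while protruded; frames with likelihood
    below ``threshold`` are spurious and are set to ``baseline``.  If no
    baseline is given it is taken as the y position on the last frame
    before the first confident protrusion (the empirically determined
    resting position).  Gating is idempotent.
    """
    low = track.likelihood < threshold
    if baseline is None:
        confident = np.flatnonzero(~low)
        if confident.size == 0:
            baseline = float(track.y[0])
        else:
            baseline = float(track.y[max(confident[0] - 1, 0)])
    y = np.where(low, baseline, track.y)
    out = replace(track, y=y)
    out.flags["gate_mask"] = low
    out.flags["gate_baseline"] = baseline
    if low.all():
        out.flags["tongue_never_detected"] = True
    return out


def detect_lick_onsets(
    track: PoseTrack,
    prominence_frac: float = 0.3,
    noise_factor: float = 3.0,
    refractory_s: float = ONSET_REFRACTORY_S,
) -> EventSeries:
    """Lick onsets as peaks of the first derivative of the jaw trajectory.

    A peak must exceed ``prominence_frac`` × the largest derivative
    excursion (licks dominate the derivative whenever they are present)
    and, as a noise floor, ``noise_factor`` × the median absolute first
    difference; peaks closer than the refractory period are merged
    (highest wins).  Returns an empty series on flat traces.
    """
    if len(track) < 3:
        return EventSeries(np.empty(0), kind="lick_onset")
    dy = np.diff(track.y)
    peak_scale = float(np.max(np.abs(dy), initial=0.0))
    if peak_scale == 0:
        return EventSeries(np.empty(0), kind="lick_onset")
    prominence = max(prominence_frac * peak_scale,
                     noise_factor * float(np.median(np.abs(dy))))
    distance = max(int(round(refractory_s * track.rate_hz)), 1)
    peaks, _ = signal.find_peaks(dy, prominence=prominence, distance=distance)
    # a single monotone step has a derivative maximum but no interior peak;
    # accept the global argmax if it clears the prominence bar
    if peaks.size == 0:
        k = int(np.argmax(dy))
        if dy[k] > prominence:
            peaks = np.array([k])
    times = track.t0_s + (peaks + 0.5) / track.rate_hz
    return EventSeries(times, kind="lick_onset")


def segment_bouts(
    onsets: EventSeries,
    max_ili_s: float = 0.5,
) -> tuple[list[LickBout], EventSeries]:
    """Split lick onsets into bouts (runs with gaps < ``max_ili_s``) and
    unitary licking events (isolated single licks)."""
    t = onsets.times_s
    bouts: list[LickBout] = []
    unitary: list[float] = []
    i = 0
    while i < t.size:
        j = i
        while j + 1 < t.size and t[j + 1] - t[j] < max_ili_s:
            j += 1
        n = j - i + 1
        if n >= 2:
            ev = EventSeries(t[i : j + 1], kind="lick_onset")
            bouts.append(LickBout(onsets=ev, n=n, span_s=float(t[j] - t[i])))
        else:
            unitary.append(float(t[i]))
        i = j + 1
    return bouts, EventSeries(np.array(unitary), kind="lick_onset")


def lick_frequency(
    bout: LickBout,
    estimator: Literal["interval", "count_over_span"] = "interval",
) -> float:
    """Licking frequency of a bout, in Hz.

    ``interval`` (default) is (n − 1)/span: the reciprocal mean inter-lick
    interval, which returns the generative rate on periodic licking.
    ``count_over_span`` is n/span, which overestimates a periodic rate by
    the factor n/(n − 1) but is kept selectable.
    """
    if bout.n < 2 or bout.span_s <= 0:
        raise ValueError("lick frequency is undefined for bouts with fewer than 2 licks")
    if estimator == "interval":
        return (bout.n - 1) / bout.span_s
    if estimator == "count_over_span":
        return bout.n / bout.span_s
    raise ValueError(f"unknown estimator {estimator!r}")
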