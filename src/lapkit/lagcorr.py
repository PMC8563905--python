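"""Lagged lick–calcium correlation with a circular-shuffle null.

For each recording session, the binary lick-port-contact regressor is
correlated with the ΔF/F trace at every integer shift of the 120 Hz grid
between −10 and +10 s (2401 lags).  Positive lag means calcium follows
contact.  Shifts use truncated overlap (no wrap-around), so edge lags are
computed from fewer samples; the per-lag sample counts are retained.

A null curve per session is built by circularly rotating the contact
regressor by random offsets (which preserves its value multiset and
autocorrelation exactly) and averaging the recomputed curves.  Session
curves and null curves are averaged per animal; the maxima of the two
mean curves enter a paired two-tailed t-test across animals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .core import EventSeries, TimeSeries
from .photometry import DffTrace

__all__ = [
    "LagCorrCurve",
    "AnimalCorrSummary",
    "contact_regressor",
    "lag_correlation_curve",
    "shuffled_null_curve",
    "summarize_animal",
    "paired_shift_test",
    "curve_argmax",
]

DEFAULT_MAX_LAG_S = 10.0
DEFAULT_N_SHUFFLES = 20


@dataclass(frozen=True)
class LagCorrCurve:
    """Pearson correlation per lag over a symmetric lag grid.

    ``lags_s`` runs from −max_lag to +max_lag inclusive at the analysis
    rate (2401 points at defaults).  ``n_samples`` holds the overlap
    length used at each lag.  ``flat_lags`` marks lags where one segment
    was constant and r was set to 0.
    """

    lags_s: np.ndarray
    r: np.ndarray
    session_id: str = ""
    is_null: bool = False
    n_samples: np.ndarray | None = None
    flat_lags: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.lags_s.shape != self.r.shape:
            raise ValueError("lag grid and r must have equal length")

    def __len__(self) -> int:
        return self.lags_s.size


@dataclass(frozen=True)
class AnimalCorrSummary:
    """Per-animal mean curves (real and null) and their maxima."""

    animal_id: str
    mean_curve: LagCorrCurve
    null_mean_curve: LagCorrCurve
    max_r: float
    max_lag_s: float
    null_max_r: float
    null_max_lag_s: float


def contact_regressor(
    contacts: EventSeries,
    rate_hz: float = 120.0,
    duration_s: float | None = None,
    n_samples: int | None = None,
) -> TimeSeries:
    """Binarize contact events onto the analysis grid: 1 in the frame
    containing each contact, 0 elsewhere.

    Pass either ``duration_s`` (grid length = floor(duration·rate) + 1)
    or an explicit ``n_samples`` to match an existing series.
    """
    if n_samples is None:
        if duration_s is None:
            raise ValueError("provide duration_s or n_samples")
        n_samples = int(np.floor(duration_s * rate_hz)) + 1
    limit = duration_s if duration_s is not None else n_samples / rate_hz
    out = np.zeros(n_samples)
    t = contacts.times_s
    if t.size and (t.min() < 0 or t.max() > limit):
        raise ValueError(
            f"contact at {t[np.argmax((t < 0) | (t > limit))]:.3f} s lies outside "
            f"the session [0, {limit:.3f}] s"
        )
    idx = np.clip(np.round(t * rate_hz).astype(int), 0, n_samples - 1)
    out[idx] = 1.0
    if t.size == 0:
        warnings.warn("no contact events: regressor is all zeros and every "
                      "lag correlation will be flagged flat", stacklevel=2)
    return TimeSeries(out, rate_hz=rate_hz)


def _lagged_pearson(x: np.ndarray, y: np.ndarray, max_shift: int):
    """Pearson r between x[i] and y[i+k] for every k in [−max_shift, max_shift],
    over the truncated (non-wrapped) overlap.

    Vectorized with an FFT cross-correlation for the cross terms and prefix
    sums for the marginal moments.  Returns (r, m, flat) where m is the
    overlap length per lag and flat marks zero-variance lags (r forced to 0).
    """
    n = x.size
    k = np.arange(-max_shift, max_shift + 1)
    m = (n - np.abs(k)).astype(float)
    # cross term: c[n-1+k] = sum_i x[i] * y[i+k]
    c = signal.correlate(y, x, mode="full", method="auto")
    sxy = c[n - 1 + k]
    cx = np.concatenate([[0.0], np.cumsum(x)])
    cx2 = np.concatenate([[0.0], np.cumsum(x * x)])
    cy = np.concatenate([[0.0], np.cumsum(y)])
    cy2 = np.concatenate([[0.0], np.cumsum(y * y)])
    # overlap for lag k: x[max(0,-k) : n-max(0,k)], y[max(0,k) : n+min(0,k)]
    xlo = np.maximum(0, -k)
    xhi = n - np.maximum(0, k)
    ylo = np.maximum(0, k)
    yhi = n + np.minimum(0, k)
    sx = cx[xhi] - cx[xlo]
    sx2 = cx2[xhi] - cx2[xlo]
    sy = cy[yhi] - cy[ylo]
    sy2 = cy2[yhi] - cy2[ylo]
    varx = m * sx2 - sx**2
    vary = m * sy2 - sy**2
    # FFT round-off can push tiny true variances negative
    varx = np.maximum(varx, 0.0)
    vary = np.maximum(vary, 0.0)
    num = m * sxy - sx * sy
    denom = np.sqrt(varx * vary)
    flat = denom <= 0
    r = np.zeros_like(num)
    np.divide(num, denom, out=r, where=~flat)
    np.clip(r, -1.0, 1.0, out=r)
    return r, m, flat


def lag_correlation_curve(
    dff: DffTrace,
    regressor: TimeSeries,
    max_lag_s: float = DEFAULT_MAX_LAG_S,
    session_id: str = "",
    is_null: bool = False,
) -> LagCorrCurve:
    """Session-wise lagged Pearson correlation between the contact
    regressor and ΔF/F, over shifts of ±``max_lag_s`` at the common rate.

    Positive lag means the calcium trace follows contact.  Lags where a
    truncated segment is constant get r = 0 and are flagged.
    """
    if abs(dff.rate_hz - regressor.rate_hz) > 1e-9 or len(dff) != len(regressor):
        raise ValueError("ΔF/F and regressor must share the same grid")
    n = len(dff)
    max_shift = int(round(max_lag_s * dff.rate_hz))
    if n <= 2 * max_shift:
        raise ValueError(
            f"session of {n} samples is too short for ±{max_lag_s} s lags "
            f"(needs > {2 * max_shift})"
        )
    r, m, flat = _lagged_pearson(regressor.values, dff.values, max_shift)
    lags = np.arange(-max_shift, max_shift + 1) / dff.rate_hz
    return LagCorrCurve(
        lags_s=lags, r=r, session_id=session_id, is_null=is_null,
        n_samples=m, flat_lags=flat,
    )


def shuffled_null_curve(
    dff: DffTrace,
    contacts: EventSeries,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int | np.random.Generator = 0,
    max_lag_s: float = DEFAULT_MAX_LAG_S,
    session_id: str = "",
) -> LagCorrCurve:
    """Null correlation curve: average of ``n_shuffles`` curves computed
    after circularly rotating the contact regressor.

    Rotation offsets are drawn uniformly from [max_lag, duration − max_lag]
    so every surrogate is displaced by at least the lag window.  Rotation
    preserves the regressor's value multiset (hence mean and variance)
    exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    reg = contact_regressor(contacts, rate_hz=dff.rate_hz, n_samples=len(dff))
    n = len(dff)
    lo = int(round(max_lag_s * dff.rate_hz))
    hi = n - lo
    if hi <= lo:
        raise ValueError("session too short to draw rotation offsets outside the lag window")
    acc = None
    for _ in range(n_shuffles):
        offset = int(rng.integers(lo, hi + 1))
        rolled = TimeSeries(np.roll(reg.values, offset), rate_hz=reg.rate_hz, t0_s=reg.t0_s)
        curve = lag_correlation_curve(dff, rolled, max_lag_s, session_id, is_null=True)
        acc = curve.r if acc is None else acc + curve.r
    return LagCorrCurve(
        lags_s=np.arange(-lo, lo + 1) / dff.rate_hz,
        r=acc / n_shuffles,
        session_id=session_id,
        is_null=True,
    )


def curve_argmax(curve: LagCorrCurve) -> tuple[float, float]:
    """(max r, lag of max).  Ties break toward the smallest |lag|, then the
    negative lag."""
    r = curve.r
    lags = curve.lags_s[np.flatnonzero(r == r.max())]
    absl = np.abs(lags)
    # |lag| compared with a small tolerance so the +/-lag pair of a
    # symmetric tie is treated as equal despite float rounding
    candidates = lags[absl <= absl.min() + 1e-9]
    lag = float(candidates.min())
    return float(r.max()), lag


def summarize_animal(
    curves: list[LagCorrCurve],
    null_curves: list[LagCorrCurve],
    animal_id: str = "",
) -> AnimalCorrSummary:
    """Average session curves and null curves into per-animal mean curves
    and extract the maxima of each."""
    if not curves or not null_curves:
        raise ValueError("need at least one real and one null curve")
    ref = curves[0].lags_s
    for c in list(curves) + list(null_curves):
        if c.lags_s.shape != ref.shape or not np.allclose(c.lags_s, ref):
            raise ValueError("all curves must share the same lag grid")
    mean_r = np.mean([c.r for c in curves], axis=0)
    null_r = np.mean([c.r for c in null_curves], axis=0)
    mean_curve = LagCorrCurve(lags_s=ref, r=mean_r, session_id=animal_id, is_null=False)
    null_curve = LagCorrCurve(lags_s=ref, r=null_r, session_id=animal_id, is_null=True)
    max_r, max_lag = curve_argmax(mean_curve)
    nmax_r, nmax_lag = curve_argmax(null_curve)
    return AnimalCorrSummary(
        animal_id=animal_id,
        mean_curve=mean_curve,
        null_mean_curve=null_curve,
        max_r=max_r,
        max_lag_s=max_lag,
        null_max_r=nmax_r,
        null_max_lag_s=nmax_lag,
    )


def paired_shift_test(summaries: list[AnimalCorrSummary]) -> tuple[float, float, int]:
    """Two-tailed paired t-test on per-animal (max_r − null_max_r).

    Returns (t statistic, p value, n animals).  Requires ≥ 2 animals and
    non-degenerate variance of the differences.
    """
    n = len(summaries)
    if n < 2:
        raise ValueError("paired test needs at least 2 animals")
    diffs = np.array([s.max_r - s.null_max_r for s in summaries])
    if np.allclose(diffs.std(ddof=1), 0.0):
        raise ValueError("degenerate variance: per-animal differences are identical")
    real = np.array([s.max_r for s in summaries])
    null = np.array([s.null_max_r for s in summaries])
    t, p = stats.ttest_rel(real, null)
    return float(t), float(p), n
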