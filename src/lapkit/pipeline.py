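"""End-to-end conveniences tying the stages together.

These helpers run the canonical analysis path — raw two-channel
photometry → ΔF/F → contact regressor → lagged correlation → per-animal
summaries → paired test — on in-memory session bundles, exactly as the
CLI does on session directories.
"""

from __future__ import annotations

import numpy as np

from . import lagcorr, photometry
from .lagcorr import AnimalCorrSummary, LagCorrCurve
from .synthetic import GeneratorConfig, SessionBundle, generate_session

__all__ = [
    "bundle_dff",
    "bundle_curves",
    "cohort_summaries",
    "cohort_peak_lag",
]


def bundle_dff(bundle: SessionBundle) -> photometry.DffTrace:
    """Run the full photometry pipeline on one session bundle.

    Uses the ``auto`` baseline rule so artifact-free synthetic sessions
    (flat 405 nm channel) degrade gracefully to the mean-ratio fit.
    """
    dff, _ = photometry.process_session(
        bundle.photometry.f465, bundle.photometry.c405, baseline_method="auto"
    )
    return dff


def bundle_curves(
    bundle: SessionBundle,
    n_shuffles: int = 0,
    seed: int | np.random.Generator = 0,
    max_lag_s: float = lagcorr.DEFAULT_MAX_LAG_S,
) -> tuple[LagCorrCurve, LagCorrCurve | None]:
    """ΔF/F and lagged correlation curve (plus shuffled null if requested)
    for one session bundle."""
    dff = bundle_dff(bundle)
    reg = lagcorr.contact_regressor(
        bundle.photometry.contacts, rate_hz=dff.rate_hz, n_samples=len(dff)
    )
    curve = lagcorr.lag_correlation_curve(
        dff, reg, max_lag_s, session_id=bundle.photometry.session_id
    )
    null = None
    if n_shuffles > 0:
        null = lagcorr.shuffled_null_curve(
            dff, bundle.photometry.contacts, n_shuffles, seed, max_lag_s,
            session_id=bundle.photometry.session_id,
        )
    return curve, null


def cohort_summaries(
    n_animals: int,
    n_sessions: int,
    base_seed: int = 1,
    n_shuffles: int = lagcorr.DEFAULT_N_SHUFFLES,
    **config_kwargs,
) -> list[AnimalCorrSummary]:
    """Generate a synthetic cohort and summarize each animal.

    Session seeds are ``base_seed + animal·n_sessions + session`` so a
    cohort is fully reproducible from ``base_seed``.
    """
    summaries = []
    for a in range(n_animals):
        curves, nulls = [], []
        for s in range(n_sessions):
            seed = base_seed + a * n_sessions + s
            config = GeneratorConfig(seed=seed, **config_kwargs)
            bundle = generate_session(
                config, session_id=f"a{a}s{s}", animal_id=f"animal{a}"
            )
            curve, null = bundle_curves(bundle, n_shuffles=n_shuffles, seed=seed)
            curves.append(curve)
            nulls.append(null)
        if n_shuffles > 0:
            summaries.append(
                lagcorr.summarize_animal(curves, nulls, animal_id=f"animal{a}"))
        else:
            # no null requested: summarize the real curves only
            mean_r = np.mean([c.r for c in curves], axis=0)
            mean_curve = LagCorrCurve(lags_s=curves[0].lags_s, r=mean_r,
                                      session_id=f"animal{a}")
            max_r, max_lag = lagcorr.curve_argmax(mean_curve)
            summaries.append(AnimalCorrSummary(
                animal_id=f"animal{a}", mean_curve=mean_curve,
                null_mean_curve=None, max_r=max_r, max_lag_s=max_lag,
                null_max_r=float("nan"), null_max_lag_s=float("nan")))
    return summaries


def cohort_peak_lag(summaries: list[AnimalCorrSummary]) -> tuple[float, float]:
    """(peak r, peak lag) of the across-animal mean correlation curve."""
    lags = summaries[0].mean_curve.lags_s
    grand = np.mean([s.mean_curve.r for s in summaries], axis=0)
    curve = LagCorrCurve(lags_s=lags, r=grand)
    return lagcorr.curve_argmax(curve)
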