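"""Lagged lick–calcium correlation, shuffle null, per-animal summary, test."""

import numpy as np
import pytest
from scipy import stats

from lapkit import lagcorr
from lapkit.core import TimeSeries
from lapkit.lagcorr import LagCorrCurve
from lapkit.photometry import DffTrace
from lapkit.pipeline import bundle_curves
from lapkit.synthetic import GeneratorConfig, generate_session

from conftest import make_events


def brute_force_curve(x, y, max_shift):
    """Naive O(n*lags) truncated-overlap Pearson oracle."""
    n = len(x)
    out = np.empty(2 * max_shift + 1)
    for i, k in enumerate(range(-max_shift, max_shift + 1)):
        if k >= 0:
            xs, ys = x[: n - k], y[k:]
        else:
            xs, ys = x[-k:], y[: n + k]
        if np.ptp(xs) == 0 or np.ptp(ys) == 0:
            out[i] = 0.0
        else:
            out[i] = stats.pearsonr(xs, ys)[0]
    return out


def as_dff(values, rate_hz=120.0):
    return DffTrace(np.asarray(values, float), rate_hz=rate_hz)


class TestContactRegressor:
    def test_single_contact_lands_in_its_frame(self):
        reg = lagcorr.contact_regressor(make_events([0.5]), 120.0, duration_s=1.0)
        assert len(reg) == 121
        assert reg.values.sum() == 1.0
        assert reg.values[60] == 1.0

    def test_no_contacts_warns_and_returns_zeros(self):
        with pytest.warns(UserWarning, match="all zeros"):
            reg = lagcorr.contact_regressor(make_events([]), 120.0, duration_s=1.0)
        assert not reg.values.any()

    def test_contact_outside_session_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            lagcorr.contact_regressor(make_events([1.5]), 120.0, duration_s=1.0)


class TestLagCorrelationCurve:
    def test_self_correlation_peaks_at_zero_with_r_one(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=6000)
        curve = lagcorr.lag_correlation_curve(
            as_dff(v), TimeSeries(v, 120.0), max_lag_s=2.0)
        k0 = len(curve) // 2
        assert curve.lags_s[k0] == 0.0
        assert curve.r[k0] == pytest.approx(1.0, abs=1e-12)
        assert np.argmax(curve.r) == k0

    def test_delayed_copy_matches_brute_force_argmax(self):
        # dF/F equal to a smoothed regressor delayed by 25 samples: the
        # curve must equal the exhaustive oracle and peak at +25/120 s
        rng = np.random.default_rng(1)
        base = np.convolve(rng.normal(size=6000), np.ones(20) / 20, mode="same")
        delayed = np.roll(base, 25)
        curve = lagcorr.lag_correlation_curve(
            as_dff(delayed), TimeSeries(base, 120.0), max_lag_s=2.0)
        oracle = brute_force_curve(base, delayed, 240)
        np.testing.assert_allclose(curve.r, oracle, atol=1e-10)
        assert curve.lags_s[np.argmax(curve.r)] == pytest.approx(25 / 120.0)

    def test_matches_brute_force_on_default_grid(self):
        # full +/-10 s grid on a 30 s session, equality to 1e-10
        rng = np.random.default_rng(2)
        n = 30 * 120 + 1
        x = (rng.random(n) < 0.02).astype(float)
        y = np.convolve(rng.normal(size=n), np.ones(40) / 40, mode="same")
        curve = lagcorr.lag_correlation_curve(as_dff(y), TimeSeries(x, 120.0))
        assert len(curve) == 2401
        oracle = brute_force_curve(x, y, 1200)
        np.testing.assert_allclose(curve.r, oracle, atol=1e-10)

    def test_white_noise_pairs_have_small_maxima(self):
        # two independent 2-min white-noise series: max |r| < 0.1 in at
        # least 95% of 100 seeds
        n = 120 * 120
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x, y = rng.normal(size=(2, n))
            curve = lagcorr.lag_correlation_curve(
                as_dff(y), TimeSeries(x, 120.0))
            hits += np.max(np.abs(curve.r)) < 0.1
        assert hits >= 95

    def test_r_bounded_by_one(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=5000)
        curve = lagcorr.lag_correlation_curve(
            as_dff(2 * x + rng.normal(size=5000)), TimeSeries(x, 120.0),
            max_lag_s=5.0)
        assert np.all(np.abs(curve.r) <= 1.0)

    def test_swapping_series_mirrors_lag_axis(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=(2, 4000))
        fwd = lagcorr.lag_correlation_curve(
            as_dff(y), TimeSeries(x, 120.0), max_lag_s=3.0)
        rev = lagcorr.lag_correlation_curve(
            as_dff(x), TimeSeries(y, 120.0), max_lag_s=3.0)
        np.testing.assert_allclose(fwd.r, rev.r[::-1], atol=1e-12)

    def test_short_session_rejected(self):
        with pytest.raises(ValueError, match="short"):
            lagcorr.lag_correlation_curve(
                as_dff(np.ones(100)), TimeSeries(np.ones(100), 120.0))

    def test_constant_segments_flagged_zero(self):
        x = np.zeros(1000)
        x[500] = 1.0
        y = np.ones(1000)  # constant dF/F: every lag degenerate
        curve = lagcorr.lag_correlation_curve(
            as_dff(y), TimeSeries(x, 120.0), max_lag_s=2.0)
        assert np.all(curve.r == 0.0)
        assert curve.flat_lags.all()


class TestShuffledNull:
    def test_rotation_preserves_value_multiset(self):
        contacts = make_events(np.sort(np.random.default_rng(0).uniform(1, 29, 40)))
        reg = lagcorr.contact_regressor(contacts, 120.0, duration_s=30.0)
        rng = np.random.default_rng(1)
        for _ in range(10):
            offset = int(rng.integers(1200, len(reg) - 1200))
            rolled = np.roll(reg.values, offset)
            # the value multiset is preserved exactly, hence sum/variance
            # up to summation order
            np.testing.assert_array_equal(np.sort(rolled), np.sort(reg.values))
            assert rolled.sum() == reg.values.sum()
            np.testing.assert_allclose(rolled.var(), reg.values.var(), rtol=1e-12)

    def test_fixed_seed_reproducible(self, short_bundle):
        from lapkit.pipeline import bundle_dff

        dff = bundle_dff(short_bundle)
        contacts = short_bundle.photometry.contacts
        a = lagcorr.shuffled_null_curve(dff, contacts, n_shuffles=5, seed=11)
        b = lagcorr.shuffled_null_curve(dff, contacts, n_shuffles=5, seed=11)
        np.testing.assert_array_equal(a.r, b.r)

    def test_planted_coupling_beats_null_across_seeds(self):
        # 50 default-coupling sessions: the real curve maximum exceeds the
        # 20-shuffle null maximum in >= 95% of them
        wins = 0
        for seed in range(50):
            cfg = GeneratorConfig(duration_s=60.0, seed=2000 + seed)
            bundle = generate_session(cfg)
            curve, null = bundle_curves(bundle, n_shuffles=20, seed=seed)
            wins += curve.r.max() > null.r.max()
        assert wins >= 48

    def test_session_too_short_for_offsets_rejected(self):
        # exactly 2 * max_lag samples: no admissible rotation offset
        dff = as_dff(np.random.default_rng(0).normal(size=2400))
        with pytest.raises(ValueError):
            lagcorr.shuffled_null_curve(dff, make_events([5.0]), 2, seed=0)


class TestSummaryAndTest:
    def _curve(self, r):
        lags = np.linspace(-10, 10, len(r))
        return LagCorrCurve(lags_s=lags, r=np.asarray(r, float))

    def test_mean_of_identical_curves_is_unchanged(self):
        c = self._curve(np.sin(np.linspace(0, 3, 241)))
        s = lagcorr.summarize_animal([c, c], [c], animal_id="m1")
        np.testing.assert_allclose(s.mean_curve.r, c.r)

    def test_maxima_located_on_mean_curve(self):
        lags = np.arange(-1200, 1201) / 120.0
        r = np.exp(-0.5 * ((lags - 1.2) / 0.5) ** 2) * 0.40
        c = LagCorrCurve(lags_s=lags, r=r)
        null = LagCorrCurve(lags_s=lags, r=np.zeros_like(r), is_null=True)
        s = lagcorr.summarize_animal([c], [null])
        assert s.max_r == pytest.approx(0.40)
        assert s.max_lag_s == pytest.approx(1.2, abs=1e-9)

    def test_flat_curve_tie_breaks_to_zero_lag(self):
        c = self._curve(np.zeros(241))
        _, lag = lagcorr.curve_argmax(c)
        assert lag == 0.0

    def test_symmetric_tie_breaks_to_negative_lag(self):
        r = np.zeros(241)
        r[100] = r[140] = 0.5  # symmetric about the center index 120
        c = self._curve(r)
        _, lag = lagcorr.curve_argmax(c)
        assert lag < 0

    def test_mixed_lag_grids_rejected(self):
        a = self._curve(np.zeros(241))
        b = LagCorrCurve(lags_s=np.linspace(-5, 5, 241), r=np.zeros(241))
        with pytest.raises(ValueError):
            lagcorr.summarize_animal([a], [b])

    def test_paired_test_matches_closed_form(self):
        diffs = np.array([0.2, 0.25, 0.18, 0.22])
        summaries = [
            lagcorr.AnimalCorrSummary(
                animal_id=str(i), mean_curve=None, null_mean_curve=None,
                max_r=0.5 + d, max_lag_s=1.2, null_max_r=0.5, null_max_lag_s=0.0)
            for i, d in enumerate(diffs)
        ]
        t, p, n = lagcorr.paired_shift_test(summaries)
        t_expected = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(4))
        p_expected = 2 * stats.t.sf(abs(t_expected), df=3)
        assert t == pytest.approx(t_expected, rel=1e-12)
        assert p == pytest.approx(p_expected, rel=1e-12)
        assert p < 0.05 and n == 4

    def test_degenerate_variance_rejected(self):
        summaries = [
            lagcorr.AnimalCorrSummary(
                animal_id=str(i), mean_curve=None, null_mean_curve=None,
                max_r=0.3, max_lag_s=1.0, null_max_r=0.1, null_max_lag_s=0.0)
            for i in range(3)
        ]
        with pytest.raises(ValueError, match="degenerate"):
            lagcorr.paired_shift_test(summaries)

    def test_single_animal_rejected(self):
        with pytest.raises(ValueError):
            lagcorr.paired_shift_test([None])


class TestLagRecovery:
    @pytest.mark.parametrize("delay", [0.5, 1.2, 3.0])
    def test_planted_delay_recovered_across_seeds(self, delay):
        # full pipeline on noisy default sessions: the planted contact-to-
        # peak latency is recovered within +/-0.05 s in >= 90% of seeds
        hits = 0
        for seed in range(10):
            cfg = GeneratorConfig(duration_s=60.0,
                                  contact_to_peak_delay_s=delay,
                                  seed=3000 + seed)
            bundle = generate_session(cfg)
            curve, _ = bundle_curves(bundle)
            _, lag = lagcorr.curve_argmax(curve)
            hits += abs(lag - delay) <= 0.05
        assert hits >= 9
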