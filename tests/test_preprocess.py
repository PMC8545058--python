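import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ntlimpact import (clamp_negatives, filter_moonless, moon_phase_angle,
                       quartile_bounds, smbq_repair)
from ntlimpact.preprocess import FLAG_HIGH, FLAG_LOW, PAPER_MOONLESS_WINDOWS

from conftest import make_stack


def brute_force_fences(series):
    """Independent quartile/fence oracle: manual linear interpolation on
    sorted order statistics."""
    v = sorted(x for x in series if np.isfinite(x))
    n = len(v)
    if n < 4:
        return None

    def quantile(q):
        h = (n - 1) * q
        lo, hi = int(np.floor(h)), int(np.ceil(h))
        return v[lo] + (h - lo) * (v[hi] - v[lo])

    q1, q3 = quantile(0.25), quantile(0.75)
    iqr = q3 - q1
    return q1, q3, q1 - 1.5 * iqr, q3 + 1.5 * iqr


class TestClamp:
    def test_negative_goes_to_zero_and_zero_stays(self):
        stack = make_stack(np.array([[[-3.2, 0.0], [1.5, -0.001]]]))
        out = clamp_negatives(stack)
        np.testing.assert_array_equal(out.data[0],
                                      [[0.0, 0.0], [1.5, 0.0]])

    def test_nonnegative_layer_unchanged_and_nan_preserved(self):
        data = np.array([[[0.4, np.nan], [2.0, 7.0]]])
        out = clamp_negatives(make_stack(data))
        assert np.isnan(out.data[0, 0, 1])
        np.testing.assert_array_equal(out.data[0, 1], [2.0, 7.0])


class TestMoonPhase:
    def test_new_moon_near_180_full_moon_near_0(self):
        # published lunar phases: new moon 2020-01-24, full moon 2020-02-09
        new = moon_phase_angle(dt.date(2020, 1, 24))
        full = moon_phase_angle(dt.date(2020, 2, 9))
        assert new > 150
        assert full < 30
        assert new > full

    @pytest.mark.parametrize("new_moon,full_moon", [
        (dt.date(2019, 3, 6), dt.date(2019, 3, 21)),
        (dt.date(2020, 3, 24), dt.date(2020, 3, 9)),
    ])
    def test_against_published_lunar_tables(self, new_moon, full_moon):
        assert moon_phase_angle(new_moon) > 150
        assert moon_phase_angle(full_moon) < 30

    def test_out_of_range_date_rejected(self):
        with pytest.raises(ValueError, match="ephemeris range"):
            moon_phase_angle(dt.date(1600, 1, 1))


class TestFilterMoonless:
    def _study_stack(self):
        n = (dt.date(2020, 3, 31) - dt.date(2020, 1, 20)).days + 1
        return make_stack(np.zeros((n, 2, 2)))

    def test_explicit_all_dates_is_identity(self):
        stack = self._study_stack()
        out = filter_moonless(stack, mode="explicit",
                              dates=list(stack.dates))
        assert out.dates == stack.dates

    def test_default_windows_retain_13_16_15_days(self):
        out = filter_moonless(self._study_stack(), mode="explicit")
        assert len(out) == 13 + 16 + 15
        assert all(any(a <= d <= b for a, b in PAPER_MOONLESS_WINDOWS)
                   for d in out.dates)

    def test_ephemeris_mode_retains_new_moon_neighbourhoods(self):
        out = filter_moonless(self._study_stack(), mode="ephemeris")
        retained = set(out.dates)
        for new_moon in (dt.date(2020, 1, 24), dt.date(2020, 2, 23),
                         dt.date(2020, 3, 24)):
            for off in range(-5, 6):
                d = new_moon + dt.timedelta(days=off)
                if dt.date(2020, 1, 20) <= d <= dt.date(2020, 3, 31):
                    assert d in retained

    def test_empty_result_warns(self):
        stack = self._study_stack()
        with pytest.warns(UserWarning, match="every date"):
            filter_moonless(stack, mode="explicit", dates=[])


class TestQuartileBounds:
    def test_hand_computed_example(self):
        b = quartile_bounds(np.array([1.0, 2, 3, 4, 100]))
        assert b.q1 == pytest.approx(2.0)
        assert b.q3 == pytest.approx(4.0)
        assert b.upper == pytest.approx(7.0)
        assert b.lower == pytest.approx(-1.0)

    def test_constant_series_collapses(self):
        b = quartile_bounds(np.full(10, 3.3))
        assert b.lower == b.upper == pytest.approx(3.3)

    def test_uniform_series_fences_bounded(self):
        v = np.random.default_rng(1).uniform(0, 1, 50)
        b = quartile_bounds(v)
        assert -1.5 <= b.lower and b.upper <= 2.5

    def test_too_few_finite_values_flagged(self):
        b = quartile_bounds(np.array([1.0, 2.0, np.nan, np.nan, 3.0]))
        assert b.unprocessable
        assert np.isnan(b.upper)


class TestSmbqRepair:
    def test_spike_clipped_to_upper_fence(self):
        stack = make_stack(np.array([1.0, 2, 3, 4, 100]).reshape(-1, 1, 1))
        out, mask = smbq_repair(stack)
        np.testing.assert_allclose(out.data[:, 0, 0], [1, 2, 3, 4, 7])
        assert list(mask.flags[:, 0, 0]) == [0, 0, 0, 0, FLAG_HIGH]

    def test_series_inside_fences_untouched(self):
        data = np.linspace(1, 2, 20).reshape(-1, 1, 1)
        out, mask = smbq_repair(make_stack(data))
        np.testing.assert_array_equal(out.data, data)
        assert (mask.flags == 0).all()

    def test_matches_brute_force_oracle_on_random_series(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(30, 91))
            series = rng.lognormal(0, 1, n)
            if rng.random() < 0.5:
                series[rng.integers(0, n)] *= 50
            stack = make_stack(series.reshape(-1, 1, 1))
            out, mask = smbq_repair(stack)
            q1, q3, lo, hi = brute_force_fences(series)
            exp = np.clip(series, lo, hi)
            np.testing.assert_allclose(out.data[:, 0, 0], exp, rtol=1e-12)
            exp_flags = np.where(series > hi, FLAG_HIGH,
                                 np.where(series < lo, FLAG_LOW, 0))
            np.testing.assert_array_equal(mask.flags[:, 0, 0], exp_flags)

    def test_idempotent_on_random_stacks(self):
        rng = np.random.default_rng(7)
        data = rng.lognormal(0, 0.5, size=(40, 6, 6))
        data[rng.random(data.shape) < 0.03] *= 20
        once, _ = smbq_repair(make_stack(data))
        twice, mask2 = smbq_repair(once)
        np.testing.assert_array_equal(once.data, twice.data)
        assert (mask2.flags == 0).all()

    def test_order_invariance_of_flags(self):
        rng = np.random.default_rng(9)
        data = rng.lognormal(0, 0.8, size=(30, 3, 3))
        _, mask = smbq_repair(make_stack(data))
        perm = rng.permutation(30)
        # repair the permuted stack; fences are order statistics so flags
        # must be the permuted flags
        _, mask_p = smbq_repair(make_stack(data[perm]))
        np.testing.assert_array_equal(mask_p.flags, mask.flags[perm])

    def test_nan_days_never_flagged(self):
        data = np.r_[np.ones(10), np.nan, 100.0].reshape(-1, 1, 1)
        out, mask = smbq_repair(make_stack(data))
        assert mask.flags[10, 0, 0] == 0
        assert np.isnan(out.data[10, 0, 0])
        assert mask.flags[11, 0, 0] == FLAG_HIGH

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 1e4), min_size=8, max_size=60),
           st.integers(0, 2 ** 31 - 1))
    def test_repaired_values_always_inside_fences(self, values, seed):
        series = np.asarray(values)
        stack = make_stack(series.reshape(-1, 1, 1))
        out, _ = smbq_repair(stack)
        q1, q3, lo, hi = brute_force_fences(series)
        assert (out.data[:, 0, 0] >= lo - 1e-9).all()
        assert (out.data[:, 0, 0] <= hi + 1e-9).all()


class TestPlantedOutlierRecovery:
    def test_spike_recall_and_asymmetry(self, default_bundle):
        cfg, (baseline, analysis, zones, truth) = default_bundle
        repaired, mask = smbq_repair(analysis)
        planted_high = truth.outlier_flags == FLAG_HIGH
        planted_low = truth.outlier_flags == FLAG_LOW
        # spikes outnumber drops by construction (spike_rate > drop_rate)
        assert planted_high.sum() > planted_low.sum()
        found_high = mask.flags == FLAG_HIGH
        # recall over spikes of magnitude >= 5x the clean value
        big = planted_high & (analysis.data >= 5.0 * truth.clean)
        recall = (big & found_high).sum() / big.sum()
        precision = (planted_high & found_high).sum() / found_high.sum()
        assert recall >= 0.95
        assert precision > 0.5
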