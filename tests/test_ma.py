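"""Truncation, simple MA, EWMA, control limits and alarm semantics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import oracle_ewma_expansion, oracle_simple_ma
from pbrtqc import (
    ControlLimits,
    EmptySeriesError,
    MAConfig,
    TruncationLimits,
    apply_truncation,
    check_alarm,
    compute_ewma,
    compute_ma_series,
    compute_simple_ma,
    derive_control_limits,
)


class TestTruncation:
    @pytest.mark.parametrize(
        "values,limits,expected",
        [
            ([4.3, 6.5, 4.1], dict(upper=6.0), [True, False, True]),
            ([1.0, 2.0, 3.0], dict(), [True, True, True]),
            ([6.0], dict(upper=6.0), [True]),  # inclusive boundary
            ([130.0, 129.9], dict(lower=130.0), [True, False]),
        ],
    )
    def test_mask(self, values, limits, expected):
        mask = apply_truncation(np.array(values), TruncationLimits(**limits))
        assert mask.tolist() == expected

    def test_limits_must_be_ordered(self):
        with pytest.raises(ValueError):
            TruncationLimits(lower=5.0, upper=5.0)


class TestSimpleMA:
    def test_mean_of_first_full_batch(self):
        s = compute_simple_ma(np.arange(1.0, 6.0), np.ones(5, bool), 5)
        assert np.isnan(s.ma[:4]).all()
        assert s.ma[4] == 3.0

    def test_window_slides(self):
        s = compute_simple_ma(np.arange(1.0, 7.0), np.ones(6, bool), 5)
        assert s.ma[5] == 4.0

    def test_matches_trailing_window_oracle_with_truncation(self, rng):
        values = rng.normal(100, 10, 200)
        mask = apply_truncation(values, TruncationLimits(lower=85, upper=115))
        s = compute_simple_ma(values, mask, 25)
        expected = oracle_simple_ma(values, mask, 25)
        np.testing.assert_allclose(s.ma, expected, rtol=1e-9)

    def test_rejected_positions_carry_forward(self):
        values = np.array([1.0, 2.0, 50.0, 3.0])
        mask = apply_truncation(values, TruncationLimits(upper=10))
        s = compute_simple_ma(values, mask, 2)
        assert s.ma[1] == 1.5
        assert s.ma[2] == 1.5  # rejected: unchanged
        assert s.ma[3] == 2.5


class TestEWMA:
    def test_hand_expanded_recursion(self):
        s = compute_ewma(np.ones(3), np.ones(3, bool), 0.5, 0.0)
        np.testing.assert_allclose(s.ma, [0.5, 0.75, 0.875])

    def test_constant_stream_is_fixed_point(self):
        s = compute_ewma(np.full(10, 7.0), np.ones(10, bool), 0.3, 7.0)
        np.testing.assert_allclose(s.ma, 7.0)

    def test_matches_explicit_expansion_oracle(self, rng):
        values = rng.normal(4.3, 0.4, 200)
        mask = np.ones(200, bool)
        s = compute_ewma(values, mask, 0.1, 4.3)
        expected = oracle_ewma_expansion(values, 0.1, 4.3)
        np.testing.assert_allclose(s.ma, expected, rtol=1e-9)

    def test_lambda_near_one_tracks_raw_values(self, rng):
        values = rng.normal(0, 1, 50)
        s = compute_ewma(values, np.ones(50, bool), 1 - 1e-12, 100.0)
        np.testing.assert_allclose(s.ma, values, atol=1e-9)

    def test_lambda_near_zero_stays_at_init(self, rng):
        values = rng.normal(0, 1, 50)
        s = compute_ewma(values, np.ones(50, bool), 1e-9, 100.0)
        np.testing.assert_allclose(s.ma, 100.0, atol=1e-5)


class TestComputeMaSeries:
    def test_simple_defined_from_batch_size(self, streams):
        cfg = MAConfig(algorithm="simple", batch_size=25)
        s = compute_ma_series(streams["sodium"], cfg)
        assert np.isnan(s.ma[:24]).all() and not np.isnan(s.ma[24:]).any()

    def test_truncated_values_never_move_the_ewma(self, streams):
        cfg = MAConfig(
            algorithm="ewma", weighting_factor=0.1,
            truncation=TruncationLimits(upper=6.0),
        )
        s = compute_ma_series(streams["potassium"], cfg)
        high = streams["potassium"].values > 6.0
        assert high.any()
        prior = np.roll(s.ma, 1)
        prior[0] = np.nan
        assert np.array_equal(
            s.ma[high & ~np.isnan(prior)], prior[high & ~np.isnan(prior)]
        )

    def test_single_value_stream_with_explicit_init(self):
        cfg = MAConfig(algorithm="ewma", weighting_factor=0.5, init_value=8.0)
        s = compute_ma_series(np.array([8.0]), cfg)
        np.testing.assert_allclose(s.ma, [8.0])

    def test_all_rejected_raises(self):
        cfg = MAConfig(
            algorithm="ewma", weighting_factor=0.5,
            truncation=TruncationLimits(upper=1.0),
        )
        with pytest.raises(EmptySeriesError):
            compute_ma_series(np.array([5.0, 6.0]), cfg)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            MAConfig(algorithm="simple", weighting_factor=0.1)
        with pytest.raises(ValueError):
            MAConfig(algorithm="ewma", batch_size=5)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(seed=st.integers(0, 2**16), n_extra=st.integers(1, 20))
    def test_truncation_invariance(self, seed, n_extra):
        """Inserting out-of-limit values leaves the accepted-position MA unchanged."""
        rng = np.random.default_rng(seed)
        base = rng.normal(100, 5, 80)
        limits = TruncationLimits(lower=80, upper=120)
        cfg = MAConfig(
            algorithm="ewma", weighting_factor=0.2, truncation=limits, init_value=100.0
        )
        positions = np.sort(rng.integers(0, len(base) + 1, n_extra))
        noisy = np.insert(base, positions, rng.uniform(150, 200, n_extra))
        s_base = compute_ma_series(base, cfg)
        s_noisy = compute_ma_series(noisy, cfg)
        np.testing.assert_allclose(
            s_noisy.ma[s_noisy.accepted], s_base.ma[s_base.accepted], rtol=1e-12
        )


class TestControlLimitsAndAlarms:
    def test_limits_are_series_extrema(self):
        s = compute_simple_ma(np.array([139.0, 140, 141]), np.ones(3, bool), 1)
        limits = derive_control_limits(s)
        assert (limits.lower, limits.upper) == (139, 141)

    def test_constant_series_degenerate_limits(self):
        s = compute_ewma(np.full(5, 4.0), np.ones(5, bool), 0.5, 4.0)
        limits = derive_control_limits(s)
        assert limits.lower == limits.upper == 4.0

    def test_limits_match_scan_oracle(self, rng):
        values = rng.normal(70, 8, 1000)
        s = compute_simple_ma(values, np.ones(1000, bool), 10)
        limits = derive_control_limits(s)
        defined = [m for m in s.ma if not np.isnan(m)]
        assert limits.lower == min(defined) and limits.upper == max(defined)

    @pytest.mark.parametrize(
        "value,expected", [(142.0, False), (142.1, True), (140.0, False), (136.9, True)]
    )
    def test_alarm_is_strict_exceedance(self, value, expected):
        assert check_alarm(value, ControlLimits(137, 142)) is expected

    def test_replaying_defining_stream_never_alarms(self, streams):
        """Min/max limits plus strict alarms give zero false alarms by construction."""
        cfg = MAConfig(algorithm="simple", batch_size=10)
        s = compute_ma_series(streams["albumin"], cfg)
        limits = derive_control_limits(s)
        assert not any(check_alarm(m, limits) for m in s.defined_values())
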