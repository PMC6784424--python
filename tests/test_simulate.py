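"""Bias injection, detection counting and per-bias aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import oracle_replay_run
from pbrtqc import (
    BiasGrid,
    ConfigMismatchError,
    ControlLimits,
    InjectionRun,
    MAConfig,
    TruncationLimits,
    compute_ma_series,
    derive_control_limits,
    inject_bias,
    round_tea,
    run_single_simulation,
    simulate_bias_grid,
    summarize_runs,
)


class TestRoundTea:
    @pytest.mark.parametrize("tea,expected", [(17.97, 18), (3.57, 4), (10.0, 10), (2.5, 3)])
    def test_nearest_integer_half_away_from_zero(self, tea, expected):
        assert round_tea(tea) == expected

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            round_tea(0.0)


class TestBiasGrid:
    def test_default_grid_includes_tea(self):
        grid = BiasGrid.default(17.97)
        assert grid.tea_percent == 18
        assert set(grid.percentages) == {
            s * m for m in (50, 40, 30, 20, 18, 10, 5, 3, 1) for s in (-1, 1)
        }

    def test_tea_coinciding_with_grid_not_duplicated(self):
        grid = BiasGrid.default(10.0)
        assert len(grid.percentages) == 16


class TestInjectBias:
    def test_multiplicative_from_start(self):
        out = inject_bias(np.array([140.0, 140.0, 140.0]), 1, 4.0)
        np.testing.assert_allclose(out, [140, 145.6, 145.6])

    def test_zero_bias_is_identity(self, rng):
        values = rng.normal(70, 8, 30)
        np.testing.assert_array_equal(inject_bias(values, 7, 0.0), values)

    def test_large_bias_can_exceed_truncation(self):
        biased = inject_bias(np.full(5, 4.3), 0, 50.0)
        assert (biased > 6.0).all()


class TestSingleSimulation:
    def test_simple_ma_closed_form_delay(self):
        """Constant stream at 140, n=25, limits 137-142, +4%: 9 results."""
        run = run_single_simulation(
            np.full(800, 140.0),
            MAConfig(algorithm="simple", batch_size=25),
            ControlLimits(137.0, 142.0),
            injection_index=400,
            bias_percent=4.0,
        )
        assert run.n_to_detection == run.n_accepted_to_detection == 9

    def test_ewma_closed_form_delay(self):
        """Constant 4.3, lambda 0.1, limits 3.9-4.8, +18%: 10 results."""
        run = run_single_simulation(
            np.full(800, 4.3),
            MAConfig(algorithm="ewma", weighting_factor=0.1, init_value=4.3),
            ControlLimits(3.9, 4.8),
            injection_index=400,
            bias_percent=18.0,
        )
        assert run.n_to_detection == 10

    def test_truncation_censors_gross_positive_bias(self):
        """+50% pushes every potassium result above the 6.0 limit: no detection."""
        run = run_single_simulation(
            np.full(800, 4.3),
            MAConfig(
                algorithm="ewma", weighting_factor=0.1, init_value=4.3,
                truncation=TruncationLimits(upper=6.0),
            ),
            ControlLimits(3.9, 4.8),
            injection_index=400,
            bias_percent=50.0,
        )
        assert run.censored
        assert run.n_to_detection is None

    def test_mismatched_limit_provenance_rejected(self, streams):
        cfg_a = MAConfig(algorithm="simple", batch_size=5)
        cfg_b = MAConfig(algorithm="simple", batch_size=10)
        limits = derive_control_limits(compute_ma_series(streams["sodium"], cfg_a))
        with pytest.raises(ConfigMismatchError):
            run_single_simulation(streams["sodium"], cfg_b, limits, 500, 10.0)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        seed=st.integers(0, 2**16),
        bias=st.sampled_from([-30.0, -10.0, -3.0, 3.0, 10.0, 30.0]),
        algorithm=st.sampled_from(["simple", "ewma"]),
        truncate=st.booleans(),
    )
    def test_engine_matches_stepwise_replay_oracle(self, seed, bias, algorithm, truncate):
        """The vectorised replay equals a one-result-at-a-time simulation."""
        rng = np.random.default_rng(seed)
        values = rng.normal(100, 5, 600)
        trunc = TruncationLimits(lower=88, upper=112) if truncate else TruncationLimits()
        if algorithm == "simple":
            cfg = MAConfig(algorithm="simple", batch_size=10, truncation=trunc)
        else:
            cfg = MAConfig(algorithm="ewma", weighting_factor=0.1, truncation=trunc)
        limits = derive_control_limits(compute_ma_series(values, cfg))
        run = run_single_simulation(values, cfg, limits, 300, bias, window=300)
        expected = oracle_replay_run(values, cfg, limits, 300, bias, 300)
        assert (run.n_to_detection, run.n_accepted_to_detection) == expected

    def test_counting_consistency(self, streams):
        """Accepted count never exceeds the presented count; equal without truncation."""
        stream = streams["potassium"]
        cfg_plain = MAConfig(algorithm="ewma", weighting_factor=0.1)
        lim = derive_control_limits(compute_ma_series(stream, cfg_plain))
        run = run_single_simulation(stream, cfg_plain, lim, 800, 20.0)
        assert run.n_accepted_to_detection == run.n_to_detection
        cfg_trunc = MAConfig(
            algorithm="ewma", weighting_factor=0.1, truncation=TruncationLimits(upper=6.0)
        )
        lim_t = derive_control_limits(compute_ma_series(stream, cfg_trunc))
        for inj in (800, 1600, 2400):
            r = run_single_simulation(stream, cfg_trunc, lim_t, inj, 20.0)
            if not r.censored:
                assert r.n_accepted_to_detection <= r.n_to_detection


class TestSummaries:
    def test_median_min_max(self):
        runs = [
            InjectionRun(400 * (i + 1), 18.0, n, n) for i, n in enumerate([4, 8, 13])
        ]
        s = summarize_runs(runs)
        assert (s.median_n, s.min_n, s.max_n) == (8, 4, 13)
        assert s.n_detected == s.n_runs == 3

    def test_even_count_median_is_mean_of_central_pair(self):
        runs = [InjectionRun(0, 5.0, n, n) for n in [2, 4, 8, 100]]
        assert summarize_runs(runs).median_n == 6.0

    def test_all_censored(self):
        runs = [InjectionRun(0, 1.0, None, None) for _ in range(4)]
        s = summarize_runs(runs)
        assert s.n_detected == 0 and s.median_n is None and s.max_n is None

    def test_matches_sort_oracle(self, rng):
        ns = rng.integers(1, 400, 100)
        runs = [InjectionRun(0, 9.0, int(n), int(n)) for n in ns]
        s = summarize_runs(runs)
        srt = np.sort(ns)
        assert s.min_n == srt[0] and s.max_n == srt[-1]
        assert s.median_n == (srt[49] + srt[50]) / 2

    def test_mixed_bias_levels_rejected(self):
        with pytest.raises(ValueError):
            summarize_runs([InjectionRun(0, 1.0, 2, 2), InjectionRun(0, 2.0, 2, 2)])


class TestBiasGridSimulation:
    def test_block_structure_yields_expected_injection_count(self, streams):
        stream = streams["sodium"]
        cfg = MAConfig(algorithm="simple", batch_size=25)
        limits = derive_control_limits(compute_ma_series(stream, cfg))
        summaries = simulate_bias_grid(
            stream, cfg, limits, BiasGrid(percentages=(10.0,)), block=400
        )
        assert summaries[0].n_runs == len(stream) // 400 - 1

    def test_zero_bias_grid_all_censored(self, streams):
        stream = streams["albumin"]
        cfg = MAConfig(algorithm="simple", batch_size=10)
        limits = derive_control_limits(compute_ma_series(stream, cfg))
        summaries = simulate_bias_grid(
            stream, cfg, limits, BiasGrid(percentages=(0.0,)), block=400
        )
        assert summaries[0].n_detected == 0

    def test_short_stream_rejected(self):
        cfg = MAConfig(algorithm="simple", batch_size=5)
        with pytest.raises(ValueError):
            simulate_bias_grid(
                np.full(500, 1.0), cfg, ControlLimits(0, 2),
                BiasGrid(percentages=(5.0,)), block=400,
            )

    def test_direction_monotonicity_without_truncation(self, streams):
        """With every run detected, the median never grows with |bias|."""
        stream = streams["sodium"]
        cfg = MAConfig(algorithm="simple", batch_size=25)
        limits = derive_control_limits(compute_ma_series(stream, cfg))
        grid = BiasGrid(percentages=(3.0, 5.0, 10.0, 20.0, 30.0, 50.0))
        summaries = simulate_bias_grid(stream, cfg, limits, grid)
        assert all(s.n_detected == s.n_runs for s in summaries)
        meds = [s.median_n for s in summaries]
        assert all(a >= b for a, b in zip(meds, meds[1:]))
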