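"""Rank candidate MA procedures for potassium by the two selection criteria.

A feasible procedure must (a) detect a bias the size of the allowable
total error (TEa, here 18%) within one day's volume in every simulated
run, and (b) keep detecting every larger bias within a day.  Among
feasible candidates, faster TEa detection wins.
"""

from pbrtqc import (
    BiasGrid,
    MAConfig,
    OptimizationCriteria,
    TruncationLimits,
    build_validation_chart,
    builtin_profiles,
    compute_ma_series,
    derive_control_limits,
    generate_stream,
    rank_candidates,
    simulate_bias_grid,
)

profile = builtin_profiles()["potassium"]
stream = generate_stream(profile, n_days=121, seed=2)
grid = BiasGrid.default(tea_percent=17.97)

candidates = [
    MAConfig(algorithm="simple", batch_size=25),
    MAConfig(algorithm="ewma", weighting_factor=0.1),
    MAConfig(algorithm="ewma", weighting_factor=0.1, truncation=TruncationLimits(upper=6.0)),
    MAConfig(algorithm="ewma", weighting_factor=0.02),
]
charts, configs = [], {}
for cfg in candidates:
    limits = derive_control_limits(compute_ma_series(stream, cfg))
    summaries = simulate_bias_grid(stream, cfg, limits, grid)
    charts.append(build_validation_chart(summaries, cfg.key))
    configs[cfg.key] = cfg

criteria = OptimizationCriteria(tea_percent=17.97, daily_volume=profile.daily_volume)
for r in rank_candidates(charts, criteria, configs):
    status = "feasible" if r.feasible else "infeasible: " + "; ".join(r.report.reasons)
    print(
        f"rank {r.rank}: {r.config_id:26s} median at +TEa {r.median_at_plus_tea}, "
        f"-TEa {r.median_at_minus_tea}  [{status}]"
    )
print(
    "\nRank 1 is the procedure a laboratory with ~60 potassium results/day "
    "would adopt: it detects a clinically significant bias within a fraction "
    "of the daily workload without going blind to gross errors."
)
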