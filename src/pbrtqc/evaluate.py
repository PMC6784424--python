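"""Bias detection curves, validation charts and candidate ranking.

Two displays summarise a candidate MA procedure's simulation results:

* the *bias detection curve* — median number of results needed to detect
  each bias size, plotted against the bias percentage;
* the *validation chart* — per bias size, the median (bar) with minimum
  and maximum (error bars) results-to-detection, i.e. the full worst-case
  picture of the procedure.

Candidates are ranked against two optimisation criteria: the procedure
must (a) detect a bias the size of the allowable total error (TEa, the
clinically significant bias) within one day's test volume in every
simulated run, and (b) remain able to detect every bias larger than the
TEa within a day — a procedure that detects the TEa quickly but goes blind
to gross errors is rejected outright.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from pydantic import BaseModel, Field

from .ma import MAConfig
from .simulate import DetectionSummary, round_tea

__all__ = [
    "BiasDetectionCurve",
    "ValidationChartData",
    "ChartRow",
    "OptimizationCriteria",
    "FeasibilityReport",
    "RankedCandidate",
    "IncompleteChartError",
    "build_bias_detection_curve",
    "build_validation_chart",
    "evaluate_candidate",
    "rank_candidates",
]


class IncompleteChartError(ValueError):
    """The chart lacks the ±TEa rows needed for feasibility evaluation."""


@dataclass(frozen=True)
class CurvePoint:
    bias_percent: float
    median_n: Optional[float]


@dataclass(frozen=True)
class BiasDetectionCurve:
    config_id: str
    points: tuple[CurvePoint, ...]

    def median_at(self, bias_percent: float) -> Optional[float]:
        for p in self.points:
            if p.bias_percent == bias_percent:
                return p.median_n
        raise KeyError(f"no point at bias {bias_percent}%")


@dataclass(frozen=True)
class ChartRow:
    bias_percent: float
    median_n: Optional[float]
    min_n: Optional[int]
    max_n: Optional[int]
    detected_fraction: float


@dataclass(frozen=True)
class ValidationChartData:
    config_id: str
    rows: tuple[ChartRow, ...]

    def row_at(self, bias_percent: float) -> ChartRow:
        for r in self.rows:
            if r.bias_percent == bias_percent:
                return r
        raise KeyError(f"no row at bias {bias_percent}%")

    def has_bias(self, bias_percent: float) -> bool:
        return any(r.bias_percent == bias_percent for r in self.rows)


def build_bias_detection_curve(
    summaries: Sequence[DetectionSummary], config_id: str
) -> BiasDetectionCurve:
    """One curve point per bias level, ordered by bias percentage."""
    seen = {}
    for s in summaries:
        if s.bias_percent in seen:
            raise ValueError(f"duplicate summary at bias {s.bias_percent}%")
        seen[s.bias_percent] = s
    points = tuple(
        CurvePoint(bias, seen[bias].median_n) for bias in sorted(seen)
    )
    return BiasDetectionCurve(config_id=config_id, points=points)


def build_validation_chart(
    summaries: Sequence[DetectionSummary], config_id: str
) -> ValidationChartData:
    """Median/min/max and detected fraction per bias level."""
    rows = tuple(
        ChartRow(
            bias_percent=s.bias_percent,
            median_n=s.median_n,
            min_n=s.min_n,
            max_n=s.max_n,
            detected_fraction=s.detected_fraction,
        )
        for s in sorted(summaries, key=lambda s: s.bias_percent)
    )
    return ValidationChartData(config_id=config_id, rows=rows)


class OptimizationCriteria(BaseModel):
    """The two selection criteria for an acceptable MA procedure."""

    tea_percent: float = Field(gt=0.0)
    daily_volume: int = Field(ge=1)
    require_all_larger_biases: bool = True

    @property
    def tea_bias(self) -> int:
        return round_tea(self.tea_percent)


@dataclass(frozen=True)
class FeasibilityReport:
    config_id: str
    tea_detectable_within_day: bool
    large_bias_safe: bool
    feasible: bool
    reasons: tuple[str, ...] = ()


def _row_within_day(row: ChartRow, daily_volume: int) -> bool:
    return row.detected_fraction == 1.0 and row.max_n is not None and row.max_n <= daily_volume


def evaluate_candidate(
    chart: ValidationChartData, criteria: OptimizationCriteria
) -> FeasibilityReport:
    """Apply both optimisation criteria to one candidate's chart.

    A bias level counts as reliably detected when every simulated run
    alarmed and the worst case stayed within one day's volume.
    """
    tea = criteria.tea_bias
    if not (chart.has_bias(tea) and chart.has_bias(-tea)):
        raise IncompleteChartError(
            f"chart {chart.config_id!r} lacks the ±{tea}% (TEa) rows"
        )
    reasons = []
    tea_ok = True
    for sign in (1, -1):
        row = chart.row_at(sign * tea)
        if not _row_within_day(row, criteria.daily_volume):
            tea_ok = False
            reasons.append(
                f"TEa bias {sign * tea:+d}% not reliably detected within "
                f"{criteria.daily_volume} results"
            )
    large_ok = True
    for row in chart.rows:
        if abs(row.bias_percent) > tea and not _row_within_day(row, criteria.daily_volume):
            large_ok = False
            reasons.append(
                f"bias {row.bias_percent:+g}% (> TEa) not reliably detected within "
                f"{criteria.daily_volume} results"
            )
    feasible = tea_ok and (large_ok or not criteria.require_all_larger_biases)
    return FeasibilityReport(
        config_id=chart.config_id,
        tea_detectable_within_day=tea_ok,
        large_bias_safe=large_ok,
        feasible=feasible,
        reasons=tuple(reasons),
    )


@dataclass(frozen=True)
class RankedCandidate:
    rank: int
    config_id: str
    feasible: bool
    report: FeasibilityReport
    median_at_plus_tea: Optional[float]
    median_at_minus_tea: Optional[float]


_INF = float("inf")


def _config_simplicity(config: Optional[MAConfig]) -> tuple:
    """Tie-break key: fewer truncation limits, then larger λ / smaller n."""
    if config is None:
        return (0, 0.0)
    trunc = config.truncation.n_limits
    if config.algorithm == "ewma":
        return (trunc, -config.weighting_factor)
    return (trunc, float(config.batch_size))


def rank_candidates(
    charts: Sequence[ValidationChartData],
    criteria: OptimizationCriteria,
    configs: Optional[dict[str, MAConfig]] = None,
) -> list[RankedCandidate]:
    """Deterministic ranking of candidate procedures.

    Feasible candidates come first, ordered by speed at the clinically
    significant bias: ascending median at +TEa, then at −TEa, then by the
    worst median over all |bias| ≥ TEa levels; remaining ties go to the
    simpler configuration (fewer truncation limits, then larger weighting
    factor / smaller batch size) and finally the config id.  ``configs``
    maps config ids to their :class:`~pbrtqc.ma.MAConfig` for the
    simplicity tie-break; without it the id alone breaks ties.
    """
    if not charts:
        raise ValueError("need at least one candidate")
    tea = criteria.tea_bias
    keyed = []
    for chart in charts:
        report = evaluate_candidate(chart, criteria)
        med_plus = chart.row_at(tea).median_n
        med_minus = chart.row_at(-tea).median_n
        worst = max(
            (
                r.median_n
                for r in chart.rows
                if abs(r.bias_percent) >= tea and r.median_n is not None
            ),
            default=_INF,
        )
        if any(
            abs(r.bias_percent) >= tea and r.median_n is None for r in chart.rows
        ):
            worst = _INF
        config = (configs or {}).get(chart.config_id)
        sort_key = (
            not report.feasible,
            med_plus if med_plus is not None else _INF,
            med_minus if med_minus is not None else _INF,
            worst,
            _config_simplicity(config),
            chart.config_id,
        )
        keyed.append((sort_key, chart, report, med_plus, med_minus))
    keyed.sort(key=lambda item: item[0])
    return [
        RankedCandidate(
            rank=i + 1,
            config_id=chart.config_id,
            feasible=report.feasible,
            report=report,
            median_at_plus_tea=med_plus,
            median_at_minus_tea=med_minus,
        )
        for i, (_, chart, report, med_plus, med_minus) in enumerate(keyed)
    ]
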