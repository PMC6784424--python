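"""Bias-injection simulation: how many results until the MA alarms?

A systematic analytical error is emulated by multiplying every patient
result from an injection point onward by ``1 + bias/100`` and replaying the
stream through the MA procedure whose control limits were derived on the
unbiased data.  The figure of merit is the number of results presented
after injection until the first alarm — the count of patient results that
would leave the laboratory before the error is noticed.  Injections are
repeated at the start of each consecutive block of results (block size 400
by default) and summarised per bias size by median, minimum and maximum
over the detected runs.

Truncation interacts with bias in an important way: a large bias can push
results *outside* the truncation limits, so they never reach the average
and detection stalls — the reason tight truncation limits can blind a
procedure to exactly the gross errors it should catch.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .ma import (
    ControlLimits,
    MAConfig,
    apply_truncation,
    ma_values_at_accepted_ewma,
    ma_values_at_accepted_simple,
    resolve_init,
)

__all__ = [
    "BiasGrid",
    "InjectionRun",
    "DetectionSummary",
    "ConfigMismatchError",
    "round_tea",
    "inject_bias",
    "run_single_simulation",
    "simulate_bias_grid",
    "summarize_runs",
    "DEFAULT_BLOCK",
]

DEFAULT_BLOCK = 400
_BASE_BIAS_MAGNITUDES = (50, 40, 30, 20, 10, 5, 3, 1)


class ConfigMismatchError(ValueError):
    """Control limits were derived under a different procedure."""


def round_tea(tea_percent: float) -> int:
    """Round an allowable-total-error percentage to the nearest integer.

    Half-values round away from zero, so a TEa of 17.97% becomes an
    injected bias of 18% and 3.57% becomes 4%.
    """
    if tea_percent <= 0:
        raise ValueError("TEa must be positive")
    return int(math.floor(tea_percent + 0.5))


@dataclass(frozen=True)
class BiasGrid:
    """Signed bias percentages to inject, optionally including ±TEa."""

    percentages: tuple[float, ...]
    tea_percent: Optional[int] = None

    @classmethod
    def default(cls, tea_percent: Optional[float] = None) -> "BiasGrid":
        """±{50, 40, 30, 20, 10, 5, 3, 1}%, plus ±TEa where distinct."""
        mags = set(_BASE_BIAS_MAGNITUDES)
        tea = None
        if tea_percent is not None:
            tea = round_tea(tea_percent)
            mags.add(tea)
        signed = sorted({s * m for m in mags for s in (-1, 1)})
        return cls(percentages=tuple(float(p) for p in signed), tea_percent=tea)

    @property
    def includes_tea(self) -> bool:
        return self.tea_percent is not None


@dataclass(frozen=True)
class InjectionRun:
    """Outcome of one bias injection at one point of the stream.

    ``n_to_detection`` counts every result presented after injection up to
    and including the alarming one (truncation-rejected results included —
    they are patient results released while the error is active);
    ``n_accepted_to_detection`` counts only the accepted ones.  Both are
    ``None`` when no alarm occurred within ``window`` results (censored).
    """

    injection_index: int
    bias_percent: float
    n_to_detection: Optional[int]
    n_accepted_to_detection: Optional[int]
    window: int = DEFAULT_BLOCK

    @property
    def censored(self) -> bool:
        return self.n_to_detection is None


@dataclass(frozen=True)
class DetectionSummary:
    """Median/min/max results-to-detection over the detected runs at one bias."""

    bias_percent: float
    median_n: Optional[float]
    min_n: Optional[int]
    max_n: Optional[int]
    n_runs: int
    n_detected: int

    @property
    def detected_fraction(self) -> float:
        return self.n_detected / self.n_runs if self.n_runs else 0.0


def inject_bias(values: np.ndarray, start: int, bias_percent: float) -> np.ndarray:
    """Multiply every value at and after ``start`` by ``1 + bias/100``."""
    values = np.asarray(values, dtype=float)
    if not 0 <= start <= len(values):
        raise ValueError(f"injection start {start} outside stream of length {len(values)}")
    out = values.copy()
    out[start:] *= 1.0 + bias_percent / 100.0
    return out


class _ReplayState:
    """Precomputed unbiased-prefix state so repeated injections are cheap.

    For the simple MA the state before index ``i`` is the tail of (at most)
    ``n`` accepted values; for the EWMA it is the z value after the last
    accepted result before ``i``.  Both are read off arrays computed once
    for the whole stream.
    """

    def __init__(self, values: np.ndarray, config: MAConfig):
        self.values = np.asarray(values, dtype=float)
        self.config = config
        self.mask = apply_truncation(self.values, config.truncation)
        self.accepted_idx = np.flatnonzero(self.mask)
        self.accepted_values = self.values[self.accepted_idx]
        if config.algorithm == "ewma":
            self.init = resolve_init(self.values, self.mask, config)
            self.z_after = ma_values_at_accepted_ewma(
                self.accepted_values, config.weighting_factor, self.init
            )
        else:
            self.init = None
            self.z_after = None

    def n_accepted_before(self, index: int) -> int:
        return int(np.searchsorted(self.accepted_idx, index))

    def simple_tail(self, index: int) -> np.ndarray:
        n = self.config.batch_size
        k = self.n_accepted_before(index)
        return self.accepted_values[max(0, k - n): k]

    def ewma_state(self, index: int) -> float:
        k = self.n_accepted_before(index)
        return self.init if k == 0 else float(self.z_after[k - 1])


def _first_alarm(ma_at_accepted: np.ndarray, limits: ControlLimits) -> Optional[int]:
    with np.errstate(invalid="ignore"):
        alarm = (ma_at_accepted > limits.upper) | (ma_at_accepted < limits.lower)
    hits = np.flatnonzero(alarm)
    return int(hits[0]) if len(hits) else None


def _run_from_state(
    state: _ReplayState,
    limits: ControlLimits,
    injection_index: int,
    bias_percent: float,
    window: int,
) -> InjectionRun:
    config = state.config
    segment = state.values[injection_index: injection_index + window] * (
        1.0 + bias_percent / 100.0
    )
    seg_mask = apply_truncation(segment, config.truncation)
    seg_accepted_pos = np.flatnonzero(seg_mask)
    seg_accepted = segment[seg_accepted_pos]

    if config.algorithm == "simple":
        n = config.batch_size
        tail = state.simple_tail(injection_index)
        combined = np.concatenate([tail, seg_accepted])
        ma_combined = ma_values_at_accepted_simple(combined, n)
        ma_new = ma_combined[len(tail):]
        # a window still containing only pre-injection values cannot alarm
        # differently from the unbiased replay, so checking from the first
        # biased accepted value onward is exhaustive
    else:
        z0 = state.ewma_state(injection_index)
        ma_new = ma_values_at_accepted_ewma(
            seg_accepted, config.weighting_factor, z0
        )

    hit = _first_alarm(ma_new, limits)
    if hit is None:
        return InjectionRun(injection_index, bias_percent, None, None, window)
    return InjectionRun(
        injection_index=injection_index,
        bias_percent=bias_percent,
        n_to_detection=int(seg_accepted_pos[hit]) + 1,
        n_accepted_to_detection=hit + 1,
        window=window,
    )


def _check_limits(config: MAConfig, limits: ControlLimits) -> None:
    if limits.config_key is not None and limits.config_key != config.key:
        raise ConfigMismatchError(
            f"control limits were derived under {limits.config_key!r}, "
            f"not {config.key!r}"
        )


def run_single_simulation(
    stream,
    config: MAConfig,
    limits: ControlLimits,
    injection_index: int,
    bias_percent: float,
    window: int = DEFAULT_BLOCK,
) -> InjectionRun:
    """Inject one bias at one point and count results to the first alarm.

    The unbiased stream up to ``injection_index`` establishes the MA state
    (truncation applied); from there results are biased, truncation is
    evaluated on the *biased* value, the MA updates on accepted results
    and the alarm is checked after each update.  ``limits`` must belong to
    the same procedure when their provenance is known.
    """
    _check_limits(config, limits)
    values = stream.values if hasattr(stream, "values") and not isinstance(stream, np.ndarray) else np.asarray(stream, dtype=float)
    if injection_index + 1 > len(values):
        raise ValueError("injection index beyond end of stream")
    state = _ReplayState(values, config)
    return _run_from_state(state, limits, injection_index, bias_percent, window)


def summarize_runs(runs: Sequence[InjectionRun]) -> DetectionSummary:
    """Aggregate runs sharing one bias: median/min/max over detected runs.

    The median of an even count is the mean of the two central values;
    censored runs contribute to ``n_runs`` only.
    """
    biases = {r.bias_percent for r in runs}
    if len(biases) != 1:
        raise ValueError(f"runs mix bias levels: {sorted(biases)}")
    detected = [r.n_to_detection for r in runs if not r.censored]
    if detected:
        return DetectionSummary(
            bias_percent=biases.pop(),
            median_n=float(statistics.median(detected)),
            min_n=min(detected),
            max_n=max(detected),
            n_runs=len(runs),
            n_detected=len(detected),
        )
    return DetectionSummary(
        bias_percent=biases.pop(),
        median_n=None,
        min_n=None,
        max_n=None,
        n_runs=len(runs),
        n_detected=0,
    )


def simulate_bias_grid(
    stream,
    config: MAConfig,
    limits: ControlLimits,
    grid: BiasGrid,
    block: int = DEFAULT_BLOCK,
    return_runs: bool = False,
):
    """Run the full bias grid over block-start injection points.

    The stream is cut into consecutive non-overlapping blocks of ``block``
    results; each block start from the second block onward is an injection
    point (the first block only warms the MA state), and the detection
    window equals the block size.  Returns one :class:`DetectionSummary`
    per bias level, ordered as in the grid; with ``return_runs`` the raw
    :class:`InjectionRun` list comes back too.
    """
    _check_limits(config, limits)
    values = stream.values if hasattr(stream, "values") and not isinstance(stream, np.ndarray) else np.asarray(stream, dtype=float)
    if len(values) < 2 * block:
        raise ValueError(
            f"stream of {len(values)} results is shorter than two blocks of {block}"
        )
    n_blocks = len(values) // block
    injection_points = [b * block for b in range(1, n_blocks)]

    state = _ReplayState(values, config)
    summaries, all_runs = [], []
    for bias in grid.percentages:
        runs = [
            _run_from_state(state, limits, i, bias, block) for i in injection_points
        ]
        summaries.append(summarize_runs(runs))
        all_runs.extend(runs)
    if return_runs:
        return summaries, all_runs
    return summaries
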