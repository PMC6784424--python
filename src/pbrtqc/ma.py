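"""Moving-average engine: truncation, simple MA, EWMA, control limits, alarms.

The QC signal is a moving average recalculated every time a patient result
arrives.  Two algorithms are supported:

* simple MA — the unweighted mean of the last ``n`` accepted results
  (``n`` is the batch size); undefined until a full batch has accrued;
* EWMA — the recursion ``z <- lambda*x + (1-lambda)*z`` with weighting
  factor ``lambda`` in (0, 1), started from a configurable value
  (by default the mean of the accepted historical population).

Truncation limits act as inclusion criteria on raw results: a value outside
the (inclusive) limits is an outlier and never enters the average; at such
positions the series simply carries its previous value forward.  Control
limits are the minimum and maximum the MA attains on unbiased historical
data — replaying that same data can therefore never alarm, because an alarm
requires *strict* exceedance of a limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.signal import lfilter

__all__ = [
    "TruncationLimits",
    "MAConfig",
    "MASeries",
    "ControlLimits",
    "EmptySeriesError",
    "apply_truncation",
    "compute_simple_ma",
    "compute_ewma",
    "compute_ma_series",
    "derive_control_limits",
    "check_alarm",
]

#: batch sizes and weighting factors conventionally screened when
#: optimising a procedure
DEFAULT_BATCH_SIZES = (5, 10, 25, 50, 100)
DEFAULT_WEIGHTING_FACTORS = (0.2, 0.1, 0.05, 0.02)


class EmptySeriesError(ValueError):
    """Raised when a stream yields no accepted values to average."""


class TruncationLimits(BaseModel):
    """Inclusive concentration range admitted to the MA calculation."""

    lower: Optional[float] = None
    upper: Optional[float] = None

    @model_validator(mode="after")
    def _ordered(self) -> "TruncationLimits":
        if self.lower is not None and self.upper is not None and not self.lower < self.upper:
            raise ValueError(f"truncation lower {self.lower} must be < upper {self.upper}")
        return self

    @property
    def is_trivial(self) -> bool:
        return self.lower is None and self.upper is None

    @property
    def n_limits(self) -> int:
        return (self.lower is not None) + (self.upper is not None)

    def label(self) -> str:
        if self.is_trivial:
            return "none"
        lo = "" if self.lower is None else f"{self.lower:g}le"
        hi = "" if self.upper is None else f"le{self.upper:g}"
        return lo + hi


class MAConfig(BaseModel):
    """One candidate MA procedure: algorithm, its parameter and truncation."""

    algorithm: Literal["simple", "ewma"]
    batch_size: Optional[int] = Field(default=None, ge=1)
    weighting_factor: Optional[float] = Field(default=None, gt=0.0, lt=1.0)
    truncation: TruncationLimits = Field(default_factory=TruncationLimits)
    init_value: Union[float, Literal["population_mean"]] = "population_mean"

    @model_validator(mode="after")
    def _one_parameter(self) -> "MAConfig":
        if self.algorithm == "simple":
            if self.batch_size is None or self.weighting_factor is not None:
                raise ValueError("simple MA takes batch_size and no weighting_factor")
        else:
            if self.weighting_factor is None or self.batch_size is not None:
                raise ValueError("EWMA takes weighting_factor and no batch_size")
        return self

    @property
    def key(self) -> str:
        """Stable identifier, e.g. ``simple_n25_trunc_none``."""
        if self.algorithm == "simple":
            core = f"simple_n{self.batch_size}"
        else:
            core = f"ewma_l{self.weighting_factor:g}"
        return f"{core}_trunc_{self.truncation.label()}"


@dataclass
class MASeries:
    """Per-result MA trace aligned with the input stream.

    ``accepted[i]`` says whether result ``i`` passed truncation; ``ma[i]``
    is the MA value in force after result ``i`` (NaN while undefined).  The
    MA only changes at accepted positions; rejected positions carry the
    previous value forward.
    """

    values: np.ndarray
    accepted: np.ndarray
    ma: np.ndarray
    config: Optional[MAConfig] = None

    def __len__(self) -> int:
        return len(self.values)

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.ma)

    def defined_values(self) -> np.ndarray:
        return self.ma[self.defined]

    def to_frame(
        self,
        timestamps: Optional[pd.Series] = None,
        limits: Optional["ControlLimits"] = None,
    ) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "index": np.arange(len(self.values)),
                "timestamp": timestamps if timestamps is not None else pd.NaT,
                "value": self.values,
                "accepted": self.accepted,
                "ma_value": self.ma,
            }
        )
        if limits is not None:
            with np.errstate(invalid="ignore"):
                frame["alarm"] = (self.ma > limits.upper) | (self.ma < limits.lower)
            frame.loc[~self.defined, "alarm"] = False
        return frame


@dataclass(frozen=True)
class ControlLimits:
    """Alarm thresholds: the extrema of the MA on unbiased historical data.

    ``config_key`` records which procedure the limits were derived under;
    limits constructed by hand (e.g. taken from a published table) carry
    ``None`` there.
    """

    lower: float
    upper: float
    config_key: Optional[str] = None

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError(f"control limits out of order: {self.lower} > {self.upper}")


def apply_truncation(values: np.ndarray, limits: TruncationLimits) -> np.ndarray:
    """Boolean acceptance mask; both limits are inclusive."""
    values = np.asarray(values, dtype=float)
    mask = np.ones(values.shape, dtype=bool)
    if limits.lower is not None:
        mask &= values >= limits.lower
    if limits.upper is not None:
        mask &= values <= limits.upper
    return mask


def _scatter_and_carry(n_total: int, accepted_idx: np.ndarray, ma_at_accepted: np.ndarray) -> np.ndarray:
    """Place per-accepted MA values into a full-length trace with carry-forward."""
    out = np.full(n_total, np.nan)
    out[accepted_idx] = ma_at_accepted
    if n_total:
        out = pd.Series(out).ffill().to_numpy()
    return out


def ma_values_at_accepted_simple(accepted_values: np.ndarray, n: int) -> np.ndarray:
    """Simple-MA value after each accepted result (NaN until n have accrued)."""
    acc = np.asarray(accepted_values, dtype=float)
    out = np.full(len(acc), np.nan)
    if len(acc) >= n:
        cs = np.concatenate(([0.0], np.cumsum(acc)))
        out[n - 1:] = (cs[n:] - cs[:-n]) / n
    return out


def ma_values_at_accepted_ewma(accepted_values: np.ndarray, lam: float, init: float) -> np.ndarray:
    """EWMA value after each accepted result, via the linear recursion."""
    acc = np.asarray(accepted_values, dtype=float)
    if len(acc) == 0:
        return acc.copy()
    z, _ = lfilter([lam], [1.0, -(1.0 - lam)], acc, zi=[(1.0 - lam) * init])
    return z


def compute_simple_ma(values: np.ndarray, mask: np.ndarray, n: int) -> MASeries:
    """Simple MA of batch size ``n`` over the accepted results of ``values``."""
    if n < 1:
        raise ValueError("batch size must be >= 1")
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    idx = np.flatnonzero(mask)
    ma_acc = ma_values_at_accepted_simple(values[idx], n)
    return MASeries(values=values, accepted=mask, ma=_scatter_and_carry(len(values), idx, ma_acc))


def compute_ewma(values: np.ndarray, mask: np.ndarray, lam: float, init: float) -> MASeries:
    """EWMA with weighting factor ``lam`` started from ``init``."""
    if not 0.0 < lam < 1.0:
        raise ValueError("weighting factor must lie in (0, 1)")
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    idx = np.flatnonzero(mask)
    ma_acc = ma_values_at_accepted_ewma(values[idx], lam, init)
    return MASeries(values=values, accepted=mask, ma=_scatter_and_carry(len(values), idx, ma_acc))


def resolve_init(values: np.ndarray, mask: np.ndarray, config: MAConfig) -> float:
    """EWMA starting value: explicit number, or the accepted-population mean."""
    if config.init_value == "population_mean":
        accepted = np.asarray(values, dtype=float)[np.asarray(mask, dtype=bool)]
        if len(accepted) == 0:
            raise EmptySeriesError("no accepted values to form the population-mean start")
        return float(accepted.mean())
    return float(config.init_value)


def compute_ma_series(stream, config: MAConfig) -> MASeries:
    """Truncation followed by the configured algorithm over a stream.

    ``stream`` may be a :class:`~pbrtqc.streams.ResultStream` or a plain
    array of values.
    """
    values = stream.values if hasattr(stream, "values") and not isinstance(stream, np.ndarray) else np.asarray(stream, dtype=float)
    mask = apply_truncation(values, config.truncation)
    if not mask.any():
        raise EmptySeriesError("truncation rejected every value in the stream")
    if config.algorithm == "simple":
        series = compute_simple_ma(values, mask, config.batch_size)
    else:
        init = resolve_init(values, mask, config)
        series = compute_ewma(values, mask, config.weighting_factor, init)
    series.config = config
    return series


def derive_control_limits(series: MASeries) -> ControlLimits:
    """Min/max of the defined MA values, stamped with the series' config."""
    defined = series.defined_values()
    if len(defined) == 0:
        raise EmptySeriesError("series has no defined MA value to derive limits from")
    return ControlLimits(
        lower=float(defined.min()),
        upper=float(defined.max()),
        config_key=series.config.key if series.config is not None else None,
    )


def check_alarm(ma_value: float, limits: ControlLimits) -> bool:
    """Strict exceedance: a value equal to a limit does not alarm."""
    if math.isnan(ma_value):
        raise ValueError("alarm check needs a defined MA value")
    return ma_value > limits.upper or ma_value < limits.lower
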