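"""LIS-like result streams: generation, summarisation and CSV round-trip.

A :class:`ResultStream` is the ordered sequence of patient results for one
analyte, each with a second-resolution timestamp, exactly as a laboratory
information system would export it with the analyser measurement order
preserved.  Streams are generated per working day: the day's result count
is Poisson around the profile's daily volume, collection times fall within
working hours, and values come from the quantile-matched mixture of
:func:`pbrtqc.profiles.fit_profile_params`, clipped to a 10% margin around
the profile's observed range.
"""

from __future__ import annotations

import datetime as _dt
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .profiles import AnalyteProfile, fit_profile_params

__all__ = [
    "ResultStream",
    "StreamSummary",
    "EmptyStreamError",
    "generate_stream",
    "summarize_stream",
]

WORKDAY_START_S = 7 * 3600   # 07:00 local
WORKDAY_END_S = 15 * 3600    # 15:00 local
DEFAULT_START_DATE = _dt.date(2024, 1, 1)


class EmptyStreamError(ValueError):
    """Raised when an operation needs at least one result."""


@dataclass
class ResultStream:
    """Ordered patient results for one analyte.

    ``frame`` has columns ``timestamp`` (datetime64, second resolution) and
    ``value`` (float, analyte units); rows are non-decreasing in timestamp.
    ``meta`` records provenance (seed, profile name) and is written as
    ``# key=value`` comment lines ahead of the CSV header.
    """

    analyte: str
    frame: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ts = self.frame["timestamp"]
        if len(ts) > 1 and not ts.is_monotonic_increasing:
            raise ValueError("result stream timestamps must be non-decreasing")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def values(self) -> np.ndarray:
        return self.frame["value"].to_numpy(dtype=float)

    @property
    def timestamps(self) -> pd.Series:
        return self.frame["timestamp"]

    def to_csv(self, path: Union[str, Path]) -> None:
        path = Path(path)
        with path.open("w") as fh:
            for key, val in self.meta.items():
                fh.write(f"# {key}={val}\n")
            fh.write("timestamp,value\n")
            ts = self.frame["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
            for t, v in zip(ts, self.frame["value"]):
                fh.write(f"{t},{float(v)!r}\n")

    @classmethod
    def from_csv(cls, path: Union[str, Path], analyte: Optional[str] = None) -> "ResultStream":
        path = Path(path)
        meta: dict = {}
        with path.open() as fh:
            text_lines = []
            for line in fh:
                if line.startswith("#"):
                    body = line.lstrip("#").strip()
                    if "=" in body:
                        key, _, val = body.partition("=")
                        meta[key.strip()] = val.strip()
                else:
                    text_lines.append(line)
        frame = pd.read_csv(
            io.StringIO("".join(text_lines)),
            parse_dates=["timestamp"],
            float_precision="round_trip",
        )
        name = analyte or meta.get("analyte") or path.stem
        return cls(analyte=name, frame=frame, meta=meta)


def generate_stream(
    profile: AnalyteProfile,
    n_days: int,
    seed: int,
    start_date: _dt.date = DEFAULT_START_DATE,
    drift_amplitude: float = 0.0,
    drift_period_days: float = 30.0,
) -> ResultStream:
    """Generate a seeded LIS-like stream for ``profile`` over ``n_days``.

    Each day draws ``Poisson(daily_volume)`` results at sorted
    second-resolution times within working hours.  Values are i.i.d. from
    the fitted mixture by default; ``drift_amplitude`` adds an optional
    slow sinusoidal day-level multiplicative drift (fraction of the value,
    period ``drift_period_days``) for experiments that need day-to-day
    structure.  All values are clipped to ``[0.9*min, 1.1*max]``.
    Identical inputs and seed reproduce the stream exactly.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    mixture = fit_profile_params(profile)
    rng = np.random.default_rng(seed)

    counts = rng.poisson(profile.daily_volume, n_days)
    day_offsets = np.repeat(np.arange(n_days), counts)
    n_total = int(counts.sum())

    seconds = rng.integers(WORKDAY_START_S, WORKDAY_END_S, n_total)
    # sort within each day; day_offsets are already grouped and sorted
    order = np.lexsort((seconds, day_offsets))
    seconds = seconds[order]

    values = mixture.sample(rng, n_total)
    if drift_amplitude != 0.0:
        phase = 2.0 * np.pi * day_offsets / drift_period_days
        values = values * (1.0 + drift_amplitude * np.sin(phase))
    values = np.clip(values, 0.9 * profile.min_value, 1.1 * profile.max_value)

    base = pd.Timestamp(start_date)
    timestamps = base + pd.to_timedelta(day_offsets * 86400 + seconds, unit="s")
    frame = pd.DataFrame({"timestamp": timestamps, "value": values})
    meta = {
        "analyte": profile.name,
        "unit": profile.unit,
        "seed": seed,
        "n_days": n_days,
        "start_date": start_date.isoformat(),
    }
    return ResultStream(analyte=profile.name, frame=frame, meta=meta)


@dataclass(frozen=True)
class StreamSummary:
    n_results: int
    median: float
    q1: float
    q3: float
    min_value: float
    max_value: float
    mean_daily_count: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def summarize_stream(stream: ResultStream) -> StreamSummary:
    """Median/quartiles/extremes and mean daily count of a stream.

    The mean daily count divides the total number of results by the number
    of *distinct* calendar days present in the stream.
    """
    if len(stream) == 0:
        raise EmptyStreamError("cannot summarise an empty stream")
    values = stream.values
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])
    n_days = stream.frame["timestamp"].dt.normalize().nunique()
    return StreamSummary(
        n_results=len(stream),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        min_value=float(values.min()),
        max_value=float(values.max()),
        mean_daily_count=len(stream) / n_days,
    )
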