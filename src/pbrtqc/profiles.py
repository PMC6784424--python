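"""Analyte population profiles and quantile-matched distribution fitting.

A laboratory that wants to tune a moving-average QC procedure usually has
only summary statistics of its patient population (median, quartiles,
observed extremes, daily test volume).  This module turns such a profile
into a concrete sampling distribution: a continuous *core* matched exactly
to the median and interquartile range, mixed with a low-weight
*pathological tail* that reaches toward the observed minimum and maximum at
a configurable rate.  The fitted mixture is what :mod:`pbrtqc.streams` draws
from when emulating a laboratory information system.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy import stats

__all__ = [
    "SkewFamily",
    "AnalyteProfile",
    "FittedMixture",
    "ParameterizationError",
    "fit_profile_params",
    "builtin_profiles",
    "CLIA_TEA_PERCENT",
]

#: z-score of the upper quartile of a standard normal.
_Z75 = float(stats.norm.ppf(0.75))


class ParameterizationError(ValueError):
    """Raised when no member of the requested family can match a profile."""


class SkewFamily(str, Enum):
    symmetric = "symmetric"
    right_tailed = "right_tailed"
    left_tailed = "left_tailed"


class AnalyteProfile(BaseModel):
    """Distributional targets for one analyte's patient-result population.

    Concentrations are in the analyte's reporting unit (``unit``);
    ``daily_volume`` is the average number of results per working day.
    """

    name: str
    unit: str
    daily_volume: int = Field(ge=1)
    median: float
    q1: float
    q3: float
    min_value: float
    max_value: float
    skew_family: SkewFamily = SkewFamily.symmetric
    outlier_rate: float = Field(default=0.0, ge=0.0, lt=0.05)

    @model_validator(mode="after")
    def _check_quantile_order(self) -> "AnalyteProfile":
        if not (self.min_value <= self.q1 <= self.median <= self.q3 <= self.max_value):
            raise ValueError(
                "quantiles must satisfy min <= q1 <= median <= q3 <= max, got "
                f"{self.min_value}, {self.q1}, {self.median}, {self.q3}, {self.max_value}"
            )
        if self.min_value <= 0:
            raise ValueError("concentrations are positive; min_value must be > 0")
        return self

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


@dataclass(frozen=True)
class FittedMixture:
    """Sampling distribution fitted to an :class:`AnalyteProfile`.

    ``kind`` is one of ``constant``, ``truncnorm``, ``lognormal`` or
    ``mirrored_lognormal``.  For the log-normal kinds the variate is
    ``shift + sign * scale * exp(sigma * Z)`` with ``sign = -1`` for the
    mirrored (left-tailed) case; ``shift``/``scale``/``sigma`` are chosen so
    that the core median and quartiles equal the profile's exactly.  With
    probability ``outlier_rate`` a draw is replaced by a uniform
    "pathological" value on [min, max].
    """

    kind: str
    median: float
    shift: float = 0.0
    scale: float = 0.0
    sigma: float = 0.0
    loc: float = 0.0
    lower: float = 0.0
    upper: float = 0.0
    outlier_rate: float = 0.0

    def sample_core(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "constant":
            return np.full(size, self.median)
        if self.kind == "truncnorm":
            a = (self.lower - self.loc) / self.scale
            b = (self.upper - self.loc) / self.scale
            return stats.truncnorm.rvs(
                a, b, loc=self.loc, scale=self.scale, size=size, random_state=rng
            )
        draws = self.shift + self.scale * np.exp(self.sigma * rng.standard_normal(size))
        if self.kind == "mirrored_lognormal":
            return 2.0 * self.median - draws
        return draws

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Core draws with pathological-tail replacement at ``outlier_rate``."""
        values = self.sample_core(rng, size)
        if self.outlier_rate > 0.0:
            is_outlier = rng.random(size) < self.outlier_rate
            n_out = int(is_outlier.sum())
            if n_out:
                values[is_outlier] = rng.uniform(self.lower, self.upper, n_out)
        return values


def _fit_shifted_lognormal(median: float, q1: float, q3: float) -> tuple[float, float, float]:
    """Shift/scale/sigma matching three quantiles of a shifted log-normal.

    Solves median = shift + scale, q3 = shift + scale * r_hi,
    q1 = shift + scale / r_hi with r_hi = exp(sigma * z75); requires a
    genuinely right-tailed triple (q3 - median > median - q1 > 0).
    """
    upper_half = q3 - median
    lower_half = median - q1
    if lower_half <= 0 or upper_half <= 0:
        raise ParameterizationError(
            "log-normal family needs strictly positive spread on both sides of the median"
        )
    ratio = upper_half / lower_half
    if ratio <= 1.0:
        raise ParameterizationError(
            f"quantiles are not right-tailed (ratio {ratio:.4g} <= 1); "
            "use the symmetric family instead"
        )
    sigma = math.log(ratio) / _Z75
    scale = lower_half * ratio / (ratio - 1.0)
    shift = median - scale
    return shift, scale, sigma


def fit_profile_params(profile: AnalyteProfile) -> FittedMixture:
    """Fit the sampling mixture for a profile.

    The core family follows the declared skew: a shifted log-normal for
    right-tailed analytes (e.g. creatinine, whose maximum sits an order of
    magnitude above the median), its mirror image for mildly left-tailed
    ones (albumin), and a truncated normal for symmetric ones (sodium,
    potassium).  Median and IQR of the core match the profile exactly by
    construction.

    Raises
    ------
    ParameterizationError
        If the quantile triple is degenerate (q1 == q3 while the observed
        range is not) or contradicts the declared skew family.
    """
    if profile.q1 == profile.q3:
        if profile.min_value == profile.max_value == profile.median:
            return FittedMixture(kind="constant", median=profile.median)
        raise ParameterizationError(
            f"profile {profile.name!r} has zero IQR but a non-degenerate range "
            f"[{profile.min_value}, {profile.max_value}]; no continuous core can match"
        )

    if profile.skew_family is SkewFamily.right_tailed:
        shift, scale, sigma = _fit_shifted_lognormal(profile.median, profile.q1, profile.q3)
        return FittedMixture(
            kind="lognormal",
            median=profile.median,
            shift=shift,
            scale=scale,
            sigma=sigma,
            lower=profile.min_value,
            upper=profile.max_value,
            outlier_rate=profile.outlier_rate,
        )
    if profile.skew_family is SkewFamily.left_tailed:
        # Fit the reflection about the median, then mirror the draws back.
        shift, scale, sigma = _fit_shifted_lognormal(
            profile.median,
            2.0 * profile.median - profile.q3,
            2.0 * profile.median - profile.q1,
        )
        return FittedMixture(
            kind="mirrored_lognormal",
            median=profile.median,
            shift=shift,
            scale=scale,
            sigma=sigma,
            lower=profile.min_value,
            upper=profile.max_value,
            outlier_rate=profile.outlier_rate,
        )

    sigma = profile.iqr / (2.0 * _Z75)
    return FittedMixture(
        kind="truncnorm",
        median=profile.median,
        loc=profile.median,
        scale=sigma,
        lower=profile.min_value,
        upper=profile.max_value,
        outlier_rate=profile.outlier_rate,
    )


#: CLIA allowable total error, percent, as used for the clinically
#: significant bias of each packaged analyte.
CLIA_TEA_PERCENT = {
    "creatinine": 15.0,
    "potassium": 17.97,
    "sodium": 3.57,
    "albumin": 10.0,
}


def builtin_profiles() -> dict[str, AnalyteProfile]:
    """The four packaged analyte profiles of a small-volume outpatient lab.

    Creatinine stands in for a high-frequency test, sodium and potassium for
    moderately frequent ones and albumin for a low-frequency test; the
    summary statistics describe an adult primary-care population.  Outlier
    rates are the package's own defaults for how often pathological
    extremes appear in such a population.
    """
    return {
        "creatinine": AnalyteProfile(
            name="creatinine", unit="umol/L", daily_volume=121,
            median=70, q1=63, q3=80, min_value=26, max_value=971,
            skew_family=SkewFamily.right_tailed, outlier_rate=0.012,
        ),
        "potassium": AnalyteProfile(
            name="potassium", unit="mmol/L", daily_volume=60,
            median=4.3, q1=4.1, q3=4.6, min_value=2.8, max_value=7.4,
            skew_family=SkewFamily.symmetric, outlier_rate=0.006,
        ),
        "sodium": AnalyteProfile(
            name="sodium", unit="mmol/L", daily_volume=55,
            median=140, q1=139, q3=141, min_value=123, max_value=149,
            skew_family=SkewFamily.symmetric, outlier_rate=0.006,
        ),
        "albumin": AnalyteProfile(
            name="albumin", unit="g/L", daily_volume=20,
            median=43, q1=41, q3=44, min_value=20, max_value=52,
            skew_family=SkewFamily.left_tailed, outlier_rate=0.012,
        ),
    }
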