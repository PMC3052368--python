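"""Age-dependent responsiveness of adult-born granule neurons.

Adult-born dentate gyrus (DG) granule cells acquire a specific Arc-expression
response to spatial exploration once they are about 30 days old, and the
fraction of a cohort that responds declines as the cohort ages.  This module
fits the linear model

    P(age) = a + r * age

to (neuron age, fraction responding) observations by ordinary least squares,
where ``a`` is the extrapolated fraction at age 0 and ``r`` the change per
day.  For a declining line the extrapolated zero crossing ``-a/r`` is the
neuron age beyond which the model predicts no recruitment at all.

The default calibration points are the group-mean Arc-response fractions of
BrdU-birthdated cohorts measured 30, 45 and 150 days after birth (5.0%, 4.8%
and 2.8% of the cohort responding to a novel spatial exploration).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ResponsePoint",
    "LinearResponsivenessModel",
    "DEFAULT_RESPONSE_POINTS",
    "DEFAULT_MATURATION_AGE_DAYS",
    "fit_responsiveness",
    "zero_crossing_age",
    "response_probability",
    "read_response_points",
]

#: Neuron age (days) below which a cohort is treated as not yet recruitable.
#: The specific response to exploration develops between 30 and 45 days of
#: neuron age; before that, Arc expression is not behaviourally driven.
DEFAULT_MATURATION_AGE_DAYS = 30


@dataclass(frozen=True)
class ResponsePoint:
    """One (neuron age, fraction of the cohort responding) observation."""

    age_days: float
    fraction_responding: float

    def __post_init__(self) -> None:
        if self.age_days < 1:
            raise ValueError(f"age_days must be >= 1, got {self.age_days}")
        if not 0.0 <= self.fraction_responding <= 1.0:
            raise ValueError(
                "fraction_responding must lie in [0, 1], got "
                f"{self.fraction_responding}"
            )


#: Group-mean response fractions at neuron ages 30, 45 and 150 days — the
#: calibration data for the default model.
DEFAULT_RESPONSE_POINTS: tuple[ResponsePoint, ...] = (
    ResponsePoint(30, 0.050),
    ResponsePoint(45, 0.048),
    ResponsePoint(150, 0.028),
)


@dataclass(frozen=True)
class LinearResponsivenessModel:
    """Fitted line P(age) = intercept_at_birth + slope_per_day * age.

    ``zero_crossing_age_days`` is ``None`` when the fitted slope is not
    negative (the line never reaches zero forward in time).  Probabilities
    are fractions in [0, 1] throughout; conversion to percent happens only
    at I/O boundaries.
    """

    intercept_at_birth: float
    slope_per_day: float
    r_squared: float
    slope_p_value: float
    zero_crossing_age_days: float | None
    n_points: int
    maturation_age_days: float = DEFAULT_MATURATION_AGE_DAYS

    def __post_init__(self) -> None:
        if self.maturation_age_days <= 0:
            raise ValueError("maturation_age_days must be positive")

    def to_dict(self) -> dict:
        return {
            "intercept_at_birth": self.intercept_at_birth,
            "slope_per_day": self.slope_per_day,
            "r_squared": self.r_squared,
            "slope_p_value": self.slope_p_value,
            "zero_crossing_age_days": self.zero_crossing_age_days,
            "n_points": self.n_points,
            "maturation_age_days": self.maturation_age_days,
        }


def fit_responsiveness(
    points: Iterable[ResponsePoint | tuple[float, float]],
    maturation_age_days: float = DEFAULT_MATURATION_AGE_DAYS,
) -> LinearResponsivenessModel:
    """Ordinary-least-squares fit of the linear responsiveness model.

    Parameters
    ----------
    points
        At least two observations with at least two distinct ages.  Plain
        ``(age_days, fraction)`` tuples are accepted and validated.
    maturation_age_days
        Stored on the model; below this neuron age the recruitment-mode
        probability is zero (see :func:`response_probability`).

    Returns
    -------
    LinearResponsivenessModel
        With the coefficient of determination, the two-sided t-test p-value
        on the slope, and the zero crossing (``None`` unless the slope is
        negative).

    Raises
    ------
    ValueError
        If fewer than two distinct ages are supplied.
    """
    pts = [p if isinstance(p, ResponsePoint) else ResponsePoint(*p) for p in points]
    ages = np.array([p.age_days for p in pts], dtype=float)
    fractions = np.array([p.fraction_responding for p in pts], dtype=float)
    if len(pts) < 2 or np.unique(ages).size < 2:
        raise ValueError(
            "need at least 2 points with at least 2 distinct ages to fit a line"
        )

    res = stats.linregress(ages, fractions)
    slope, intercept = float(res.slope), float(res.intercept)
    # linregress leaves r undefined for zero response variance; a perfectly
    # flat input is an exact (if degenerate) fit.
    if np.allclose(fractions, fractions[0]):
        r_squared = 1.0
    else:
        r_squared = float(res.rvalue) ** 2
    p_value = float(res.pvalue) if math.isfinite(res.pvalue) else 1.0

    zero_crossing = -intercept / slope if slope < 0 else None
    return LinearResponsivenessModel(
        intercept_at_birth=intercept,
        slope_per_day=slope,
        r_squared=r_squared,
        slope_p_value=p_value,
        zero_crossing_age_days=zero_crossing,
        n_points=len(pts),
        maturation_age_days=maturation_age_days,
    )


def zero_crossing_age(model: LinearResponsivenessModel) -> float:
    """Neuron age at which the fitted line extrapolates to zero probability.

    Only defined for a declining line (negative slope); for the default
    calibration this is 300.85 days, i.e. 301 when rounded for reporting.

    Raises
    ------
    ValueError
        If the slope is non-negative (the line never reaches zero at a
        positive age).
    """
    if model.slope_per_day >= 0:
        raise ValueError(
            "zero crossing undefined: slope is non-negative "
            f"({model.slope_per_day!r}); the line never reaches 0"
        )
    return -model.intercept_at_birth / model.slope_per_day


def response_probability(
    model: LinearResponsivenessModel,
    age_days,
    recruitment_mode: bool = False,
):
    """Probability that a neuron of the given age responds to exploration.

    In raw mode the fitted line is evaluated and clamped below at zero
    (which also zeroes it beyond the zero crossing for a declining line).
    In recruitment mode the probability is additionally zero below
    ``model.maturation_age_days``: immature neurons do not yet show the
    specific response, and their early non-specific Arc expression is
    modelled separately (see :mod:`dgrecruit.recruitment`).

    Accepts scalars or numpy arrays; negative ages raise ``ValueError``.
    """
    age = np.asarray(age_days, dtype=float)
    if np.any(age < 0):
        raise ValueError("age_days must be non-negative")
    prob = np.maximum(model.intercept_at_birth + model.slope_per_day * age, 0.0)
    if recruitment_mode:
        prob = np.where(age < model.maturation_age_days, 0.0, prob)
    if np.isscalar(age_days):
        return float(prob)
    return prob


def read_response_points(
    path: str | Path, percent: bool = False
) -> list[ResponsePoint]:
    """Read response points from a 2-column CSV.

    Expected header: ``age_days,fraction_responding``.  With ``percent=True``
    the second column is interpreted as percentages and divided by 100.
    """
    import pandas as pd

    df = pd.read_csv(path, comment="#")
    required = {"age_days", "fraction_responding"}
    if not required.issubset(df.columns):
        raise ValueError(f"CSV must have columns {sorted(required)}, got {list(df.columns)}")
    scale = 0.01 if percent else 1.0
    return [
        ResponsePoint(float(a), float(f) * scale)
        for a, f in zip(df["age_days"], df["fraction_responding"])
    ]
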