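"""Power-law decline of adult neurogenesis and cohort survival.

Proliferation in the adult DG declines with animal age.  Writing ``N(tau)``
for the number of granule cells born on animal-age day ``tau`` that survive
their first ~30 days (and are then assumed immortal), the decline is
modelled as a power law

    N(tau) = scale * tau ** exponent        (exponent < 0 in practice)

The shape (exponent) can be fitted by log-log OLS to proliferation-vs-age
observations; the scale is then anchored so the curve passes exactly through
a directly observed cohort size.  The default anchor is the 345 surviving
cells counted in the sampled region 45 days after labelling, placed at
animal age 150; the published scale N0 = 2218.2 determines the default
exponent s = log(345/2218.2)/log(150) = -0.37139.

Cohorts are summed on a daily grid: one day of labelling defines one birth
cohort, so discrete sums (not integrals) are exact for this model.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy import stats

__all__ = [
    "ProliferationObservation",
    "PowerSurvivalModel",
    "DEFAULT_SCALE",
    "DEFAULT_ANCHOR_AGE_DAYS",
    "DEFAULT_ANCHOR_COUNT",
    "ADULT_START_AGE_DAYS",
    "POSTNATAL_START_AGE_DAYS",
    "fit_power_survival",
    "solve_exponent_from_scale",
    "default_survival_model",
    "cohort_size",
    "cumulative_survivors",
    "read_proliferation_observations",
    "write_survival_model",
]

#: Published scale of the anchored power model (cells at tau = 1).
DEFAULT_SCALE = 2218.2
#: Anchor: 345 surviving cells in the sampled region for the cohort at age 150.
DEFAULT_ANCHOR_AGE_DAYS = 150
DEFAULT_ANCHOR_COUNT = 345.0
#: Sexual maturity: cohorts born from post-natal day 70 count as adult-born.
ADULT_START_AGE_DAYS = 70
#: Variant including every post-natal cohort.
POSTNATAL_START_AGE_DAYS = 1


@dataclass(frozen=True)
class ProliferationObservation:
    """Surviving cohort size for cells born at one animal age."""

    animal_age_days: float
    surviving_cohort_size: float

    def __post_init__(self) -> None:
        if self.animal_age_days < 1:
            raise ValueError("animal_age_days must be >= 1")
        if self.surviving_cohort_size < 0:
            raise ValueError("surviving_cohort_size must be >= 0")


@dataclass(frozen=True)
class PowerSurvivalModel:
    """Anchored power-law cohort-survival curve N(tau) = scale * tau**exponent."""

    scale: float
    exponent: float
    anchor_age_days: float = DEFAULT_ANCHOR_AGE_DAYS
    anchor_count: float = DEFAULT_ANCHOR_COUNT
    start_age_days: int = ADULT_START_AGE_DAYS

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.start_age_days < 1:
            raise ValueError("start_age_days must be >= 1")
        anchored = self.scale * self.anchor_age_days ** self.exponent
        if abs(anchored - self.anchor_count) > 1e-9 * max(abs(self.anchor_count), 1.0):
            raise ValueError(
                f"model is not anchored: N({self.anchor_age_days}) = {anchored!r} "
                f"but anchor_count = {self.anchor_count!r}"
            )

    def with_start_age(self, start_age_days: int) -> "PowerSurvivalModel":
        return replace(self, start_age_days=start_age_days)

    def to_dict(self) -> dict:
        return {
            "scale": self.scale,
            "exponent": self.exponent,
            "anchor_age_days": self.anchor_age_days,
            "anchor_count": self.anchor_count,
            "start_age_days": self.start_age_days,
        }


def solve_exponent_from_scale(
    scale: float, anchor_age: float, anchor_count: float
) -> float:
    """Exponent s such that scale * anchor_age**s = anchor_count.

    Inverts the published parametrization: with scale 2218.2 and anchor
    (150, 345) this gives s = -0.37139.  ``anchor_age`` must exceed 1
    (at age 1 the power law equals its scale regardless of s).
    """
    if scale <= 0 or anchor_count <= 0:
        raise ValueError("scale and anchor_count must be positive")
    if anchor_age <= 1:
        raise ValueError("anchor_age must be > 1")
    return math.log(anchor_count / scale) / math.log(anchor_age)


def default_survival_model(
    start_age_days: int = ADULT_START_AGE_DAYS,
) -> PowerSurvivalModel:
    """The published parametrization (scale 2218.2 anchored at N(150) = 345)."""
    exponent = solve_exponent_from_scale(
        DEFAULT_SCALE, DEFAULT_ANCHOR_AGE_DAYS, DEFAULT_ANCHOR_COUNT
    )
    return PowerSurvivalModel(
        scale=DEFAULT_SCALE,
        exponent=exponent,
        start_age_days=start_age_days,
    )


def fit_power_survival(
    observations: Iterable[ProliferationObservation | tuple[float, float]],
    anchor_age: float = DEFAULT_ANCHOR_AGE_DAYS,
    anchor_count: float = DEFAULT_ANCHOR_COUNT,
    start_age_days: int = ADULT_START_AGE_DAYS,
) -> PowerSurvivalModel:
    """Fit the power law by log-log OLS, then anchor the scale.

    The exponent comes from ordinary least squares on (log age, log count);
    the scale is then set so the curve passes exactly through
    ``(anchor_age, anchor_count)``.  Ages and counts must all be positive
    (the logarithm is undefined otherwise) and at least two distinct ages
    are required.
    """
    obs = [
        o if isinstance(o, ProliferationObservation) else ProliferationObservation(*o)
        for o in observations
    ]
    ages = np.array([o.animal_age_days for o in obs], dtype=float)
    counts = np.array([o.surviving_cohort_size for o in obs], dtype=float)
    if np.any(counts <= 0):
        raise ValueError("all surviving_cohort_size values must be positive to fit logs")
    if len(obs) < 2 or np.unique(ages).size < 2:
        raise ValueError("need at least 2 observations with distinct ages")

    res = stats.linregress(np.log(ages), np.log(counts))
    exponent = float(res.slope)
    scale = anchor_count / anchor_age ** exponent
    return PowerSurvivalModel(
        scale=scale,
        exponent=exponent,
        anchor_age_days=anchor_age,
        anchor_count=anchor_count,
        start_age_days=start_age_days,
    )


def cohort_size(model: PowerSurvivalModel, birth_age):
    """Surviving size of the cohort born at animal age ``birth_age`` (days >= 1).

    Continuous (not rounded); accepts scalars or arrays.
    """
    age = np.asarray(birth_age, dtype=float)
    if np.any(age < 1):
        raise ValueError("birth_age must be >= 1")
    out = model.scale * age ** model.exponent
    if np.isscalar(birth_age):
        return float(out)
    return out


def cumulative_survivors(model: PowerSurvivalModel, t: float) -> float:
    """Total survivors from all cohorts born on days start_age_days..t.

    Daily inclusive sum; assumes no mortality after the 30-day maturation
    window, so every cohort persists once counted.  Returns 0 for
    ``t < start_age_days`` (no cohorts born yet).
    """
    t = int(t)
    if t < model.start_age_days:
        return 0.0
    taus = np.arange(model.start_age_days, t + 1, dtype=float)
    return float(np.sum(model.scale * taus ** model.exponent))


def read_proliferation_observations(path: str | Path) -> list[ProliferationObservation]:
    """Read a 2-column CSV with header animal_age_days,surviving_cohort_size."""
    import pandas as pd

    df = pd.read_csv(path, comment="#")
    required = {"animal_age_days", "surviving_cohort_size"}
    if not required.issubset(df.columns):
        raise ValueError(f"CSV must have columns {sorted(required)}, got {list(df.columns)}")
    return [
        ProliferationObservation(float(a), float(c))
        for a, c in zip(df["animal_age_days"], df["surviving_cohort_size"])
    ]


def write_survival_model(model: PowerSurvivalModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=2) + "\n")
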