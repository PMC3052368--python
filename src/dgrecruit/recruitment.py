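"""Recruitment of adult-born neurons into the spatial exploration response.

The central quantity is the discrete convolution of cohort survival with
age-dependent responsiveness,

    R(t) = sum_{tau = start}^{t - maturation} N(tau) * P(t - tau),

the predicted number of adult-born granule cells that respond to a spatial
exploration at animal age ``t``.  ``N(tau)`` is the surviving size of the
cohort born on day ``tau`` (:mod:`dgrecruit.survival`) and ``P(age)`` the
recruitment-mode responsiveness probability, non-zero only for neuron ages
between maturation (30 d) and the zero crossing of the fitted line
(:mod:`dgrecruit.responsiveness`).

Time-axis conventions
---------------------
The curve lives on an animal-age grid.  Its first possible non-zero day is
``onset = start_age + maturation_age`` (day 100 for the adult parametrization:
the first adult cohort, born on day 70, matures on day 100).  Peak locations
are therefore reported twice: as the animal age of the maximum, and as days
since onset — the index of the maximum within the curve's support, which is
the convention in which the headline peak day of this model is usually
quoted.

A separate two-segment linear model covers the non-specific Arc expression
of immature (1-30 day old) neurons; convolving it with the standing size of
those young cohorts gives the unstimulated "background" proportion of
Arc-expressing granule cells attributable to neurons born in the previous
month.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, NamedTuple

import numpy as np

from .responsiveness import LinearResponsivenessModel, response_probability
from .survival import PowerSurvivalModel, cohort_size

__all__ = [
    "RecruitmentCurve",
    "RecruitmentPeak",
    "EarlyExpressionModel",
    "recruitment_curve",
    "peak_recruitment",
    "recruitment_share",
    "early_background_curve",
    "background_share_of_cc",
    "standing_cohort_multiplier",
    "DEFAULT_EARLY_SEGMENT1_POINTS",
    "DEFAULT_EARLY_SEGMENT2_POINTS",
    "OBSERVED_BRDU_FRACTION_BY_AGE",
]


@dataclass(frozen=True)
class RecruitmentCurve:
    """Predicted responding adult-born cells (or proportions) per animal age.

    ``ages`` is an ascending integer day grid with step 1; ``values`` the
    predicted counts (cells) or proportions (fractions) at each age.
    ``onset_age_days`` is the first animal age at which the curve can be
    non-zero.
    """

    ages: np.ndarray
    values: np.ndarray
    onset_age_days: int

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages)
        values = np.asarray(self.values, dtype=float)
        if ages.shape != values.shape:
            raise ValueError("ages and values must have the same length")
        if ages.size and np.any(np.diff(ages) != 1):
            raise ValueError("ages must be an ascending daily grid")
        if np.any(values < -1e-12):
            raise ValueError("curve values must be non-negative")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "values", values)

    # counts is the natural name when the curve is in cells
    @property
    def counts(self) -> np.ndarray:
        return self.values

    def value_at(self, age: int) -> float:
        idx = int(age) - int(self.ages[0])
        if idx < 0 or idx >= self.ages.size:
            raise IndexError(f"age {age} outside curve grid")
        return float(self.values[idx])

    def to_csv(self, path: str | Path, value_name: str = "count",
               header_lines: list[str] | None = None) -> None:
        lines = [f"# {h}" for h in (header_lines or [])]
        lines.append(f"age_days,{value_name}")
        lines += [f"{int(a)},{v:.10g}" for a, v in zip(self.ages, self.values)]
        Path(path).write_text("\n".join(lines) + "\n")


class RecruitmentPeak(NamedTuple):
    """Location and height of the maximum of a recruitment curve."""

    age_days: int
    count: float
    days_since_onset: int
    degenerate: bool = False


def recruitment_curve(
    survival: PowerSurvivalModel,
    response: LinearResponsivenessModel,
    t_max: int,
) -> RecruitmentCurve:
    """Convolve cohort survival with responsiveness up to animal age t_max.

    For each animal age t on the grid 1..t_max,

        R(t) = sum_{tau = start}^{t - maturation} N(tau) * P(t - tau)

    with P in recruitment mode (zero below the maturation age and, for a
    declining line, beyond its zero crossing).  Implemented as a single
    ``numpy.convolve`` of the cohort-size sequence with the probability
    sequence, which is exactly the daily double sum.

    Raises
    ------
    ValueError
        If ``t_max`` is before the first possible recruitment day
        (``start_age_days + maturation_age_days``).
    """
    start = int(survival.start_age_days)
    maturation = int(np.ceil(response.maturation_age_days))
    onset = start + maturation
    if t_max < onset:
        raise ValueError(
            f"t_max = {t_max} is before the recruitment onset at "
            f"{onset} = start ({start}) + maturation ({maturation})"
        )

    taus = np.arange(start, t_max - maturation + 1)
    n = cohort_size(survival, taus)
    ages_in_window = np.arange(0, t_max - start + 1)
    p = response_probability(response, ages_in_window, recruitment_mode=True)
    # full convolution index k corresponds to animal age start + k
    conv = np.convolve(n, p)

    grid = np.arange(1, t_max + 1)
    values = np.zeros_like(grid, dtype=float)
    k = grid - start  # index into conv for each animal age
    valid = (k >= 0) & (k < conv.size)
    values[valid] = conv[k[valid]]
    return RecruitmentCurve(ages=grid, values=values, onset_age_days=onset)


def peak_recruitment(curve: RecruitmentCurve) -> RecruitmentPeak:
    """Age and height of the curve maximum (smallest age on ties).

    An all-zero curve is flagged degenerate rather than raising.
    """
    if curve.ages.size == 0:
        raise ValueError("empty curve")
    idx = int(np.argmax(curve.values))  # argmax takes the first maximum
    peak_age = int(curve.ages[idx])
    value = float(curve.values[idx])
    return RecruitmentPeak(
        age_days=peak_age,
        count=value,
        days_since_onset=peak_age - curve.onset_age_days,
        degenerate=(value == 0.0),
    )


def recruitment_share(peak_count: float, total_responding: float) -> float:
    """Peak adult-born responders as a percentage of all responding cells."""
    if total_responding <= 0:
        raise ValueError("total_responding must be positive")
    return 100.0 * peak_count / total_responding


# ---------------------------------------------------------------------------
# Early (1-30 day) non-specific Arc expression
# ---------------------------------------------------------------------------

#: Cage-control Arc fractions among BrdU-positive cells at early neuron ages,
#: used to calibrate the first segment (OLS) ...
DEFAULT_EARLY_SEGMENT1_POINTS: tuple[tuple[float, float], ...] = (
    (1, 0.013),
    (7, 0.021),
    (15, 0.023),
)
#: ... and the second segment (exact line through two points).
DEFAULT_EARLY_SEGMENT2_POINTS: tuple[tuple[float, float], ...] = (
    (15, 0.023),
    (30, 0.015),
)

#: Observed BrdU-positive fractions of the granule population by cohort age
#: (days): attrition is still ongoing during the first ~45 days, so the
#: standing size of a young cohort exceeds its eventual survivor count.
OBSERVED_BRDU_FRACTION_BY_AGE: tuple[tuple[float, float], ...] = (
    (1, 0.0026),
    (7, 0.0035),
    (15, 0.0023),
    (30, 0.0017),
    (45, 0.0015),
)


def standing_cohort_multiplier(age_days) -> np.ndarray | float:
    """Standing-to-surviving cohort size ratio at a young neuron age.

    The survival curve N(tau) counts the cells of a cohort that outlive the
    early attrition period (calibrated on the 45-day-old count).  A cohort
    observed at age 1-30 days is still larger than that: this multiplier is
    the observed BrdU fraction at the given age divided by the 45-day
    fraction, linearly interpolated between the measured ages (e.g. 2.33 at
    age 7, 1.13 at age 30, 1.0 at 45).
    """
    xs, ys = zip(*OBSERVED_BRDU_FRACTION_BY_AGE)
    base = ys[-1]
    out = np.interp(np.asarray(age_days, dtype=float), xs, np.asarray(ys) / base)
    if np.isscalar(age_days):
        return float(out)
    return out


@dataclass(frozen=True)
class EarlyExpressionModel:
    """Two-segment linear model of non-specific Arc expression at ages 1-30 d.

    ``segment1`` = (intercept, slope) valid on [1, breakpoint];
    ``segment2`` = (intercept, slope) valid on (breakpoint, 30].
    Both segments must stay within [0, 1] over their windows.
    """

    segment1: tuple[float, float]
    segment2: tuple[float, float]
    breakpoint: float = 15.0

    def __post_init__(self) -> None:
        if not 1 < self.breakpoint < 30:
            raise ValueError("breakpoint must lie strictly between 1 and 30")
        for (a, b), lo, hi in (
            (self.segment1, 1.0, self.breakpoint),
            (self.segment2, self.breakpoint, 30.0),
        ):
            ends = (a + b * lo, a + b * hi)
            if min(ends) < 0 or max(ends) > 1:
                raise ValueError(
                    f"segment evaluates outside [0, 1] on [{lo}, {hi}]: {ends}"
                )

    @classmethod
    def default_calibration(cls) -> "EarlyExpressionModel":
        """Segments calibrated to the cage-control early Arc fractions.

        Segment 1 is the OLS line through the age-1/7/15 points; segment 2
        the exact line through the age-15 and age-30 points; breakpoint 15.
        """
        from scipy import stats

        x1, y1 = zip(*DEFAULT_EARLY_SEGMENT1_POINTS)
        res = stats.linregress(x1, y1)
        (xa, ya), (xb, yb) = DEFAULT_EARLY_SEGMENT2_POINTS
        slope2 = (yb - ya) / (xb - xa)
        intercept2 = ya - slope2 * xa
        return cls(
            segment1=(float(res.intercept), float(res.slope)),
            segment2=(intercept2, slope2),
            breakpoint=float(xa),
        )

    def probability(self, age_days) -> np.ndarray | float:
        """Expression probability at a neuron age; zero outside [1, 30]."""
        age = np.asarray(age_days, dtype=float)
        a1, b1 = self.segment1
        a2, b2 = self.segment2
        prob = np.where(age <= self.breakpoint, a1 + b1 * age, a2 + b2 * age)
        prob = np.where((age < 1) | (age > 30), 0.0, prob)
        if np.isscalar(age_days):
            return float(prob)
        return prob


def early_background_curve(
    early: EarlyExpressionModel,
    survival: PowerSurvivalModel,
    granule_total: float,
    t_max: int,
    attrition: Callable[[np.ndarray], np.ndarray] | None = standing_cohort_multiplier,
) -> RecruitmentCurve:
    """Unstimulated Arc-expressing proportion due to 1-30 day old neurons.

    Convolves the standing size of each young cohort with the two-segment
    expression probability and divides by ``granule_total``:

        B(t) = sum_{age=1}^{30} N(t - age) * m(age) * p_early(age) / G

    where ``m`` is the standing-cohort multiplier accounting for the
    attrition still ongoing at ages below 45 days (pass ``attrition=None``
    to use the bare survivor counts instead).  Cohorts are taken from the
    survival model's start age onward.
    """
    if granule_total <= 0:
        raise ValueError("granule_total must be positive")
    start = int(survival.start_age_days)
    onset = start + 1  # youngest expressing age is 1 day

    early_ages = np.arange(1, 31)
    p = early.probability(early_ages)
    if np.any(p < 0):
        raise ValueError("early expression model yields negative probabilities")
    if attrition is not None:
        p = p * np.asarray(attrition(early_ages), dtype=float)

    grid = np.arange(1, t_max + 1)
    values = np.zeros_like(grid, dtype=float)
    for i, t in enumerate(grid):
        taus = t - early_ages
        ok = taus >= start
        if np.any(ok):
            values[i] = np.sum(cohort_size(survival, taus[ok]) * p[ok])
    return RecruitmentCurve(
        ages=grid, values=values / granule_total, onset_age_days=onset
    )


def background_share_of_cc(background_max: float, cc_arc_fraction: float) -> float:
    """Background maximum as a percentage of an observed Arc fraction.

    Typical comparisons: against the 0.31% cage-control Arc fraction
    (roughly half of the unstimulated Arc signal is then attributable to
    neurons born in the previous month) and against the 1.5% fraction after
    spatial exploration (roughly a tenth).
    """
    if cc_arc_fraction <= 0:
        raise ValueError("cc_arc_fraction must be positive")
    return 100.0 * background_max / cc_arc_fraction
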