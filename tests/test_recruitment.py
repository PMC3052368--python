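import numpy as np
import pytest

import dgrecruit as dg
from dgrecruit.recruitment import EarlyExpressionModel, RecruitmentCurve
from dgrecruit.responsiveness import LinearResponsivenessModel
from dgrecruit.survival import PowerSurvivalModel

from conftest import brute_force_recruitment


def make_response(intercept, slope, maturation=30):
    zc = -intercept / slope if slope < 0 else None
    return LinearResponsivenessModel(
        intercept_at_birth=intercept, slope_per_day=slope, r_squared=1.0,
        slope_p_value=0.05, zero_crossing_age_days=zc, n_points=3,
        maturation_age_days=maturation,
    )


def make_survival(scale, exponent, start=70):
    return PowerSurvivalModel(
        scale=scale, exponent=exponent, anchor_age_days=150,
        anchor_count=scale * 150 ** exponent, start_age_days=start,
    )


class TestConvolution:
    def test_zero_before_onset(self, default_survival, default_response_model):
        """No cohort has matured before animal age start + maturation."""
        curve = dg.recruitment_curve(default_survival, default_response_model, 300)
        assert curve.value_at(99) == 0.0
        assert np.all(curve.values[curve.ages < 100] == 0)

    def test_first_day_is_single_cohort_term(
        self, default_survival, default_response_model
    ):
        """At day 100 only the day-70 cohort, aged exactly 30, contributes."""
        curve = dg.recruitment_curve(default_survival, default_response_model, 120)
        expected = dg.cohort_size(default_survival, 70) * dg.response_probability(
            default_response_model, 30
        )
        assert curve.value_at(100) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(23.062, abs=1e-3)

    def test_matches_brute_force_on_default_parametrization(
        self, default_survival, default_response_model
    ):
        curve = dg.recruitment_curve(default_survival, default_response_model, 450)
        for t in (100, 150, 217, 301, 400, 450):
            assert curve.value_at(t) == pytest.approx(
                brute_force_recruitment(default_survival, default_response_model, t),
                rel=1e-9,
            )

    def test_matches_brute_force_on_random_parametrizations(self, rng):
        """Spot check of the double-sum identity away from the defaults."""
        for _ in range(15):
            survival = make_survival(
                scale=rng.uniform(100, 5000),
                exponent=rng.uniform(-1.2, 0.2),
                start=int(rng.integers(1, 90)),
            )
            response = make_response(
                intercept=rng.uniform(0.01, 0.2),
                slope=-rng.uniform(1e-5, 2e-3),
                maturation=int(rng.integers(5, 45)),
            )
            t_max = survival.start_age_days + response.maturation_age_days + int(
                rng.integers(20, 150)
            )
            curve = dg.recruitment_curve(survival, response, t_max)
            for t in rng.integers(1, t_max + 1, size=4):
                assert curve.value_at(int(t)) == pytest.approx(
                    brute_force_recruitment(survival, response, int(t)),
                    rel=1e-9, abs=1e-12,
                )

    def test_t_max_before_onset_rejected(self, default_survival, default_response_model):
        with pytest.raises(ValueError, match="onset"):
            dg.recruitment_curve(default_survival, default_response_model, 99)

    def test_curve_invariant_to_extension(self, default_survival, default_response_model):
        short = dg.recruitment_curve(default_survival, default_response_model, 300)
        long = dg.recruitment_curve(default_survival, default_response_model, 600)
        np.testing.assert_allclose(long.values[:300], short.values, rtol=1e-12)

    def test_rise_then_decline_shape(self, default_survival, default_response_model):
        """The default curve rises to a unique interior maximum and declines."""
        curve = dg.recruitment_curve(default_survival, default_response_model, 600)
        peak = dg.peak_recruitment(curve)
        assert 100 < peak.age_days < 600
        active = curve.values[curve.ages >= 100]
        d = np.diff(active)
        turn = int(np.argmax(active))
        assert np.all(d[:turn] > 0) and np.all(d[turn:] < 0)

    def test_postnatal_variant_dominates_adult(self, default_response_model):
        adult = dg.recruitment_curve(
            dg.default_survival_model(70), default_response_model, 500
        )
        postnatal = dg.recruitment_curve(
            dg.default_survival_model(1), default_response_model, 500
        )
        # pointwise domination up to floating error (the curves coincide
        # exactly at late ages once the extra young cohorts have aged out)
        assert np.all(postnatal.values >= adult.values - 1e-9 * adult.values.max())
        assert postnatal.values.max() > adult.values.max()

    def test_bounded_by_cumulative_times_max_probability(
        self, default_survival, default_response_model
    ):
        curve = dg.recruitment_curve(default_survival, default_response_model, 500)
        pmax = dg.response_probability(default_response_model, 30)
        for t in (100, 200, 350, 500):
            bound = dg.cumulative_survivors(default_survival, t - 30) * pmax
            assert curve.value_at(t) <= bound + 1e-9

    def test_constant_cohorts_linear_probability_arithmetic_series(self):
        """Flat cohorts x linear P reduce to an arithmetic-series sum."""
        survival = make_survival(scale=10.0, exponent=0.0, start=50)
        response = make_response(intercept=0.1, slope=-1e-3, maturation=20)
        t = 120  # ages 20..70 in window, all with positive probability
        ages = np.arange(20, 71)
        expected = 10.0 * np.sum(0.1 - 1e-3 * ages)
        curve = dg.recruitment_curve(survival, response, 150)
        assert curve.value_at(t) == pytest.approx(expected, rel=1e-12)


class TestPeak:
    def test_default_peak_location_and_height(
        self, default_survival, default_response_model
    ):
        curve = dg.recruitment_curve(default_survival, default_response_model, 600)
        peak = dg.peak_recruitment(curve)
        assert peak.age_days == 318
        assert peak.days_since_onset == 218
        assert peak.count == pytest.approx(2084.33, abs=0.01)
        assert not peak.degenerate

    def test_monotone_curve_peaks_at_last_age(self):
        curve = RecruitmentCurve(
            ages=np.arange(1, 6), values=np.arange(5.0), onset_age_days=2
        )
        assert dg.peak_recruitment(curve).age_days == 5

    def test_tie_broken_toward_smaller_age(self):
        curve = RecruitmentCurve(
            ages=np.arange(1, 6), values=np.array([0, 2.0, 1.0, 2.0, 0]),
            onset_age_days=1,
        )
        assert dg.peak_recruitment(curve).age_days == 2

    def test_all_zero_curve_flagged_degenerate(self):
        curve = RecruitmentCurve(
            ages=np.arange(1, 4), values=np.zeros(3), onset_age_days=1
        )
        peak = dg.peak_recruitment(curve)
        assert peak.degenerate and peak.count == 0.0


class TestShares:
    @pytest.mark.parametrize(
        "peak, total, expected",
        [(2057, 3465, 59.4), (0, 100, 0.0), (42, 42, 100.0)],
    )
    def test_recruitment_share(self, peak, total, expected):
        assert dg.recruitment_share(peak, total) == pytest.approx(expected, abs=0.05)

    def test_share_requires_positive_total(self):
        with pytest.raises(ValueError):
            dg.recruitment_share(10, 0)

    @pytest.mark.parametrize(
        "bg, ref, expected",
        [(0.0016, 0.0031, 51.6), (0.0, 0.01, 0.0), (0.0016, 0.015, 10.7)],
    )
    def test_background_share(self, bg, ref, expected):
        assert dg.background_share_of_cc(bg, ref) == pytest.approx(expected, abs=0.1)


class TestEarlyBackground:
    def test_default_calibration_segments(self):
        """Segment 1 is the OLS line through the early cage-control points;
        segment 2 joins the day-15 and day-30 points exactly."""
        m = EarlyExpressionModel.default_calibration()
        assert m.probability(15) == pytest.approx(0.024054, abs=1e-5)  # OLS at 15
        assert m.probability(16) == pytest.approx(0.031 - 0.0005333 * 16, abs=1e-5)
        assert m.probability(30) == pytest.approx(0.015, abs=1e-9)
        assert m.probability(0.5) == 0.0 and m.probability(31) == 0.0

    def test_invalid_segment_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            EarlyExpressionModel(segment1=(-0.05, 0.0), segment2=(0.02, 0.0))

    def test_all_zero_model_gives_all_zero_curve(self, default_survival):
        m = EarlyExpressionModel(segment1=(0.0, 0.0), segment2=(0.0, 0.0))
        curve = dg.early_background_curve(m, default_survival, 231_000, 200)
        assert np.all(curve.values == 0)

    def test_constant_probability_steady_state_closed_form(self):
        """Constant cohorts c and constant probability p give 30*c*p/G."""
        survival = make_survival(scale=100.0, exponent=0.0, start=10)
        m = EarlyExpressionModel(segment1=(0.02, 0.0), segment2=(0.02, 0.0))
        curve = dg.early_background_curve(
            m, survival, granule_total=10_000, t_max=120, attrition=None
        )
        assert curve.value_at(100) == pytest.approx(30 * 100 * 0.02 / 10_000, rel=1e-12)

    def test_default_background_maximum_and_timing(self, default_survival):
        """The unstimulated background peaks at ~0.17% of granule cells as
        soon as a full 1-30 day window of adult cohorts exists."""
        curve = dg.early_background_curve(
            EarlyExpressionModel.default_calibration(), default_survival, 231_000, 400
        )
        peak = dg.peak_recruitment(curve)
        assert peak.age_days == 100
        assert 100 * peak.count == pytest.approx(0.1719, abs=1e-3)

    def test_attrition_multiplier_interpolates_observed_fractions(self):
        assert dg.standing_cohort_multiplier(7) == pytest.approx(0.0035 / 0.0015)
        assert dg.standing_cohort_multiplier(45) == pytest.approx(1.0)
        mids = dg.standing_cohort_multiplier(np.arange(1, 31))
        assert np.all(mids >= 1.0)
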