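import numpy as np
import pandas as pd
import pytest

import dgrecruit as dg
from dgrecruit.census import LAYERS, AnimalCountRecord, LayerDistribution


def record(animal_id="a1", pbi=30, cond="SE", counts=None, total=80_000):
    counts = counts or {
        "SGZ": (20, 0, 0), "L1": (70, 30, 6), "L2": (30, 20, 1), "L3": (16, 10, 0),
    }
    return AnimalCountRecord(animal_id, pbi, cond, counts, total)


class TestArithmetic:
    def test_region_scaling_reproduces_census(self):
        """80,000 cells over 450 um scale to 231,000 over 1300 um."""
        assert dg.scale_to_region(80_000, 450, 1300, round_to_thousand=True) == 231_000
        assert dg.scale_to_region(80_000, 450, 1300) == pytest.approx(231_111.1, abs=0.1)

    @pytest.mark.parametrize(
        "cells, sampled, region, expected",
        [(1234, 100, 100, 1234), (1000, 100, 250, 2500)],
    )
    def test_region_scaling_identity_and_linear(self, cells, sampled, region, expected):
        assert dg.scale_to_region(cells, sampled, region) == pytest.approx(expected)

    def test_scaling_linear_in_cells_rounding_last(self):
        a = dg.scale_to_region(40_000, 450, 1300)
        b = dg.scale_to_region(80_000, 450, 1300)
        assert b == pytest.approx(2 * a, rel=1e-12)
        # rounding applied to the scaled value, not the input
        assert dg.scale_to_region(80_100, 450, 1300, round_to_thousand=True) == 231_000

    def test_non_positive_extent_rejected(self):
        with pytest.raises(ValueError):
            dg.scale_to_region(1000, 0, 1300)

    @pytest.mark.parametrize(
        "total, fraction, expected",
        [
            (231_000, 0.015, 3_465),     # granule cells responding to exploration
            (1_200_000, 0.0015, 1_800),  # daily surviving births, whole DG
            (500, 0.0, 0),
        ],
    )
    def test_responding_population(self, total, fraction, expected):
        assert dg.responding_population(total, fraction) == expected

    @pytest.mark.parametrize(
        "f7, f45, expected",
        [(0.0035, 0.0015, 57.1), (0.002, 0.002, 0.0), (0.004, 0.001, 75.0)],
    )
    def test_survival_decline(self, f7, f45, expected):
        assert dg.survival_decline(f7, f45) == pytest.approx(expected, abs=0.05)

    def test_survival_decline_needs_positive_day7(self):
        with pytest.raises(ValueError):
            dg.survival_decline(0.0, 0.001)


class TestLayerDistribution:
    def test_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            LayerDistribution(0.5, 0.5, 0.5, 0.0)

    def test_from_counts_normalizes(self):
        d = LayerDistribution.from_counts([1, 1, 1, 1])
        assert d.as_array().sum() == pytest.approx(1.0)


class TestRecordValidation:
    def test_double_cannot_exceed_brdu_or_arc(self):
        with pytest.raises(ValueError, match="double"):
            record(counts={
                "SGZ": (0, 0, 0), "L1": (5, 10, 6), "L2": (0, 0, 0), "L3": (0, 0, 0),
            })

    def test_layer_sums_bounded_by_total(self):
        with pytest.raises(ValueError, match="exceed total"):
            record(counts={
                "SGZ": (50, 0, 0), "L1": (30, 10, 5), "L2": (20, 5, 0), "L3": (10, 2, 0),
            }, total=100)


class TestGroupSummaries:
    def test_single_animal_all_brdu_in_one_layer(self):
        r = record(counts={
            "SGZ": (0, 0, 0), "L1": (40, 12, 5), "L2": (0, 0, 0), "L3": (0, 0, 0),
        })
        groups = dg.group_summaries([r]).groups
        dist = groups[[f"brdu_dist_{l}" for l in LAYERS]].iloc[0].to_numpy()
        np.testing.assert_allclose(dist, [0, 1, 0, 0])

    def test_two_identical_animals_match_single(self):
        r1, r2 = record("a1"), record("a2")
        one = dg.group_summaries([r1]).groups
        two = dg.group_summaries([r1, r2]).groups
        for col in ("brdu_fraction", "double_of_brdu", "arc_fraction"):
            assert two[col].iloc[0] == pytest.approx(one[col].iloc[0], rel=1e-12)

    def test_permutation_invariance(self):
        recs = dg.generate_study(seed=5)
        a = dg.group_summaries(recs).groups
        b = dg.group_summaries(recs[::-1]).groups
        pd.testing.assert_frame_equal(
            a.sort_values(["pbi_days", "condition"]).reset_index(drop=True),
            b.sort_values(["pbi_days", "condition"]).reset_index(drop=True),
        )

    def test_zero_brdu_animal_excluded_with_warning(self):
        empty = record("z0", counts={l: (0, 5 if l == "L1" else 0, 0) for l in LAYERS})
        with pytest.warns(UserWarning, match="zero BrdU"):
            summary = dg.group_summaries([record("a1"), empty])
        assert np.isnan(
            summary.per_animal.set_index("animal_id").loc["z0", "double_of_brdu"]
        )
        assert not np.isnan(summary.groups["double_of_brdu"].iloc[0])

    def test_day30_brdu_fraction_within_binomial_interval(self):
        """Synthetic day-30 cohorts average ~0.17% BrdU-positive cells."""
        design = dg.StudyDesign(pbi_days=(30,), animals_se=(4,), animals_cc=(3,))
        fractions = []
        for seed in range(20):
            recs = dg.generate_study(design, seed=seed)
            fractions += [r.brdu_total / r.total_granule_sampled for r in recs]
        mean = np.mean(fractions)
        n_cells = 80_000 * len(fractions)
        half_width = 1.96 * np.sqrt(0.0017 * (1 - 0.0017) / n_cells)
        assert abs(mean - 0.0017) < half_width


class TestCompareGroups:
    @staticmethod
    def frame(groups: dict[str, np.ndarray]) -> pd.DataFrame:
        rows = [
            {"condition": g, "pbi_days": 30, "double_of_brdu": v}
            for g, vals in groups.items() for v in vals
        ]
        return pd.DataFrame(rows)

    def test_identical_groups_not_declared_different(self):
        df = self.frame({"CC": [0.1, 0.2, 0.3], "SE": [0.1, 0.2, 0.3]})
        table = dg.compare_groups(df, factors=["condition"])
        omnibus = table[table["comparison"] == "omnibus"].iloc[0]
        assert omnibus["p"] > 0.99

    def test_large_offset_declared_different(self, rng):
        base = rng.normal(0.0, 1.0, 8)
        df = self.frame({"CC": base, "SE": base + 10.0})  # 10 pooled SDs apart
        table = dg.compare_groups(df, factors=["condition"])
        assert (table["corrected_p"] < 0.01).all()

    def test_insufficient_replication_raises(self):
        df = self.frame({"CC": [0.1], "SE": [0.2]})
        with pytest.raises(ValueError, match="replication"):
            dg.compare_groups(df, factors=["condition"])

    def test_two_factor_anova_returns_interaction_term(self):
        recs = dg.generate_study(seed=11)
        table = dg.compare_groups(dg.group_summaries(recs))
        terms = set(table.loc[table["comparison"] == "omnibus", "term"])
        assert any(":" in t for t in terms)  # interaction present
        assert (table["corrected_p"] >= table["p"] - 1e-12).all()

    def test_type_one_error_rate_near_nominal(self):
        """Two groups from one distribution: ~5% false positives at alpha 0.05."""
        rng = np.random.default_rng(99)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            df = self.frame({
                "CC": rng.normal(0.02, 0.005, 10), "SE": rng.normal(0.02, 0.005, 10),
            })
            table = dg.compare_groups(df, factors=["condition"])
            p = table[table["comparison"] == "omnibus"]["p"].iloc[0]
            rejections += p < 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.02)


class TestCountTableIO:
    def test_csv_roundtrip(self, tmp_path):
        recs = dg.generate_study(seed=3)
        path = tmp_path / "counts.csv"
        dg.write_animal_counts(recs, path, header_lines=["test"])
        back = dg.read_animal_counts(path)
        assert len(back) == len(recs)
        orig = {r.animal_id: r for r in recs}
        for r in back:
            assert r.layer_counts == orig[r.animal_id].layer_counts
            assert r.total_granule_sampled == orig[r.animal_id].total_granule_sampled
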