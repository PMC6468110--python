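import numpy as np
import pandas as pd
import pytest
from scipy import stats as spstats

from ictalpipe.synthetic import TrialDesign, generate_trial_counts
from ictalpipe.trial_stats import (
    PowerDesign,
    apply_inclusion_filter,
    fano_factor,
    lehr_sample_size,
    mann_whitney_exact,
    normalize_cumulative_daily,
    normalize_frequency,
    per_animal_fano,
    permutation_interaction_test,
    power_normal_approximation,
    power_simulation,
    seizure_burden,
    sqrt_z_test,
    tidy_model_frame,
)


def small_table(baseline_counts, post_counts, groups=None):
    """Hand-built count table: one baseline week (-1) + post weeks 0..k."""
    rows = []
    for i, (animal, bl) in enumerate(baseline_counts.items()):
        g = (groups or {}).get(animal, "treated" if i % 2 == 0 else "control")
        rows.append((animal, g, "week", -1, bl, True))
        for w, c in enumerate(post_counts.get(animal, [])):
            rows.append((animal, g, "week", w, c, False))
    return pd.DataFrame(
        rows,
        columns=["animal_id", "group", "period_type", "period_index", "count", "is_baseline"],
    )


class TestInclusionFilter:
    def test_strictly_fewer_than_five_excluded(self):
        table = small_table({"a": 4, "b": 5, "c": 11}, {})
        kept, report = apply_inclusion_filter(table)
        assert set(kept.animal_id) == {"b", "c"}
        assert list(report.animal_id) == ["a"]

    def test_no_exclusions(self):
        table = small_table({"a": 5, "b": 9}, {})
        kept, report = apply_inclusion_filter(table)
        assert report.empty and set(kept.animal_id) == {"a", "b"}

    def test_synthetic_trial_exclusions_match_construction(self):
        design = TrialDesign(n_per_group=10, baseline_rate=5.0, seed=0)
        table = generate_trial_counts(design)
        kept, report = apply_inclusion_filter(table, min_baseline=5)
        bl = table[(table.period_type == "week") & (table.period_index == -1)]
        expected = set(bl.loc[bl["count"] < 5, "animal_id"])
        assert set(report.animal_id) == expected
        assert set(kept.animal_id) == set(bl.animal_id) - expected

    def test_missing_baseline_week_named(self):
        table = small_table({"a": 6}, {"a": [3]})
        table = table[~table.is_baseline]
        with pytest.raises(ValueError, match="a has no baseline"):
            apply_inclusion_filter(table)


class TestNormalization:
    def test_last_week_mode(self):
        table = small_table({"a": 10}, {"a": [10, 5, 2]})
        norm = normalize_frequency(table, "last_week")
        vals = norm.sort_values("period_index")["normalized"].tolist()
        assert vals == pytest.approx([1.0, 1.0, 0.5, 0.2])  # week -1 first

    def test_baseline_week_normalizes_to_one_for_every_animal(self):
        table = generate_trial_counts(TrialDesign(n_per_group=6, seed=1))
        table, _ = apply_inclusion_filter(table, min_baseline=1)
        norm = normalize_frequency(table, "last_week")
        base = norm[norm.period_index == -1]["normalized"]
        assert np.allclose(base, 1.0)

    def test_mean_of_baseline_mode(self):
        rows = [
            ("a", "treated", "week", -2, 30, True),
            ("a", "treated", "week", -1, 50, True),
            ("a", "treated", "week", 0, 20, False),
        ]
        table = pd.DataFrame(
            rows,
            columns=["animal_id", "group", "period_type", "period_index", "count", "is_baseline"],
        )
        norm = normalize_frequency(table, "mean_of_baseline")
        assert norm.loc[norm.period_index == 0, "normalized"].iloc[0] == pytest.approx(0.5)

    def test_cumulative_daily(self):
        rows = [("a", "treated", "week", -1, 4, True)]
        rows += [("a", "treated", "day", d, c, False) for d, c in enumerate([1, 1, 0, 2])]
        table = pd.DataFrame(
            rows,
            columns=["animal_id", "group", "period_type", "period_index", "count", "is_baseline"],
        )
        cum = normalize_cumulative_daily(table)
        assert cum["cumulative_normalized"].tolist() == pytest.approx([0.25, 0.5, 0.5, 1.0])

    def test_animal_relabeling_invariance(self):
        table = small_table({"a": 10, "b": 8}, {"a": [5, 4], "b": [2, 6]})
        renamed = table.assign(animal_id=table.animal_id.map({"a": "z9", "b": "k2"}))
        n1 = normalize_frequency(table)
        n2 = normalize_frequency(renamed)
        assert sorted(n1["normalized"]) == pytest.approx(sorted(n2["normalized"]))


class TestBurden:
    def test_hand_computed_burden(self):
        table = small_table({"a": 10}, {"a": [3, 4]})
        burden, _ = seizure_burden(table)
        assert burden.burden.iloc[0] == pytest.approx(0.7)

    def test_identical_groups_give_p_one(self):
        table = small_table(
            {"a": 10, "b": 10, "c": 10, "d": 10},
            {"a": [5], "b": [5], "c": [5], "d": [5]},
            groups={"a": "treated", "b": "control", "c": "treated", "d": "control"},
        )
        _, comp = seizure_burden(table)
        assert comp["p_value"] == pytest.approx(1.0)

    def test_treated_burden_lower_under_effect(self):
        design = TrialDesign(n_per_group=8, treatment_rate_ratio=0.4, seed=2)
        table, _ = apply_inclusion_filter(generate_trial_counts(design))
        burden, comp = seizure_burden(table)
        med = burden.groupby("group")["burden"].median()
        assert med["treated"] < med["control"]


class TestFano:
    @pytest.mark.parametrize(
        "counts,expected",
        [([3, 3, 3, 3], 0.0), ([0, 0, 10, 0, 0], 10.0)],
    )
    def test_hand_computed(self, counts, expected):
        assert fano_factor(np.array(counts)) == pytest.approx(expected)

    def test_poisson_fano_near_one(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(4.0, size=20_000)
        # var of sample Fano for Poisson ~ sqrt(2/(n-1))
        assert fano_factor(counts) == pytest.approx(1.0, abs=2 * np.sqrt(2 / 19_999))

    def test_thinning_preserves_poisson_fano(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(10.0, size=20_000)
        thinned = rng.binomial(counts, 0.3)
        assert fano_factor(thinned) == pytest.approx(1.0, abs=0.03)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            fano_factor(np.zeros(5))

    def test_per_animal_fano_groups(self):
        design = TrialDesign(n_per_group=5, cluster_intensity=1.0, seed=3)
        table = generate_trial_counts(design)
        fanos = per_animal_fano(table)
        assert set(fanos.columns) == {"animal_id", "group", "fano"}
        assert len(fanos) == 10


class TestMannWhitney:
    def test_fully_separated_exact_p(self):
        u, p = mann_whitney_exact([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(2 / 20)

    def test_identical_multisets(self):
        x = [1.0, 2.0, 3.0]
        u, p = mann_whitney_exact(x, x)
        assert u == pytest.approx(len(x) ** 2 / 2)
        assert p == pytest.approx(1.0)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=6), rng.normal(1.0, 1.0, size=5)
        u, p = mann_whitney_exact(x, y)
        ref = spstats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_asymptotic_close_to_exact_at_n7(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=7), rng.normal(size=7)
        _, p_exact = mann_whitney_exact(x, y, exact_limit=14)
        _, p_asym = mann_whitney_exact(x, y, exact_limit=0)
        assert abs(p_exact - p_asym) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_exact([], [1.0])


class TestLehr:
    def test_worked_case_ten_to_six(self):
        n, ceil = lehr_sample_size(PowerDesign(10.0, 6.0))
        assert n == pytest.approx(7.87, abs=0.005)
        assert ceil == 8

    def test_closed_form_case(self):
        n, ceil = lehr_sample_size(PowerDesign(9.0, 4.0))
        assert n == pytest.approx(4.0) and ceil == 4

    def test_symmetric_in_rates(self):
        assert lehr_sample_size(PowerDesign(10.0, 6.0))[0] == pytest.approx(
            lehr_sample_size(PowerDesign(6.0, 10.0))[0]
        )

    def test_equal_rates_rejected(self):
        with pytest.raises(ValueError, match="infinite"):
            lehr_sample_size(PowerDesign(5.0, 5.0))


class TestPower:
    def test_null_rejection_matches_alpha(self):
        res = power_simulation(PowerDesign(8.0, 8.0), n_per_group=8, reps=4000, seed=0)
        se = np.sqrt(0.05 * 0.95 / 4000)
        assert abs(res["power"] - 0.05) < 3 * se

    def test_design_case_near_closed_form(self):
        design = PowerDesign(10.0, 6.0)
        res = power_simulation(design, n_per_group=8, reps=10_000, seed=1)
        approx = power_normal_approximation(design, 8)
        assert approx == pytest.approx(0.814, abs=0.005)
        assert abs(res["power"] - approx) < 3 * res["se"] + 0.01

    def test_power_monotone_in_n(self):
        design = PowerDesign(10.0, 6.0)
        powers = [
            power_simulation(design, n_per_group=n, reps=4000, seed=2)["power"]
            for n in (4, 8, 16)
        ]
        assert powers[0] < powers[1] < powers[2]

    def test_sqrt_z_test_direction(self):
        z, reject = sqrt_z_test(np.full(8, 16.0), np.full(8, 4.0))
        assert z > 0 and reject


class TestPermutationInteraction:
    def test_zero_reps_gives_p_one(self):
        table = small_table({"a": 10, "b": 9}, {"a": [5, 4], "b": [8, 9]},
                            groups={"a": "treated", "b": "control"})
        norm = normalize_frequency(table)
        assert permutation_interaction_test(norm, reps=0)["p_value"] == 1.0

    def test_detects_strong_effect(self):
        rejections = 0
        for s in range(10):
            design = TrialDesign(n_per_group=8, treatment_rate_ratio=0.3, seed=100 + s)
            table, _ = apply_inclusion_filter(generate_trial_counts(design))
            norm = normalize_frequency(table)
            p = permutation_interaction_test(norm, reps=399, seed=s)["p_value"]
            rejections += p < 0.05
        assert rejections >= 8

    def test_single_group_rejected(self):
        table = small_table({"a": 10, "b": 9}, {"a": [5, 4], "b": [8, 9]},
                            groups={"a": "treated", "b": "treated"})
        norm = normalize_frequency(table)
        with pytest.raises(ValueError, match="both groups"):
            permutation_interaction_test(norm, reps=10)


class TestTidyFrame:
    def test_shape_and_columns(self):
        design = TrialDesign(n_per_group=4, post_periods=3, seed=6)
        table, _ = apply_inclusion_filter(generate_trial_counts(design))
        frame = tidy_model_frame(table)
        n_animals = table.animal_id.nunique()
        assert set(frame.columns) == {"animal_id", "group", "week", "normalized", "count"}
        assert len(frame) == n_animals * 3
        assert (frame.week >= 0).all()
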