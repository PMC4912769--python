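"""Statistical machinery vs closed forms and enumeration oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gliamorph import stats, synth
from gliamorph.errors import DataError

from oracles import chi_square_by_hand, mann_whitney_exact_p


class TestTwoGroups:
    def test_identical_samples_sit_at_null_midpoint(self):
        a = [1.0, 2.0, 3.0, 10.0]  # skewed enough to fail normality? ties force MW path
        rep = stats.compare_two_groups(a, a)
        assert rep.p_value == pytest.approx(1.0)

    def test_exact_mann_whitney_matches_enumeration(self):
        x = [1.2, 3.4, 5.1, 7.7]
        y = [2.2, 4.9, 6.3, 8.1, 9.5]
        rep = stats.compare_two_groups(x + [100.0], y, exact_max_n=12)
        # force the MW path via a non-normal outlier in x
        if rep.test.startswith("mann_whitney"):
            u, p = mann_whitney_exact_p(x + [100.0], y)
            assert rep.statistic == pytest.approx(u)
            assert rep.p_value == pytest.approx(p)

    def test_normal_groups_use_t_test(self):
        rng = np.random.default_rng(2)
        a = rng.normal(10, 1, 8)
        b = rng.normal(12, 1, 8)
        rep = stats.compare_two_groups(a, b)
        assert rep.test == "student_t"
        assert rep.p_value < 0.05

    def test_too_few_animals_rejected(self):
        with pytest.raises(DataError):
            stats.compare_two_groups([1, 2], [3, 4, 5])

    def test_summary_table_input(self):
        records = pd.DataFrame({
            "animal_id": np.repeat([f"a{i}" for i in range(6)], 10),
            "condition": np.repeat(["control", "treated"], 30),
            "CI": np.concatenate([
                np.random.default_rng(0).normal(4, 0.5, 30),
                np.random.default_rng(1).normal(6, 0.5, 30),
            ]),
        })
        summary = stats.summarize_by_animal(records)
        a = summary[summary["condition"] == "control"]
        b = summary[summary["condition"] == "treated"]
        rep = stats.compare_two_groups(a, b, criterion="CI")
        assert rep.n_a == 3 and rep.n_b == 3


class TestRegions:
    def test_identical_groups_give_null_result(self):
        g = [1.0, 2.0, 3.0, 4.0]
        rep = stats.compare_regions([g, g, g])
        assert rep.statistic == pytest.approx(0.0, abs=1e-9)
        assert rep.p_value == pytest.approx(1.0)

    def test_shifted_region_detected_and_order_invariant(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 7)
        b = rng.normal(0, 1, 7)
        c = rng.normal(3, 1, 7)  # three pooled SDs away
        r1 = stats.compare_regions([a, b, c])
        r2 = stats.compare_regions([c, a, b])
        assert r1.p_value < 0.01
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_two_groups_insufficient(self):
        with pytest.raises(DataError):
            stats.compare_regions([[1, 2, 3], [4, 5, 6]])


class TestProportions:
    def test_equal_distributions_give_zero_chi2(self):
        rep = stats.compare_proportions([[50, 50], [50, 50]])
        assert rep.statistic == pytest.approx(0.0)
        assert rep.p_value == pytest.approx(1.0)

    def test_matches_hand_computed_chi2(self):
        table = [[90, 10, 40, 60], [50, 50, 30, 70]]
        rep = stats.compare_proportions(table)
        assert rep.statistic == pytest.approx(chi_square_by_hand(table))
        assert rep.detail == "df=3"

    def test_column_permutation_invariant(self):
        t1 = [[30, 50, 20], [10, 60, 30]]
        t2 = [[20, 30, 50], [30, 10, 60]]
        assert stats.compare_proportions(t1).statistic == pytest.approx(
            stats.compare_proportions(t2).statistic
        )

    def test_zero_expected_count_advises_pooling(self):
        with pytest.raises(DataError, match="pool"):
            stats.compare_proportions([[10, 0], [20, 0]])


class TestSpearman:
    def test_monotone_relations(self):
        x = np.arange(10.0)
        assert stats.correlate(x, x).statistic == pytest.approx(1.0)
        assert stats.correlate(x, -x).statistic == pytest.approx(-1.0)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(7)
        rep = stats.correlate(rng.normal(size=1000), rng.normal(size=1000))
        assert abs(rep.statistic) < 0.1

    def test_constant_vector_undefined(self):
        rep = stats.correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(rep.statistic)
        assert "undefined" in rep.detail


class TestSampleSize:
    def test_multiplier_value(self):
        assert stats.normal_multiplier() == pytest.approx(10.507, abs=0.001)

    @pytest.mark.parametrize(
        "ma, mb, sd, expected",
        [
            (74.4, 149.4, 42.2, 7),   # hippocampus cytoplasm
            (62.4, 123.0, 33.0, 7),   # frontal cortex cytoplasm
            (66.3, 129.2, 34.1, 7),   # striatum cytoplasm
            (123.4, 177.0, 37.9, 11), # cerebellum cytoplasm
            (4.5, 3.6, 0.5, 7),       # cerebellum CI
        ],
    )
    def test_published_design_rows(self, ma, mb, sd, expected):
        assert stats.required_sample_size(ma, mb, sd) == expected

    def test_symmetry_and_sigma_scaling(self):
        n1 = stats.required_sample_size(10, 20, 5)
        n2 = stats.required_sample_size(20, 10, 5)
        assert n1 == n2
        raw = lambda s: 2 * stats.normal_multiplier() * s**2 / 100.0
        assert raw(10) == pytest.approx(4 * raw(5))

    @given(
        delta=st.floats(0.5, 50, allow_nan=False),
        sd1=st.floats(0.5, 30, allow_nan=False),
        bump=st.floats(0.1, 10, allow_nan=False),
    )
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_sigma_and_effect(self, delta, sd1, bump):
        n_small_sd = stats.required_sample_size(0.0 + 1, 1 + delta, sd1)
        n_large_sd = stats.required_sample_size(0.0 + 1, 1 + delta, sd1 + bump)
        assert n_large_sd >= n_small_sd
        n_big_delta = stats.required_sample_size(1, 1 + delta + bump, sd1)
        assert n_big_delta <= n_small_sd

    def test_equal_means_is_an_error(self):
        with pytest.raises(DataError):
            stats.required_sample_size(5.0, 5.0, 1.0)


class TestCohortLevelBehaviour:
    def test_null_ci_comparison_rejects_at_about_alpha(self):
        rejections = 0
        n_sims = 150
        for i in range(n_sims):
            cohort = synth.generate_cohort(
                7, 6, cells_per_animal=10, seed=90_000 + i,
                treatment_effect={"cytoplasm_factor": 1.0},
            )
            a = [s.records["CI"].mean() for s in cohort if s.condition == "control"]
            b = [s.records["CI"].mean() for s in cohort if s.condition == "treated"]
            rejections += stats.compare_two_groups(a, b).p_value < 0.05
        assert rejections / n_sims < 0.14  # loose binomial bound around 0.05
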