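"""Agreement and comparison statistics against independent oracles."""

import math

import numpy as np
import pytest

from odacs.errors import DomainError
from odacs.stats import (
    DegenerateStatisticWarning,
    bland_altman,
    cohort_analysis,
    confusion_matrix,
    shift_proportion,
    weighted_kappa,
    wilcoxon_one_sided,
)

from conftest import brute_force_weighted_kappa, exact_wilcoxon_pvalue

CATS = (0, 1, 2, 3)


class TestWeightedKappa:
    def test_perfect_agreement(self):
        labels = [0, 1, 2, 3, 2, 1, 0, 3]
        assert weighted_kappa(labels, labels) == pytest.approx(1.0)

    def test_constant_rater_not_positive(self):
        a = [0, 1, 2, 3, 1, 2]
        b = [2, 2, 2, 2, 2, 2]
        assert weighted_kappa(a, b) <= 0.0

    def test_matches_brute_force_on_random_tables(self, rng):
        for _ in range(100):
            n = 50
            a = rng.integers(0, 4, size=n).tolist()
            b = np.clip(np.asarray(a) + rng.integers(-1, 2, size=n), 0, 3).tolist()
            expected = brute_force_weighted_kappa(a, b, CATS)
            assert weighted_kappa(a, b) == pytest.approx(expected, abs=1e-12)

    def test_matches_sklearn_cross_check(self, rng):
        from sklearn.metrics import cohen_kappa_score

        for _ in range(20):
            a = rng.integers(0, 4, size=40)
            b = rng.integers(0, 4, size=40)
            expected = cohen_kappa_score(a, b, labels=list(CATS), weights="quadratic")
            assert weighted_kappa(a.tolist(), b.tolist()) == pytest.approx(expected)

    def test_symmetry(self, rng):
        a = rng.integers(0, 4, size=30).tolist()
        b = rng.integers(0, 4, size=30).tolist()
        assert weighted_kappa(a, b) == pytest.approx(weighted_kappa(b, a))

    def test_undefined_pairs_dropped(self):
        a = [0, 1, None, 2]
        b = [0, 1, 2, 2]
        assert weighted_kappa(a, b) == pytest.approx(1.0)

    def test_degenerate_constant_agreement(self):
        # both raters constant on one category: zero expected AND zero
        # observed disagreement -> perfect agreement by convention.  (Zero
        # expected with nonzero observed disagreement cannot occur: any
        # off-diagonal observation forces its expected cell positive.)
        assert weighted_kappa([2, 2, 2], [2, 2, 2]) == pytest.approx(1.0)

    def test_fully_crossed_constant_raters(self):
        # a always 0, b always 1: kappa reduces to 0 (pure chance level)
        assert weighted_kappa([0] * 5, [1] * 5) == pytest.approx(0.0)

    def test_length_mismatch(self):
        with pytest.raises(DomainError):
            weighted_kappa([0, 1], [0, 1, 2])


class TestWilcoxon:
    def test_elementwise_smaller_n8_exact(self):
        # x strictly below y with distinct gaps: the minimum possible
        # signed-rank statistic, p = 1 / 2^8
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0]
        y = [v + 0.5 + 0.1 * i for i, v in enumerate(x)]
        _, p = wilcoxon_one_sided(x, y, alternative="less")
        assert p == pytest.approx(1 / 256)

    def test_exact_p_matches_enumeration(self, rng):
        for n in (5, 8, 10, 12):
            for _ in range(3):
                d = rng.normal(size=n)
                while np.unique(np.abs(d)).size < n or (d == 0).any():
                    d = rng.normal(size=n)
                x = np.zeros(n)
                y = -d  # so x - y = d
                for alt in ("less", "greater"):
                    _, p = wilcoxon_one_sided(x.tolist(), y.tolist(), alternative=alt)
                    assert p == pytest.approx(exact_wilcoxon_pvalue(d, alt), abs=1e-12)

    def test_exact_p_bounds(self, rng):
        for n in (6, 10, 12):
            d = np.arange(1, n + 1, dtype=float)
            _, p = wilcoxon_one_sided(d.tolist(), [0.0] * n, alternative="less")
            assert 2.0**-n <= p <= 1.0

    def test_all_zero_differences_flagged(self):
        with pytest.warns(DegenerateStatisticWarning):
            stat, p = wilcoxon_one_sided([1.0, 2.0], [1.0, 2.0])
        assert math.isnan(p)

    def test_ties_fall_back_to_normal_approximation(self, rng):
        x = [1.0, 2.0, 3.0, 4.0, 1.0, 2.0]
        y = [2.0, 3.0, 4.0, 5.0, 2.0, 3.0]  # all |d| = 1: heavy ties
        _, p = wilcoxon_one_sided(x, y, alternative="less")
        assert 0.0 < p < 0.2


class TestBlandAltman:
    def test_hand_example(self):
        x = [1.1, 1.2, 1.3]
        y = [1.0, 1.0, 1.0]
        mean_diff, lo, hi, _, d = bland_altman(x, y)
        assert mean_diff == pytest.approx(0.2)
        assert lo == pytest.approx(0.004, abs=1e-12)
        assert hi == pytest.approx(0.396, abs=1e-12)
        np.testing.assert_allclose(d, [0.1, 0.2, 0.3])

    def test_identical_sequences(self):
        m, lo, hi, _, _ = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (m, lo, hi) == (0.0, 0.0, 0.0)

    def test_antisymmetry_under_swap(self, rng):
        x = rng.normal(size=10).tolist()
        y = rng.normal(size=10).tolist()
        m1, lo1, hi1, _, _ = bland_altman(x, y)
        m2, lo2, hi2, _, _ = bland_altman(y, x)
        assert m2 == pytest.approx(-m1)
        assert lo2 == pytest.approx(-hi1)
        assert hi2 == pytest.approx(-lo1)

    def test_too_few_pairs(self):
        with pytest.raises(DomainError):
            bland_altman([1.0], [2.0])


class TestShiftProportion:
    def test_all_shift(self):
        num, den, frac = shift_proportion([2] * 10, [1] * 10)
        assert (num, den, frac) == (10, 10, 1.0)

    def test_no_good_reference(self):
        num, den, frac = shift_proportion([0, 1, 1, 0], [0, 0, 1, 1])
        assert (num, den, frac) == (0, 4, 0.0)

    def test_mixed_hand_count(self):
        ref = [2, 3, 1, 2, 3, 0]
        new = [1, 3, 0, 0, 2, 0]
        num, den, frac = shift_proportion(ref, new)
        assert (num, den) == (2, 6)
        assert frac == pytest.approx(2 / 6)

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            shift_proportion([], [])


class TestConfusionMatrix:
    def test_diagonal_for_identical_labels(self):
        labels = [0, 1, 1, 2, 3, 3, 3]
        m = confusion_matrix(labels, labels)
        assert m.sum() == 7
        np.testing.assert_array_equal(m, np.diag([1, 2, 1, 3]))

    def test_marginals_reproduce_histograms(self, rng):
        a = rng.integers(0, 4, size=60).tolist()
        b = rng.integers(0, 4, size=60).tolist()
        m = confusion_matrix(a, b)
        np.testing.assert_array_equal(m.sum(axis=1), np.bincount(a, minlength=4))
        np.testing.assert_array_equal(m.sum(axis=0), np.bincount(b, minlength=4))

    def test_fixed_category_set_even_when_unobserved(self):
        m = confusion_matrix([1, 1], [1, 2])
        assert m.shape == (4, 4)

    def test_label_outside_categories(self):
        with pytest.raises(DomainError):
            confusion_matrix([5], [1])


@pytest.fixture(scope="module")
def table():
    from odacs.phantom import generate_cohort

    _, table = generate_cohort(16, seed=5)
    return table


class TestCohortAnalysis:
    def test_structure_and_medians(self, table):
        report = cohort_analysis(table)
        assert set(report) == {"overall", "proximal_M1", "distal_M1", "M2"}
        overall = report["overall"]
        assert overall["n"] == 16
        med = overall["quantitative_odacs"]["median"]
        assert med == pytest.approx(float(np.median(table["odacs_ratio"].dropna())))
        q1 = overall["quantitative_odacs"]["iqr_low"]
        assert q1 == pytest.approx(float(np.percentile(table["odacs_ratio"].dropna(), 25)))

    def test_small_groups_flagged_undefined(self, table):
        sub = table.head(3).copy()
        sub["occlusion_location"] = ["proximal_M1", "proximal_M1", "M2"]
        sub["patient_id"] = ["a", "b", "c"]
        report = cohort_analysis(sub)
        assert report["M2"]["bland_altman"] is None
        assert report["distal_M1"] is None

    def test_identical_scores_no_shift(self, table):
        sub = table.copy()
        sub["mca_ratio"] = sub["odacs_ratio"]
        sub["mca_category"] = sub["odacs_category"]
        report = cohort_analysis(sub)
        assert report["overall"]["shift_good_to_poor"]["numerator"] == 0

    def test_duplicate_patient_ids_rejected(self, table):
        bad = table.copy()
        bad.loc[1, "patient_id"] = bad.loc[0, "patient_id"]
        with pytest.raises(DomainError):
            cohort_analysis(bad)
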