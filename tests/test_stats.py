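import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binom, chi2_contingency

from c9screen.io import Subject
from c9screen.stats import (
    chi_square_test,
    clopper_pearson,
    demographics_table,
    frequency_table,
)


def bisect_cp_bounds(k, n, conf=0.95, tol=1e-12):
    """Bisection oracle: invert the binomial tail equations directly,
    independent of any beta-quantile code."""
    alpha = 1 - conf

    def solve(f, lo, hi):
        for _ in range(200):
            mid = (lo + hi) / 2
            if f(mid) > 0:
                hi = mid
            else:
                lo = mid
        return (lo + hi) / 2

    lower = 0.0 if k == 0 else solve(
        lambda p: binom.sf(k - 1, n, p) - alpha / 2, 0.0, 1.0
    )
    upper = 1.0 if k == n else solve(
        lambda p: -(binom.cdf(k, n, p) - alpha / 2), 0.0, 1.0
    )
    return lower, upper


class TestClopperPearson:
    @pytest.mark.parametrize(
        "k,n,lo,hi",
        [
            (61, 289, 16.5, 26.3),
            (0, 3, 0.0, 70.8),
            (1, 1, 2.5, 100.0),
            (52, 112, 37.0, 56.1),
        ],
    )
    def test_printed_interval_bounds(self, k, n, lo, hi):
        ci = clopper_pearson(k, n)
        assert round(100 * ci.lower, 1) == lo
        assert round(100 * ci.upper, 1) == hi

    def test_agrees_with_binomial_tail_bisection(self):
        for k, n in [(2, 10), (0, 7), (7, 7), (13, 40), (61, 289)]:
            ci = clopper_pearson(k, n)
            lo, hi = bisect_cp_bounds(k, n)
            assert ci.lower == pytest.approx(lo, abs=1e-10)
            assert ci.upper == pytest.approx(hi, abs=1e-10)

    def test_degenerate_endpoints(self):
        assert clopper_pearson(0, 5).lower == 0.0
        assert clopper_pearson(5, 5).upper == 1.0

    def test_bounds_bracket_the_point_estimate(self):
        for k in range(0, 21):
            ci = clopper_pearson(k, 20)
            assert ci.lower <= ci.p_hat <= ci.upper

    def test_monotone_in_k_and_narrowing_in_n(self):
        lowers = [clopper_pearson(k, 30).lower for k in range(31)]
        uppers = [clopper_pearson(k, 30).upper for k in range(31)]
        assert lowers == sorted(lowers)
        assert uppers == sorted(uppers)
        w_small = clopper_pearson(5, 50)
        w_big = clopper_pearson(50, 500)
        assert (w_big.upper - w_big.lower) < (w_small.upper - w_small.lower)

    @settings(derandomize=True, max_examples=150)
    @given(
        n=st.integers(min_value=1, max_value=500),
        frac=st.floats(min_value=0.0, max_value=1.0),
        conf=st.floats(min_value=0.5, max_value=0.999),
    )
    def test_interval_invariants_hold_for_arbitrary_counts(self, n, frac, conf):
        k = round(frac * n)
        ci = clopper_pearson(k, n, conf)
        assert 0.0 <= ci.lower <= ci.p_hat <= ci.upper <= 1.0
        if k == 0:
            assert ci.lower == 0.0
        if k == n:
            assert ci.upper == 1.0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            clopper_pearson(5, 4)
        with pytest.raises(ValueError):
            clopper_pearson(0, 0)

    def test_exact_coverage_is_conservative(self, rng):
        """Over 2000 simulated binomials at n=50, p=0.1 the interval covers
        the true p at >= 95% (the exact method over-covers)."""
        p, n = 0.1, 50
        ks = rng.binomial(n, p, size=2000)
        covered = sum(
            clopper_pearson(int(k), n).lower <= p <= clopper_pearson(int(k), n).upper
            for k in ks
        )
        assert covered / 2000 >= 0.95


class TestChiSquare:
    def test_sex_table_counts(self):
        """Carriers 232 male / 233 female vs non-carriers 2251 / 1602."""
        res = chi_square_test([[232, 233], [2251, 1602]], yates=False)
        assert res.statistic == pytest.approx(12.353, abs=1e-3)
        assert res.df == 1

    def test_identical_row_proportions_score_zero(self):
        res = chi_square_test([[10, 20], [30, 60]], yates=False)
        assert res.statistic == pytest.approx(0.0)

    def test_oracle_equivalence_2x3(self):
        table = [[106, 11, 7], [685, 165, 195]]
        res = chi_square_test(table)
        ref = chi2_contingency(np.array(table), correction=False)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-9)
        assert res.df == 2
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_oracle_equivalence_random_tables(self, rng):
        for _ in range(100):
            shape = rng.choice([(2, 2), (2, 3), (3, 4)])
            t = rng.integers(1, 200, size=tuple(shape))
            for yates in (False, True):
                res = chi_square_test(t, yates=yates)
                ref = chi2_contingency(t, correction=yates and t.shape == (2, 2))
                assert res.statistic == pytest.approx(ref.statistic, abs=1e-9)
                assert res.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_invariant_to_row_and_column_swaps(self):
        t = np.array([[5, 10, 15], [20, 10, 5]])
        base = chi_square_test(t).statistic
        assert chi_square_test(t[::-1]).statistic == pytest.approx(base)
        assert chi_square_test(t[:, ::-1]).statistic == pytest.approx(base)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_test([[0, 0], [5, 10]])

    def test_low_expected_count_flagged(self):
        res = chi_square_test([[1, 2], [3, 4]])
        assert res.low_expected


def make_cohort(k, n, region="X"):
    subjects = []
    for i in range(n):
        subjects.append(
            Subject(
                f"{region}{i}", "ALS", False, region=region,
                carrier=i < k, age_onset_y=55.0,
            )
        )
    return subjects


class TestFrequencyTable:
    def test_single_carrier_row_matches_printed_ci(self):
        table = frequency_table(make_cohort(1, 1), ["region"])
        row = table[table.region == "X"].iloc[0]
        assert (row.k, row.n) == (1, 1)
        assert round(100 * row.ci_lower, 1) == 2.5
        assert round(100 * row.ci_upper, 1) == 100.0

    def test_totals_row_conserves_counts(self):
        subjects = make_cohort(3, 10, "A") + make_cohort(5, 20, "B")
        table = frequency_table(subjects, ["region"])
        total = table[table.region == "__total__"].iloc[0]
        strata = table[table.region != "__total__"]
        assert total.k == strata.k.sum() == 8
        assert total.n == strata.n.sum() == 30

    def test_unknown_carriers_excluded(self):
        subjects = make_cohort(2, 5)
        subjects.append(Subject("u", "ALS", False, carrier=None))
        table = frequency_table(subjects, ["region"])
        assert table[table.region == "X"].iloc[0].n == 5

    def test_empty_strata_rejected(self):
        with pytest.raises(ValueError):
            frequency_table(make_cohort(1, 2), [])

    def test_true_rate_covered_by_interval(self, rng):
        """Simulated binomial cohorts at the familial-disease carrier rate
        0.393: the exact CI covers the truth in >= 93 of 100 replicates."""
        hits = 0
        for _ in range(100):
            k = rng.binomial(552, 0.393)
            ci = clopper_pearson(int(k), 552)
            hits += ci.lower <= 0.393 <= ci.upper
        assert hits >= 93


class TestDemographics:
    def test_single_subject_group_conventions(self):
        s = [Subject("a", "ALS", True, sex="male", carrier=True,
                     age_onset_y=50.0, onset_site="bulbar")]
        df = demographics_table(s)
        row = df.iloc[0]
        assert row.onset_mean == row.onset_min == row.onset_max == 50.0
        assert row.onset_sd == 0.0
        assert row.male_pct == 100.0

    def test_family_history_percentage(self):
        subjects = [
            Subject(f"s{i}", "ALS", i < 221, carrier=True, age_onset_y=55.0)
            for i in range(465)
        ]
        df = demographics_table(subjects)
        row = df.iloc[0]
        assert row.familial_k == 221
        assert row.familial_pct == pytest.approx(100 * 221 / 465, abs=1e-9)
        assert round(row.familial_pct, 1) == 47.5

    def test_group_onset_mean_recovery(self, rng):
        """Onset drawn at mean 56.8, SD 9.1, n=465: the summary mean lands
        within ~2 SE of the generative mean."""
        subjects = [
            Subject(f"s{i}", "ALS", False, carrier=True,
                    age_onset_y=float(rng.normal(56.8, 9.1)))
            for i in range(465)
        ]
        df = demographics_table(subjects)
        assert df.iloc[0].onset_mean == pytest.approx(56.8, abs=0.9)

    def test_missing_counts_reported(self):
        subjects = [
            Subject("a", "ALS", False, carrier=True, age_onset_y=50.0),
            Subject("b", "ALS", False, carrier=True),
        ]
        df = demographics_table(subjects)
        assert df.iloc[0].onset_missing == 1
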