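import numpy as np
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from c9screen.io import Subject
from c9screen.penetrance import (
    age_at_penetrance,
    km_curve,
    logrank_test,
    onset_and_censor_ages,
    penetrance_by_group,
)


class TestKMCurve:
    def test_hand_worked_product_limit(self):
        """Events at 40 and 50, one censoring at 45:
        S(40) = 1 - 1/3 = 2/3; at 50 the risk set is 1 so S(50) = 0."""
        c = km_curve([40, 50], [45])
        assert c.survival_at(40) == pytest.approx(2 / 3)
        assert c.survival_at(50) == 0.0
        assert c.penetrance_at(50) == 1.0
        assert c.survival_at(39) == 1.0

    def test_reduces_to_ecdf_without_censoring(self, rng):
        ages = rng.uniform(30, 80, size=40)
        c = km_curve(ages)
        for t in [35.0, 50.0, 79.0, 90.0]:
            assert c.penetrance_at(t) == pytest.approx((ages <= t).mean())

    def test_requires_events_and_positive_ages(self):
        with pytest.raises(ValueError, match="onset event"):
            km_curve([], [50, 60])
        with pytest.raises(ValueError, match="> 0"):
            km_curve([40, -1])

    def test_early_censoring_changes_nothing(self, rng):
        """A subject censored before the first event never enters any event
        risk set, so the curve is unchanged.  (A censoring *older* than all
        events does change the curve: it inflates every risk set.)"""
        events = sorted(rng.uniform(30, 70, size=25))
        cens = list(rng.uniform(30, 70, size=5))
        base = km_curve(events, cens)
        extended = km_curve(events, cens + [min(events) - 5.0])
        np.testing.assert_allclose(extended.survival, base.survival)
        late = km_curve(events, cens + [99.0])
        assert late.survival[0] > base.survival[0]

    def test_greenwood_variance_shape(self, rng):
        """The *relative* variance (Greenwood's cumulative sum, i.e.
        Var[S]/S^2) is non-decreasing in age; the absolute variance need not
        be, since S^2 shrinks toward the tail."""
        events = rng.uniform(30, 70, size=30)
        cens = rng.uniform(30, 70, size=10)
        c = km_curve(events, cens)
        alive = c.survival > 0
        rel = c.greenwood_var[alive] / c.survival[alive] ** 2
        assert (np.diff(rel) >= -1e-12).all()
        assert (c.greenwood_var >= 0).all()
        assert c.survival_at(events.min() - 1) == 1.0  # variance-free region

    def test_matches_reference_implementation_on_random_data(self, rng):
        """Product-limit curve equals lifelines on 100 random small datasets
        to 1e-12, including tied events and event/censoring ties."""
        kmf = KaplanMeierFitter()
        for _ in range(100):
            n = int(rng.integers(2, 31))
            ages = np.round(rng.uniform(20, 80, size=n), 1)
            observed = rng.random(n) < 0.7
            if not observed.any():
                observed[0] = True
            c = km_curve(ages[observed], ages[~observed])
            kmf.fit(ages, observed)
            ours = np.array([c.survival_at(t) for t in c.event_ages])
            ref = kmf.survival_function_at_times(c.event_ages).to_numpy()
            np.testing.assert_allclose(ours, ref, atol=1e-12)


class TestAgeAtPenetrance:
    def test_median_age_on_hand_curve(self):
        c = km_curve([40, 50], [45])
        # P(40) = 1/3 < 0.5; the smallest event age with P >= 0.5 is 50
        assert age_at_penetrance(c, 0.5) == 50.0

    def test_unreached_quantile_is_flagged(self):
        c = km_curve([40], [99, 99, 99, 99, 99, 99, 99, 99, 99])
        assert age_at_penetrance(c, 0.99) is None

    @pytest.mark.parametrize("q", [0.0, 1.0, -0.1, 1.5])
    def test_quantile_domain(self, q):
        c = km_curve([40, 50], [45])
        with pytest.raises(ValueError):
            age_at_penetrance(c, q)

    def test_recovers_generative_median_on_synthetic_onsets(self, rng):
        """n = 598 events from a truncated Normal(56.8, 9.1) plus 5 early
        censorings: the KM median age estimates the generative median to
        within a year on average over 20 replicates."""
        from scipy.stats import truncnorm

        a = (0 - 56.8) / 9.1
        true_median = truncnorm.median(a, np.inf, loc=56.8, scale=9.1)
        errors = []
        for _ in range(20):
            onsets = truncnorm.rvs(a, np.inf, loc=56.8, scale=9.1,
                                   size=598, random_state=rng)
            curve = km_curve(onsets, [40.0] * 5)
            errors.append(age_at_penetrance(curve, 0.5) - true_median)
        assert abs(np.mean(errors)) < 1.0


class TestLogrank:
    def test_identical_single_subject_groups_score_zero(self):
        res = logrank_test([([50.0], []), ([50.0], [])])
        assert res.statistic == pytest.approx(0.0)
        assert res.df == 1

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            logrank_test([([50.0], [])])

    def test_matches_reference_implementation(self, rng):
        import pandas as pd

        for k in (2, 3):
            for _ in range(20):
                times, events, labels = [], [], []
                for g in range(k):
                    n = int(rng.integers(5, 40))
                    t = np.round(rng.uniform(20, 80, size=n), 0)
                    obs = rng.random(n) < 0.7
                    times.extend(t)
                    events.extend(obs)
                    labels.extend([g] * n)
                df = pd.DataFrame(
                    {"t": times, "e": events, "g": labels}
                )
                groups = [
                    (
                        df.t[(df.g == g) & df.e].tolist(),
                        df.t[(df.g == g) & ~df.e].tolist(),
                    )
                    for g in range(k)
                ]
                if sum(len(e) for e, _ in groups) == 0:
                    continue
                ours = logrank_test(groups)
                ref = multivariate_logrank_test(df.t, df.g, df.e)
                assert ours.statistic == pytest.approx(
                    ref.test_statistic, abs=1e-8
                )
                assert ours.p_value == pytest.approx(ref.p_value, abs=1e-8)

    def test_type_one_error_calibration(self, rng):
        """Two groups from the same onset distribution: rejection rate at
        alpha = 0.05 stays within [0.03, 0.07] over 1000 simulations."""
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            a = rng.normal(58, 9, size=200)
            b = rng.normal(58, 9, size=200)
            ca = rng.uniform(40, 80, size=20)
            cb = rng.uniform(40, 80, size=20)
            res = logrank_test([(a, ca), (b, cb)])
            rejections += res.p_value < 0.05
        assert 0.03 <= rejections / n_sim <= 0.07

    def test_power_against_a_twenty_year_shift(self, rng):
        hits = 0
        for _ in range(40):
            a = rng.normal(55, 9, size=200)
            res = logrank_test([(a, []), (a + 20, [])])
            hits += res.p_value < 0.001
        assert hits >= 38


class TestSubjectWiring:
    def make_subjects(self):
        return [
            Subject("a", "ALS", True, carrier=True, age_onset_y=50.0),
            Subject("b", "FTD", False, carrier=True, age_onset_y=60.0),
            Subject("c", "control", False, carrier=True, age_last_y=55.0),
            Subject("d", "ALS", False, carrier=False, age_onset_y=45.0),
            Subject("e", "ALS", True, carrier=True),  # missing onset: dropped
        ]

    def test_onset_censor_split_and_carrier_filter(self):
        events, cens = onset_and_censor_ages(self.make_subjects())
        assert sorted(events) == [50.0, 60.0]
        assert cens == [55.0]

    def test_grouped_curves_with_logrank(self):
        subjects = self.make_subjects()
        curves, test = penetrance_by_group(subjects, by="diagnosis")
        assert set(curves) <= {"ALS", "FTD", "control"}
        assert ("ALS" in curves) and ("FTD" in curves)
        assert test is not None and test.df == 1
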