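import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eaccd import (harrell_c_index, initial_dissimilarity, km_estimate,
                   mann_whitney_parameter, reverse_km_median_followup,
                   survival_rate_at)

from conftest import random_censored_cohort


def brute_force_c_index(scores, times, events):
    """Exhaustive pair enumeration with the classical permissibility rule."""
    conc = tied = perm = 0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if not (events[i] == 1 and (times[i] < times[j]
                    or (times[i] == times[j] and events[j] == 0))):
                continue
            perm += 1
            if scores[i] > scores[j]:
                conc += 1
            elif scores[i] == scores[j]:
                tied += 1
    return (conc + 0.5 * tied) / perm


class TestKaplanMeier:
    def test_uncensored_reduces_to_empirical(self):
        km = km_estimate([1, 2, 3], [1, 1, 1])
        assert np.allclose(km.survival, [2 / 3, 1 / 3, 0.0])

    def test_all_censored_stays_at_one(self):
        km = km_estimate([5, 8, 13], [0, 0, 0])
        assert km.times.size == 0
        assert km.surv_at(100.0) == 1.0

    def test_hand_product_limit(self):
        km = km_estimate([1, 1, 2, 3, 4], [1, 0, 1, 1, 0])
        assert np.allclose(km.survival, [4 / 5, 8 / 15, 4 / 15])

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            km_estimate([], [])

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(3)
        t, e = random_censored_cohort(rng, 200)
        km = km_estimate(t, e)
        kmf = lifelines.KaplanMeierFitter().fit(t, e)
        ours = [survival_rate_at(km, x) for x in km.times]
        theirs = [float(kmf.predict(x)) for x in km.times]
        assert np.allclose(ours, theirs, atol=1e-10)

    def test_survival_non_increasing_property(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            t, e = random_censored_cohort(rng, 50)
            km = km_estimate(t, e)
            assert (np.diff(km.survival) <= 1e-15).all()


class TestSurvivalRateAt:
    km = km_estimate([1, 1, 2, 3, 4], [1, 0, 1, 1, 0])

    def test_zero_is_one(self):
        assert survival_rate_at(self.km, 0) == 1.0

    def test_step_evaluation(self):
        assert survival_rate_at(self.km, 2.5) == pytest.approx(8 / 15)

    def test_beyond_followup_holds_last_value(self):
        assert survival_rate_at(self.km, 99) == pytest.approx(4 / 15)


class TestReverseKM:
    def test_single_censoring_time(self):
        assert reverse_km_median_followup([70] * 6, [0] * 6) == 70

    def test_four_censored_points(self):
        assert reverse_km_median_followup([60, 70, 80, 90], [0, 0, 0, 0]) == 80

    def test_no_censoring_undefined(self):
        assert reverse_km_median_followup([1, 2, 3], [1, 1, 1]) is None


class TestMannWhitney:
    def test_identical_cohorts_give_half(self):
        t = np.array([3, 5, 5, 9, 20.0])
        e = np.array([1, 1, 0, 1, 0])
        est = mann_whitney_parameter(t, e, t, e)
        assert est.theta == pytest.approx(0.5, abs=1e-12)

    def test_uncensored_equals_classical_u(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n, m = rng.integers(5, 60, 2)
            x = rng.integers(1, 25, n).astype(float)
            y = rng.integers(1, 25, m).astype(float)
            est = mann_whitney_parameter(x, np.ones(n, int), y, np.ones(m, int))
            u = (np.sum(x[:, None] < y[None, :])
                 + 0.5 * np.sum(x[:, None] == y[None, :])) / (n * m)
            assert est.theta == pytest.approx(u, abs=1e-12)

    def test_symmetrization_property(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            ti, ei = random_censored_cohort(rng, int(rng.integers(10, 80)))
            tj, ej = random_censored_cohort(rng, int(rng.integers(10, 80)),
                                            scale=rng.uniform(10, 60))
            a = mann_whitney_parameter(ti, ei, tj, ej).theta
            b = mann_whitney_parameter(tj, ej, ti, ei).theta
            assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_exponential_limit(self):
        rng = np.random.default_rng(5)
        lam_i, lam_j = 0.08, 0.02
        xi = rng.exponential(1 / lam_i, 4000)
        xj = rng.exponential(1 / lam_j, 4000)
        e = np.ones(4000, int)
        est = mann_whitney_parameter(xi, e, xj, e)
        assert est.theta == pytest.approx(lam_i / (lam_i + lam_j), abs=0.03)

    def test_zero_event_cohort_warns_not_errors(self):
        t = np.array([10.0, 20, 30])
        est = mann_whitney_parameter(t, np.zeros(3, int), t, np.ones(3, int))
        assert 0.0 <= est.theta <= 1.0
        assert est.tail_mass_i == 1.0


class TestInitialDissimilarity:
    @pytest.mark.parametrize("theta, d", [(0.5, 0.0), (1.0, 1.0), (0.0, 1.0),
                                          (0.8, 0.6)])
    def test_formula(self, theta, d):
        assert initial_dissimilarity(theta) == pytest.approx(d)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            initial_dissimilarity(1.2)


class TestHarrellC:
    def test_perfect_ordering(self):
        assert harrell_c_index([5, 4, 3, 2, 1], [1, 2, 3, 4, 5], [1] * 5) == 1.0

    def test_all_tied_scores(self):
        assert harrell_c_index([2] * 5, [1, 2, 3, 4, 5], [1] * 5) == 0.5

    def test_mixed_censoring_matches_brute_force(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = int(rng.integers(5, 200))
            t, e = random_censored_cohort(rng, n)
            s = rng.integers(0, 6, n).astype(float)
            if not e.any():
                continue
            assert harrell_c_index(s, t, e) == pytest.approx(
                brute_force_c_index(s, t, e), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(8)
        t, e = random_censored_cohort(rng, 120)
        s = rng.normal(size=120)
        c1 = harrell_c_index(s, t, e)
        c2 = harrell_c_index(np.exp(3 * s) + 7, t, e)
        assert c1 == pytest.approx(c2, abs=1e-12)

    def test_matches_lifelines_on_untied_scores(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(10)
        t, e = random_censored_cohort(rng, 150)
        s = rng.normal(size=150)
        # lifelines orients concordance toward predicted survival times
        theirs = lifelines.utils.concordance_index(t, -s, e)
        assert harrell_c_index(s, t, e) == pytest.approx(theirs, abs=1e-12)

    def test_no_permissible_pairs_errors(self):
        with pytest.raises(ValueError):
            harrell_c_index([1, 2], [5, 5], [0, 0])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 15), st.booleans(),
                              st.integers(0, 4)), min_size=3, max_size=40))
    def test_brute_force_agreement_hypothesis(self, rows):
        t = np.array([r[0] for r in rows], float)
        e = np.array([int(r[1]) for r in rows])
        s = np.array([r[2] for r in rows], float)
        try:
            ours = harrell_c_index(s, t, e)
        except ValueError:
            return
        assert ours == pytest.approx(brute_force_c_index(s, t, e), abs=1e-12)
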