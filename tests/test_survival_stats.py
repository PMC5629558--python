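import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from survstrat import (
    RiskGrouping,
    bh_fdr,
    cox_binary_wald,
    km_curve,
    logrank,
    weighted_kappa,
)
from survstrat.errors import (
    DegenerateGroupError,
    EmptyCohortError,
    NoContrastError,
    SeparationError,
    ValidationError,
)


def censored_sample(seed, n=100, k_groups=1):
    r = np.random.default_rng(seed)
    g = r.integers(0, k_groups, n)
    lam = 0.3 * np.exp(0.4 * g)
    T = r.exponential(1 / lam)
    C = r.uniform(0, 6, n)
    return np.minimum(T, C), (T <= C).astype(int), g


class TestKaplanMeier:
    def test_no_events_means_flat_survival(self):
        km = km_curve([1.0, 2.0, 3.0], [0, 0, 0])
        assert km.at(0.5) == 1.0 and km.at(10.0) == 1.0

    def test_hand_product_limit(self):
        km = km_curve([1.0, 2.0, 3.0], [1, 1, 0])
        assert km.at(1.5) == pytest.approx(2 / 3)
        assert km.at(2.5) == pytest.approx(1 / 3)
        assert km.at(100.0) == pytest.approx(1 / 3)

    def test_matches_lifelines_product_limit(self):
        from lifelines import KaplanMeierFitter

        t, e, _ = censored_sample(3)
        km = km_curve(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        theirs = np.array([kmf.predict(ti) for ti in km.event_times])
        assert np.max(np.abs(km.survival - theirs)) < 1e-12

    def test_permutation_invariant(self, rng):
        t, e, _ = censored_sample(4)
        perm = rng.permutation(len(t))
        a, b = km_curve(t, e), km_curve(t[perm], e[perm])
        np.testing.assert_array_equal(a.event_times, b.event_times)
        np.testing.assert_allclose(a.survival, b.survival, rtol=0, atol=0)

    def test_empty_rejected(self):
        with pytest.raises(EmptyCohortError):
            km_curve([], [])


def brute_logrank_two_group(g, t, e):
    """Observed-minus-expected by direct enumeration over event times."""
    O = E = V = 0.0
    for tau in sorted(set(t[e == 1])):
        at_risk = t >= tau
        r, r1 = at_risk.sum(), (at_risk & (g == 1)).sum()
        d = ((t == tau) & (e == 1)).sum()
        d1 = ((t == tau) & (e == 1) & (g == 1)).sum()
        O += d1
        E += d * r1 / r
        if r > 1:
            V += d * (r1 / r) * (1 - r1 / r) * (r - d) / (r - 1)
    return (O - E) ** 2 / V


class TestLogrank:
    def test_identical_groups_give_null_statistic(self):
        t = np.array([1.0, 2, 3, 1, 2, 3])
        e = np.array([1, 0, 1, 1, 0, 1])
        g = np.array([0, 0, 0, 1, 1, 1])
        chi2, p = logrank(g, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_six_patient_hand_oracle(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        e = np.array([1, 1, 0, 1, 1, 0])
        g = np.array([0, 1, 0, 1, 0, 1])
        chi2, _ = logrank(g, t, e)
        assert chi2 == pytest.approx(brute_logrank_two_group(g, t, e), abs=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_three_groups_match_lifelines(self, seed):
        from lifelines.statistics import multivariate_logrank_test

        t, e, g = censored_sample(seed, n=240, k_groups=3)
        chi2, p = logrank(g, t, e)
        res = multivariate_logrank_test(t, g, e)
        assert chi2 == pytest.approx(res.test_statistic, abs=1e-8)
        assert p == pytest.approx(res.p_value, abs=1e-8)

    def test_empty_group_rejected(self):
        with pytest.raises(DegenerateGroupError):
            logrank(np.zeros(5, dtype=int), np.arange(1.0, 6.0), np.ones(5, dtype=int))


class TestCoxBinaryWald:
    def test_label_swap_flips_beta_only(self):
        t, e, _ = censored_sample(5)
        z = (np.arange(len(t)) % 3 == 0).astype(int)
        a = cox_binary_wald(z, t, e)
        b = cox_binary_wald(1 - z, t, e)
        assert a.beta == pytest.approx(-b.beta, abs=1e-10)
        assert a.p == pytest.approx(b.p, abs=1e-10)

    def test_planted_hazard_ratio_matches_library_fit(self):
        import pandas as pd
        from lifelines import CoxPHFitter

        r = np.random.default_rng(12)
        n = 500
        z = (r.random(n) > 0.5).astype(float)
        lam = 0.3 * np.exp(np.log(3.0) * z)
        T = r.exponential(1 / lam)
        C = r.uniform(0, 10, n)
        t, e = np.minimum(T, C), (T <= C).astype(int)
        mine = cox_binary_wald(z, t, e)
        cph = CoxPHFitter().fit(pd.DataFrame({"t": t, "e": e, "z": z}), "t", "e")
        lo, hi = np.exp(cph.confidence_intervals_.iloc[0])
        assert lo < 3.0 < hi  # planted HR inside the oracle's 95% CI
        assert mine.beta == pytest.approx(cph.params_.iloc[0], abs=1e-6)
        assert mine.se == pytest.approx(cph.standard_errors_.iloc[0], abs=1e-6)

    def test_efron_ties_match_library(self):
        import pandas as pd
        from lifelines import CoxPHFitter

        t, e, _ = censored_sample(6, n=200)
        t = np.round(t, 1) + 0.05
        z = (np.arange(len(t)) % 2).astype(float)
        mine = cox_binary_wald(z, t, e)
        cph = CoxPHFitter().fit(pd.DataFrame({"t": t, "e": e, "z": z}), "t", "e")
        assert mine.beta == pytest.approx(cph.params_.iloc[0], abs=1e-6)

    def test_single_valued_indicator_rejected(self):
        with pytest.raises(NoContrastError):
            cox_binary_wald(np.ones(20), np.arange(1.0, 21.0), np.ones(20, dtype=int))

    def test_monotone_likelihood_raises_separation(self):
        # all events in group 1, none in group 0 -> diverging estimate
        t = np.concatenate([np.arange(1.0, 11.0), np.arange(1.0, 11.0)])
        e = np.array([1] * 10 + [0] * 10)
        z = np.array([1.0] * 10 + [0.0] * 10)
        with pytest.raises(SeparationError) as exc:
            cox_binary_wald(z, t, e)
        assert exc.value.diagnostics["events_group0"] == 0


class TestBhFdr:
    def test_all_ones_unchanged(self):
        np.testing.assert_array_equal(bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_hand_step_up(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_brute_force_step_up(self, pvals):
        p = np.array(pvals)
        q = bh_fdr(p)
        m = len(p)
        order = np.argsort(p, kind="stable")
        expect = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            i = order[rank]
            running = min(running, p[i] * m / (rank + 1))
            expect[i] = running
        np.testing.assert_allclose(q, expect, atol=1e-12)
        assert np.all(q >= p - 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.5])


class TestWeightedKappa:
    def _grouping(self, labels):
        return RiskGrouping({f"S{i}": lab for i, lab in enumerate(labels)},
                            k=3 if "intermediate" in labels else 2)

    def test_perfect_agreement(self):
        labs = ["low", "intermediate", "high"] * 10
        k, p = weighted_kappa(self._grouping(labs), self._grouping(labs))
        assert k == pytest.approx(1.0)
        assert p < 0.01

    def test_independent_labelings_near_zero(self):
        r = np.random.default_rng(2)
        labs = (["low"] * 170 + ["intermediate"] * 170 + ["high"] * 160)
        perm = list(np.array(labs)[r.permutation(500)])
        k, _ = weighted_kappa(self._grouping(labs), self._grouping(perm))
        assert abs(k) < 0.1

    def test_symmetric(self):
        r = np.random.default_rng(3)
        a = list(r.choice(["low", "intermediate", "high"], 200))
        b = list(r.choice(["low", "intermediate", "high"], 200))
        kab, pab = weighted_kappa(self._grouping(a), self._grouping(b))
        kba, pba = weighted_kappa(self._grouping(b), self._grouping(a))
        assert kab == pytest.approx(kba, abs=1e-12)
        assert pab == pytest.approx(pba, abs=1e-12)

    def test_point_estimate_matches_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        r = np.random.default_rng(4)
        a = r.choice([0, 1, 2], 300, p=[0.5, 0.3, 0.2])
        b = np.where(r.random(300) < 0.6, a, r.choice([0, 1, 2], 300))
        levels = ["low", "intermediate", "high"]
        ka, _ = weighted_kappa(self._grouping([levels[i] for i in a]),
                               self._grouping([levels[i] for i in b]))
        theirs = cohen_kappa_score(a, b, weights="linear")
        assert ka == pytest.approx(theirs, abs=1e-10)


class TestCrossPrimitiveConsistency:
    def test_cox_sign_agrees_with_km_ordering(self):
        from conftest import make_cohort

        x, t, e, c = make_cohort(seed=9, n=300, hr=2.5)
        z = (x > c).astype(int)
        w = cox_binary_wald(z, t, e)
        km_hi = km_curve(t[z == 1], e[z == 1])
        km_lo = km_curve(t[z == 0], e[z == 0])
        t_probe = np.median(t)
        below = km_hi.at(t_probe) < km_lo.at(t_probe)
        assert (w.beta > 0) == below
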