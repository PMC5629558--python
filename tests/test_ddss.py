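import itertools

import numpy as np
import pytest

from conftest import make_cohort
from survstrat import (
    classify_phenotype,
    enumerate_designs,
    scan_1d,
    scan_1d_double,
    scan_2d,
    synergy_frequency,
)
from survstrat.ddss import PairScanner, scan_profile_1d
from survstrat.errors import NoValidCutoffError, ValidationError
from survstrat.survival_stats import cox_binary_wald


class TestDesignEnumeration:
    def test_exactly_seven_designs(self):
        assert len(enumerate_designs()) == 7

    def test_matches_brute_force_dedup_of_quadrant_labelings(self):
        # 2^4 - 2 proper nonempty labelings, identified under label exchange
        seen = set()
        for mask in range(1, 15):
            seen.add(min(mask, 15 - mask))
        assert len(seen) == 7
        assert sorted(d.id for d in enumerate_designs()) == sorted(seen)

    def test_each_design_uses_both_risk_labels(self):
        for d in enumerate_designs():
            labels = set(d.risk_map.values())
            assert labels == {"lower-risk", "higher-risk"}

    def test_designs_pairwise_distinct(self):
        masks = [d.quadrant_mask() for d in enumerate_designs()]
        assert len(set(masks)) == 7
        # distinct also under label exchange
        complements = [tuple(not b for b in m) for m in masks]
        assert not set(masks) & set(complements)


class TestPhenotype:
    def test_sign_rules(self):
        assert classify_phenotype(0.7) == "pro-oncogenic"
        assert classify_phenotype(-0.7) == "tumor-suppressor-like"
        assert classify_phenotype(0.0) == "indeterminate"

    def test_only_two_proper_outcome_classes(self):
        outcomes = {classify_phenotype(b) for b in
                    (-3.0, -0.5, -1e-9, 1e-9, 0.5, 3.0)}
        assert outcomes == {"pro-oncogenic", "tumor-suppressor-like"}


def brute_force_scan(x, t, e, min_group_frac=0.10):
    """Reference scan: loop over admissible cut-offs with single Cox fits."""
    n = len(x)
    min_n = int(np.ceil(min_group_frac * n))
    best = None
    for c in np.unique(x):
        z = (x > c).astype(int)
        if z.sum() < min_n or (n - z.sum()) < min_n:
            continue
        try:
            w = cox_binary_wald(z, t, e)
        except Exception:
            continue
        if best is None or w.p < best[1]:
            best = (float(c), w.p, w.beta)
    return best


class TestScan1D:
    def test_constant_feature_rejected(self, small_cohort):
        _, t, e, _ = small_cohort
        with pytest.raises(NoValidCutoffError):
            scan_1d(np.full(len(t), 5.0), (t, e))

    def test_too_few_events_rejected(self):
        r = np.random.default_rng(0)
        x = r.normal(5, 1, 50)
        t = r.uniform(1, 5, 50)
        e = np.zeros(50, dtype=int)
        e[:5] = 1
        with pytest.raises(ValidationError):
            scan_1d(x, (t, e))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_equals_brute_force_minimum(self, seed):
        x, t, e, _ = make_cohort(seed=seed, n=120, hr=2.0)
        m = scan_1d(x, (t, e))
        c_ref, p_ref, _ = brute_force_scan(x, t, e)
        assert m.cutoff == pytest.approx(c_ref, abs=0)
        assert m.wald.p == pytest.approx(p_ref, rel=1e-9)

    def test_planted_cutoff_recovered(self):
        x, t, e, c_true = make_cohort(seed=42, n=400, hr=3.0)
        m = scan_1d(x, (t, e), feature_id="planted")
        assert abs(m.cutoff - c_true) < 0.25
        assert m.phenotype == "pro-oncogenic"
        assert m.n_low + m.n_high == 400

    def test_suppressor_phenotype_recovered(self):
        x, t, e, c_true = make_cohort(seed=43, n=400, hr=3.0,
                                      pro_oncogenic=False)
        m = scan_1d(x, (t, e))
        assert m.phenotype == "tumor-suppressor-like"
        # high-expression samples are labelled low-risk
        high_expr_sample = int(np.argmax(x))
        assert m.grouping.labels[f"S{high_expr_sample}"] == "low"

    def test_min_group_frac_relaxation_never_hurts(self):
        x, t, e, _ = make_cohort(seed=7, n=150, hr=2.0)
        p_tight = scan_1d(x, (t, e), min_group_frac=0.25).wald.p
        p_loose = scan_1d(x, (t, e), min_group_frac=0.10).wald.p
        assert p_loose <= p_tight + 1e-15

    def test_tie_break_smallest_cutoff(self):
        # duplicate the dataset so two adjacent cut-offs give identical splits
        x, t, e, _ = make_cohort(seed=8, n=80, hr=2.0)
        prof = scan_profile_1d(x, t, e)
        # the reported minimum is the first index achieving it
        p = np.where(prof.ok, prof.p, np.inf)
        m = scan_1d(x, (t, e))
        assert m.cutoff == prof.cutoffs[np.argmin(p)]

    def test_permutation_adjusted_p_in_range(self):
        x, t, e, _ = make_cohort(seed=9, n=100, hr=1.0)
        m = scan_1d(x, (t, e), permutations=99, seed=5)
        assert 0.01 <= m.p_permutation <= 1.0
        # raw minimized P is selection-biased below the adjusted one
        assert m.wald.p <= m.p_permutation

    def test_model_serialization_round_trip(self, small_cohort):
        from survstrat.ddss import CutoffModel1D

        x, t, e, _ = small_cohort
        m = scan_1d(x, (t, e), feature_id="mir-x")
        back = CutoffModel1D.from_dict(m.to_dict())
        assert back.cutoff == m.cutoff
        assert back.grouping.labels == m.grouping.labels
        assert back.wald.p == m.wald.p


class TestScan1DDouble:
    def test_planted_three_strata_recovered(self):
        r = np.random.default_rng(12)
        n = 600
        x = r.normal(5, 1, n)
        q1, q2 = np.quantile(x, [0.33, 0.66])
        lam = 0.2 * np.where(x > q2, 4.0, np.where(x > q1, 2.0, 1.0))
        T = r.exponential(1 / lam)
        C = r.uniform(0, 12, n)
        t, e = np.minimum(T, C), (T <= C).astype(int)
        m = scan_1d_double(x, (t, e))
        assert m.accepted
        assert abs(m.cutoff_lo - q1) < 0.3
        assert abs(m.cutoff_hi - q2) < 0.3
        # hazard order: higher expression interval = higher risk here
        codes = m.grouping.codes(sorted(m.grouping.labels))
        assert set(codes) == {0, 1, 2}

    def test_single_cutoff_data_falls_back(self):
        x, t, e, _ = make_cohort(seed=3, n=100, hr=3.0)
        m = scan_1d_double(x, (t, e), min_cutoff_gap_frac=0.95)
        assert not m.accepted
        assert m.fallback is not None
        assert m.reason


class TestScan2D:
    @pytest.mark.parametrize("seed", [20, 21, 22])
    def test_planted_interaction_design_identified(self, seed):
        r = np.random.default_rng(seed)
        n = 400
        x1, x2 = r.normal(5, 1, n), r.normal(5, 1, n)
        c1, c2 = np.quantile(x1, 0.6), np.quantile(x2, 0.6)
        lam = 0.29 * np.exp(np.log(3.0) * ((x1 > c1) & (x2 > c2)))
        T = r.exponential(1 / lam)
        C = r.uniform(0, 8, n)
        t, e = np.minimum(T, C), (T <= C).astype(int)
        pm = scan_2d(x1, x2, (t, e), feature_pair=("a", "b"))
        assert pm.design.id == 7  # high/high vs rest bipartition
        assert pm.design.risk_map["high/high"] == "higher-risk"
        assert abs(pm.cutoffs[0] - c1) < 1.5 and abs(pm.cutoffs[1] - c2) < 1.5

    def test_self_pair_nested_in_1d(self, small_cohort):
        x, t, e, _ = small_cohort
        pm = scan_2d(x, x, (t, e), feature_pair=("f", "f"))
        assert pm.wald.p <= min(pm.p_1d) + 1e-15

    def test_screen_matches_exhaustive(self):
        r = np.random.default_rng(30)
        n = 200
        T = r.exponential(1 / 0.3, n)
        C = r.uniform(0, 6, n)
        t, e = np.minimum(T, C), (T <= C).astype(int)
        feats = r.normal(5, 1, (4, n))
        fast = PairScanner((t, e), refine=128)
        slow = PairScanner((t, e), refine=None)
        for i in range(4):
            fast.add_feature(f"f{i}", feats[i])
            slow.add_feature(f"f{i}", feats[i])
        for i, j in itertools.combinations(range(4), 2):
            a = fast.scan(f"f{i}", f"f{j}")
            b = slow.scan(f"f{i}", f"f{j}")
            assert a.design.id == b.design.id
            assert a.wald.p == pytest.approx(b.wald.p, rel=1e-12)

    def test_grid_1d_profile_agrees_with_direct_scan(self, small_cohort):
        # the single-feature minima used for the synergy comparison equal a
        # direct scan restricted to the same quantile grid
        from survstrat._cox import prepare_risk_sets
        from survstrat.ddss import _best_1d_on_grid, _quantile_levels

        x, t, e, _ = small_cohort
        rs = prepare_risk_sets(t, e)
        q = np.unique(np.quantile(x, _quantile_levels(49)))
        p_grid = _best_1d_on_grid(rs, x, q, 0.10)
        prof = scan_profile_1d(x, t, e, cutoffs=q)
        p_direct = np.where(prof.ok, prof.p, np.inf).min()
        assert p_grid == pytest.approx(p_direct, rel=1e-12)


class TestSynergyFrequency:
    def test_counts_match_brute_force(self):
        r = np.random.default_rng(31)
        n = 250
        feats = {}
        x0, t, e, c0 = make_cohort(seed=32, n=n, hr=2.5)
        feats["f0"] = x0
        for i in range(1, 5):
            feats[f"f{i}"] = r.normal(5, 1, n)
        scanner = PairScanner((t, e))
        for fid, x in feats.items():
            scanner.add_feature(fid, x)
        pms = [scanner.scan(a, b)
               for a, b in itertools.combinations(sorted(feats), 2)]
        counts = synergy_frequency(pms, p_threshold=0.05)
        for fid in feats:
            expect = sum(1 for pm in pms
                         if fid in pm.feature_pair and pm.synergistic
                         and pm.wald.p < 0.05)
            assert counts[fid] == expect

    def test_feature_without_synergy_counts_zero(self):
        from survstrat.ddss import Design2D, PairModel2D
        from survstrat.survival_stats import WaldResult

        pm = PairModel2D(
            feature_pair=("a", "b"), cutoffs=(1.0, 2.0),
            design=Design2D(7, {q: "lower-risk" for q in
                                ("low/low", "low/high", "high/low", "high/high")}),
            wald=WaldResult(0.5, 0.2, 2.5, 0.2, np.exp(0.5)),
            synergistic=False, grouping=None, p_1d=(0.01, 0.02))
        assert synergy_frequency([pm])["a"] == 0
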