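import numpy as np
import pytest

from conftest import make_cohort
from survstrat import (
    SurvivalTable,
    build_votes,
    cv_stability,
    scan_1d,
    score_patients,
    select,
    stratify,
)
from survstrat.errors import AlignmentError, ValidationError
from survstrat.swvg import VoteMatrix


def fitted_models(seed, n=250, n_info=3, n_null=2, hr=2.5):
    r = np.random.default_rng(seed)
    feats, effects = {}, []
    for i in range(n_info):
        x = r.normal(5, 1, n)
        feats[f"info{i}"] = x
        effects.append((x > np.quantile(x, 0.5)).astype(float) * np.log(hr))
    for i in range(n_null):
        feats[f"null{i}"] = r.normal(5, 1, n)
    lam = 0.25 * np.exp(np.sum(effects, axis=0))
    T = r.exponential(1 / lam)
    C = r.uniform(0, 10, n)
    t, e = np.minimum(T, C), (T <= C).astype(int)
    ids = [f"S{i}" for i in range(n)]
    surv = SurvivalTable(ids, t, e)
    models = [scan_1d(x, surv, feature_id=fid, keep_profile=False)
              for fid, x in feats.items()]
    return models, surv, feats


class TestBuildVotes:
    def test_vote_definitions_follow_phenotype(self):
        x, t, e, _ = make_cohort(seed=1, n=200, hr=3.0, pro_oncogenic=True)
        ids = [f"S{i:03d}" for i in range(200)]
        surv = SurvivalTable(ids, t, e)
        m_pro = scan_1d(x, surv, feature_id="pro")
        vm = build_votes([m_pro])
        above = ids[int(np.argmax(x))]
        j = vm.sample_ids.index(above)
        assert vm.votes[0, j] == 1.0  # pro-oncogenic: high expression -> +1

        x2, t2, e2, _ = make_cohort(seed=2, n=200, hr=3.0, pro_oncogenic=False)
        surv2 = SurvivalTable(ids, t2, e2)
        m_sup = scan_1d(x2, surv2, feature_id="sup")
        vm2 = build_votes([m_sup])
        j2 = vm2.sample_ids.index(ids[int(np.argmax(x2))])
        assert vm2.votes[0, j2] == -1.0  # suppressor-like: high expr -> -1

    def test_mismatched_cohorts_rejected(self):
        models, _, _ = fitted_models(3, n=250)
        other_models, _, _ = fitted_models(4, n=200)
        with pytest.raises(AlignmentError):
            build_votes([models[0], other_models[0]])

    def test_votes_survive_model_serialization(self):
        from survstrat.ddss import CutoffModel1D

        models, _, _ = fitted_models(5)
        vm = build_votes(models)
        rebuilt = build_votes([CutoffModel1D.from_dict(m.to_dict())
                               for m in models])
        np.testing.assert_array_equal(vm.votes, rebuilt.votes)
        assert vm.sample_ids == rebuilt.sample_ids


class TestScorePatients:
    def _vm(self, votes):
        votes = np.asarray(votes, dtype=float)
        return VoteMatrix([f"f{i}" for i in range(votes.shape[0])],
                          [f"S{j}" for j in range(votes.shape[1])], votes)

    def test_all_positive_votes_score_one(self):
        vm = self._vm([[1, 1], [1, 1], [1, 1]])
        np.testing.assert_allclose(score_patients(vm, [1, 2, 3]), [1.0, 1.0])

    def test_hand_arithmetic(self):
        vm = self._vm([[1], [-1], [1]])
        assert score_patients(vm, [3, 2, 1])[0] == pytest.approx(1 / 3)

    def test_balanced_votes_score_zero(self):
        vm = self._vm([[1], [-1]])
        assert score_patients(vm, [2, 2])[0] == pytest.approx(0.0)

    def test_duplicating_feature_with_half_weight_invariant(self):
        rng = np.random.default_rng(0)
        votes = rng.choice([-1.0, 1.0], (4, 30))
        vm = self._vm(votes)
        w = np.array([4.0, 3.0, 2.0, 1.0])
        base = score_patients(vm, w)
        vm_dup = self._vm(np.vstack([votes, votes[:1]]))
        w_dup = np.array([2.0, 3.0, 2.0, 1.0, 2.0])
        np.testing.assert_allclose(score_patients(vm_dup, w_dup), base, atol=1e-12)

    def test_nonpositive_weights_rejected(self):
        vm = self._vm([[1], [-1]])
        with pytest.raises(ValidationError):
            score_patients(vm, [1.0, 0.0])


class TestStratify:
    def test_separated_bimodal_recovers_sign_partition(self):
        r = np.random.default_rng(6)
        n = 300
        scores = np.where(r.random(n) < 0.5, -0.8, 0.8)
        lam = 0.25 * np.exp(np.log(3.0) * (scores > 0))
        T = r.exponential(1 / lam)
        C = r.uniform(0, 10, n)
        surv = SurvivalTable([f"S{i}" for i in range(n)],
                             np.minimum(T, C), (T <= C).astype(int))
        grouping, p = stratify(scores, surv, k=2)
        codes = grouping.codes([f"S{i}" for i in range(n)])
        np.testing.assert_array_equal(codes, (scores > 0).astype(int))
        assert p < 1e-6

    def test_k2_groups_monotone_in_score(self):
        models, surv, _ = fitted_models(7)
        vm = build_votes(models)
        w = np.array([-np.log10(m.wald.p) for m in models])
        scores = score_patients(vm, w)
        pos = {s: i for i, s in enumerate(vm.sample_ids)}
        aligned = scores[[pos[s] for s in surv.sample_ids]]
        grouping, _ = stratify(aligned, surv, k=2)
        codes = grouping.codes(surv.sample_ids)
        assert aligned[codes == 1].min() > aligned[codes == 0].max()


class TestSelect:
    def test_single_candidate_reproduces_own_grouping(self):
        models, surv, _ = fitted_models(8, n_info=1, n_null=0)
        vm = select(models, surv, k=2)
        codes_model = models[0].grouping.codes(surv.sample_ids)
        codes_vm = vm.grouping.codes(surv.sample_ids)
        # identical partition (up to, possibly, label orientation)
        same = np.array_equal(codes_model, codes_vm)
        flipped = np.array_equal(codes_model, 1 - codes_vm)
        assert same or flipped

    @pytest.mark.parametrize("seed", [10, 11])
    def test_selected_subset_beats_best_single_feature(self, seed):
        models, surv, _ = fitted_models(seed, n_info=4, n_null=4)
        vm = select(models, surv, k=2)
        best_single = min(m.wald.p for m in models)
        assert vm.overall_logrank_p <= best_single * 10  # parsimony tolerance

    def test_trace_final_entry_is_full_set(self):
        models, surv, _ = fitted_models(12, n_info=3, n_null=1)
        vm = select(models, surv, k=2)
        qs = [q for q, _ in vm.selection_trace]
        assert qs == list(range(1, len(models) + 1))

    def test_informative_features_preferentially_selected(self):
        hits = total = 0
        for seed in (13, 14, 15):
            models, surv, _ = fitted_models(seed, n=300, n_info=4, n_null=8,
                                            hr=3.0)
            vm = select(models, surv, k=2)
            sel = set(vm.selected_features)
            hits += sum(1 for f in sel if f.startswith("info"))
            total += 4
        assert hits / total >= 0.75


class TestCVStability:
    def test_strong_feature_fully_confident(self):
        x, t, e, _ = make_cohort(seed=16, n=500, hr=5.0)
        ids = [f"S{i}" for i in range(500)]
        res = cv_stability(x, SurvivalTable(ids, t, e), repeats=5, seed=3)
        assert res.confidence == 1.0
        assert res.cutoff_cv < 5.0

    def test_noise_feature_not_confident(self):
        r = np.random.default_rng(17)
        n = 300
        x = r.normal(5, 1, n)
        T = r.exponential(1 / 0.3, n)
        C = r.uniform(0, 8, n)
        surv = SurvivalTable([f"S{i}" for i in range(n)],
                             np.minimum(T, C), (T <= C).astype(int))
        res = cv_stability(x, surv, repeats=5, seed=4)
        assert res.confidence < 0.997

    def test_cutoff_cv_is_sd_over_mean(self):
        x, t, e, _ = make_cohort(seed=18, n=400, hr=3.0)
        res = cv_stability(x, SurvivalTable([f"S{i}" for i in range(400)], t, e),
                           repeats=3, seed=5)
        c = res.fold_cutoffs[~np.isnan(res.fold_cutoffs)]
        expect = np.std(c, ddof=1) / np.mean(c) * 100
        assert res.cutoff_cv == pytest.approx(expect, rel=1e-12)
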