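"""Statistically weighted voting grouping (SWVg).

Each selected feature's fitted dichotomization casts a per-patient risk
vote (+1 high-risk, -1 low-risk); votes are combined into a patient score
as a weighted mean with weights -log10 of each feature's Wald P, so the
score lives in [-1, +1].  The score is then treated as a derived variable
and stratified with the same cut-off scans used for single features into
two or three ordered risk groups.  Forward selection in weight order picks
the smallest feature subset whose stratification P-value is within one
order of magnitude of the best achievable, and a repeated ten-fold
cross-validation screen measures how stable each feature's optimal
cut-off and significance are across training subsets.

The exact combination rule is a reconstruction (vote encoding, weight
normalisation); it is isolated in :func:`score_patients` so an alternative
rule can be swapped in without touching the rest of the stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._cox import newton_counts, prepare_risk_sets, threshold_counts
from .core_data import RiskGrouping, SurvivalTable
from .ddss import _admissible_cutoffs, scan_1d, scan_1d_double
from .errors import (
    AlignmentError,
    NoValidCutoffError,
    ScanFailedError,
    SelectionFailedError,
    UnstablePartitionError,
    ValidationError,
)
from .survival_stats import logrank_grouping, neg_log10


@dataclass
class VoteMatrix:
    """Per-feature, per-sample risk votes in {+1, -1}."""

    feature_ids: list
    sample_ids: list
    votes: np.ndarray  # (features, samples)
    sources: dict = field(default_factory=dict)  # feature -> CutoffModel1D


def build_votes(models) -> VoteMatrix:
    """Risk votes from fitted 1D cut-off models sharing one cohort."""
    models = list(models)
    if not models:
        raise ValidationError("no models supplied")
    ref = sorted(models[0].grouping.labels)
    sample_ids = ref
    votes = np.empty((len(models), len(sample_ids)))
    for i, m in enumerate(models):
        if sorted(m.grouping.labels) != ref:
            raise AlignmentError(
                f"model {m.feature_id!r} was fitted on a different cohort"
            )
        votes[i] = [1.0 if m.grouping.labels[s] == "high" else -1.0
                    for s in sample_ids]
    return VoteMatrix([m.feature_id for m in models], list(sample_ids), votes,
                      {m.feature_id: m for m in models})


def score_patients(votes: VoteMatrix, weights) -> np.ndarray:
    """Weighted mean vote per patient: sum(w v) / sum(w), in [-1, +1]."""
    w = np.asarray(weights, dtype=float)
    if w.shape[0] != len(votes.feature_ids):
        raise ValidationError("weights not aligned to features")
    if np.any(w <= 0):
        raise ValidationError("weights must be positive")
    tot = w.sum()
    if tot <= 0:
        raise ValidationError("total weight must be positive")
    return (w @ votes.votes) / tot


def stratify(scores, surv, k: int = 2, min_group_frac: float = 0.10):
    """Cut the patient score into k ordered risk groups.

    The score is passed through the same optimal-cut-off machinery as a
    single feature (one cut-off for k=2, two for k=3) and the groups are
    relabelled so that a higher score always means higher risk.

    Returns (RiskGrouping, overall log-rank P).
    """
    if k not in (2, 3):
        raise ValidationError("k must be 2 or 3")
    ids, times, events = _ids_times_events(surv)
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValidationError("scores must be finite")
    if k == 2:
        m = scan_1d(scores, surv, min_group_frac, feature_id="swvg-score",
                    keep_profile=False)
        labels = {s: ("high" if sc > m.cutoff else "low")
                  for s, sc in zip(ids, scores)}
        grouping = RiskGrouping(labels, 2, provenance="swvg:k2")
    else:
        tm = scan_1d_double(scores, surv, min_group_frac,
                            feature_id="swvg-score")
        if tm.grouping is None:
            raise NoValidCutoffError(
                f"no two-cut-off stratification of the score: {tm.reason}"
            )
        code = np.where(scores > tm.cutoff_hi, 2,
                        np.where(scores > tm.cutoff_lo, 1, 0))
        grouping = RiskGrouping.from_codes(ids, code, 3, provenance="swvg:k3")
    _, p = logrank_grouping(grouping, surv if isinstance(surv, SurvivalTable)
                            else _as_table(ids, times, events))
    return grouping, float(p)


@dataclass
class VotingModel:
    selected_features: list
    weights: dict            # feature -> -log10 P
    patient_scores: dict     # sample -> score in [-1, 1]
    score_cutoffs: list
    grouping: RiskGrouping
    overall_logrank_p: float
    selection_trace: list    # (subset size, stratification P)
    k: int

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "model": "swvg",
            "k": self.k,
            "selected_features": list(self.selected_features),
            "weights": self.weights,
            "patient_scores": self.patient_scores,
            "score_cutoffs": list(self.score_cutoffs),
            "overall_logrank_p": self.overall_logrank_p,
            "selection_trace": [[int(q), float(p)] for q, p in self.selection_trace],
            "grouping": {"labels": self.grouping.labels, "k": self.grouping.k,
                         "provenance": self.grouping.provenance},
        }


def select(models, surv, k: int = 2, min_group_frac: float = 0.10,
           parsimony_factor: float = 10.0) -> VotingModel:
    """Forward feature selection in weight order.

    Features are ranked by weight (-log10 of their Wald P) and included one
    at a time; at each subset size the stratification P of the weighted
    score is recorded.  The chosen size is the smallest whose P is within
    ``parsimony_factor`` (one order of magnitude) of the global minimum of
    the trace - beyond that point extra features barely move the P-value.
    """
    models = sorted(models, key=lambda m: (m.wald.p, m.feature_id))
    if len(models) < 1:
        raise ValidationError("need at least one candidate model")
    ids, times, events = _ids_times_events(surv)
    trace = []
    cached = []
    for q in range(1, len(models) + 1):
        vm = build_votes(models[:q])
        w = neg_log10([m.wald.p for m in models[:q]])
        scores = score_patients(vm, w)
        # align score order to the survival table's sample order
        pos = {s: i for i, s in enumerate(vm.sample_ids)}
        s_aligned = scores[[pos[s] for s in ids]]
        try:
            grouping, p = stratify(s_aligned, surv, k, min_group_frac)
        except (NoValidCutoffError, ScanFailedError, ValidationError):
            trace.append((q, np.inf))
            cached.append(None)
            continue
        trace.append((q, p))
        cached.append((vm, w, s_aligned, grouping, p))
    ps = np.array([p for _, p in trace])
    if not np.isfinite(ps).any():
        raise SelectionFailedError("no candidate subset could be stratified")
    p_min = np.nanmin(ps[np.isfinite(ps)])
    q_star = int(np.flatnonzero(ps <= p_min * parsimony_factor)[0])
    vm, w, s_aligned, grouping, p = cached[q_star]
    cutoffs = _score_cutoffs(s_aligned, grouping, ids)
    return VotingModel(
        selected_features=list(vm.feature_ids),
        weights={f: float(wi) for f, wi in zip(vm.feature_ids, w)},
        patient_scores={s: float(v) for s, v in zip(ids, s_aligned)},
        score_cutoffs=cutoffs,
        grouping=grouping,
        overall_logrank_p=float(p),
        selection_trace=trace,
        k=k,
    )


def _score_cutoffs(scores, grouping, ids):
    codes = grouping.codes(ids)
    cuts = []
    for level in range(grouping.k - 1):
        below = scores[codes <= level]
        cuts.append(float(below.max()) if below.size else float("nan"))
    return cuts


@dataclass
class CVStability:
    feature_id: str
    fold_pvalues: np.ndarray   # (repeats, folds), NaN where skipped
    fold_cutoffs: np.ndarray
    confidence: float          # fraction of completed fold-fits with P < threshold
    cutoff_cv: float           # sd/mean of fold cut-offs, percent
    n_skipped: int
    pass_confidence: bool
    pass_cutoff_cv: bool

    @property
    def passes(self) -> bool:
        return self.pass_confidence and self.pass_cutoff_cv


def cv_stability(
    x,
    surv,
    repeats: int = 100,
    folds: int = 10,
    seed: int = 0,
    min_group_frac: float = 0.10,
    p_threshold: float = 0.05,
    confidence_threshold: float = 0.997,
    cv_threshold_pct: float = 1.0,
    feature_id: str = "feature",
) -> CVStability:
    """Repeated ten-fold cross-validation of a feature's optimal cut-off.

    Each repeat draws a fresh event-stratified fold partition; the scan
    runs on every 9/10 training split.  ``confidence`` is the fraction of
    completed fold fits significant at ``p_threshold``; ``cutoff_cv`` is
    the percent coefficient of variation of the fold cut-offs.  The dual
    pass criterion is confidence > 99.7% and cut-off CV < 1%.
    """
    ids, times, events = _ids_times_events(surv)
    x = np.asarray(x, dtype=float)
    rng = np.random.default_rng(seed)
    n = x.size
    pvals = np.full((repeats, folds), np.nan)
    cuts = np.full((repeats, folds), np.nan)
    skipped = 0
    idx_event = np.flatnonzero(events == 1)
    idx_cens = np.flatnonzero(events == 0)
    for rep in range(repeats):
        fold_of = np.empty(n, dtype=int)
        for idx in (idx_event, idx_cens):
            perm = rng.permutation(idx)
            fold_of[perm] = np.arange(perm.size) % folds
        for f in range(folds):
            tr = fold_of != f
            try:
                cut, p = _scan_min(x[tr], times[tr], events[tr], min_group_frac)
            except (NoValidCutoffError, ScanFailedError, ValidationError):
                skipped += 1
                continue
            pvals[rep, f] = p
            cuts[rep, f] = cut
    total = repeats * folds
    if skipped > 0.2 * total:
        raise UnstablePartitionError(
            f"{skipped}/{total} folds violated scan preconditions"
        )
    done = ~np.isnan(pvals)
    confidence = float((pvals[done] < p_threshold).mean()) if done.any() else 0.0
    c = cuts[~np.isnan(cuts)]
    mean_c = float(np.mean(c)) if c.size else np.nan
    sd_c = float(np.std(c, ddof=1)) if c.size > 1 else np.nan
    cutoff_cv = abs(sd_c / mean_c) * 100.0 if c.size > 1 and mean_c != 0 else np.nan
    return CVStability(
        feature_id=feature_id,
        fold_pvalues=pvals,
        fold_cutoffs=cuts,
        confidence=confidence,
        cutoff_cv=cutoff_cv,
        n_skipped=skipped,
        pass_confidence=confidence > confidence_threshold,
        pass_cutoff_cv=bool(np.isfinite(cutoff_cv) and cutoff_cv < cv_threshold_pct),
    )


def _scan_min(x, times, events, min_group_frac):
    """Lightweight optimal-cut-off scan: returns (cutoff, min P) only."""
    if x.size < 30 or int(events.sum()) < 10:
        raise ValidationError("training split too small for a scan")
    cand = _admissible_cutoffs(x, min_group_frac)
    if cand.size == 0:
        raise NoValidCutoffError("no admissible cut-off")
    rs = prepare_risk_sets(times, events)
    bins = np.searchsorted(cand, x, side="left")
    r1, s = threshold_counts(rs, bins, cand.size)
    _, _, p, ok = newton_counts(rs.d, rs.r, r1, s)
    if not ok.any():
        raise ScanFailedError("all candidate fits failed")
    p = np.where(ok, p, np.inf)
    i = int(np.argmin(p))
    return float(cand[i]), float(p[i])


def _ids_times_events(surv):
    if isinstance(surv, SurvivalTable):
        s = surv.included()
        return list(s.sample_ids), s.time, s.event
    times, events = surv
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    return [f"S{i}" for i in range(len(times))], times, events


def _as_table(ids, times, events) -> SurvivalTable:
    return SurvivalTable(ids, times, events)
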