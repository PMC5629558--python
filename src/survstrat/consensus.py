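"""Robust K-means subtyping by co-clustering consensus.

K-means with the Manhattan (L1) distance and component-wise median
centroid update is repeated many times from random initialisations; the
fraction of runs in which two samples land in the same cluster is
accumulated into a co-assignment matrix.  Samples that co-cluster in
*every* completed run form the robust sample cores; features are
clustered the same way (in the transposed space) with a softer 90%
threshold.  Working with co-assignment frequencies sidesteps the
label-switching problem entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_data import ExpressionMatrix, RiskGrouping, SurvivalTable
from .errors import DegenerateGroupError, ValidationError
from .survival_stats import logrank

_KMEANS_MAX_ITER = 300


@dataclass
class ConsensusResult:
    sample_ids: list
    feature_ids: list
    sample_coassignment: np.ndarray   # symmetric, in [0, 1]
    feature_coassignment: np.ndarray
    robust_sample_cores: list         # lists of sample ids, largest first
    robust_feature_clusters: list
    runs: int                         # completed runs (the denominator)
    runs_requested: int
    discarded_runs: int

    @property
    def core_fraction(self) -> float:
        return sum(len(c) for c in self.robust_sample_cores) / len(self.sample_ids)


def _kmeans_l1(X, k, rng, max_iter=_KMEANS_MAX_ITER):
    """One L1 K-means run; returns labels or None if not converged."""
    n = X.shape[0]
    centroids = X[rng.choice(n, size=k, replace=False)].copy()
    labels = np.full(n, -1)
    for _ in range(max_iter):
        d = np.abs(X[:, None, :] - centroids[None, :, :]).sum(axis=2)
        new_labels = np.argmin(d, axis=1)
        for j in range(k):
            members = new_labels == j
            if not members.any():  # re-seed an empty cluster
                members = np.zeros(n, dtype=bool)
                members[rng.integers(n)] = True
                new_labels[members] = j
            centroids[j] = np.median(X[members], axis=0)
        if np.array_equal(new_labels, labels):
            return labels
        labels = new_labels
    return None


def _greedy_cliques(adj: np.ndarray) -> list:
    """Deterministic partition of a graph into cliques (index order greedy)."""
    n = adj.shape[0]
    unassigned = list(range(n))
    cliques = []
    while unassigned:
        seed = unassigned.pop(0)
        clique = [seed]
        rest = []
        for v in unassigned:
            if all(adj[v, u] for u in clique):
                clique.append(v)
            else:
                rest.append(v)
        unassigned = rest
        cliques.append(clique)
    return cliques


def _robust_groups(coassign, min_count, ids, min_size=2):
    """Cliques of the co-assignment-count >= min_count graph, largest first."""
    adj = coassign >= min_count
    np.fill_diagonal(adj, True)
    groups = [g for g in _greedy_cliques(adj) if len(g) >= min_size]
    groups.sort(key=lambda g: (-len(g), g))
    return [[ids[i] for i in g] for g in groups]


def robust_kmeans(
    expr: ExpressionMatrix,
    k: int = 2,
    runs: int = 1000,
    feature_threshold: float = 0.90,
    seed: int = 0,
) -> ConsensusResult:
    """Consensus of repeated L1 K-means over samples and over features.

    Samples are clustered as points in feature space and features as
    points in sample space, independently, with ``runs`` random
    initialisations each (run seeds derive from ``seed``).  Runs that fail
    to converge within 300 Lloyd iterations are discarded and the
    co-assignment denominator adjusts.  Sample cores require co-assignment
    in 100% of completed runs; feature clusters use ``feature_threshold``.
    """
    if expr.n_samples < 2 * k:
        raise ValidationError(f"need at least {2 * k} samples for k={k}")
    if not np.all(np.isfinite(expr.values)):
        raise ValidationError("expression matrix must be finite")
    Xs = expr.values.T  # samples as points
    Xf = expr.values    # features as points
    n_s, n_f = Xs.shape[0], Xf.shape[0]
    co_s = np.zeros((n_s, n_s))
    co_f = np.zeros((n_f, n_f))
    seeds = np.random.SeedSequence(seed).spawn(2 * runs)
    done_s = done_f = 0
    for i in range(runs):
        lab = _kmeans_l1(Xs, k, np.random.default_rng(seeds[2 * i]))
        if lab is not None:
            onehot = np.eye(k)[lab]
            co_s += onehot @ onehot.T
            done_s += 1
        lab = _kmeans_l1(Xf, k, np.random.default_rng(seeds[2 * i + 1]))
        if lab is not None:
            onehot = np.eye(k)[lab]
            co_f += onehot @ onehot.T
            done_f += 1
    if done_s == 0 or done_f == 0:
        raise ValidationError("no K-means run converged")
    cores = _robust_groups(co_s, done_s, list(expr.sample_ids))
    # "> threshold fraction of completed runs", strict
    fclust = _robust_groups(co_f, int(np.floor(feature_threshold * done_f)) + 1,
                            list(expr.feature_ids))
    return ConsensusResult(
        sample_ids=list(expr.sample_ids),
        feature_ids=list(expr.feature_ids),
        sample_coassignment=co_s / done_s,
        feature_coassignment=co_f / done_f,
        robust_sample_cores=cores,
        robust_feature_clusters=fclust,
        runs=done_s,
        runs_requested=runs,
        discarded_runs=runs - min(done_s, done_f),
    )


def compare_cores(result: ConsensusResult, surv: SurvivalTable):
    """Log-rank comparison of the two largest robust sample cores.

    Returns (chi2, p)."""
    if len(result.robust_sample_cores) < 2:
        raise DegenerateGroupError("need at least two robust cores to compare")
    a, b = result.robust_sample_cores[0], result.robust_sample_cores[1]
    surv_ok = surv.included() if isinstance(surv, SurvivalTable) else surv
    ids = set(surv_ok.sample_ids)
    a = [s for s in a if s in ids]
    b = [s for s in b if s in ids]
    if not a or not b:
        raise DegenerateGroupError("cores contain no samples with follow-up")
    sub = surv_ok.subset(a + b)
    codes = np.array([0] * len(a) + [1] * len(b))
    return logrank(codes, sub.time, sub.event)


def cores_to_grouping(result: ConsensusResult, surv: SurvivalTable) -> RiskGrouping:
    """Label the two largest cores low/high risk by their event rates."""
    if len(result.robust_sample_cores) < 2:
        raise DegenerateGroupError("need two cores")
    a, b = result.robust_sample_cores[0], result.robust_sample_cores[1]
    surv_ok = surv.included()
    ids = set(surv_ok.sample_ids)
    a = [s for s in a if s in ids]
    b = [s for s in b if s in ids]
    idx = {s: i for i, s in enumerate(surv_ok.sample_ids)}

    def rate(core):
        e = [surv_ok.event[idx[s]] for s in core]
        t = [surv_ok.time[idx[s]] for s in core]
        return float(np.sum(e) / max(np.sum(t), 1e-12))  # crude hazard

    high, low = (a, b) if rate(a) > rate(b) else (b, a)
    labels = {s: "high" for s in high}
    labels.update({s: "low" for s in low})
    return RiskGrouping(labels, 2, provenance="consensus-kmeans")
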