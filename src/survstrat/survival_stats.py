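"""Censored-data statistical primitives.

Kaplan-Meier product-limit estimation, the k-sample log-rank test, the
binary-covariate Cox/Wald test, Benjamini-Hochberg FDR and linear-weighted
kappa agreement.  These are the building blocks every cut-off scan and
grouping comparison in the package reduces to.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._cox import cox_binary_single, prepare_risk_sets  # noqa: F401 (re-export)
from .core_data import RiskGrouping
from .errors import (
    AlignmentError,
    DegenerateGroupError,
    EmptyCohortError,
    ValidationError,
)

#: P-values are floored here before -log10 weighting to avoid infinities.
P_FLOOR = 1e-300


@dataclass
class KMCurve:
    """Product-limit survival estimate at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    deaths: np.ndarray

    def at(self, t: float) -> float:
        """S(t), right-continuous."""
        i = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if i == 0 else float(self.survival[i - 1])


@dataclass
class WaldResult:
    """Cox fit summary for a binary contrast."""

    beta: float
    se: float
    z: float
    p: float
    hr: float


def km_curve(times, events) -> KMCurve:
    """Kaplan-Meier estimate; censored times thin the risk set without steps."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise EmptyCohortError("no samples for Kaplan-Meier estimate")
    if np.any(times <= 0):
        raise ValidationError("follow-up times must be positive")
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    ev = np.flatnonzero(e == 1)
    if ev.size == 0:
        return KMCurve(np.array([]), np.array([]), np.array([]), np.array([]))
    tau, first = np.unique(t[ev], return_index=True)
    d = np.diff(np.append(np.searchsorted(t[ev], tau, side="left"), ev.size))
    r = t.size - np.searchsorted(t, tau, side="left")
    surv = np.cumprod(1.0 - d / r)
    return KMCurve(tau, surv, r, d)


def logrank(grouping_codes, times, events) -> tuple[float, float]:
    """k-sample log-rank test.

    Parameters
    ----------
    grouping_codes
        Integer group code per sample (k >= 2 distinct values, all present),
        or a :class:`RiskGrouping` paired with times/events in its sample
        order via :func:`logrank_grouping`.

    Returns
    -------
    (chi2, p) with k-1 degrees of freedom.
    """
    g = np.asarray(grouping_codes)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    levels, g = np.unique(g, return_inverse=True)
    k = levels.size
    if k < 2:
        raise DegenerateGroupError("log-rank needs >= 2 non-empty groups")
    if events.sum() == 0:
        raise EmptyCohortError("log-rank needs at least one event")
    order = np.argsort(times, kind="stable")
    t, e, gg = times[order], events[order], g[order]
    ev = np.flatnonzero(e == 1)
    tau = np.unique(t[ev])
    starts = np.searchsorted(t, tau, side="left")
    n = t.size
    # at-risk per group at each event time: suffix counts
    onehot = np.zeros((n, k))
    onehot[np.arange(n), gg] = 1.0
    suffix = np.cumsum(onehot[::-1], axis=0)[::-1]
    r_g = suffix[starts]                     # (J, k)
    r_tot = n - starts
    # deaths per group at each event time
    d_oh = onehot[ev]
    bounds = np.searchsorted(t[ev], tau, side="left")
    d_g = np.add.reduceat(d_oh, bounds, axis=0)
    d_tot = d_g.sum(axis=1)

    O = d_g.sum(axis=0)
    E = (r_g * (d_tot / r_tot)[:, None]).sum(axis=0)
    # hypergeometric covariance, summed over event times
    with np.errstate(divide="ignore", invalid="ignore"):
        cfac = d_tot * (r_tot - d_tot) / np.maximum(r_tot - 1.0, 1.0)
    P = r_g / r_tot[:, None]
    V = np.einsum("j,jk,jl->kl", cfac, P, -P)
    V[np.diag_indices(k)] = (cfac[:, None] * P * (1.0 - P)).sum(axis=0)
    diff = (O - E)[:-1]
    try:
        chi2 = float(diff @ np.linalg.solve(V[:-1, :-1], diff))
    except np.linalg.LinAlgError:
        chi2 = float(diff @ np.linalg.pinv(V[:-1, :-1]) @ diff)
    p = float(stats.chi2.sf(chi2, df=k - 1))
    return chi2, max(p, P_FLOOR)


def logrank_grouping(grouping: RiskGrouping, surv) -> tuple[float, float]:
    """Log-rank test of a :class:`RiskGrouping` against a survival table."""
    ids = [s for s in surv.sample_ids if s in grouping.labels]
    if len(ids) != len(surv.sample_ids) or len(ids) != len(grouping.labels):
        if not ids:
            raise AlignmentError("grouping and survival table share no samples")
    sub = surv.subset(ids)
    codes = grouping.codes(ids)
    if np.unique(codes).size < 2:
        raise DegenerateGroupError("grouping collapses to one group on this cohort")
    return logrank(codes, sub.time, sub.event)


def cox_binary_wald(group_indicator, times, events) -> WaldResult:
    """Wald test of a binary group indicator under the Cox model (Efron ties)."""
    beta, se, p = cox_binary_single(times, events, np.asarray(group_indicator))
    return WaldResult(beta=beta, se=se, z=beta / se, p=max(p, P_FLOOR), hr=float(np.exp(beta)))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def neg_log10(p) -> np.ndarray:
    """-log10 of floored p-values (the voting weights of the toolkit)."""
    return -np.log10(np.maximum(np.asarray(p, dtype=float), P_FLOOR))


def _linear_weights(k: int) -> np.ndarray:
    i = np.arange(k)
    return 1.0 - np.abs(i[:, None] - i[None, :]) / max(k - 1, 1)


def weighted_kappa_table(table: np.ndarray) -> tuple[float, float]:
    """Linear-weighted kappa and asymptotic two-sided p for a square table."""
    table = np.asarray(table, dtype=float)
    k = table.shape[0]
    if table.shape != (k, k):
        raise ValidationError("contingency table must be square")
    n = table.sum()
    if n == 0:
        raise EmptyCohortError("empty contingency table")
    p_obs = table / n
    w = _linear_weights(k)
    pi = p_obs.sum(axis=1)
    pj = p_obs.sum(axis=0)
    po = float((w * p_obs).sum())
    pe = float((pi[:, None] * pj[None, :] * w).sum())
    if pe >= 1.0:
        return 1.0, 1.0
    kappa = (po - pe) / (1.0 - pe)
    # Fleiss-Cohen asymptotic variance under H0 of independence
    wi = w @ pj
    wj = pi @ w
    var0 = ((pi[:, None] * pj[None, :]) * (w - (wi[:, None] + wj[None, :])) ** 2).sum() - pe**2
    var0 /= n * (1.0 - pe) ** 2
    if var0 <= 0:
        return float(kappa), 1.0
    z = kappa / np.sqrt(var0)
    p = float(stats.norm.sf(abs(z)) * 2)
    return float(np.clip(kappa, -1.0, 1.0)), max(min(p, 1.0), P_FLOOR)


def weighted_kappa(labels_a: RiskGrouping, labels_b: RiskGrouping) -> tuple[float, float]:
    """Agreement between two ordinal risk groupings (linear weights).

    The two groupings must cover the same samples; the contingency table is
    built over the union of the two label scales so k=2 vs k=3 groupings
    remain comparable.
    """
    common = [s for s in labels_a.labels if s in labels_b.labels]
    if not common:
        raise AlignmentError("groupings share no samples")
    k = max(labels_a.k, labels_b.k)
    levels = ("low", "intermediate", "high") if k == 3 else ("low", "high")
    lut = {lev: i for i, lev in enumerate(levels)}
    table = np.zeros((k, k))
    for s in common:
        table[lut[labels_a.labels[s]], lut[labels_b.labels[s]]] += 1
    return weighted_kappa_table(table)
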