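"""Vectorized Cox partial-likelihood machinery for binary covariates.

The cut-off scans evaluate a proportional-hazards fit for thousands of
candidate dichotomizations of one cohort.  For a single 0/1 covariate the
Efron-tie partial likelihood depends on the data only through per-event-time
aggregates (at-risk and death counts inside the high-expression group), so
a whole batch of candidate indicator columns can be Newton-iterated at
once.  Because candidate groups are threshold sets of one (or two)
features, the aggregates themselves come from cumulative histograms of the
feature ranks rather than per-column sums, which keeps the 2D pair scan
tractable.  This module is the hot path of the package.

Notation, for distinct event time ``tau_j`` with ``d_j`` tied deaths,
``r_j`` at risk, of which ``r1_j`` (``s_j``) at-risk (dead) samples carry
indicator 1:

    S0_j(b) = (r_j - r1_j) + r1_j e^b        S1_j(b) = r1_j e^b
    S0d_j(b) = (d_j - s_j) + s_j e^b         S1d_j(b) = s_j e^b

and the Efron score subtracts, for l = 0..d_j-1, the ratio
``E = (S1 - (l/d) S1d) / (S0 - (l/d) S0d)``.  For a 0/1 covariate the
second moment equals the first, so the information contribution is
``E (1 - E)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erfc

from .errors import EmptyCohortError, NoContrastError, SeparationError

#: |beta| beyond which the partial likelihood is declared monotone
SEPARATION_BETA = 15.0


@dataclass
class RiskSetData:
    """Per-event-time aggregates of a cohort, reusable across batches."""

    order: np.ndarray        # ascending time order of the input samples
    n: int
    event_starts: np.ndarray  # sorted-order index of first at-risk sample per event time
    d: np.ndarray            # deaths per distinct event time
    r: np.ndarray            # at-risk per distinct event time
    event_rows: np.ndarray   # sorted-order row indices with event==1
    event_group_starts: np.ndarray  # reduceat boundaries of event_rows per event time


def prepare_risk_sets(times, events) -> RiskSetData:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n = times.shape[0]
    if n == 0:
        raise EmptyCohortError("no samples")
    order = np.argsort(times, kind="stable")
    t = times[order]
    e = events[order]
    ev_idx = np.flatnonzero(e == 1)
    if ev_idx.size == 0:
        raise EmptyCohortError("no events in cohort")
    ev_t = t[ev_idx]
    new = np.empty(ev_idx.size, dtype=bool)
    new[0] = True
    new[1:] = ev_t[1:] != ev_t[:-1]
    group_starts = np.flatnonzero(new)
    tau = ev_t[group_starts]
    d = np.diff(np.append(group_starts, ev_idx.size))
    starts = np.searchsorted(t, tau, side="left")
    r = n - starts
    return RiskSetData(order, n, starts, d, r, ev_idx, group_starts)


# ---------------------------------------------------------------------------
# Aggregation


def aggregate_columns(rs: RiskSetData, Z: np.ndarray):
    """(r1, s) per event time for arbitrary indicator columns, shape (J, C)."""
    Z = np.asarray(Z, dtype=float)
    Zs = Z[rs.order]
    pref = np.cumsum(Zs, axis=0)
    tot = pref[-1]
    r1 = np.empty((rs.d.size, Z.shape[1]))
    nz = rs.event_starts > 0
    r1[~nz] = tot
    r1[nz] = tot - pref[rs.event_starts[nz] - 1]
    s = np.add.reduceat(Zs[rs.event_rows], rs.event_group_starts, axis=0)
    return r1, s


def bin_histograms(rs: RiskSetData, bins: np.ndarray, n_bins: int,
                   dtype=np.float64):
    """At-risk and death histograms over integer bins, per event time.

    Returns (H, Hd) of shape (J, n_bins): H[j, b] is the number of samples
    at risk at event time j whose bin equals b; Hd counts the deaths tied
    at event time j.  Samples censored before the first event time never
    enter any risk set and are dropped up front.
    """
    bins = np.asarray(bins)
    sorted_bins = bins[rs.order]
    J = rs.d.size
    # scatter each sample into (segment-between-event-times, bin); a reverse
    # cumsum over segments gives the at-risk histogram at each event time
    seg_of = np.searchsorted(rs.event_starts, np.arange(rs.n), side="right") - 1
    inside = seg_of >= 0  # samples censored before the first event never at risk
    seg = np.bincount(seg_of[inside] * n_bins + sorted_bins[inside],
                      minlength=J * n_bins).astype(dtype)
    H = seg.reshape(J, n_bins)[::-1].cumsum(axis=0, dtype=dtype)[::-1]
    ev_seg = np.searchsorted(rs.event_group_starts,
                             np.arange(rs.event_rows.size), side="right") - 1
    Hd = np.bincount(ev_seg * n_bins + sorted_bins[rs.event_rows],
                     minlength=J * n_bins).astype(dtype)
    return np.ascontiguousarray(H), Hd.reshape(J, n_bins)


def threshold_counts(rs: RiskSetData, bins: np.ndarray, n_levels: int):
    """(r1, s) for the threshold family ``indicator_k = (bin > k)``.

    ``bins`` holds, per sample, the number of candidate cut-offs strictly
    below the sample's value, so bin > k is the strict ``x > c_k`` split.
    Output shape (J, n_levels).
    """
    H, Hd = bin_histograms(rs, bins, n_levels + 1)
    r1 = H[:, ::-1].cumsum(axis=1)[:, ::-1][:, 1:]
    s = Hd[:, ::-1].cumsum(axis=1)[:, ::-1][:, 1:]
    return np.ascontiguousarray(r1), np.ascontiguousarray(s)


# ---------------------------------------------------------------------------
# Score test and Newton refinement on aggregate counts


def score_chi2_counts(d, r, r1, s):
    """Efron score-test chi-square at beta=0 for each column of (r1, s)."""
    d = np.asarray(d, dtype=float)
    r = np.asarray(r, dtype=float)
    U = s.sum(axis=0)
    I = np.zeros(r1.shape[1])
    maxd = int(d.max())
    if maxd == 1:
        E = r1 / r[:, None]
        U = U - E.sum(axis=0)
        I = (E * (1.0 - E)).sum(axis=0)
    else:
        for l in range(maxd):
            m = d > l
            frac = (l / d[m])[:, None]
            E = (r1[m] - frac * s[m]) / (r[m] - l)[:, None]
            U = U - E.sum(axis=0)
            I = I + (E * (1.0 - E)).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(I > 0, U * U / I, 0.0)
    return chi2


def newton_counts(d, r, r1, s, max_iter: int = 50, tol: float = 1e-11):
    """Newton-Raphson on the Efron partial likelihood, per column.

    Returns (beta, se, p, ok); failed columns (no contrast among events,
    monotone likelihood, non-convergence) get ok=False and NaN estimates.
    """
    d = np.asarray(d, dtype=float)
    r = np.asarray(r, dtype=float)
    r1 = np.asarray(r1, dtype=np.float64)
    s = np.asarray(s, dtype=np.float64)
    C = r1.shape[1]
    s_tot = s.sum(axis=0)
    d_tot = d.sum()
    n1 = r1.max(axis=0)  # proxy for group-1 presence among at-risk
    ok = (n1 > 0) & (s_tot > 0) & (s_tot < d_tot)

    beta = np.zeros(C)
    info = np.full(C, np.nan)
    sep = np.zeros(C, dtype=bool)
    maxd = int(d.max())
    active = np.flatnonzero(ok)
    live = active.copy()
    while live.size and max_iter > 0:
        max_iter -= 1
        b = beta[live]
        eb = np.exp(b)
        r1l = r1[:, live]
        sl = s[:, live]
        S0 = r[:, None] + r1l * (eb - 1.0)
        S1 = r1l * eb
        U = s_tot[live].copy()
        I = np.zeros(live.size)
        if maxd == 1:
            E = S1 / S0
            U -= E.sum(axis=0)
            I += (E * (1.0 - E)).sum(axis=0)
        else:
            S0d = d[:, None] + sl * (eb - 1.0)
            S1d = sl * eb
            for l in range(maxd):
                m = d > l
                frac = (l / d[m])[:, None]
                E = (S1[m] - frac * S1d[m]) / (S0[m] - frac * S0d[m])
                U -= E.sum(axis=0)
                I += (E * (1.0 - E)).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            step = U / I
        step = np.where(np.isfinite(step), step, 0.0)
        np.clip(step, -2.0, 2.0, out=step)
        beta[live] = b + step
        info[live] = I
        blown = np.abs(beta[live]) > SEPARATION_BETA
        done = (np.abs(step) < tol) & ~blown
        if blown.any():
            sep[live[blown]] = True
        live = live[~(done | blown)]
    if live.size:
        sep[live] = True
    ok = ok & ~sep

    with np.errstate(divide="ignore", invalid="ignore"):
        se = 1.0 / np.sqrt(info)
        z = beta / se
    p = erfc(np.abs(z) / np.sqrt(2.0))
    p = np.clip(p, 1e-300, 1.0)
    beta = np.where(ok, beta, np.nan)
    se = np.where(ok, se, np.nan)
    p = np.where(ok, p, np.nan)
    return beta, se, p, ok


def cox_binary_batch(rs: RiskSetData, Z: np.ndarray, **kw):
    """Fit the binary-covariate Cox model for every column of ``Z``.

    ``Z`` is a 0/1 indicator matrix (n_samples x n_candidates) in the
    original sample order.  Returns (beta, se, p, ok).
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    r1, s = aggregate_columns(rs, Z)
    beta, se, p, ok = newton_counts(rs.d, rs.r, r1, s, **kw)
    n1 = Z.sum(axis=0)
    bad = (n1 == 0) | (n1 == rs.n)
    if bad.any():
        ok = ok & ~bad
        beta = np.where(bad, np.nan, beta)
        se = np.where(bad, np.nan, se)
        p = np.where(bad, np.nan, p)
    return beta, se, p, ok


def cox_binary_single(times, events, indicator):
    """Single-covariate wrapper with strict error reporting."""
    indicator = np.asarray(indicator)
    if np.unique(indicator).size < 2:
        raise NoContrastError("covariate takes a single value")
    rs = prepare_risk_sets(times, events)
    beta, se, p, ok = cox_binary_batch(rs, indicator.astype(float)[:, None])
    if not ok[0]:
        events_arr = np.asarray(events)
        mask = indicator.astype(bool)
        diag = {
            "events_group1": int(events_arr[mask].sum()),
            "events_group0": int(events_arr[~mask].sum()),
            "n_group1": int(mask.sum()),
            "n_group0": int((~mask).sum()),
        }
        raise SeparationError("monotone partial likelihood", diag)
    return float(beta[0]), float(se[0]), float(p[0])
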