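"""Data-driven survival stratification scans (DDSS).

DDSS-1D searches every admissible cut-off of one feature's expression for
the dichotomization whose Cox/Wald P-value is smallest; the sign of the
fitted log hazard ratio classifies the feature as pro-oncogenic (high
expression, high risk) or tumor-suppressor-like.  The two-cut-off variant
reads the two strongest local maxima off the -log10 P profile and splits
the cohort into three ordered risk groups.  DDSS-2D scans a quantile grid
of paired cut-offs crossed with the seven distinct quadrant bipartitions
and flags pairs whose joint model beats both single-feature models
(synergy).

Because the minimized P-value of a scan is selection-biased (it is the
minimum over many correlated tests), an optional permutation adjustment
re-runs the scan on label-permuted data and reports the rank of the
observed minimum; the raw minimized P matches the values the scans are
conventionally reported with.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import find_peaks

from ._cox import (
    RiskSetData,
    bin_histograms,
    newton_counts,
    prepare_risk_sets,
    threshold_counts,
)
from .core_data import RiskGrouping, SurvivalTable
from .errors import (
    NoValidCutoffError,
    ScanFailedError,
    ValidationError,
)
from .survival_stats import P_FLOOR, WaldResult, logrank

QUADRANTS = ("low/low", "low/high", "high/low", "high/high")

PRO_ONCOGENIC = "pro-oncogenic"
TUMOR_SUPPRESSOR = "tumor-suppressor-like"
INDETERMINATE = "indeterminate"

#: smoothing window (candidates) applied to the -log10 P profile before
#: local-maximum detection in the two-cut-off scan
PROFILE_SMOOTH_WINDOW = 5


# ---------------------------------------------------------------------------
# Model containers


@dataclass
class ScanProfile:
    """Per-candidate results of a 1D cut-off scan."""

    cutoffs: np.ndarray
    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    ok: np.ndarray
    n_high: np.ndarray  # samples with x > cutoff


@dataclass
class CutoffModel1D:
    feature_id: str
    cutoff: float
    wald: WaldResult
    phenotype: str
    grouping: RiskGrouping
    n_low: int
    n_high: int
    profile: ScanProfile | None = None
    p_permutation: float | None = None

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "model": "cutoff_1d",
            "feature_id": self.feature_id,
            "cutoff": self.cutoff,
            "wald": vars(self.wald),
            "phenotype": self.phenotype,
            "n_low": self.n_low,
            "n_high": self.n_high,
            "p_permutation": self.p_permutation,
            "grouping": {"labels": self.grouping.labels, "k": self.grouping.k,
                         "provenance": self.grouping.provenance},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CutoffModel1D":
        g = d["grouping"]
        return cls(
            feature_id=d["feature_id"],
            cutoff=d["cutoff"],
            wald=WaldResult(**d["wald"]),
            phenotype=d["phenotype"],
            grouping=RiskGrouping(dict(g["labels"]), g["k"], g["provenance"]),
            n_low=d["n_low"],
            n_high=d["n_high"],
            p_permutation=d.get("p_permutation"),
        )


@dataclass
class TripleCutoffModel:
    feature_id: str
    cutoff_lo: float | None
    cutoff_hi: float | None
    grouping: RiskGrouping | None
    overall_logrank_p: float | None
    pairwise_wald_p: tuple | None
    accepted: bool
    reason: str = ""
    fallback: CutoffModel1D | None = None

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "model": "cutoff_1d_double",
            "feature_id": self.feature_id,
            "cutoff_lo": self.cutoff_lo,
            "cutoff_hi": self.cutoff_hi,
            "overall_logrank_p": self.overall_logrank_p,
            "pairwise_wald_p": list(self.pairwise_wald_p) if self.pairwise_wald_p else None,
            "accepted": self.accepted,
            "reason": self.reason,
            "grouping": None if self.grouping is None else {
                "labels": self.grouping.labels, "k": self.grouping.k,
                "provenance": self.grouping.provenance},
        }


@dataclass(frozen=True)
class Design2D:
    """One of the seven quadrant bipartitions of a paired cut-off model.

    ``id`` is the canonical bitmask over the quadrant order (low/low,
    low/high, high/low, high/high); a mask and its complement describe the
    same bipartition, so the representative with the high/high bit clear is
    used (ids 1..7).  ``risk_map`` gives the nominal orientation (masked
    quadrants = "higher-risk"); a fitted pair model re-orients by the sign
    of the Cox coefficient.
    """

    id: int
    risk_map: dict = field(hash=False)

    def quadrant_mask(self) -> tuple:
        return tuple(self.risk_map[q] == "higher-risk" for q in QUADRANTS)


def enumerate_designs() -> list[Design2D]:
    """The seven distinct bipartitions of the four quadrants.

    Of the 2^4 - 2 = 14 nonempty proper labelings, each bipartition is
    counted twice (label exchange), leaving seven; the canonical
    representative of mask m is min(m, 15 - m), i.e. masks 1..7.
    """
    designs = []
    for mask in range(1, 8):
        rm = {
            q: ("higher-risk" if (mask >> i) & 1 else "lower-risk")
            for i, q in enumerate(QUADRANTS)
        }
        designs.append(Design2D(id=mask, risk_map=rm))
    return designs


@dataclass
class PairModel2D:
    feature_pair: tuple
    cutoffs: tuple
    design: Design2D
    wald: WaldResult
    synergistic: bool
    grouping: RiskGrouping | None
    p_1d: tuple  # best single-feature P of each member on the same grid

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "model": "pair_2d",
            "feature_pair": list(self.feature_pair),
            "cutoffs": list(self.cutoffs),
            "design_id": self.design.id,
            "risk_map": self.design.risk_map,
            "wald": vars(self.wald),
            "synergistic": self.synergistic,
            "p_1d": list(self.p_1d),
            "grouping": None if self.grouping is None else {
                "labels": self.grouping.labels, "k": self.grouping.k,
                "provenance": self.grouping.provenance},
        }


# ---------------------------------------------------------------------------
# 1D scan


def _surv_arrays(surv):
    if isinstance(surv, SurvivalTable):
        s = surv.included()
        return list(s.sample_ids), s.time, s.event
    times, events = surv
    ids = [f"S{i}" for i in range(len(times))]
    return ids, np.asarray(times, float), np.asarray(events, int)


def _check_scan_pre(x, events, min_samples=30, min_events=10):
    if x.size < min_samples:
        raise ValidationError(f"scan needs >= {min_samples} samples, got {x.size}")
    if int(np.sum(events)) < min_events:
        raise ValidationError(f"scan needs >= {min_events} events, got {int(np.sum(events))}")
    if np.unique(x).size < 2:
        raise NoValidCutoffError("feature is constant; no cut-off exists")


def _admissible_cutoffs(x, min_group_frac):
    """Observed unique values whose strict split keeps both groups large enough."""
    n = x.size
    min_n = int(np.ceil(min_group_frac * n))
    uniq = np.unique(x)
    # n_high for cutoff c = # x > c
    n_high = n - np.searchsorted(np.sort(x), uniq, side="right")
    keep = (n_high >= min_n) & (n - n_high >= min_n)
    return uniq[keep]


def scan_profile_1d(x, times, events, min_group_frac: float = 0.10,
                    cutoffs=None) -> ScanProfile:
    """Evaluate the Cox/Wald fit at every admissible cut-off of ``x``."""
    x = np.asarray(x, dtype=float)
    _check_scan_pre(x, events)
    if cutoffs is None:
        cand = _admissible_cutoffs(x, min_group_frac)
    else:
        cand = np.unique(np.asarray(cutoffs, dtype=float))
        n = x.size
        min_n = int(np.ceil(min_group_frac * n))
        n_high = (x[:, None] > cand[None, :]).sum(axis=0)
        cand = cand[(n_high >= min_n) & (n - n_high >= min_n)]
    if cand.size == 0:
        raise NoValidCutoffError("no cut-off satisfies the group-size constraint")
    rs = prepare_risk_sets(times, events)
    bins = np.searchsorted(cand, x, side="left")
    r1, s = threshold_counts(rs, bins, cand.size)
    beta, se, p, ok = newton_counts(rs.d, rs.r, r1, s)
    n_high = (x[:, None] > cand[None, :]).sum(axis=0)
    return ScanProfile(cand, beta, se, p, ok, n_high)


def _pick_min(profile: ScanProfile):
    if not profile.ok.any():
        raise ScanFailedError("Cox fit failed at every admissible cut-off")
    p = np.where(profile.ok, profile.p, np.inf)
    i = int(np.argmin(p))  # first minimum = smallest cutoff on ties
    return i


def classify_phenotype(model: "CutoffModel1D | float") -> str:
    """Sign rule: positive coefficient for (x > cutoff) means pro-oncogenic."""
    beta = model.wald.beta if isinstance(model, CutoffModel1D) else float(model)
    if beta > 0:
        return PRO_ONCOGENIC
    if beta < 0:
        return TUMOR_SUPPRESSOR
    return INDETERMINATE


def scan_1d(
    x,
    surv,
    min_group_frac: float = 0.10,
    feature_id: str = "feature",
    permutations: int = 0,
    seed: int | None = None,
    keep_profile: bool = True,
) -> CutoffModel1D:
    """Optimal single cut-off of one feature against censored survival.

    Every admissible observed value (both induced groups >=
    ``min_group_frac`` of the cohort) is evaluated with a binary-covariate
    Cox fit; the cut-off with the smallest Wald P wins, ties broken toward
    the smallest cut-off.  With ``permutations`` > 0 a label-permutation
    rank of the minimized P is reported alongside (the raw minimum is
    biased below uniform under the null).
    """
    ids, times, events = _surv_arrays(surv)
    x = np.asarray(x, dtype=float)
    profile = scan_profile_1d(x, times, events, min_group_frac)
    i = _pick_min(profile)
    cutoff = float(profile.cutoffs[i])
    beta = float(profile.beta[i])
    se = float(profile.se[i])
    wald = WaldResult(beta=beta, se=se, z=beta / se,
                      p=max(float(profile.p[i]), P_FLOOR), hr=float(np.exp(beta)))
    phenotype = classify_phenotype(beta)
    high_expr = x > cutoff
    high_risk = high_expr if beta >= 0 else ~high_expr
    grouping = RiskGrouping(
        {s: ("high" if h else "low") for s, h in zip(ids, high_risk)},
        k=2,
        provenance=f"ddss1d:{feature_id}@{cutoff:g}",
    )
    model = CutoffModel1D(
        feature_id=feature_id,
        cutoff=cutoff,
        wald=wald,
        phenotype=phenotype,
        grouping=grouping,
        n_low=int((~high_risk).sum()),
        n_high=int(high_risk.sum()),
        profile=profile if keep_profile else None,
    )
    if permutations > 0:
        model.p_permutation = _permutation_p(
            x, times, events, min_group_frac, wald.p, permutations, seed
        )
    return model


def _permutation_p(x, times, events, min_group_frac, observed_p, B, seed):
    """Rank of the observed minimized P among label-permutation minima."""
    rng = np.random.default_rng(seed)
    cand = _admissible_cutoffs(x, min_group_frac)
    rs = prepare_risk_sets(times, events)
    bins = np.searchsorted(cand, x, side="left")
    n = x.size
    hits = 0
    chunk = max(1, int(2_000_000 / max(cand.size * len(rs.d), 1)))
    done = 0
    while done < B:
        b = min(chunk, B - done)
        # permuted indicator columns for b permutations, stacked
        perm_bins = np.empty((n, b), dtype=np.int64)
        for j in range(b):
            perm_bins[:, j] = bins[rng.permutation(n)]
        Z = perm_bins[:, :, None] > np.arange(cand.size)[None, None, :]
        Z = Z.reshape(n, b * cand.size)
        from ._cox import aggregate_columns  # local import to avoid cycle noise

        r1, s = aggregate_columns(rs, Z.astype(float))
        _, _, p, ok = newton_counts(rs.d, rs.r, r1, s)
        p = np.where(ok, p, np.inf).reshape(b, cand.size)
        pmin = np.where(np.isfinite(p.min(axis=1)), p.min(axis=1), 1.0)
        hits += int(np.sum(pmin <= observed_p))
        done += b
    return (1 + hits) / (B + 1)


# ---------------------------------------------------------------------------
# Two-cut-off (three-group) scan


def scan_1d_double(
    x,
    surv,
    min_group_frac: float = 0.10,
    min_cutoff_gap_frac: float = 0.15,
    feature_id: str = "feature",
    logrank_threshold: float = 0.005,
    pairwise_threshold: float = 0.05,
) -> TripleCutoffModel:
    """Two-cut-off, three-risk-group variant of the 1D scan.

    The -log10 P profile of the single-cut-off scan is median-smoothed and
    its two strongest local maxima, separated by at least
    ``min_cutoff_gap_frac`` of the candidate value range and leaving a
    middle group of at least ``min_group_frac``, become the cut-off pair.
    The model is ``accepted`` when the three-group log-rank P falls below
    ``logrank_threshold`` and all pairwise Wald P below
    ``pairwise_threshold``.  With fewer than two qualifying maxima the
    single-cut-off model is returned as a fallback with accepted=False.
    """
    ids, times, events = _surv_arrays(surv)
    x = np.asarray(x, dtype=float)
    profile = scan_profile_1d(x, times, events, min_group_frac)

    height = np.where(profile.ok, -np.log10(np.maximum(profile.p, P_FLOOR)), 0.0)
    smooth = median_filter(height, size=PROFILE_SMOOTH_WINDOW, mode="nearest")
    peaks, _ = find_peaks(smooth)

    def fallback(reason):
        m1 = scan_1d(x, surv, min_group_frac, feature_id=feature_id, keep_profile=False)
        return TripleCutoffModel(
            feature_id=feature_id, cutoff_lo=None, cutoff_hi=None, grouping=None,
            overall_logrank_p=None, pairwise_wald_p=None, accepted=False,
            reason=reason, fallback=m1,
        )

    if peaks.size < 2:
        return fallback(f"fewer than two local maxima in the P profile ({peaks.size})")

    vrange = float(profile.cutoffs[-1] - profile.cutoffs[0])
    min_gap = min_cutoff_gap_frac * vrange
    n = x.size
    min_n = int(np.ceil(min_group_frac * n))
    # rank peak pairs by combined strength, deterministically
    pairs = []
    for ai in range(peaks.size):
        for bi in range(ai + 1, peaks.size):
            i, j = peaks[ai], peaks[bi]
            c_lo, c_hi = float(profile.cutoffs[i]), float(profile.cutoffs[j])
            if c_hi - c_lo < min_gap:
                continue
            mid = int(np.sum((x > c_lo) & (x <= c_hi)))
            if mid < min_n:
                continue
            pairs.append((-(smooth[i] + smooth[j]), c_lo, c_hi))
    if not pairs:
        return fallback("no peak pair satisfies gap/size constraints")
    pairs.sort()
    _, c_lo, c_hi = pairs[0]

    expr_code = np.where(x > c_hi, 2, np.where(x > c_lo, 1, 0))
    chi2, p_overall = logrank(expr_code, times, events)
    # pairwise Wald: mid-vs-lowexpr, highexpr-vs-lowexpr, highexpr-vs-mid
    pw = []
    betas_vs_low = []
    for a, b in ((0, 1), (0, 2), (1, 2)):
        m = np.isin(expr_code, (a, b))
        ind = (expr_code[m] == b).astype(float)
        r1sub, ssub = None, None
        try:
            from ._cox import cox_binary_single

            beta, se, pv = cox_binary_single(times[m], events[m], ind)
        except Exception:
            beta, se, pv = np.nan, np.nan, 1.0
        pw.append(pv)
        if a == 0:
            betas_vs_low.append(beta)
    # order risk by estimated hazard relative to the low-expression group
    hazard_rank = np.argsort(np.argsort([0.0] + [b if np.isfinite(b) else 0.0
                                                 for b in betas_vs_low]))
    grouping = RiskGrouping.from_codes(
        ids, hazard_rank[expr_code], k=3,
        provenance=f"ddss1d-double:{feature_id}@({c_lo:g},{c_hi:g})",
    )
    accepted = bool(p_overall < logrank_threshold and all(pv < pairwise_threshold for pv in pw))
    return TripleCutoffModel(
        feature_id=feature_id, cutoff_lo=c_lo, cutoff_hi=c_hi, grouping=grouping,
        overall_logrank_p=float(p_overall), pairwise_wald_p=tuple(float(v) for v in pw),
        accepted=accepted,
        reason="" if accepted else "significance thresholds not met",
    )


# ---------------------------------------------------------------------------
# 2D pair scan

#: higher-risk-nominal quadrant coefficients (LL, LH, HL) per canonical design;
#: the high/high bit is always clear in the canonical representative.
_DESIGN_COEFS = {
    1: (1, 0, 0), 2: (0, 1, 0), 3: (1, 1, 0), 4: (0, 0, 1),
    5: (1, 0, 1), 6: (0, 1, 1), 7: (1, 1, 1),
}


def _quantile_levels(n_quantiles: int) -> np.ndarray:
    return np.linspace(0.0, 1.0, n_quantiles + 2)[1:-1]


class PairScanner:
    """Shared state for scanning many feature pairs on one cohort.

    Caches the risk-set structure and the per-feature quantile grid, rank
    bins and best single-feature P so a pairwise sweep pays only the joint
    (pair-specific) work per pair.  The score statistic at beta=0 is
    linear/quadratic in the quadrant at-risk counts, which lets all
    7 x grid^2 configurations be ranked from a handful of precomputed
    grids; only the ``refine`` strongest are Newton-polished to their Wald
    P.  In float32 the score ranking is approximate, but the refined set
    comfortably brackets the argmin; pass ``refine=None`` for an
    exhaustive float64 Wald evaluation.
    """

    def __init__(self, surv, min_group_frac: float = 0.10, n_quantiles: int = 49,
                 refine: int | None = 128, keep_grouping: bool = True):
        self.keep_grouping = keep_grouping
        self.ids, self.times, self.events = _surv_arrays(surv)
        self.n = len(self.ids)
        self.rs = prepare_risk_sets(self.times, self.events)
        self.min_group_frac = min_group_frac
        self.min_n = int(np.ceil(min_group_frac * self.n))
        self.levels = _quantile_levels(n_quantiles)
        self.refine = refine
        self._feat: dict[str, tuple] = {}
        d = self.rs.d.astype(float)
        r = self.rs.r.astype(float)
        self._d, self._r = d, r
        self._tied = int(d.max()) > 1
        self._dtype = np.float64 if refine is None else np.float32

    def add_feature(self, feature_id: str, x) -> None:
        x = np.asarray(x, dtype=float)
        _check_scan_pre(x, self.events)
        q = np.unique(np.quantile(x, self.levels))
        bins = np.searchsorted(q, x, side="left")  # strict x > c split
        p_best = _best_1d_on_grid(self.rs, x, q, self.min_group_frac)
        self._feat[feature_id] = (x, q, bins)
        if not hasattr(self, "_p1d"):
            self._p1d = {}
        self._p1d[feature_id] = p_best

    def scan(self, f1: str, f2: str) -> PairModel2D:
        x1, q1, b1 = self._feat[f1]
        x2, q2, b2 = self._feat[f2]
        L1, L2 = q1.size, q2.size
        n, J = self.n, self._d.size
        dt = self._dtype
        rs = self.rs

        joint = b1 * (L2 + 1) + b2
        d, r = self._d, self._r
        tied = self._tied
        H, Hd = bin_histograms(rs, joint, (L1 + 1) * (L2 + 1), dtype=dt)
        H = H.reshape(J, L1 + 1, L2 + 1)

        def suffix2d(A):
            A = A[:, ::-1, :].cumsum(axis=1, dtype=dt)[:, ::-1, :]
            return A[:, :, ::-1].cumsum(axis=2, dtype=dt)[:, :, ::-1]

        def quad_counts(Cg, tot):
            HH = Cg[:, 1:, 1:]
            A = Cg[:, 1:, :1]
            B = Cg[:, :1, 1:]
            # stacked (3, J, M): LL, LH, HL
            return np.stack([
                (tot[:, None, None] - A - B + HH).reshape(J, -1),
                np.broadcast_to(B - HH, (J, L1, L2)).reshape(J, -1),
                np.broadcast_to(A - HH, (J, L1, L2)).reshape(J, -1),
            ])

        Cge = suffix2d(H)    # at-risk with bin1 >= a, bin2 >= b
        Qr = quad_counts(Cge, r.astype(dt))

        def flat_quads(hist2d, tot):
            """Quadrant totals (3, M) of a plain 2D histogram."""
            Fge = hist2d[::-1, :].cumsum(0)[::-1, :][:, ::-1].cumsum(1)[:, ::-1]
            fHH = Fge[1:, 1:]
            fA = np.broadcast_to(Fge[1:, :1], (L1, L2))
            fB = np.broadcast_to(Fge[:1, 1:], (L1, L2))
            return np.stack([(tot - fA - fB + fHH).ravel(), (fB - fHH).ravel(),
                             (fA - fHH).ravel()])

        full = np.bincount(joint, minlength=(L1 + 1) * (L2 + 1)).astype(float)
        fQ = flat_quads(full.reshape(L1 + 1, L2 + 1), n)

        # death totals per quadrant (enter the score linearly)
        deaths = np.zeros(n, dtype=bool)
        deaths[rs.order[rs.event_rows]] = True
        dhist = np.bincount(joint[deaths],
                            minlength=(L1 + 1) * (L2 + 1)).astype(float)
        sQ = flat_quads(dhist.reshape(L1 + 1, L2 + 1), float(deaths.sum()))

        # Efron score at beta=0 decomposed over event-time coefficients:
        #   E_jl = alpha_jl r1_j - beta_jl s_j,
        #   alpha = 1/(r_j - l), beta = (l/d_j) alpha,
        # so both the score and its variance are quadratic forms in the
        # quadrant counts with per-time weights; the s-dependent weights
        # vanish wherever d_j = 1, so tie corrections only touch tied rows.
        maxd = int(d.max())
        a_c = np.zeros(J)
        b_c = np.zeros(J)
        A_c = np.zeros(J)
        B_c = np.zeros(J)
        C_c = np.zeros(J)
        for l in range(maxd):
            m = d > l
            alpha = 1.0 / (r[m] - l)
            beta_w = (l / d[m]) * alpha
            a_c[m] += alpha
            b_c[m] += beta_w
            A_c[m] += alpha * alpha
            B_c[m] += alpha * beta_w
            C_c[m] += beta_w * beta_w

        u_R = np.einsum("j,qjm->qm", a_c.astype(dt), Qr)
        G_RR = np.einsum("j,ajm,bjm->abm", A_c.astype(dt), Qr, Qr)
        tied_rows = np.flatnonzero(d > 1)
        if tied_rows.size:
            Hdt = Hd.reshape(J, L1 + 1, L2 + 1)[tied_rows]
            Jt = tied_rows.size
            Cgt = Hdt[:, ::-1, :].cumsum(axis=1, dtype=dt)[:, ::-1, :]
            Cgt = Cgt[:, :, ::-1].cumsum(axis=2, dtype=dt)[:, :, ::-1]
            HHt = Cgt[:, 1:, 1:]
            At = Cgt[:, 1:, :1]
            Bt = Cgt[:, :1, 1:]
            dt_tot = d[tied_rows].astype(dt)
            St = np.stack([
                (dt_tot[:, None, None] - At - Bt + HHt).reshape(Jt, -1),
                np.broadcast_to(Bt - HHt, (Jt, L1, L2)).reshape(Jt, -1),
                np.broadcast_to(At - HHt, (Jt, L1, L2)).reshape(Jt, -1),
            ])
            Rt = Qr[:, tied_rows, :]
            u_S = np.einsum("j,qjm->qm", b_c[tied_rows].astype(dt), St)
            G_RS = np.einsum("j,ajm,bjm->abm", B_c[tied_rows].astype(dt), Rt, St)
            G_SS = np.einsum("j,ajm,bjm->abm", C_c[tied_rows].astype(dt), St, St)
        else:
            u_S = G_RS = G_SS = None

        # score-rank candidates per design, then one Newton pass over the union
        sel_all, design_all = [], []
        for design_id, coefs in _DESIGN_COEFS.items():
            c = np.asarray(coefs, dtype=dt)
            n1 = c @ fQ
            admissible = (n1 >= self.min_n) & (n - n1 >= self.min_n)
            if not admissible.any():
                continue
            sumE = c @ u_R
            sumE2 = np.einsum("a,abm,b->m", c, G_RR, c)
            if tied_rows.size:
                sumE = sumE - c @ u_S
                sumE2 = sumE2 - 2.0 * np.einsum("a,abm,b->m", c, G_RS, c) \
                    + np.einsum("a,abm,b->m", c, G_SS, c)
            U = c @ sQ - sumE
            I = sumE - sumE2
            with np.errstate(divide="ignore", invalid="ignore"):
                chi2 = np.where(I > 0, U * U / I, 0.0)
            chi2 = np.where(admissible, chi2, -np.inf)
            if self.refine is None:
                sel = np.flatnonzero(admissible)
            else:
                k = min(self.refine, chi2.size)
                sel = np.argpartition(-chi2, k - 1)[:k]
                sel = sel[np.isfinite(chi2[sel])]
                sel.sort()
            if sel.size:
                sel_all.append(sel)
                design_all.append(np.full(sel.size, design_id))
        if not sel_all:
            raise NoValidCutoffError("no admissible 2D configuration could be fitted")
        sel_all = np.concatenate(sel_all)
        design_all = np.concatenate(design_all)
        Cmat = np.array([_DESIGN_COEFS[did] for did in design_all], dtype=dt).T
        r1_sel = (Qr[:, :, sel_all] * Cmat[:, None, :]).sum(axis=0)
        # exact per-event-time death counts for the refined columns, built
        # from the individual deaths' grid bins
        ev_seg = np.searchsorted(rs.event_group_starts,
                                 np.arange(rs.event_rows.size),
                                 side="right") - 1
        orig = rs.order[rs.event_rows]
        p_bin, q_bin = b1[orig], b2[orig]
        ai_all, bi_all = np.unravel_index(sel_all, (L1, L2))
        lo1d = p_bin[:, None] <= ai_all[None, :]
        lo2d = q_bin[:, None] <= bi_all[None, :]
        c0k, c1k, c2k = (Cmat[0] > 0), (Cmat[1] > 0), (Cmat[2] > 0)
        in_mask_d = ((lo1d & lo2d) & c0k) | ((lo1d & ~lo2d) & c1k) \
            | ((~lo1d & lo2d) & c2k)
        s_sel = np.zeros((J, sel_all.size))
        np.add.at(s_sel, ev_seg, in_mask_d.astype(float))
        beta_a, se_a, p_a, ok_a = newton_counts(d, r, r1_sel.astype(np.float64),
                                                s_sel)
        if not ok_a.any():
            raise NoValidCutoffError("no admissible 2D configuration could be fitted")
        p_a = np.where(ok_a, p_a, np.inf)
        # deterministic argmin: designs iterate in id order, sel ascending
        i = int(np.argmin(p_a))
        p_best = float(p_a[i])
        design_id = int(design_all[i])
        flat = int(sel_all[i])
        beta, se = float(beta_a[i]), float(se_a[i])
        ai, bi = np.unravel_index(flat, (L1, L2))
        c1, c2 = float(q1[ai]), float(q2[bi])
        coefs = _DESIGN_COEFS[design_id]
        lo1, lo2 = x1 <= c1, x2 <= c2
        in_mask = np.zeros(n, dtype=bool)
        if coefs[0]:
            in_mask |= lo1 & lo2
        if coefs[1]:
            in_mask |= lo1 & ~lo2
        if coefs[2]:
            in_mask |= ~lo1 & lo2
        high_risk = in_mask if beta >= 0 else ~in_mask
        flip = beta < 0
        nominal = {q: ("higher-risk" if (m >> i_) & 1 else "lower-risk")
                   for m in (design_id,) for i_, q in enumerate(QUADRANTS)}
        risk_map = {
            q: ("higher-risk" if (lab == "higher-risk") != flip else "lower-risk")
            for q, lab in nominal.items()
        }
        design = Design2D(id=design_id, risk_map=risk_map)
        wald = WaldResult(beta=beta, se=se, z=beta / se, p=max(p_best, P_FLOOR),
                          hr=float(np.exp(beta)))
        p1, p2 = self._p1d[f1], self._p1d[f2]
        grouping = None
        if self.keep_grouping:
            grouping = RiskGrouping(
                {sid: ("high" if h else "low") for sid, h in zip(self.ids, high_risk)},
                k=2,
                provenance=f"ddss2d:{f1}@{c1:g},{f2}@{c2:g},design{design_id}",
            )
        return PairModel2D(
            feature_pair=(f1, f2),
            cutoffs=(c1, c2),
            design=design,
            wald=wald,
            synergistic=bool(wald.p < min(p1, p2)),
            grouping=grouping,
            p_1d=(float(p1), float(p2)),
        )


def scan_2d(
    x1,
    x2,
    surv,
    min_group_frac: float = 0.10,
    n_quantiles: int = 49,
    feature_pair: tuple = ("f1", "f2"),
    refine: int | None = 128,
) -> PairModel2D:
    """Joint cut-off/design search for one feature pair.

    Both cut-offs range over ``n_quantiles`` evenly spaced quantile
    levels; each admissible grid point is crossed with the seven quadrant
    bipartitions and fitted with the binary Cox model; the global
    minimum-Wald-P configuration wins.  See :class:`PairScanner` (used for
    pairwise sweeps) for the score-screen/Newton-refine strategy and the
    meaning of ``refine``.
    """
    scanner = PairScanner(surv, min_group_frac, n_quantiles, refine)
    scanner.add_feature(feature_pair[0], x1)
    scanner.add_feature(feature_pair[1], x2)
    return scanner.scan(*feature_pair)


def _best_1d_on_grid(rs: RiskSetData, x, cutoffs, min_group_frac):
    n = x.size
    min_n = int(np.ceil(min_group_frac * n))
    n_high = (x[:, None] > cutoffs[None, :]).sum(axis=0)
    keep = (n_high >= min_n) & (n - n_high >= min_n)
    if not keep.any():
        return np.inf
    cand = cutoffs[keep]
    bins = np.searchsorted(cand, x, side="left")
    r1, s = threshold_counts(rs, bins, cand.size)
    _, _, p, ok = newton_counts(rs.d, rs.r, r1, s)
    p = np.where(ok, p, np.inf)
    return float(p.min())


def synergy_frequency(pair_models, p_threshold: float = 0.05) -> dict:
    """Per feature, the number of synergistic pairs (P below threshold)."""
    counts: dict[str, int] = {}
    for pm in pair_models:
        for f in pm.feature_pair:
            counts.setdefault(f, 0)
        if pm.synergistic and pm.wald.p < p_threshold:
            for f in pm.feature_pair:
                counts[f] += 1
    return counts
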