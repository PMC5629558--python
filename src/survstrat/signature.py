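"""Signature construction: ranking, intersections and clinical association.

A prognostic signature here is a small feature subset surviving several
independent screens: the top survival-significant features of the 1D scan,
the cross-validation-stable subset, and the features recurring in
synergistic pairs of the 2D scan (three-way intersection), or
alternatively the overlap between the top set and published literature
signatures (consensus construction).  Feature identifiers are matched
after normalisation (lower case, optional "hsa-" prefix stripped); arm
suffixes (-3p/-5p) denote distinct mature features and are never merged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import RiskGrouping
from .errors import EmptySignatureWarning
from .survival_stats import weighted_kappa_table

log = logging.getLogger(__name__)


def normalize_id(feature_id: str) -> str:
    """Canonical form for matching: lower-case, tolerate a hsa- prefix."""
    fid = feature_id.strip().lower()
    if fid.startswith("hsa-"):
        fid = fid[4:]
    return fid


@dataclass
class SignatureSpec:
    name: str
    member_features: list
    construction: dict = field(default_factory=dict)
    grouping: RiskGrouping | None = None

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "model": "signature",
            "name": self.name,
            "member_features": list(self.member_features),
            "construction": self.construction,
            "grouping": None if self.grouping is None else {
                "labels": self.grouping.labels, "k": self.grouping.k,
                "provenance": self.grouping.provenance},
        }


def rank_top(models, n: int = 100, p_max: float = 0.05) -> list:
    """Feature ids of the n most significant 1D models below ``p_max``.

    Sorted by P ascending with the feature id as a deterministic
    tie-break.
    """
    ranked = sorted(models, key=lambda m: (m.wald.p, m.feature_id))
    return [m.feature_id for m in ranked if m.wald.p < p_max][:n]


def intersect_signature(top_set, cv_set, synergy_set,
                        name: str = "intersection") -> SignatureSpec:
    """Three-way intersection of the screening sets, in top-set order."""
    cv_norm = {normalize_id(f) for f in cv_set}
    syn_norm = {normalize_id(f) for f in synergy_set}
    members = [f for f in top_set
               if normalize_id(f) in cv_norm and normalize_id(f) in syn_norm]
    if not members:
        warnings.warn("signature intersection is empty", EmptySignatureWarning)
    return SignatureSpec(
        name=name,
        member_features=members,
        construction={
            "type": "intersection",
            "sources": {"top": len(list(top_set)), "cv": len(list(cv_set)),
                        "synergy": len(list(synergy_set))},
        },
    )


def consensus_signature(top_set, literature_sets, name: str = "consensus",
                        set_names=None) -> SignatureSpec:
    """Overlap of the top set with the union of literature signatures.

    ``literature_sets`` is a sequence of plain feature-id lists; per-member
    provenance records which literature set(s) matched, and literature ids
    matching nothing in the top set are listed in the reconciliation
    report rather than silently dropped.
    """
    literature_sets = [list(s) for s in literature_sets]
    if set_names is None:
        set_names = [f"set{i + 1}" for i in range(len(literature_sets))]
    lut = {}
    for sname, ids in zip(set_names, literature_sets):
        for fid in ids:
            lut.setdefault(normalize_id(fid), []).append(sname)
    members, provenance = [], {}
    top_norm = {}
    for f in top_set:
        top_norm[normalize_id(f)] = f
        if normalize_id(f) in lut:
            members.append(f)
            provenance[f] = sorted(set(lut[normalize_id(f)]))
    unmatched = sorted(
        {fid for ids in literature_sets for fid in ids
         if normalize_id(fid) not in top_norm}
    )
    if not members:
        warnings.warn("no literature feature overlaps the top set",
                      EmptySignatureWarning)
    return SignatureSpec(
        name=name,
        member_features=members,
        construction={
            "type": "consensus",
            "sources": {"top": len(list(top_set)),
                        "literature_union": len(lut)},
            "provenance": provenance,
            "unmatched_literature_ids": unmatched,
        },
    )


def associate_clinical(grouping: RiskGrouping, clinical: pd.DataFrame,
                       age_bins=(50, 70)) -> pd.DataFrame:
    """Chi-square and weighted-kappa association of a grouping with
    clinical categories.

    Numeric columns named ``age`` are binned at ``age_bins``.  Rows with a
    missing/blank/"unknown" category are dropped per variable; a variable
    with no usable rows is skipped (logged).  ``low_expected`` flags
    tables where >20% of expected counts fall below 5.
    """
    rows = []
    samples = [s for s in clinical.index if s in grouping.labels]
    glabels = [grouping.labels[s] for s in samples]
    glevels = ["low", "intermediate", "high"] if grouping.k == 3 else ["low", "high"]
    gcodes = np.array([glevels.index(lab) for lab in glabels])
    for col in clinical.columns:
        vals = clinical.loc[samples, col]
        if col == "age" and pd.api.types.is_numeric_dtype(vals):
            vals = pd.cut(vals, [-np.inf, *age_bins, np.inf],
                          labels=[f"<{age_bins[0]}",
                                  f"{age_bins[0]}-{age_bins[1]}",
                                  f">{age_bins[1]}"]).astype(str)
        vals = vals.astype(str).str.strip()
        usable = ~vals.isin(("", "nan", "None", "unknown", "NA"))
        if not usable.any():
            log.info("associate_clinical: no usable values for %r, skipped", col)
            continue
        v = vals[usable.to_numpy()]
        g = gcodes[usable.to_numpy()]
        # category levels in ordinal order: risk-label names keep the risk
        # order, anything else sorts lexically (I/II/III, G1/G2/G3 ...)
        uniq = set(v.unique())
        if uniq <= {"low", "intermediate", "high"}:
            clevels = [lev for lev in ("low", "intermediate", "high")
                       if lev in uniq]
        else:
            clevels = sorted(uniq)
        table = np.zeros((len(glevels), len(clevels)))
        cidx = {c: i for i, c in enumerate(clevels)}
        for gi, ci in zip(g, v):
            table[gi, cidx[ci]] += 1
        trimmed = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
        if trimmed.shape[0] < 2 or trimmed.shape[1] < 2:
            log.info("associate_clinical: %r degenerate table, skipped", col)
            continue
        chi2, chi2_p, _, expected = stats.chi2_contingency(trimmed, correction=False)
        low_expected = bool(np.mean(expected < 5) > 0.20)
        # square table over the union of ordinal scales for the kappa
        kdim = max(len(glevels), len(clevels))
        sq = np.zeros((kdim, kdim))
        sq[: table.shape[0], : table.shape[1]] = table
        kappa, kappa_p = weighted_kappa_table(sq)
        rows.append({
            "category": col,
            "chi2": float(chi2),
            "chi2_p": float(chi2_p),
            "kappa": float(kappa),
            "kappa_p": float(kappa_p),
            "low_expected": low_expected,
        })
    return pd.DataFrame(rows)
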