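"""Domain containers and tab-separated I/O.

The toolkit works on two aligned tables: a log2 expression matrix
(features x samples) and a per-sample clinical survival table (follow-up
time in years plus a binary death indicator, with optional categorical
covariates such as stage or therapy outcome).  Both are plain
tab-separated text on disk and thin dataclasses around numpy/pandas in
memory.  Fitted models elsewhere in the package serialize to JSON with a
``schema_version`` field; the helpers for that live next to the types they
serialize.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    DegenerateGroupError,
    DuplicateIdError,
    ParseError,
    ValidationError,
)

SCHEMA_VERSION = 1

#: canonical ordinal order of risk labels
RISK_LEVELS = ("low", "intermediate", "high")

CLINICAL_COLUMNS = ("stage", "grade", "residual", "therapy_outcome", "age")


def _check_unique(ids, kind: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise DuplicateIdError(f"duplicate {kind} id: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Log2 intensity matrix, features in rows, samples in columns."""

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError(
                f"value matrix shape {self.values.shape} inconsistent with "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            r, c = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                "expression matrix contains non-finite values (first at "
                f"feature {self.feature_ids[r]!r}, sample {self.sample_ids[c]!r}); "
                "pre-impute missing cells before loading"
            )

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def feature(self, feature_id: str) -> np.ndarray:
        return self.values[self.feature_ids.index(feature_id)]

    def subset_features(self, keep) -> "ExpressionMatrix":
        keep = list(keep)
        idx = [self.feature_ids.index(f) for f in keep]
        return ExpressionMatrix(keep, list(self.sample_ids), self.values[idx])

    def subset_samples(self, keep) -> "ExpressionMatrix":
        keep = list(keep)
        idx = [self.sample_ids.index(s) for s in keep]
        return ExpressionMatrix(list(self.feature_ids), keep, self.values[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)


@dataclass
class SurvivalTable:
    """Per-sample follow-up time (years), event indicator and covariates.

    Samples that arrived without a usable time or event are *retained* with
    ``excluded=True`` rather than silently dropped; ``n_excluded`` reports
    how many.  Analysis code should call :meth:`included` to get the clean
    cohort.
    """

    sample_ids: list[str]
    time: np.ndarray          # years; NaN where excluded
    event: np.ndarray         # 1 death observed, 0 censored; -1 where excluded
    excluded: np.ndarray = None  # bool mask
    clinical: pd.DataFrame | None = None

    def __post_init__(self):
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.sample_ids, "sample")
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        n = len(self.sample_ids)
        if self.excluded is None:
            self.excluded = np.zeros(n, dtype=bool)
        self.excluded = np.asarray(self.excluded, dtype=bool)
        if not (len(self.time) == len(self.event) == len(self.excluded) == n):
            raise ValidationError("survival table columns have inconsistent lengths")
        ok = ~self.excluded
        if np.any(self.time[ok] <= 0) or np.any(~np.isfinite(self.time[ok])):
            bad = np.array(self.sample_ids)[ok][
                (self.time[ok] <= 0) | ~np.isfinite(self.time[ok])
            ][0]
            raise ValidationError(f"non-positive follow-up time for sample {bad!r}")
        if np.any(~np.isin(self.event[ok], (0, 1))):
            bad = np.array(self.sample_ids)[ok][~np.isin(self.event[ok], (0, 1))][0]
            raise ValidationError(f"event indicator outside {{0,1}} for sample {bad!r}")
        if self.clinical is not None and list(self.clinical.index) != self.sample_ids:
            self.clinical = self.clinical.reindex(self.sample_ids)

    @property
    def n_excluded(self) -> int:
        return int(self.excluded.sum())

    def included(self) -> "SurvivalTable":
        """The analyzable cohort (rows with usable time and event)."""
        keep = ~self.excluded
        ids = [s for s, k in zip(self.sample_ids, keep) if k]
        clin = self.clinical.loc[ids] if self.clinical is not None else None
        return SurvivalTable(ids, self.time[keep], self.event[keep], None, clin)

    def subset(self, keep_ids) -> "SurvivalTable":
        keep_ids = list(keep_ids)
        idx = [self.sample_ids.index(s) for s in keep_ids]
        clin = self.clinical.loc[keep_ids] if self.clinical is not None else None
        return SurvivalTable(
            keep_ids, self.time[idx], self.event[idx], self.excluded[idx], clin
        )


@dataclass
class RiskGrouping:
    """Assignment of samples to ordered risk groups (low < intermediate < high)."""

    labels: dict[str, str]
    k: int
    provenance: str = ""

    def __post_init__(self):
        allowed = set(RISK_LEVELS) if self.k == 3 else {"low", "high"}
        for s, lab in self.labels.items():
            if lab not in allowed:
                raise ValidationError(f"label {lab!r} not allowed for k={self.k}")
        counts = self.counts()
        if sum(1 for v in counts.values() if v > 0) < 2:
            raise DegenerateGroupError(
                f"grouping needs >= 2 non-empty groups, got counts {counts}"
            )

    def counts(self) -> dict[str, int]:
        levels = RISK_LEVELS if self.k == 3 else ("low", "high")
        out = {lev: 0 for lev in levels}
        for lab in self.labels.values():
            out[lab] += 1
        return out

    def codes(self, sample_ids) -> np.ndarray:
        """Ordinal codes (low=0 .. high=k-1) aligned to ``sample_ids``."""
        levels = RISK_LEVELS if self.k == 3 else ("low", "high")
        lut = {lev: i for i, lev in enumerate(levels)}
        try:
            return np.array([lut[self.labels[s]] for s in sample_ids])
        except KeyError as e:  # pragma: no cover - defensive
            raise AlignmentError(f"sample {e.args[0]!r} missing from grouping") from e

    @classmethod
    def from_codes(cls, sample_ids, codes, k: int, provenance: str = "") -> "RiskGrouping":
        levels = RISK_LEVELS if k == 3 else ("low", "high")
        labels = {s: levels[int(c)] for s, c in zip(sample_ids, codes)}
        return cls(labels, k, provenance)


# ---------------------------------------------------------------------------
# Readers / writers


def read_expression(path) -> ExpressionMatrix:
    """Read a features-x-samples TSV (first column feature ids, header samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    feature_ids = [str(f) for f in df.index]
    sample_ids = [str(s) for s in df.columns]
    _check_unique(feature_ids, "feature")
    _check_unique(sample_ids, "sample")
    values = np.empty(df.shape, dtype=float)
    # cell-wise float() parsing: correctly rounded (pandas' fast parser can
    # be one ulp off) and lets errors carry exact coordinates
    for j, col in enumerate(df.columns):
        raw = df[col]
        for i, cell in enumerate(raw):
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise ParseError(
                    f"non-numeric expression cell at feature "
                    f"{feature_ids[i]!r}, sample {sample_ids[j]!r}: {cell!r}",
                    row=feature_ids[i],
                    column=sample_ids[j],
                ) from None
    return ExpressionMatrix(feature_ids, sample_ids, values)


def write_expression(expr: ExpressionMatrix, path) -> None:
    # repr() gives the shortest decimal that round-trips a float64 exactly
    with open(path, "w") as fh:
        fh.write("feature_id\t" + "\t".join(expr.sample_ids) + "\n")
        for fid, row in zip(expr.feature_ids, expr.values):
            fh.write(fid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_clinical(path) -> SurvivalTable:
    """Read the clinical TSV (sample_id, time_years, event [, covariates]).

    Rows with a missing/blank time or event are flagged ``excluded`` (never
    silently dropped); invalid values in present fields raise
    :class:`ValidationError`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ("sample_id", "time_years", "event")
    for col in required:
        if col not in df.columns:
            raise ParseError(f"clinical table missing required column {col!r}")
    ids = [str(s) for s in df["sample_id"]]
    _check_unique(ids, "sample")
    time_raw = pd.to_numeric(df["time_years"], errors="coerce").to_numpy()
    event_raw = pd.to_numeric(df["event"], errors="coerce").to_numpy()
    excluded = np.isnan(time_raw) | np.isnan(event_raw)
    time = np.where(excluded, np.nan, time_raw)
    event = np.where(excluded, -1, np.nan_to_num(event_raw, nan=-1)).astype(float)
    ok = ~excluded
    if np.any(time[ok] <= 0):
        bad = np.array(ids)[ok][time[ok] <= 0][0]
        raise ValidationError(f"non-positive time_years for sample {bad!r}")
    if np.any(~np.isin(event[ok], (0.0, 1.0))):
        bad = np.array(ids)[ok][~np.isin(event[ok], (0.0, 1.0))][0]
        raise ValidationError(f"event outside {{0,1}} for sample {bad!r}")
    clin_cols = [c for c in df.columns if c in CLINICAL_COLUMNS]
    clinical = df.set_index(pd.Index(ids))[clin_cols] if clin_cols else None
    return SurvivalTable(ids, time, event.astype(int), excluded, clinical)


def write_clinical(surv: SurvivalTable, path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": surv.sample_ids,
            "time_years": ["" if e else repr(float(t)) for t, e in zip(surv.time, surv.excluded)],
            "event": ["" if e else str(int(v)) for v, e in zip(surv.event, surv.excluded)],
        }
    )
    if surv.clinical is not None:
        for col in surv.clinical.columns:
            df[col] = surv.clinical[col].to_numpy()
    df.to_csv(path, sep="\t", index=False)


def align(expr: ExpressionMatrix, surv: SurvivalTable):
    """Join on the sample-id intersection, preserving expression column order.

    Returns ``(expr, surv, n_discarded)`` where ``n_discarded`` counts samples
    present in only one of the two inputs.  The excluded-flagged survival rows
    are dropped here as well (they carry no usable follow-up).
    """
    surv_ok = surv.included()
    common = [s for s in expr.sample_ids if s in set(surv_ok.sample_ids)]
    if not common:
        raise AlignmentError("expression and survival tables share no samples")
    discarded = (expr.n_samples - len(common)) + (len(surv_ok.sample_ids) - len(common))
    return expr.subset_samples(common), surv_ok.subset(common), discarded
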