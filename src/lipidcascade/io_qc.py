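"""Lipid matrix container, log/normalization transform and QC-sample checks.

Abundances arrive in mol/L. The analysis transform is a natural-log transform
followed by per-lipid standardization to mean 0, SD 1 (population SD, divisor
n). The container tracks its transform state so the transform can only be
applied once, matching how the downstream statistics expect their input.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["LipidMatrix", "QCReport", "log_normalize", "qc_check",
           "read_lipid_csv", "write_lipid_csv"]

_CLASS_RE = re.compile(r"^[A-Za-z][A-Za-z0-9]*?(?=\d+:)|^[A-Za-z]+")


def lipid_class(lipid_id: str) -> str:
    """Class prefix of a lipid name, e.g. 'PC38:6(20:4)' -> 'PC'."""
    m = _CLASS_RE.match(lipid_id)
    return m.group(0) if m else "other"


@dataclass
class LipidMatrix:
    """Subjects x lipids abundance matrix with an explicit transform state."""

    values: pd.DataFrame
    transform_state: str = "raw"  # "raw" | "lognorm"
    degenerate: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.transform_state not in ("raw", "lognorm"):
            raise ValueError(f"unknown transform_state {self.transform_state!r}")
        if self.values.index.duplicated().any():
            raise ValueError("duplicated subject IDs")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicated lipid IDs")
        if self.values.isna().any().any():
            bad = self.values.columns[self.values.isna().any()][0]
            raise ValueError(f"missing abundances not supported (e.g. column {bad!r})")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def lipid_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def classes(self) -> pd.Series:
        return pd.Series({c: lipid_class(c) for c in self.values.columns})

    def subset(self, subject_ids: Sequence[str] | None = None,
               lipid_ids: Sequence[str] | None = None) -> "LipidMatrix":
        v = self.values
        if subject_ids is not None:
            v = v.loc[list(subject_ids)]
        if lipid_ids is not None:
            v = v[list(lipid_ids)]
        return LipidMatrix(v.copy(), self.transform_state, list(self.degenerate))


def log_normalize(m: LipidMatrix) -> LipidMatrix:
    """Natural log then per-lipid standardization (mean 0, population SD 1).

    Zero-variance columns cannot be standardized: they are flagged in
    ``degenerate`` and their standardized values set to NaN.

    Raises if the matrix is already transformed or contains non-positive
    values (the offending cell is named).
    """
    if m.transform_state != "raw":
        raise ValueError("log_normalize requires a raw matrix (already lognorm)")
    vals = m.values.to_numpy(float)
    if (vals <= 0).any():
        i, j = np.argwhere(vals <= 0)[0]
        raise ValueError(
            f"non-positive abundance at subject {m.values.index[i]!r}, "
            f"lipid {m.values.columns[j]!r}")
    logv = np.log(vals)
    mu = logv.mean(axis=0)
    sd = logv.std(axis=0)  # population SD (divisor n)
    degenerate = [c for c, s in zip(m.values.columns, sd) if s == 0.0]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (logv - mu) / sd
    out[:, sd == 0.0] = np.nan
    res = LipidMatrix.__new__(LipidMatrix)
    res.values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    res.transform_state = "lognorm"
    res.degenerate = degenerate
    return res


@dataclass
class QCReport:
    correlations: pd.DataFrame  # pairwise rank correlations among QC rows
    min_r: float
    max_r: float
    drift: float
    drift_by_column: pd.Series
    r_threshold: float
    drift_threshold: float
    passed: bool

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "min_r": self.min_r, "max_r": self.max_r, "drift": self.drift,
            "r_threshold": self.r_threshold,
            "drift_threshold": self.drift_threshold, "passed": bool(self.passed),
            "correlations": self.correlations.round(6).to_dict(),
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def qc_check(
    qc: pd.DataFrame,
    r_threshold: float = 0.96,
    drift_threshold: float = 0.20,
    internal_standard_ids: Sequence[str] | None = None,
    run_order: Sequence[str] | None = None,
) -> QCReport:
    """QC acceptance: pairwise Spearman correlation (midranks for ties) among
    QC replicate rows and relative intensity drift across run order.

    Pass requires every pairwise r >= ``r_threshold`` (default 0.96) and the
    maximum relative change of internal-standard intensities across the run
    within ``drift_threshold`` (default 20%).
    """
    if len(qc) < 2:
        raise ValueError("qc_check needs at least 2 QC samples")
    order = list(run_order) if run_order is not None else list(qc.index)
    q = qc.loc[order]
    cols = list(internal_standard_ids) if internal_standard_ids is not None \
        else list(q.columns)
    rho, _ = stats.spearmanr(q.to_numpy(), axis=1)  # rows = QC replicates
    if np.ndim(rho) == 0:  # scipy returns a scalar for exactly 2 rows
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    corr = pd.DataFrame(rho, index=q.index, columns=q.index)
    off = rho[~np.eye(len(q), dtype=bool)]
    first = q[cols].iloc[0].to_numpy(float)
    if (first == 0).any():
        raise ValueError("zero intensity in the first QC run")
    rel = np.abs(q[cols].to_numpy(float) - first) / np.abs(first)
    drift_col = pd.Series(rel.max(axis=0), index=cols)
    drift = float(drift_col.max())
    min_r, max_r = float(off.min()), float(off.max())
    return QCReport(
        correlations=corr, min_r=min_r, max_r=max_r, drift=drift,
        drift_by_column=drift_col, r_threshold=r_threshold,
        drift_threshold=drift_threshold,
        passed=bool(min_r >= r_threshold and drift <= drift_threshold))


def write_lipid_csv(m: LipidMatrix, path: str | Path) -> None:
    df = m.values.copy()
    df.index.name = "subject_id"
    df.to_csv(path)


def read_lipid_csv(path: str | Path, transform_state: str = "raw") -> LipidMatrix:
    """Read a subjects x lipids CSV; first column is the subject ID."""
    df = pd.read_csv(path, index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no lipid columns")
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"{path}: non-numeric lipid column {non_numeric[0]!r}")
    return LipidMatrix(df, transform_state=transform_state)
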