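"""Reading, validation, and rescaling of trial-level truth-judgment data.

The analysis operates on long-format data: one row per (participant,
statement) judgment, with a repetition indicator (0 = new, 1 = repeated),
a factual-truth indicator (0 = false, 1 = true), and a truth rating.
Ratings given on an arbitrary bounded Likert-type scale are linearly
rescaled to [-1, 1] so that effects are comparable across studies; on this
scale the individual truth effect (mean repeated minus mean new rating)
ranges from -2 to 2.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("truthfx")

REQUIRED_COLUMNS = ("subject", "statement", "repeated", "truth", "rating")


class DataValidationError(ValueError):
    """Raised when a dataset violates a structural invariant."""


@dataclass
class RatingDataset:
    """Validated trial-level truth-rating data on the [-1, 1] analysis scale.

    The ``table`` holds one row per judgment with contiguous 1-based
    ``subject`` and ``statement`` indices; the original file labels are kept
    in ``subject_labels`` / ``statement_labels`` (position ``i - 1`` holds
    the label of index ``i``).
    """

    table: pd.DataFrame
    scale_min: float = -1.0
    scale_max: float = 1.0
    dataset_label: str = ""
    subject_labels: list = field(default_factory=list)
    statement_labels: list = field(default_factory=list)

    @property
    def n_subjects(self) -> int:
        return int(self.table["subject"].max()) if len(self.table) else 0

    @property
    def n_statements(self) -> int:
        return int(self.table["statement"].max()) if len(self.table) else 0

    @property
    def n_trials(self) -> int:
        return len(self.table)

    # 0-based arrays used by the numerical modules
    @property
    def subject_index0(self) -> np.ndarray:
        return self.table["subject"].to_numpy(dtype=np.int64) - 1

    @property
    def truth(self) -> np.ndarray:
        return self.table["truth"].to_numpy(dtype=np.float64)

    @property
    def repeated(self) -> np.ndarray:
        return self.table["repeated"].to_numpy(dtype=np.float64)

    @property
    def rating(self) -> np.ndarray:
        return self.table["rating"].to_numpy(dtype=np.float64)


@dataclass
class ValidationReport:
    issues: list

    def __bool__(self) -> bool:  # truthy iff clean
        return not self.issues

    def __str__(self) -> str:
        if not self.issues:
            return "dataset valid: no issues found"
        return "\n".join(self.issues)


def rescale_rating(raw, scale_min: float, scale_max: float):
    """Map a rating from [scale_min, scale_max] linearly onto [-1, 1].

    Endpoint-exact: ``scale_min`` maps to -1 and ``scale_max`` to 1.
    """
    if not scale_min < scale_max:
        raise ValueError(f"scale_min ({scale_min}) must be < scale_max ({scale_max})")
    raw_arr = np.asarray(raw, dtype=np.float64)
    bad = (raw_arr < scale_min) | (raw_arr > scale_max)
    if np.any(bad):
        rows = np.flatnonzero(np.atleast_1d(bad))
        raise DataValidationError(
            f"rating(s) outside [{scale_min}, {scale_max}] at row(s) {rows.tolist()[:10]}"
        )
    out = 2.0 * (raw_arr - scale_min) / (scale_max - scale_min) - 1.0
    return float(out) if np.isscalar(raw) else out


def _collect_issues(df: pd.DataFrame, check_bounds: bool = True) -> list:
    issues = []
    ratings = df["rating"].to_numpy(dtype=float)
    if np.any(~np.isfinite(ratings)):
        issues.append("non-finite rating values present")
    out = (ratings < -1 - 1e-12) | (ratings > 1 + 1e-12)
    if check_bounds and np.any(out):
        issues.append(f"{int(out.sum())} rating(s) outside [-1, 1]")
    for col in ("repeated", "truth"):
        vals = set(pd.unique(df[col]))
        if not vals <= {0, 1}:
            issues.append(f"column '{col}' contains non-binary values {sorted(vals - {0, 1})[:5]}")
    dup = df.duplicated(subset=["subject", "statement"])
    if dup.any():
        pairs = df.loc[dup, ["subject", "statement"]].head(5).to_records(index=False)
        issues.append(f"duplicate (subject, statement) pairs: {list(pairs)}")
    truth_counts = df.groupby("statement")["truth"].nunique()
    mixed = truth_counts[truth_counts > 1]
    if len(mixed):
        issues.append(
            f"statement(s) {mixed.index.tolist()[:5]} have inconsistent truth status across rows"
        )
    cond = df.groupby("subject")["repeated"].agg(["min", "max"])
    no_new = cond.index[cond["min"] > 0].tolist()
    no_rep = cond.index[cond["max"] < 1].tolist()
    if no_new:
        issues.append(f"subject(s) {no_new[:5]} have no new (repeated=0) trials")
    if no_rep:
        issues.append(f"subject(s) {no_rep[:5]} have no repeated (repeated=1) trials")
    return issues


def validate_dataset(data: RatingDataset, check_bounds: bool = True) -> ValidationReport:
    """Check every structural invariant; returns a report listing violations.

    ``check_bounds=False`` skips the [-1, 1] range check — appropriate for
    synthetic data left unclipped, as the unbounded normal model permits.
    """
    return ValidationReport(_collect_issues(data.table, check_bounds=check_bounds))


def from_frame(
    df: pd.DataFrame,
    scale_min: float = -1.0,
    scale_max: float = 1.0,
    dataset_label: str = "",
    validate: bool = True,
) -> RatingDataset:
    """Build a RatingDataset from a long-format frame with raw-scale ratings.

    Subject and statement labels may be arbitrary; they are mapped to
    contiguous 1-based indices (in order of first appearance). Rows with a
    missing rating are dropped with a logged count. If ``scale_min == -1``
    and ``scale_max == 1`` rescaling is the identity.
    """
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise DataValidationError(f"missing required column(s): {missing_cols}")
    df = df.loc[:, list(REQUIRED_COLUMNS)].copy()
    n_missing = int(df["rating"].isna().sum())
    if n_missing:
        logger.info("dropping %d row(s) with missing rating", n_missing)
        df = df.dropna(subset=["rating"]).reset_index(drop=True)
    else:
        df = df.reset_index(drop=True)

    for col in ("repeated", "truth"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or not set(pd.unique(vals.dropna())) <= {0, 1}:
            raise DataValidationError(f"column '{col}' must be binary 0/1")
        df[col] = vals.astype(np.int64)

    subj_labels = list(pd.unique(df["subject"]))
    stmt_labels = list(pd.unique(df["statement"]))
    df["subject"] = df["subject"].map({lab: i + 1 for i, lab in enumerate(subj_labels)})
    df["statement"] = df["statement"].map({lab: i + 1 for i, lab in enumerate(stmt_labels)})

    identity_scale = scale_min == -1.0 and scale_max == 1.0
    if identity_scale:
        # already on the analysis scale: rescaling is the identity, and the
        # values may legitimately exceed [-1, 1] (unclipped synthetic data)
        df["rating"] = pd.to_numeric(df["rating"]).to_numpy(dtype=float)
    else:
        df["rating"] = rescale_rating(
            pd.to_numeric(df["rating"]).to_numpy(dtype=float), scale_min, scale_max
        )
    data = RatingDataset(
        table=df,
        scale_min=float(scale_min),
        scale_max=float(scale_max),
        dataset_label=dataset_label,
        subject_labels=subj_labels,
        statement_labels=stmt_labels,
    )
    if validate:
        report = validate_dataset(data, check_bounds=not identity_scale)
        if not report:
            raise DataValidationError(str(report))
    return data


def read_dataset(
    path,
    scale_min: float = -1.0,
    scale_max: float = 1.0,
    dataset_label: str | None = None,
) -> RatingDataset:
    """Read a CSV with header ``subject,statement,repeated,truth,rating``."""
    path = Path(path)
    df = pd.read_csv(path)
    return from_frame(
        df,
        scale_min=scale_min,
        scale_max=scale_max,
        dataset_label=dataset_label if dataset_label is not None else path.stem,
    )


def write_dataset(data: RatingDataset, path) -> None:
    """Write a RatingDataset as CSV, restoring the original labels.

    Ratings are written on the [-1, 1] analysis scale, so the file reads
    back (with default scale bounds) to an identical dataset.
    """
    df = data.table.copy()
    if data.subject_labels:
        df["subject"] = [data.subject_labels[i - 1] for i in df["subject"]]
    if data.statement_labels:
        df["statement"] = [data.statement_labels[i - 1] for i in df["statement"]]
    df.to_csv(path, index=False)


def write_json(obj, path) -> None:
    """Write an analysis-result mapping as pretty-printed JSON."""

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")
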