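"""Observed individual truth effects and study-level summary statistics.

The observed truth effect for participant i is the difference between their
mean rating of repeated and of new statements, M_rep - M_new; on the [-1, 1]
rating scale it ranges from -2 (perfect reversal) to 2. Study-level
descriptives summarize these per-person effects: their mean, SD, a paired
t statistic t = mean / (SD / sqrt(N)), and Cohen's d = mean / SD = t / sqrt(N).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import RatingDataset, validate_dataset, DataValidationError


@dataclass(frozen=True)
class DatasetSummary:
    """One published truth-effect study's reported descriptives."""

    label: str
    source: str
    n_subjects: int
    statements_per_subject: int
    mean_effect: float
    sd_effect: float
    t_statistic: float
    df: int
    cohens_d: float


#: Reported summaries for the eight published individual-level truth-effect
#: data sets (rating scales rescaled to [-1, 1]); used as reference values
#: in consistency checks. SDs are the across-participant SDs of effects.
PUBLISHED_SUMMARIES: tuple[DatasetSummary, ...] = (
    DatasetSummary("1", "Nadarevic et al. (2018)", 267, 20, 0.20, 0.34, 9.47, 266, 0.58),
    DatasetSummary("2", "Nadarevic & Rinnewitz", 139, 20, 0.28, 0.36, 9.16, 138, 0.78),
    DatasetSummary("3", "Nadarevic & Assfalg, Exp. 1", 33, 88, 0.11, 0.10, 6.54, 32, 1.14),
    DatasetSummary("4", "Nadarevic & Assfalg, Exp. 2", 98, 80, 0.20, 0.23, 8.61, 97, 0.87),
    DatasetSummary("5", "Nadarevic & Erdfelder, Exp. 1", 85, 88, 0.05, 0.10, 5.09, 84, 0.55),
    DatasetSummary("6", "Nadarevic & Erdfelder, Exp. 2", 35, 88, 0.07, 0.17, 2.51, 34, 0.42),
    DatasetSummary("7", "Brashier et al., Exp. 1", 52, 120, 0.09, 0.12, 5.52, 51, 0.77),
    DatasetSummary("8", "Pennycook et al., Exp. 1", 396, 20, 0.14, 0.27, 10.08, 395, 0.51),
)


def expected_effect_from_d(cohens_d: float, sigma: float) -> float:
    """Observed-effect scale implied by a trial-level effect size.

    A standardized effect of size d with trial noise sigma corresponds to a
    raw repeated-minus-new difference of d * sigma; e.g. the meta-analytic
    d = 0.50 with sigma = 0.50 implies an expected effect of 0.25 on the
    [-1, 1] rating scale. This is the reasoning behind the default g-prior
    scales r = 1/2.
    """
    return cohens_d * sigma


@dataclass
class SummaryTable:
    """Across-participant summary of observed individual effects."""

    n_subjects: int
    statements_per_subject: int  # modal trials-per-subject count
    mean_effect: float
    sd_effect: float
    t_statistic: float
    df: int
    cohens_d: float
    degenerate: bool = False  # SD of effects is (numerically) zero


def _welch_ci(rep: np.ndarray, new: np.ndarray, ci_level: float) -> tuple[float, float, bool]:
    """Welch two-sample t interval for mean(rep) - mean(new).

    Returns (low, high, defined). With fewer than 2 trials in a condition
    the interval is undefined; with zero variance in both conditions it
    collapses to a point.
    """
    n1, n2 = len(rep), len(new)
    diff = rep.mean() - new.mean()
    if n1 < 2 or n2 < 2:
        return np.nan, np.nan, False
    v1, v2 = rep.var(ddof=1), new.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    if se2 == 0.0:
        return diff, diff, True
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    half = stats.t.ppf(0.5 + ci_level / 2, df) * np.sqrt(se2)
    return diff - half, diff + half, True


def individual_effects(data: RatingDataset, ci_level: float = 0.95) -> pd.DataFrame:
    """Per-subject observed effects with confidence intervals.

    Returns a frame with columns ``subject``, ``n_new``, ``n_repeated``,
    ``observed_effect``, ``ci_low``, ``ci_high``, ``ci_defined``, sorted
    ascending by effect (the ordering used in individual-effect plots).
    """
    report = validate_dataset(data, check_bounds=False)
    if not report:
        raise DataValidationError(str(report))
    if not 0 < ci_level < 1:
        raise ValueError("ci_level must lie in (0, 1)")
    rows = []
    g = data.table.groupby("subject")
    for subject, sub in g:
        rep = sub.loc[sub["repeated"] == 1, "rating"].to_numpy(float)
        new = sub.loc[sub["repeated"] == 0, "rating"].to_numpy(float)
        lo, hi, ok = _welch_ci(rep, new, ci_level)
        rows.append(
            {
                "subject": subject,
                "n_new": len(new),
                "n_repeated": len(rep),
                "observed_effect": rep.mean() - new.mean(),
                "ci_low": lo,
                "ci_high": hi,
                "ci_defined": ok,
            }
        )
    out = pd.DataFrame(rows).sort_values("observed_effect", kind="mergesort")
    return out.reset_index(drop=True)


def summary_table(data: RatingDataset) -> SummaryTable:
    """Mean/SD of individual effects, paired t, and Cohen's d."""
    effects_frame = individual_effects(data)
    effects = effects_frame["observed_effect"].to_numpy(float)
    n = len(effects)
    if n < 2:
        raise ValueError("summary_table needs at least 2 subjects")
    mean = float(effects.mean())
    sd = float(effects.std(ddof=1))
    degenerate = sd == 0.0
    t_stat = mean / (sd / np.sqrt(n)) if not degenerate else np.nan
    d = mean / sd if not degenerate else np.nan
    trials = (effects_frame["n_new"] + effects_frame["n_repeated"]).mode()
    return SummaryTable(
        n_subjects=n,
        statements_per_subject=int(trials.iloc[0]),
        mean_effect=mean,
        sd_effect=sd,
        t_statistic=float(t_stat),
        df=n - 1,
        cohens_d=float(d),
        degenerate=degenerate,
    )
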