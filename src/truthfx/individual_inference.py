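"""Shrinkage estimates, sign classification, and prevalence of negative effects.

Under the unconstrained model each person's truth effect theta_i has a full
posterior; hierarchical pooling shrinks extreme observed effects toward the
group mean. Individuals are classified by the posterior probability of a
positive effect, P(theta_i > 0 | data): above a threshold they count as
positive truthers, below one minus the threshold as negative truthers, and
otherwise as undecided. The population prevalence of negative truthers is
the posterior of Phi(-nu / delta), evaluated per MCMC draw with each draw's
own delta = sqrt(g_theta * sigma^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data_io import RatingDataset
from .sampler import PosteriorSamples, conditional_theta_moments

#: Odds-based classification thresholds: 10-to-1, 3-to-1, and 2-to-1.
ODDS_THRESHOLDS = {"10-to-1": 10 / 11, "3-to-1": 0.75, "2-to-1": 2 / 3}


def shrinkage_estimates(samples: PosteriorSamples, ci_level: float = 0.95) -> pd.DataFrame:
    """Posterior mean and equal-tailed credible interval of each theta_i."""
    if samples.model != "Mu":
        raise ValueError("shrinkage estimates require an Mu fit")
    lo_q, hi_q = (1 - ci_level) / 2, 1 - (1 - ci_level) / 2
    theta = samples.theta
    return pd.DataFrame(
        {
            "subject": np.arange(1, samples.n_subjects + 1),
            "post_mean": theta.mean(axis=0),
            "ci_low": np.quantile(theta, lo_q, axis=0),
            "ci_high": np.quantile(theta, hi_q, axis=0),
        }
    )


@dataclass
class ClassificationSummary:
    prop_positive: float
    prop_negative: float
    prop_undecided: float
    threshold: float


def classify(
    samples: PosteriorSamples,
    threshold: float = 0.75,
    method: str = "count",
    data: RatingDataset | None = None,
) -> pd.DataFrame:
    """Label each person positive/negative/undecided by P(theta_i > 0 | data).

    ``method="count"`` (the default) takes the fraction of retained draws
    with theta_i > 0 — exactly what the posterior-probability plots show;
    ``"rao_blackwell"`` averages Phi(m_i/s_i) over the full-conditional
    moments for extra precision (requires ``data``). The default threshold
    .75 is 3-to-1 odds: p >= .75 positive, p <= .25 negative, else undecided.
    """
    if samples.model != "Mu":
        raise ValueError("classification requires an Mu fit")
    if not 0.5 < threshold < 1:
        raise ValueError("threshold must lie in (0.5, 1)")
    if method == "count":
        p_pos = (samples.theta > 0).mean(axis=0)
    elif method == "rao_blackwell":
        if data is None:
            raise ValueError("rao_blackwell method requires the fitted dataset")
        means, sds = conditional_theta_moments(samples, data)
        p_pos = norm.cdf(means / sds).mean(axis=0)
    else:
        raise ValueError("method must be 'count' or 'rao_blackwell'")

    label = np.where(
        p_pos >= threshold, "positive", np.where(p_pos <= 1 - threshold, "negative", "undecided")
    )
    return pd.DataFrame(
        {
            "subject": np.arange(1, samples.n_subjects + 1),
            "p_positive": p_pos,
            "label": label,
            "threshold": threshold,
        }
    )


def classification_summary(classification: pd.DataFrame) -> ClassificationSummary:
    """Proportions of the three labels (they sum to one)."""
    n = len(classification)
    counts = classification["label"].value_counts()
    return ClassificationSummary(
        prop_positive=counts.get("positive", 0) / n,
        prop_negative=counts.get("negative", 0) / n,
        prop_undecided=counts.get("undecided", 0) / n,
        threshold=float(classification["threshold"].iloc[0]),
    )


@dataclass
class PrevalenceEstimate:
    """Posterior for the population share of negative truthers."""

    posterior_mean: float
    ci_low: float
    ci_high: float
    n_draws: int
    ci_level: float

    def draws_summary(self) -> dict:
        return {
            "posterior_mean": self.posterior_mean,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_draws": self.n_draws,
            "ci_level": self.ci_level,
        }


def prevalence_draws(samples: PosteriorSamples) -> np.ndarray:
    """Per-draw Phi(-nu/delta), the modeled share of negative effects."""
    if samples.model != "Mu":
        raise ValueError("prevalence requires an Mu fit")
    return norm.cdf(-samples.nu / samples.delta)


def prevalence(samples: PosteriorSamples, ci_level: float = 0.95) -> PrevalenceEstimate:
    """Posterior mean and equal-tailed credible interval of the prevalence."""
    if not 0 < ci_level < 1:
        raise ValueError("ci_level must lie in (0, 1)")
    draws = prevalence_draws(samples)
    lo, hi = np.quantile(draws, [(1 - ci_level) / 2, 1 - (1 - ci_level) / 2])
    return PrevalenceEstimate(
        posterior_mean=float(draws.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        n_draws=len(draws),
        ci_level=ci_level,
    )
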