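"""Synthetic truth-judgment data with the structure the models assume.

Each generated dataset follows the trial-level linear model

    Y = mu + alpha_i + t_j * beta + x_k * theta_i + Normal(0, sigma^2)

with individual truth effects theta_i drawn under one of four population
structures: the null model (M0: theta_i = 0), the common-effect model
(M1: theta_i = nu), the positive-effects model (Mplus: truncated normal,
lower bound 0), or the unconstrained model (Mu: Normal(nu, delta^2)).

Defaults mirror the range of published truth-effect studies: about a
hundred participants, 40 statements per person (half repeated, half new),
trial noise sigma = 0.5 on the [-1, 1] rating scale, and individual effects
with mean and spread around 0.15.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import RatingDataset

MODELS = ("M0", "M1", "Mplus", "Mu")


@dataclass
class GeneratorConfig:
    """Generative settings; defaults give a realistic unconstrained study.

    ``n_statements_per_subject`` must be even: half the statements are
    repeated, half new. Under M0 ``effect_mean`` and ``effect_sd`` are
    ignored; under M1 ``effect_sd`` is ignored. ``discretize_to_k`` snaps
    ratings to a K-point grid on [-1, 1] (deliberate misspecification that
    emulates real Likert data); by default ratings are left continuous and
    unclipped, faithful to the unbounded normal model.
    """

    model: str = "Mu"
    n_subjects: int = 100
    n_statements_per_subject: int = 40
    grand_mean: float = 0.0
    subject_sd: float = 0.2
    truth_effect: float = 0.2
    trial_sd: float = 0.5
    effect_mean: float = 0.15
    effect_sd: float = 0.15
    prop_true: float = 0.5
    missing_rate: float = 0.0
    discretize_to_k: int | None = None
    shared_pool: int | None = None
    seed: int = 1

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_statements_per_subject < 2 or self.n_statements_per_subject % 2:
            raise ValueError("n_statements_per_subject must be an even integer >= 2")
        if self.trial_sd <= 0:
            raise ValueError("trial_sd must be > 0")
        if self.subject_sd < 0 or self.effect_sd < 0:
            raise ValueError("standard deviations must be nonnegative")
        if not 0 < self.prop_true < 1:
            raise ValueError("prop_true must lie in (0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.discretize_to_k is not None and self.discretize_to_k < 2:
            raise ValueError("discretize_to_k must be >= 2")


@dataclass
class TrueParameters:
    """The drawn latent quantities behind one synthetic dataset."""

    config: GeneratorConfig
    alpha: np.ndarray
    theta: np.ndarray

    def as_dict(self) -> dict:
        return {
            "config": asdict(self.config),
            "alpha": self.alpha.tolist(),
            "theta": self.theta.tolist(),
        }


def _draw_theta(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    I = config.n_subjects
    nu, delta = config.effect_mean, config.effect_sd
    if config.model == "M0":
        return np.zeros(I)
    if config.model == "M1":
        return np.full(I, nu)
    if config.model == "Mplus":
        if delta == 0:
            if nu < 0:
                raise ValueError(
                    "Mplus with effect_sd=0 and effect_mean<0 has empty support"
                )
            return np.full(I, nu)
        a = (0.0 - nu) / delta  # standardized lower bound
        return stats.truncnorm.rvs(a, np.inf, loc=nu, scale=delta, size=I, random_state=rng)
    # Mu
    return nu + delta * rng.standard_normal(I)


def generate(config: GeneratorConfig) -> tuple[RatingDataset, TrueParameters]:
    """Draw one dataset (and its latent truth) under the configured model.

    Deterministic given (config, seed). By default statements are nested
    within subjects (fresh statements per person); with ``shared_pool`` set,
    each subject rates a random subset of a common statement pool, giving a
    crossed but unbalanced design.
    """
    rng = np.random.default_rng(config.seed)
    I, n_per = config.n_subjects, config.n_statements_per_subject
    half = n_per // 2

    alpha = config.subject_sd * rng.standard_normal(I)
    theta = _draw_theta(config, rng)

    if config.shared_pool is not None:
        pool = int(config.shared_pool)
        if pool < n_per:
            raise ValueError("shared_pool must be >= n_statements_per_subject")
        pool_truth = (rng.random(pool) < config.prop_true).astype(np.int64)
        statement = np.concatenate(
            [rng.choice(pool, size=n_per, replace=False) for _ in range(I)]
        )
        truth = pool_truth[statement]
        statement = statement + 1
    else:
        statement = np.arange(I * n_per, dtype=np.int64) + 1
        truth = (rng.random(I * n_per) < config.prop_true).astype(np.int64)

    subject = np.repeat(np.arange(1, I + 1, dtype=np.int64), n_per)
    repeated = np.tile(np.r_[np.ones(half, np.int64), np.zeros(half, np.int64)], I)

    mean = (
        config.grand_mean
        + alpha[subject - 1]
        + truth * config.truth_effect
        + repeated * theta[subject - 1]
    )
    rating = mean + config.trial_sd * rng.standard_normal(I * n_per)

    if config.discretize_to_k is not None:
        k = config.discretize_to_k
        grid = np.linspace(-1.0, 1.0, k)
        rating = grid[np.abs(rating[:, None] - grid[None, :]).argmin(axis=1)]

    df = pd.DataFrame(
        {
            "subject": subject,
            "statement": statement,
            "repeated": repeated,
            "truth": truth,
            "rating": rating,
        }
    )
    if config.missing_rate > 0:
        keep = rng.random(len(df)) >= config.missing_rate
        df = df.loc[keep].reset_index(drop=True)

    # Built directly (not via from_frame): ratings are deliberately unclipped,
    # so they may fall outside [-1, 1] as the unbounded normal model allows.
    present = np.unique(df["statement"].to_numpy())
    remap = {s: i + 1 for i, s in enumerate(present)}
    df["statement"] = df["statement"].map(remap).astype(np.int64)
    data = RatingDataset(
        table=df,
        scale_min=-1.0,
        scale_max=1.0,
        dataset_label=f"synthetic-{config.model}-seed{config.seed}",
        subject_labels=list(range(1, I + 1)),
        statement_labels=[int(s) for s in present],
    )
    return data, TrueParameters(config=replace(config), alpha=alpha, theta=theta)


def true_negative_proportion(config: GeneratorConfig) -> float:
    """Generative share of negative truthers, Phi(-nu/delta), under Mu."""
    if config.model != "Mu":
        raise ValueError("true_negative_proportion is defined for the Mu model only")
    if config.effect_sd == 0:
        return 0.0 if config.effect_mean > 0 else (1.0 if config.effect_mean < 0 else 0.5)
    return float(stats.norm.cdf(-config.effect_mean / config.effect_sd))
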