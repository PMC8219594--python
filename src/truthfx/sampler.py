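"""Gibbs sampler for the hierarchical truth-effect model.

The trial-level model is

    Y_ijk ~ Normal(mu + alpha_i + t_j * beta + x_k * theta_i, sigma^2)

with person intercepts alpha_i, a factual-truth effect beta, and individual
repetition (truth) effects theta_i. Under the unconstrained model Mu the
effects are theta_i = nu + eta_i with eta_i ~ Normal(0, delta^2); under the
common-effect model M1, theta_i = nu; under the null model M0, theta_i = 0.

Priors follow the default g-prior construction: effects are scaled to the
trial noise through signal-to-noise ratios g = (effect variance) / sigma^2,

    nu  ~ Normal(0, g_nu * sigma^2),    g_nu    ~ Inverse-chi^2(1, r_nu^2),
    eta_i ~ Normal(0, g_theta sigma^2), g_theta ~ Inverse-chi^2(1, r_theta^2),

so delta^2 = g_theta * sigma^2. Nuisance blocks get the companion
specification: Jeffreys prior on (mu, sigma^2), alpha_i ~ N(0, g_alpha
sigma^2) and beta ~ N(0, g_beta sigma^2) with unit-scale Inverse-chi^2
hyperpriors. Every full conditional is conjugate (normal or inverse gamma),
so the sampler is a plain deterministic-scan Gibbs sampler.

The scaled inverse chi-square with 1 degree of freedom and scale r^2 has
density proportional to g^(-3/2) exp(-r^2 / (2g)); equivalently
Inverse-Gamma(shape 1/2, rate r^2/2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.tsa.stattools import acf as _sm_acf

from .data_io import RatingDataset, DataValidationError

FITTABLE_MODELS = ("M0", "M1", "Mu")


@dataclass(frozen=True)
class PriorSettings:
    """Scales r^2 of the Inverse-chi^2(1, r^2) priors on the g parameters.

    The defaults r_nu = r_theta = 1/2 encode the expectation that the mean
    and spread of individual effects are about half the trial-by-trial
    noise sigma (with sigma near 0.5 on the [-1, 1] scale, an expected
    effect near 0.25). The alpha/beta scales are nuisance settings with
    unit default.
    """

    r_nu_sq: float = 0.25
    r_theta_sq: float = 0.25
    r_alpha_sq: float = 1.0
    r_beta_sq: float = 1.0

    def __post_init__(self):
        for name in ("r_nu_sq", "r_theta_sq", "r_alpha_sq", "r_beta_sq"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def sample_inverse_chisq(rng: np.random.Generator, r_sq: float, size=None) -> np.ndarray:
    """Draw from the scaled inverse chi-square with 1 df and scale r^2."""
    return r_sq / rng.chisquare(1, size=size)


def _inv_gamma(rng: np.random.Generator, shape: float, rate, size=None):
    return rate / rng.gamma(shape, 1.0, size=size)


@dataclass
class PosteriorSamples:
    """Retained MCMC draws from one model fit.

    Arrays have shape (n_retained,) for scalars and (n_retained, I) for
    per-subject parameters. ``theta`` always holds the individual effects
    (zeros under M0, the common nu under M1, nu + eta under Mu).
    """

    model: str
    mu: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    nu: np.ndarray
    eta: np.ndarray
    theta: np.ndarray
    sigma2: np.ndarray
    g_alpha: np.ndarray
    g_beta: np.ndarray
    g_nu: np.ndarray
    g_theta: np.ndarray
    n_iterations: int
    burn_in: int
    thinning: int
    seed: int
    priors: PriorSettings = field(default_factory=PriorSettings)

    @property
    def n_retained(self) -> int:
        return len(self.sigma2)

    @property
    def n_subjects(self) -> int:
        return self.theta.shape[1]

    @property
    def delta(self) -> np.ndarray:
        """Per-draw population SD of individual effects, sqrt(g_theta sigma^2)."""
        return np.sqrt(self.g_theta * self.sigma2)

    def to_frame(self):
        """Flat table of draws (one column per scalar) for external tools."""
        import pandas as pd

        cols = {
            "mu": self.mu,
            "beta": self.beta,
            "nu": self.nu,
            "sigma2": self.sigma2,
            "g_alpha": self.g_alpha,
            "g_beta": self.g_beta,
            "g_nu": self.g_nu,
            "g_theta": self.g_theta,
        }
        for i in range(self.n_subjects):
            cols[f"alpha_{i + 1}"] = self.alpha[:, i]
        for i in range(self.n_subjects):
            cols[f"theta_{i + 1}"] = self.theta[:, i]
        return pd.DataFrame(cols)


def _check_data(data: RatingDataset, model: str) -> None:
    if model not in FITTABLE_MODELS:
        raise ValueError(
            f"model must be one of {FITTABLE_MODELS} (Mplus is handled by the "
            "encompassing-prior method on an Mu fit)"
        )
    if data.n_trials == 0:
        return  # prior-sampling mode
    y = data.rating
    if not np.all(np.isfinite(y)):
        raise DataValidationError("non-finite rating values")
    x = data.repeated
    if x.sum() == 0 or x.sum() == len(x):
        raise DataValidationError("a repetition condition is entirely empty")
    s = data.subject_index0
    if s.min() < 0 or s.max() >= data.n_subjects:
        raise DataValidationError("subject indices are not contiguous 1..I")


def fit(
    data: RatingDataset,
    model: str = "Mu",
    priors: PriorSettings | None = None,
    n_iterations: int = 10_000,
    burn_in: int = 1_000,
    thinning: int = 1,
    seed: int = 0,
) -> PosteriorSamples:
    """Run the Gibbs sampler; returns ``n_iterations`` retained draws.

    The chain is seed-deterministic. With an empty dataset the sampler
    draws from the prior instead of the posterior, holding mu = 0 and
    sigma^2 = 1 fixed (their improper flat/Jeffreys conditionals are not
    samplable without data); this mode exists for prior-consistency checks.
    """
    if priors is None:
        priors = PriorSettings()
    if n_iterations <= 0 or burn_in < 0 or thinning < 1:
        raise ValueError("need n_iterations > 0, burn_in >= 0, thinning >= 1")
    _check_data(data, model)

    rng = np.random.default_rng(seed)
    I = data.n_subjects
    n = data.n_trials
    s = data.subject_index0
    x = data.repeated
    t = data.truth
    y = data.rating
    prior_only = n == 0

    n_i = np.bincount(s, minlength=I).astype(float) if n else np.zeros(I)
    m_i = np.bincount(s, weights=x, minlength=I) if n else np.zeros(I)
    T_true = float(t.sum()) if n else 0.0
    M_rep = float(x.sum()) if n else 0.0

    has_nu = model in ("M1", "Mu")
    has_eta = model == "Mu"
    # count of sigma^2-scaled coefficients entering the sigma^2 conditional
    p_scaled = I + 1 + (1 if has_nu else 0) + (I if has_eta else 0)

    # initial state
    mu = float(y.mean()) if n else 0.0
    alpha = np.zeros(I)
    beta = 0.0
    nu = 0.0
    eta = np.zeros(I)
    sigma2 = float(y.var()) + 1e-6 if n else 1.0
    g_alpha = float(sample_inverse_chisq(rng, priors.r_alpha_sq))
    g_beta = float(sample_inverse_chisq(rng, priors.r_beta_sq))
    g_nu = float(sample_inverse_chisq(rng, priors.r_nu_sq))
    g_theta = float(sample_inverse_chisq(rng, priors.r_theta_sq))

    resid = (
        y - (mu + alpha[s] + beta * t + (nu + eta[s]) * x) if n else np.zeros(0)
    )

    keep = n_iterations
    out = {
        "mu": np.empty(keep),
        "alpha": np.empty((keep, I)),
        "beta": np.empty(keep),
        "nu": np.empty(keep),
        "eta": np.empty((keep, I)),
        "sigma2": np.empty(keep),
        "g_alpha": np.empty(keep),
        "g_beta": np.empty(keep),
        "g_nu": np.empty(keep),
        "g_theta": np.empty(keep),
    }

    total = burn_in + n_iterations * thinning
    stored = 0
    for it in range(total):
        if n and not prior_only:
            # -- grand mean (flat prior)
            resid += mu
            mu = rng.normal(resid.mean(), np.sqrt(sigma2 / n))
            resid -= mu
        # -- person intercepts
        if I:
            if n:
                resid += alpha[s]
                S = np.bincount(s, weights=resid, minlength=I)
            else:
                S = np.zeros(I)
            prec = (n_i + 1.0 / g_alpha) / sigma2
            alpha = S / sigma2 / prec + rng.standard_normal(I) / np.sqrt(prec)
            if n:
                resid -= alpha[s]
        # -- factual-truth effect
        if n:
            resid += beta * t
            Sb = float(t @ resid)
        else:
            Sb = 0.0
        prec_b = (T_true + 1.0 / g_beta) / sigma2
        beta = Sb / sigma2 / prec_b + rng.standard_normal() / np.sqrt(prec_b)
        if n:
            resid -= beta * t
        # -- mean individual effect
        if has_nu:
            if n:
                resid += nu * x
                Sn = float(x @ resid)
            else:
                Sn = 0.0
            prec_n = (M_rep + 1.0 / g_nu) / sigma2
            nu = Sn / sigma2 / prec_n + rng.standard_normal() / np.sqrt(prec_n)
            if n:
                resid -= nu * x
        # -- individual deviations
        if has_eta and I:
            if n:
                resid += eta[s] * x
                Se = np.bincount(s, weights=resid * x, minlength=I)
            else:
                Se = np.zeros(I)
            prec_e = (m_i + 1.0 / g_theta) / sigma2
            eta = Se / sigma2 / prec_e + rng.standard_normal(I) / np.sqrt(prec_e)
            if n:
                resid -= eta[s] * x
        # -- trial noise (Jeffreys), includes the scaled-prior terms
        quad = float(alpha @ alpha) / g_alpha + beta**2 / g_beta
        if has_nu:
            quad += nu**2 / g_nu
        if has_eta:
            quad += float(eta @ eta) / g_theta
        if not prior_only:
            shape = (n + p_scaled) / 2.0
            rate = (float(resid @ resid) + quad) / 2.0
            sigma2 = float(_inv_gamma(rng, shape, rate))
        # -- signal-to-noise ratios
        g_alpha = float(
            _inv_gamma(rng, (1 + I) / 2.0, (priors.r_alpha_sq + float(alpha @ alpha) / sigma2) / 2.0)
        )
        g_beta = float(_inv_gamma(rng, 1.0, (priors.r_beta_sq + beta**2 / sigma2) / 2.0))
        if has_nu:
            g_nu = float(_inv_gamma(rng, 1.0, (priors.r_nu_sq + nu**2 / sigma2) / 2.0))
        if has_eta:
            g_theta = float(
                _inv_gamma(
                    rng, (1 + I) / 2.0, (priors.r_theta_sq + float(eta @ eta) / sigma2) / 2.0
                )
            )

        if it >= burn_in and (it - burn_in) % thinning == 0:
            out["mu"][stored] = mu
            out["alpha"][stored] = alpha
            out["beta"][stored] = beta
            out["nu"][stored] = nu
            out["eta"][stored] = eta
            out["sigma2"][stored] = sigma2
            out["g_alpha"][stored] = g_alpha
            out["g_beta"][stored] = g_beta
            out["g_nu"][stored] = g_nu
            out["g_theta"][stored] = g_theta
            stored += 1

    if model == "M0":
        theta = np.zeros((keep, I))
    elif model == "M1":
        theta = np.repeat(out["nu"][:, None], I, axis=1)
    else:
        theta = out["nu"][:, None] + out["eta"]

    return PosteriorSamples(
        model=model,
        mu=out["mu"],
        alpha=out["alpha"],
        beta=out["beta"],
        nu=out["nu"],
        eta=out["eta"],
        theta=theta,
        sigma2=out["sigma2"],
        g_alpha=out["g_alpha"],
        g_beta=out["g_beta"],
        g_nu=out["g_nu"],
        g_theta=out["g_theta"],
        n_iterations=n_iterations,
        burn_in=burn_in,
        thinning=thinning,
        seed=seed,
        priors=priors,
    )


def conditional_theta_moments(
    samples: PosteriorSamples, data: RatingDataset, iteration: int | None = None
):
    """Exact normal full-conditional moments of each theta_i per Gibbs state.

    Given the rest of a state (mu, alpha, beta, nu, g_theta, sigma^2), the
    theta_i are conditionally independent with

        precision = m_i / sigma^2 + 1 / (g_theta sigma^2)
        mean = (sum of repeated-trial residuals / sigma^2
                + nu / (g_theta sigma^2)) / precision

    where m_i counts subject i's repeated trials. A subject with no
    repeated trials gets the group prior Normal(nu, g_theta sigma^2).
    Returns (means, sds), each (n_retained, I), or (I,) for one iteration.
    """
    if samples.model != "Mu":
        raise ValueError("conditional moments of theta require an Mu fit")
    s = data.subject_index0
    x = data.repeated
    t = data.truth
    y = data.rating
    I = samples.n_subjects
    m_i = np.bincount(s, weights=x, minlength=I)
    sxy = np.bincount(s, weights=x * y, minlength=I)
    stx = np.bincount(s, weights=x * t, minlength=I)

    if iteration is None:
        mu = samples.mu[:, None]
        alpha = samples.alpha
        beta = samples.beta[:, None]
        nu = samples.nu[:, None]
        sig2 = samples.sigma2[:, None]
        g_t = samples.g_theta[:, None]
    else:
        mu = samples.mu[iteration]
        alpha = samples.alpha[iteration]
        beta = samples.beta[iteration]
        nu = samples.nu[iteration]
        sig2 = samples.sigma2[iteration]
        g_t = samples.g_theta[iteration]

    resid_sum = sxy - m_i * (mu + alpha) - beta * stx
    prec = (m_i + 1.0 / g_t) / sig2
    mean = (resid_sum / sig2 + nu / (g_t * sig2)) / prec
    sd = 1.0 / np.sqrt(prec)
    return mean, sd


def gibbs_conditionals(
    state: dict, data: RatingDataset, priors: PriorSettings, model: str = "Mu"
) -> dict:
    """Exact full-conditional distributions at one Gibbs state.

    ``state`` maps parameter names (mu, alpha, beta, nu, eta, sigma2,
    g_alpha, g_beta, g_nu, g_theta) to values. Returns, for each sampled
    block, the parameters of its conjugate full conditional evaluated at
    the given state: ``(mean, sd)`` for normal blocks and ``(shape, rate)``
    (inverse-gamma) for the variance blocks. Useful for verifying the
    sampler against direct evaluation of the joint density and for
    Rao-Blackwellized estimators.
    """
    s = data.subject_index0
    x = data.repeated
    t = data.truth
    y = data.rating
    n = len(y)
    I = data.n_subjects
    mu = state["mu"]
    alpha = np.asarray(state["alpha"], float)
    beta = state["beta"]
    nu = state.get("nu", 0.0)
    eta = np.asarray(state.get("eta", np.zeros(I)), float)
    sig2 = state["sigma2"]
    has_nu = model in ("M1", "Mu")
    has_eta = model == "Mu"
    if not has_nu:
        nu = 0.0
    if not has_eta:
        eta = np.zeros(I)

    fitted = mu + alpha[s] + beta * t + (nu + eta[s]) * x
    resid = y - fitted
    n_i = np.bincount(s, minlength=I).astype(float)
    m_i = np.bincount(s, weights=x, minlength=I)

    out = {}
    r = resid + mu
    out["mu"] = (float(r.mean()), float(np.sqrt(sig2 / n)))

    r = resid + alpha[s]
    S = np.bincount(s, weights=r, minlength=I)
    prec = (n_i + 1.0 / state["g_alpha"]) / sig2
    out["alpha"] = (S / sig2 / prec, 1.0 / np.sqrt(prec))

    r = resid + beta * t
    prec_b = (float(t.sum()) + 1.0 / state["g_beta"]) / sig2
    out["beta"] = (float(t @ r) / sig2 / prec_b, float(1.0 / np.sqrt(prec_b)))

    if has_nu:
        r = resid + nu * x
        prec_n = (float(x.sum()) + 1.0 / state["g_nu"]) / sig2
        out["nu"] = (float(x @ r) / sig2 / prec_n, float(1.0 / np.sqrt(prec_n)))

    if has_eta:
        r = resid + eta[s] * x
        Se = np.bincount(s, weights=r * x, minlength=I)
        prec_e = (m_i + 1.0 / state["g_theta"]) / sig2
        out["eta"] = (Se / sig2 / prec_e, 1.0 / np.sqrt(prec_e))

    quad = float(alpha @ alpha) / state["g_alpha"] + beta**2 / state["g_beta"]
    p_scaled = I + 1
    if has_nu:
        quad += nu**2 / state["g_nu"]
        p_scaled += 1
    if has_eta:
        quad += float(eta @ eta) / state["g_theta"]
        p_scaled += I
    out["sigma2"] = ((n + p_scaled) / 2.0, (float(resid @ resid) + quad) / 2.0)

    out["g_alpha"] = ((1 + I) / 2.0, (priors.r_alpha_sq + float(alpha @ alpha) / sig2) / 2.0)
    out["g_beta"] = (1.0, (priors.r_beta_sq + beta**2 / sig2) / 2.0)
    if has_nu:
        out["g_nu"] = (1.0, (priors.r_nu_sq + nu**2 / sig2) / 2.0)
    if has_eta:
        out["g_theta"] = ((1 + I) / 2.0, (priors.r_theta_sq + float(eta @ eta) / sig2) / 2.0)
    return out


def effective_sample_size(chain: np.ndarray) -> float | None:
    """ESS from the empirical ACF with Geyer initial-positive truncation."""
    chain = np.asarray(chain, float)
    n = len(chain)
    if n < 4 or np.ptp(chain) == 0:
        return None
    nlags = min(n - 2, 1000)
    rho = _sm_acf(chain, nlags=nlags, fft=True)[1:]
    # sum consecutive pairs while positive
    npairs = len(rho) // 2
    pair = rho[: 2 * npairs].reshape(npairs, 2).sum(axis=1)
    acc = 0.0
    for p in pair:
        if p <= 0:
            break
        acc += p
    return float(n / (1.0 + 2.0 * acc))


def diagnostics(
    samples: PosteriorSamples,
    parameters: list | None = None,
    n_lags: int = 20,
    theta_subset: tuple = (),
) -> dict:
    """Lag-1..n autocorrelations and ESS for the requested parameters.

    Defaults to the critical group-level parameters nu, g_nu, g_theta;
    ``theta_subset`` adds individual effects by 1-based subject index.
    Constant (degenerate) chains are flagged and their ESS reported None.
    """
    if samples.n_retained < 100:
        raise ValueError("diagnostics need at least 100 retained draws")
    if parameters is None:
        parameters = ["nu", "g_nu", "g_theta"]
    chains = {}
    for name in parameters:
        chains[name] = getattr(samples, name)
    for i in theta_subset:
        chains[f"theta_{i}"] = samples.theta[:, i - 1]

    report = {}
    for name, chain in chains.items():
        chain = np.asarray(chain, float)
        if np.ptp(chain) == 0:
            report[name] = {"acf": None, "ess": None, "degenerate": True}
            continue
        rho = _sm_acf(chain, nlags=n_lags, fft=True)[1:]
        report[name] = {
            "acf": rho,
            "ess": effective_sample_size(chain),
            "degenerate": False,
        }
    return report
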