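"""Independent oracles used by the test suite.

These deliberately avoid the closed-form linear-algebra route of the
package: the marginal-likelihood oracle Monte-Carlos the proper parameters
(the g ratios and the sigma-scaled effects) and integrates the improper
(mu, sigma^2) block numerically — mu by the elementary one-dimensional
Gaussian integral, sigma^2 by wide trapezoid quadrature on the log scale
where the Jeffreys weight is flat. The joint-density evaluator supports
brute-force checks of the Gibbs full conditionals.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm


def oracle_log_marginal(
    data,
    model: str,
    priors,
    n_draws: int,
    seed: int,
    sigma_lo: float = 0.02,
    sigma_hi: float = 8.0,
    n_sigma: int = 301,
) -> tuple[float, float]:
    """Naive Monte-Carlo estimate of log p(y) with its standard error."""
    rng = np.random.default_rng(seed)
    s, x, t, y = data.subject_index0, data.repeated, data.truth, data.rating
    I, n = data.n_subjects, len(y)

    cols = [(s == i).astype(float) for i in range(I)]
    g_names = ["g_alpha"] * I
    cols.append(t)
    g_names.append("g_beta")
    if model in ("M1", "Mu"):
        cols.append(x)
        g_names.append("g_nu")
    if model == "Mu":
        cols += [x * (s == i) for i in range(I)]
        g_names += ["g_theta"] * I
    X = np.column_stack(cols)

    r_sq = {
        "g_alpha": priors.r_alpha_sq,
        "g_beta": priors.r_beta_sq,
        "g_nu": priors.r_nu_sq,
        "g_theta": priors.r_theta_sq,
    }
    g_draws = {k: r_sq[k] / rng.chisquare(1, n_draws) for k in set(g_names)}
    G = np.stack([g_draws[k] for k in g_names], axis=1)
    U = rng.standard_normal((n_draws, X.shape[1])) * np.sqrt(G)  # sigma-scaled effects

    A = U @ X.T  # (draws, n): X u per draw
    SA = A.sum(axis=1)
    SAA = (A * A).sum(axis=1)
    SYA = A @ y
    Sy, Syy = y.sum(), y @ y

    sig = np.exp(np.linspace(np.log(sigma_lo), np.log(sigma_hi), n_sigma))
    log_grid = 2 * np.log(sig)
    weights = np.gradient(log_grid)  # flat Jeffreys weight in log sigma^2

    logw = np.empty((n_draws, n_sigma))
    for j, sg in enumerate(sig):
        # residual sum of squares minimized over mu (exact Gaussian integral)
        C = Syy - 2 * sg * SYA + sg * sg * SAA
        S = C - (Sy - sg * SA) ** 2 / n
        logw[:, j] = (
            -(n - 1) / 2 * np.log(2 * np.pi * sg * sg) - 0.5 * np.log(n) - S / (2 * sg * sg)
        )

    shift = logw.max()
    v = (np.exp(logw - shift) * weights[None, :]).sum(axis=1)  # per-draw integral
    est = v.mean()
    se = v.std(ddof=1) / np.sqrt(n_draws)
    return float(shift + np.log(est)), float(se / est)


def log_joint_density(state: dict, data, priors, model: str = "Mu") -> float:
    """Brute-force log joint density of data and all parameters at a state."""
    s, x, t, y = data.subject_index0, data.repeated, data.truth, data.rating
    alpha = np.asarray(state["alpha"], float)
    eta = np.asarray(state.get("eta", np.zeros(data.n_subjects)), float)
    nu = state.get("nu", 0.0)
    if model == "M0":
        nu = 0.0
    if model != "Mu":
        eta = np.zeros(data.n_subjects)
    sig2 = state["sigma2"]
    sig = np.sqrt(sig2)

    fitted = state["mu"] + alpha[s] + state["beta"] * t + (nu + eta[s]) * x
    lp = norm.logpdf(y, fitted, sig).sum()
    lp += norm.logpdf(alpha, 0, np.sqrt(state["g_alpha"] * sig2)).sum()
    lp += float(norm.logpdf(state["beta"], 0, np.sqrt(state["g_beta"] * sig2)))
    if model in ("M1", "Mu"):
        lp += float(norm.logpdf(nu, 0, np.sqrt(state["g_nu"] * sig2)))
    if model == "Mu":
        lp += norm.logpdf(eta, 0, np.sqrt(state["g_theta"] * sig2)).sum()
    lp += -np.log(sig2)  # Jeffreys
    pairs = [("g_alpha", priors.r_alpha_sq), ("g_beta", priors.r_beta_sq)]
    if model in ("M1", "Mu"):
        pairs.append(("g_nu", priors.r_nu_sq))
    if model == "Mu":
        pairs.append(("g_theta", priors.r_theta_sq))
    for name, r2 in pairs:
        g = state[name]
        lp += -1.5 * np.log(g) - r2 / (2 * g)  # scaled inverse chi-square, 1 df
    return float(lp)
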