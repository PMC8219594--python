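"""Bayes-factor comparison of the four individual-differences models.

Marginal likelihoods for M0 (no effect), M1 (common effect), and Mu
(unconstrained normal effects) are computed by analytically integrating all
location parameters and sigma^2 conditional on the signal-to-noise ratios
g, then averaging over prior draws of the low-dimensional g block by Monte
Carlo with log-sum-exp accumulation.

Conditional on g, the model is y ~ N(mu 1 + X b, sigma^2 I) with b ~
N(0, sigma^2 G), flat prior on mu and Jeffreys prior on sigma^2, giving

    log p(y | g) = -((n-1)/2) log(2 pi) - (1/2) log n - (1/2) log|G|
                   - (1/2) log|A| + lgamma((n-1)/2) - ((n-1)/2) log(S/2)

with A = Xc' Xc + G^-1 (Xc column-centered) and S = yc' yc - bc' A^-1 bc,
bc = Xc' yc. The per-subject columns make A block-diagonal (1x1 or 2x2
blocks) up to a rank-3 correction (the truth column, the repetition column,
and the centering), so |A| and the quadratic forms cost O(I) per g draw.

The positive-effects model M+ is handled by the encompassing-prior method:
BF(+, u) is the ratio of the posterior to the prior probability, under Mu,
that every theta_i is positive. Its marginal likelihood is then
log m(M+) = log m(Mu) + log BF(+, u).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, log_ndtr

from .data_io import RatingDataset
from .sampler import (
    PosteriorSamples,
    PriorSettings,
    conditional_theta_moments,
    fit,
    sample_inverse_chisq,
)

MODEL_IDS = ("M0", "M1", "Mplus", "Mu")


@dataclass
class MarginalLikelihood:
    model: str
    log_value: float
    mc_standard_error: float
    n_g_draws: int
    seed: int


@dataclass
class _DataStats:
    """Sufficient statistics for the marginal-likelihood computation."""

    n: int
    I: int
    yc_ss: float  # centered sum of squares of y
    n_i: np.ndarray
    m_i: np.ndarray  # repeated-trial counts
    tau_i: np.ndarray  # per-subject sum of t
    taux_i: np.ndarray  # per-subject sum of t*x
    sy_i: np.ndarray  # per-subject sum of centered y
    sxy_i: np.ndarray  # per-subject sum over repeated trials of centered y
    T: float  # total true statements
    M: float  # total repeated trials
    TX: float  # sum of t*x
    bt: float  # t' yc
    bx: float  # x' yc


def _data_stats(data: RatingDataset) -> _DataStats:
    s = data.subject_index0
    x = data.repeated
    t = data.truth
    y = data.rating
    I = data.n_subjects
    yc = y - y.mean()
    return _DataStats(
        n=len(y),
        I=I,
        yc_ss=float(yc @ yc),
        n_i=np.bincount(s, minlength=I).astype(float),
        m_i=np.bincount(s, weights=x, minlength=I),
        tau_i=np.bincount(s, weights=t, minlength=I),
        taux_i=np.bincount(s, weights=t * x, minlength=I),
        sy_i=np.bincount(s, weights=yc, minlength=I),
        sxy_i=np.bincount(s, weights=x * yc, minlength=I),
        T=float(t.sum()),
        M=float(x.sum()),
        TX=float((t * x).sum()),
        bt=float(t @ yc),
        bx=float(x @ yc),
    )


def _log_marginal_given_g_q1(st: _DataStats, model: str, g: dict) -> np.ndarray:
    """Models whose per-subject block is the intercept alone (M0, M1)."""
    ga = g["g_alpha"][:, None]  # (D, 1)
    w = 1.0 / (st.n_i[None, :] + 1.0 / ga)  # (D, I) inverse diagonal blocks

    n = st.n
    vecs = {"b": st.sy_i, "c": st.n_i / n, "ft": st.tau_i}
    f_cols = ["ft"]
    P_ff = [[st.T]]
    b_f = [st.bt]
    c_f = [st.T / n]
    g_diag = [g["g_beta"]]
    log_G = st.I * np.log(g["g_alpha"]) + np.log(g["g_beta"])
    if model == "M1":
        vecs["fx"] = st.m_i
        f_cols.append("fx")
        P_ff = [[st.T, st.TX], [st.TX, st.M]]
        b_f = [st.bt, st.bx]
        c_f = [st.T / n, st.M / n]
        g_diag = [g["g_beta"], g["g_nu"]]
        log_G = log_G + np.log(g["g_nu"])

    def S(u, v):  # u' Pzz^-1 v summed over subjects, per draw
        return (w * (vecs[u] * vecs[v])[None, :]).sum(axis=1)

    D = len(g["g_alpha"])
    f = len(f_cols)
    Sf = np.empty((D, f, f))
    for a in range(f):
        for b in range(f):
            Sf[:, a, b] = P_ff[a][b] - S(f_cols[a], f_cols[b])
        Sf[:, a, a] += 1.0 / g_diag[a]
    bt_f = np.stack([b_f[a] - S(f_cols[a], "b") for a in range(f)], axis=1)
    ct_f = np.stack([c_f[a] - S(f_cols[a], "c") for a in range(f)], axis=1)

    logdet_blocks = -np.log(w).sum(axis=1)
    return _assemble(st, log_G, logdet_blocks, Sf, S("b", "b"), S("b", "c"), S("c", "c"), bt_f, ct_f)


def _log_marginal_given_g_q2(st: _DataStats, g: dict) -> np.ndarray:
    """The unconstrained model: 2x2 per-subject blocks (alpha_i, eta_i)."""
    a = (1.0 / g["g_alpha"])[:, None]  # (D, 1)
    e = (1.0 / g["g_theta"])[:, None]
    n_i = st.n_i[None, :]
    m_i = st.m_i[None, :]
    det = (n_i + a) * (m_i + e) - st.m_i[None, :] ** 2  # (D, I)
    invdet = 1.0 / det

    n = st.n
    # per-subject 2-vectors (components on the alpha and eta coordinates)
    vecs = {
        "b": (st.sy_i, st.sxy_i),
        "c": (st.n_i / n, st.m_i / n),
        "ft": (st.tau_i, st.taux_i),
        "fx": (st.m_i, st.m_i),
    }

    def S(u, v):
        u1, u2 = vecs[u]
        v1, v2 = vecs[v]
        k11 = u1 * v1  # multiplies (m_i + e)
        kx = u1 * v2 + u2 * v1  # multiplies -m_i
        k22 = u2 * v2  # multiplies (n_i + a)
        num = (k11 * st.m_i - kx * st.m_i + k22 * st.n_i)[None, :] + e * k11[None, :] + a * k22[None, :]
        return (num * invdet).sum(axis=1)

    f_cols = ["ft", "fx"]
    P_ff = [[st.T, st.TX], [st.TX, st.M]]
    b_f = [st.bt, st.bx]
    c_f = [st.T / n, st.M / n]
    g_diag = [g["g_beta"], g["g_nu"]]

    D = len(g["g_alpha"])
    Sf = np.empty((D, 2, 2))
    for i in range(2):
        for j in range(2):
            Sf[:, i, j] = P_ff[i][j] - S(f_cols[i], f_cols[j])
        Sf[:, i, i] += 1.0 / g_diag[i]
    bt_f = np.stack([b_f[i] - S(f_cols[i], "b") for i in range(2)], axis=1)
    ct_f = np.stack([c_f[i] - S(f_cols[i], "c") for i in range(2)], axis=1)

    log_G = (
        st.I * (np.log(g["g_alpha"]) + np.log(g["g_theta"]))
        + np.log(g["g_beta"])
        + np.log(g["g_nu"])
    )
    logdet_blocks = np.log(det).sum(axis=1)
    return _assemble(st, log_G, logdet_blocks, Sf, S("b", "b"), S("b", "c"), S("c", "c"), bt_f, ct_f)


def _assemble(st, log_G, logdet_blocks, Sf, Sbb, Sbc, Scc, bt_f, ct_f):
    """Combine the Schur pieces and the rank-1 centering downdate."""
    f = Sf.shape[1]
    if f == 1:
        det_Sf = Sf[:, 0, 0]
        inv = (1.0 / det_Sf)[:, None, None]
        Sf_inv = inv
    else:
        det_Sf = Sf[:, 0, 0] * Sf[:, 1, 1] - Sf[:, 0, 1] * Sf[:, 1, 0]
        Sf_inv = np.empty_like(Sf)
        Sf_inv[:, 0, 0] = Sf[:, 1, 1]
        Sf_inv[:, 1, 1] = Sf[:, 0, 0]
        Sf_inv[:, 0, 1] = -Sf[:, 0, 1]
        Sf_inv[:, 1, 0] = -Sf[:, 1, 0]
        Sf_inv /= det_Sf[:, None, None]

    def quad(u_f, v_f):
        return np.einsum("di,dij,dj->d", u_f, Sf_inv, v_f)

    bPb = Sbb + quad(bt_f, bt_f)
    bPc = Sbc + quad(bt_f, ct_f)
    cPc = Scc + quad(ct_f, ct_f)

    n = st.n
    denom = 1.0 - n * cPc
    # A = P - n c c'; valid draws have denom > 0 (A positive definite)
    with np.errstate(divide="ignore", invalid="ignore"):
        bAb = bPb + n * bPc**2 / denom
        log_det_A = logdet_blocks + np.log(det_Sf) + np.log(denom)
        S_resid = st.yc_ss - bAb
        out = (
            -0.5 * (n - 1) * np.log(2 * np.pi)
            - 0.5 * np.log(n)
            - 0.5 * log_G
            - 0.5 * log_det_A
            + gammaln((n - 1) / 2.0)
            - 0.5 * (n - 1) * np.log(S_resid / 2.0)
        )
    bad = ~np.isfinite(out) | (denom <= 0) | (S_resid <= 0)
    out[bad] = -np.inf
    return out


def log_marginal(
    data: RatingDataset,
    model: str,
    priors: PriorSettings | None = None,
    n_g_draws: int = 100_000,
    seed: int = 0,
    chunk: int = 8192,
) -> MarginalLikelihood:
    """Monte-Carlo marginal likelihood over prior draws of the g parameters.

    Seed-deterministic; the Monte-Carlo standard error of the log marginal
    is reported alongside (delta-method on the mean of the per-draw
    conditional marginals).
    """
    if model not in ("M0", "M1", "Mu"):
        raise ValueError(
            "log_marginal supports M0, M1, Mu; Mplus is derived via encompassing_bf"
        )
    if priors is None:
        priors = PriorSettings()
    st = _data_stats(data)
    p_cols = st.I + 1 + (1 if model != "M0" else 0) + (st.I if model == "Mu" else 0)
    if st.n - 1 - p_cols < 1:
        raise ValueError(
            f"no residual degrees of freedom: n={st.n} rows for {p_cols} effect columns"
        )
    if st.yc_ss <= 0:
        raise ValueError("ratings are constant; the marginal likelihood is degenerate")

    rng = np.random.default_rng(seed)
    logp = np.empty(n_g_draws)
    done = 0
    while done < n_g_draws:
        d = min(chunk, n_g_draws - done)
        g = {
            "g_alpha": sample_inverse_chisq(rng, priors.r_alpha_sq, d),
            "g_beta": sample_inverse_chisq(rng, priors.r_beta_sq, d),
        }
        if model != "M0":
            g["g_nu"] = sample_inverse_chisq(rng, priors.r_nu_sq, d)
        if model == "Mu":
            g["g_theta"] = sample_inverse_chisq(rng, priors.r_theta_sq, d)
            logp[done : done + d] = _log_marginal_given_g_q2(st, g)
        else:
            logp[done : done + d] = _log_marginal_given_g_q1(st, model, g)
        done += d

    shift = logp.max()
    w = np.exp(logp - shift)
    mean_w = w.mean()
    log_value = shift + np.log(mean_w)
    se_log = w.std(ddof=1) / np.sqrt(n_g_draws) / mean_w
    return MarginalLikelihood(
        model=model,
        log_value=float(log_value),
        mc_standard_error=float(se_log),
        n_g_draws=n_g_draws,
        seed=seed,
    )


@dataclass
class EncompassingBF:
    """BF(+, u): evidence for all-positive effects relative to Mu."""

    log_bf: float
    mc_error: float
    posterior_prob: float
    posterior_se: float
    prior_prob: float
    prior_se: float
    method: str
    n_prior_draws: int
    seed: int


def prior_all_positive_probability(
    n_subjects: int,
    priors: PriorSettings | None = None,
    n_draws: int = 100_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Prior P(all theta_i > 0) under Mu, by Monte Carlo over (nu, g) draws.

    With nu ~ N(0, g_nu sigma^2) and delta = sqrt(g_theta) sigma, the ratio
    nu/delta = z sqrt(g_nu / g_theta) for standard-normal z, so the
    probability is free of sigma. For a single subject it is exactly 1/2 by
    symmetry.
    """
    if priors is None:
        priors = PriorSettings()
    rng = np.random.default_rng(seed)
    g_nu = sample_inverse_chisq(rng, priors.r_nu_sq, n_draws)
    g_theta = sample_inverse_chisq(rng, priors.r_theta_sq, n_draws)
    z = rng.standard_normal(n_draws)
    p = np.exp(n_subjects * log_ndtr(z * np.sqrt(g_nu / g_theta)))
    return float(p.mean()), float(p.std(ddof=1) / np.sqrt(n_draws))


def encompassing_bf(
    posterior: PosteriorSamples,
    priors: PriorSettings | None = None,
    data: RatingDataset | None = None,
    method: str = "rao_blackwell",
    n_prior_draws: int = 100_000,
    seed: int = 0,
) -> EncompassingBF:
    """Encompassing-prior Bayes factor BF(+, u) from an Mu fit.

    BF(+, u) = P(min_i theta_i > 0 | data, Mu) / P(min_i theta_i > 0 | Mu).
    ``method="count"`` estimates the posterior probability as the fraction
    of retained draws with every theta_i positive; ``"rao_blackwell"``
    averages prod_i Phi(m_i / s_i) over draws using the exact normal full
    conditionals of the theta_i (requires ``data``), which remains informative
    when the count is exactly zero.
    """
    if posterior.model != "Mu":
        raise ValueError("encompassing_bf needs a posterior fitted under Mu")
    if priors is None:
        priors = posterior.priors
    n_draws = posterior.n_retained

    if method == "count":
        hits = np.all(posterior.theta > 0, axis=1)
        post_p = float(hits.mean())
        post_se = float(np.sqrt(max(post_p * (1 - post_p), 0.0) / n_draws))
    elif method == "rao_blackwell":
        if data is None:
            raise ValueError("rao_blackwell method requires the fitted dataset")
        means, sds = conditional_theta_moments(posterior, data)
        log_pd = log_ndtr(means / sds).sum(axis=1)
        pd_draws = np.exp(log_pd)
        post_p = float(pd_draws.mean())
        post_se = float(pd_draws.std(ddof=1) / np.sqrt(n_draws))
    else:
        raise ValueError("method must be 'count' or 'rao_blackwell'")

    prior_p, prior_se = prior_all_positive_probability(
        posterior.n_subjects, priors, n_draws=n_prior_draws, seed=seed
    )

    if post_p == 0.0:
        warnings.warn(
            "no retained draw satisfies the all-positive constraint; "
            "BF(+,u) is -inf on the log scale — use method='rao_blackwell'",
            RuntimeWarning,
        )
        return EncompassingBF(
            -np.inf, np.nan, post_p, post_se, prior_p, prior_se, method, n_prior_draws, seed
        )
    log_bf = float(np.log(post_p) - np.log(prior_p))
    mc_error = float(np.sqrt((post_se / post_p) ** 2 + (prior_se / prior_p) ** 2))
    return EncompassingBF(
        log_bf, mc_error, post_p, post_se, prior_p, prior_se, method, n_prior_draws, seed
    )


@dataclass
class BayesFactorTable:
    """Log marginals for all four models and the pairwise Bayes factors.

    Pairwise factors are assembled from the log marginals, so transitivity
    log BF(A, C) = log BF(A, B) + log BF(B, C) holds exactly.
    """

    log_marginals: dict
    mc_errors: dict
    log_bf_plus_u: float
    preferred: str
    ambiguous: bool
    encompassing: EncompassingBF = None
    seed: int = 0

    def log_bf(self, model_a: str, model_b: str) -> float:
        return self.log_marginals[model_a] - self.log_marginals[model_b]

    def bf_against_preferred(self) -> dict:
        return {
            m: float(np.exp(self.log_bf(m, self.preferred))) for m in self.log_marginals
        }

    def to_frame(self) -> pd.DataFrame:
        """Comparison table: each model's BF against the preferred model."""
        rows = []
        for m in MODEL_IDS:
            if m not in self.log_marginals:
                continue
            rows.append(
                {
                    "model": m,
                    "log_marginal": self.log_marginals[m],
                    "mc_error": self.mc_errors[m],
                    "log10_bf_vs_preferred": self.log_bf(m, self.preferred) / np.log(10),
                    "bf_vs_preferred": np.exp(self.log_bf(m, self.preferred)),
                    "preferred": m == self.preferred,
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "log_marginals": {k: float(v) for k, v in self.log_marginals.items()},
            "mc_errors": {k: float(v) for k, v in self.mc_errors.items()},
            "log10_bf_vs_preferred": {
                m: float(self.log_bf(m, self.preferred) / np.log(10))
                for m in self.log_marginals
            },
            "log_bf_plus_u": float(self.log_bf_plus_u),
            "preferred": self.preferred,
            "ambiguous": bool(self.ambiguous),
            "seed": int(self.seed),
        }


def compare(
    data: RatingDataset,
    priors: PriorSettings | None = None,
    n_iterations: int = 10_000,
    burn_in: int = 1_000,
    n_g_draws: int = 100_000,
    n_prior_draws: int = 100_000,
    method: str = "rao_blackwell",
    seed: int = 0,
    posterior: PosteriorSamples | None = None,
) -> BayesFactorTable:
    """Full four-model Bayes-factor comparison on one dataset.

    Computes Monte-Carlo marginals for M0/M1/Mu, fits Mu by Gibbs sampling
    (or reuses ``posterior``), derives the positive-effects marginal via the
    encompassing-prior factor, and identifies the preferred model (largest
    log marginal; flagged ambiguous when the runner-up is within two joint
    Monte-Carlo standard errors).
    """
    if priors is None:
        priors = PriorSettings()
    children = np.random.SeedSequence(seed).spawn(5)
    sub_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in children]

    log_m, errs = {}, {}
    for model, s_i in zip(("M0", "M1", "Mu"), sub_seeds[:3]):
        ml = log_marginal(data, model, priors, n_g_draws=n_g_draws, seed=s_i)
        log_m[model] = ml.log_value
        errs[model] = ml.mc_standard_error

    if posterior is None:
        posterior = fit(
            data,
            "Mu",
            priors,
            n_iterations=n_iterations,
            burn_in=burn_in,
            seed=sub_seeds[3],
        )
    enc = encompassing_bf(
        posterior, priors, data=data, method=method, n_prior_draws=n_prior_draws, seed=sub_seeds[4]
    )
    log_m["Mplus"] = log_m["Mu"] + enc.log_bf
    errs["Mplus"] = float(np.sqrt(errs["Mu"] ** 2 + (enc.mc_error if np.isfinite(enc.mc_error) else 0.0) ** 2))

    order = sorted(log_m, key=log_m.get, reverse=True)
    preferred, runner_up = order[0], order[1]
    joint_se = np.sqrt(errs[preferred] ** 2 + errs[runner_up] ** 2)
    ambiguous = (log_m[preferred] - log_m[runner_up]) <= 2 * joint_se

    return BayesFactorTable(
        log_marginals=log_m,
        mc_errors=errs,
        log_bf_plus_u=enc.log_bf,
        preferred=preferred,
        ambiguous=ambiguous,
        encompassing=enc,
        seed=seed,
    )


#: Table-style labels for the 3x3 sensitivity grid; the starred default is
#: (r_nu, r_theta) = (1/2, 1/2).
GRID_LABELS = {
    (0.25, 0.25): "A",
    (0.25, 0.5): "B",
    (0.25, 1.0): "C",
    (0.5, 0.25): "D",
    (0.5, 1.0): "E",
    (1.0, 0.25): "F",
    (1.0, 0.5): "G",
    (1.0, 1.0): "H",
    (0.5, 0.5): "*",
}


def sensitivity_grid(
    data: RatingDataset,
    r_nu_values=(0.25, 0.5, 1.0),
    r_theta_values=(0.25, 0.5, 1.0),
    base_priors: PriorSettings | None = None,
    **compare_kwargs,
) -> pd.DataFrame:
    """Rerun the model comparison over a factorial grid of prior scales.

    ``r_nu_values`` / ``r_theta_values`` are the scales r (not r^2); the
    default 3x3 grid yields exactly nine settings. The output reports, per
    setting, each model's log10 Bayes factor against the model preferred
    under the default setting, mirroring a prior-sensitivity figure.
    """
    if base_priors is None:
        base_priors = PriorSettings()

    def dedup(vals, name):
        out = []
        for v in vals:
            if v in out:
                warnings.warn(f"duplicate {name} value {v} dropped", UserWarning)
            else:
                out.append(v)
        return out

    r_nus = dedup(list(r_nu_values), "r_nu")
    r_thetas = dedup(list(r_theta_values), "r_theta")

    results = {}
    for r_nu in r_nus:
        for r_theta in r_thetas:
            priors = PriorSettings(
                r_nu_sq=r_nu**2,
                r_theta_sq=r_theta**2,
                r_alpha_sq=base_priors.r_alpha_sq,
                r_beta_sq=base_priors.r_beta_sq,
            )
            results[(r_nu, r_theta)] = compare(data, priors, **compare_kwargs)

    default_key = (0.5, 0.5)
    ref_table = results.get(default_key, next(iter(results.values())))
    reference_model = ref_table.preferred

    rows = []
    for (r_nu, r_theta), table in results.items():
        row = {
            "label": GRID_LABELS.get((r_nu, r_theta), f"r{r_nu}x{r_theta}"),
            "r_nu": r_nu,
            "r_theta": r_theta,
            "preferred": table.preferred,
            "ambiguous": table.ambiguous,
            "reference_model": reference_model,
        }
        for m in MODEL_IDS:
            row[f"log10_bf_{m}_vs_ref"] = table.log_bf(m, reference_model) / np.log(10)
        rows.append(row)
    return pd.DataFrame(rows)
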