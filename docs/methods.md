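# Methods notes

This note records the model, the priors, the estimators, and the numerical
and design choices behind them — the things a maintainer or reviewer would
want to know that the API reference does not say.

## Model and assumptions

Trial-level truth judgments are treated as conditionally normal,

    Y_ijk ~ Normal(mu + alpha_i + t_j beta + x_k theta_i, sigma^2),

with person intercepts alpha_i, a factual-truth effect beta, and individual
repetition effects theta_i. The likelihood is continuous and unbounded even
though real ratings are bounded Likert responses; this is the standard
linear-model idealization for this design. There is no statement random
effect: under the model, statements only enter through their truth status,
so a design in which every participant sees fresh statements is
statistically equivalent to a crossed unbalanced design. Designs may be
unbalanced in general — participants can rate different numbers of
statements — and the likelihood handles this natively.

Four structures on theta_i encode the competing positions: M0 (theta_i = 0),
M1 (theta_i = nu), M+ (truncated normal, all positive: quantitative
differences only) and Mu (Normal(nu, delta^2): qualitative differences
allowed). Evidence between them is quantified by Bayes factors, not by
inspecting individual estimates: whether *someone* is negative is a global
property of the population distribution and is badly resolved by local
per-person inference.

## Priors

Effect parameters are scaled to the trial noise via signal-to-noise ratios
(g-priors): theta_i ~ N(nu, g_theta sigma^2), nu ~ N(0, g_nu sigma^2), with

    g_nu ~ Inverse-chi^2(1, r_nu^2),   g_theta ~ Inverse-chi^2(1, r_theta^2).

Parameterization (a notorious ambiguity, fixed here once): the scaled
inverse chi-square with 1 degree of freedom and scale r^2 has density
proportional to g^(-3/2) exp(-r^2/(2g)), i.e. Inverse-Gamma(1/2, r^2/2);
unit tests pin this via the closed-form mean of 1/g and a KS test.

Default scales: r_nu = r_theta = 1/2. Rationale: trial-to-trial variability
of truth ratings on the [-1, 1] scale is about sigma = 0.50, and the
meta-analytic effect size d = 0.50 then corresponds to an expected observed
effect of d*sigma = 0.25 — about half of sigma — so the prior mass for both
the mean and the spread of individual effects is centered on "half the
trial noise". `expected_effect_from_d` documents this arithmetic.

Nuisance blocks use the companion default specification: an improper
Jeffreys prior p(mu, sigma^2) ∝ 1/sigma^2, alpha_i ~ N(0, g_alpha sigma^2)
and beta ~ N(0, g_beta sigma^2) with Inverse-chi^2(1, 1) hyperpriors. These
are this package's own documented choices for the nuisance structure; they
are deliberately vague relative to the data and the comparison statistics
are insensitive to them. Identifiability of mu versus the alpha_i is
resolved by the zero-centered shrinkage prior (no sum-to-zero constraint);
the posterior of mu + alpha_i is invariant to this convention.

## Gibbs sampler

Mu is parameterized as theta_i = nu + eta_i, eta_i ~ N(0, g_theta sigma^2),
so M1 (eta = 0) and Mu share the nu block and the encompassing construction
is explicit. Every full conditional is conjugate (normal for location
blocks, inverse gamma for sigma^2 and the g's); the sampler is a
deterministic-scan Gibbs sampler with a per-iteration cost linear in the
number of trials. Defaults: 10,000 retained draws after 1,000 burn-in, no
thinning, seed-deterministic throughout. On these models the chains mix
well; lag-1 autocorrelations of the group-level parameters are small, and
`diagnostics` reports ACF (via statsmodels) and an effective sample size
using Geyer's initial-positive-sequence truncation.

`gibbs_conditionals` exposes the exact full-conditional parameters at an
arbitrary state; the test suite verifies every block against brute-force
evaluation of the joint density on a small instance (agreement to 1e-6 and
better). Degenerate inputs are rejected before sampling (non-finite
ratings, a globally empty repetition condition); a subject lacking one
condition still contributes through the remaining blocks, and their theta_i
conditional collapses to the group prior.

Edge convention: fitting an *empty* dataset draws from the prior rather
than the posterior, holding mu = 0 and sigma^2 = 1 fixed — the flat and
Jeffreys conditionals are not samplable without data. This mode exists so
a Geweke-style check can compare the chain's prior marginals against
direct draws, and it is what the empty-likelihood tests exercise.

## Marginal likelihoods and Bayes factors

Conditional on the g's, all location parameters and sigma^2 integrate
analytically (multivariate normal with the Jeffreys scale prior), leaving a
2–4 dimensional integral over the g's that is estimated by plain Monte
Carlo over prior draws with log-sum-exp accumulation (default 100,000
draws; the delta-method standard error of the log marginal is always
reported). The per-draw evaluation exploits the design structure: the
Gram matrix is block-diagonal per subject (1x1 or 2x2 blocks) up to a
rank-3 correction from the truth column, the repetition column, and the
grand-mean centering, so each draw costs O(I) rather than O((2I)^3). The
estimator is validated on a small fixed instance against a naive
Monte-Carlo oracle that integrates sigma^2 by quadrature and everything
else by prior sampling, written independently of the closed form.

Because the g-priors scale everything to sigma, all Bayes factors are
invariant under a common rescaling of the ratings (tested). Transitivity of
the assembled pairwise factors holds exactly by construction.

M+ is never sampled directly: BF(+, u) is the encompassing-prior ratio
P(all theta_i > 0 | data, Mu) / P(all theta_i > 0 | Mu). The posterior
probability is estimated either by counting qualifying draws or by
Rao-Blackwellization — averaging prod_i Phi(m_i/s_i) over the exact
conditional moments — and the prior probability by Monte Carlo over
(nu, g) draws, where nu/delta = z sqrt(g_nu/g_theta) is free of sigma, so
no data-dependent quantity enters the prior term. The Rao-Blackwellized
estimator is the default: at realistic sample sizes the count of
all-positive draws is frequently exactly zero, and the count estimator then
degenerates to -inf (it is kept as a cross-check; the two agree within
Monte-Carlo error on smaller problems). Consequences of the construction —
BF(+,u) <= 1/priorP, and priorP = 1/2 exactly for a single subject — are
asserted in tests.

"Preferred model" means largest log marginal; when the runner-up is within
two joint Monte-Carlo standard errors the verdict is flagged ambiguous
rather than resolved.

The prior-sensitivity grid reruns the full comparison over the factorial
{1/4, 1/2, 1} x {1/4, 1/2, 1} of (r_nu, r_theta) — nine settings, labeled
A–H plus the starred default — and reports every model's Bayes factor
against the model preferred under the default setting.

## Classification and prevalence

P(theta_i > 0 | data) is estimated by the fraction of retained draws with
theta_i > 0 (exactly what the posterior-probability figures plot; a
Rao-Blackwellized variant is available). Labels use odds thresholds:
3-to-1 (p >= .75 positive, p <= .25 negative, else undecided) by default,
with 10-to-1 and 2-to-1 as standard alternatives. Classification is local
and noisy by design — the tests assert the documented divergence: on data
generated with a single common positive effect, the Bayes factors can
firmly prefer M1 while classification still leaves individuals undecided.

Prevalence of negative truthers is the posterior of Phi(-nu/delta)
computed per retained draw with that draw's own delta = sqrt(g_theta
sigma^2) — full posterior uncertainty propagates, no plug-in sigma. The
estimate is prior-sensitive when the data lack resolution (the
Inverse-chi^2 prior has no mass near zero, so delta cannot shrink
arbitrarily); the recommended response is the sensitivity rerun, not an ad
hoc change of the prior family.

## Synthetic data

The generator emulates the published study designs: 30–400 participants,
20–120 statements each (half repeated, half new, each independently true
with probability 1/2), trial noise sigma ~ 0.5 on the rescaled scale,
person intercept SD ~ 0.2, and individual effects with mean and SD in the
0.05–0.35 range; the default preset is I = 100, 40 statements, mu = 0,
subject SD 0.2, beta = 0.2, sigma = 0.5, nu = delta = 0.15 (≈16% negative
truthers). Statements are nested within subjects by default (equivalent
under the model); a shared-pool option gives crossed, unbalanced exposure.
Uniform missingness is available, and rows with missing ratings are
dropped at ingest with a logged count — the models handle unbalanced data
natively, so no imputation is attempted.

Generated ratings are *not* clipped to [-1, 1]: the fitted model is an
unbounded normal, and clipping would silently misspecify the
data-generating process relative to it. An optional `discretize_to_k`
snaps ratings to a K-point grid to emulate real Likert responses —
deliberate misspecification for robustness checks. What passing tests on
generator output therefore show is that the estimators are correct *under
the model*; they do not certify behavior under ordinal, bounded, or
sequence-dependent response processes found in real data.

## Problem sizes in the test suite

The recovery and consistency harnesses use the generator's study-scale
presets: parameter recovery at I = 100 with 40 trials and 10,000 retained
draws over ten seeds; model selection at I = 80/100/150 with Bayes-factor
wins required in at least 8 of 10 seeds; prevalence recovery at I = 150.
Marginal-likelihood draws in the harnesses (20,000–30,000) are chosen so
the Monte-Carlo error is far below the factor-of-10 decision margin;
oracle comparisons use 400,000 draws on an 8-observation fixture. These
sizes make the full suite run in a couple of minutes on one core.

## Known limitations

- Continuous-normal likelihood for ordinal ratings; no cumulative-link
  variant.
- No statement random effects and no latent-class ("cleaving") mixture
  model for classification — the latter is a natural extension but out of
  scope here.
- The prior-draw Monte-Carlo marginal estimator is simple and honest about
  its error, but importance-sampling refinements would reduce variance on
  very large data sets; the interface allows swapping estimators.
- Monte-Carlo standard errors for the posterior probability in BF(+,u)
  treat retained draws as independent; with well-mixing chains the
  understatement is mild, and the count/RB cross-check guards against it.
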