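import numpy as np
import pandas as pd
import pytest
from scipy import stats

import truthfx as tx
from conftest import make_dummy_samples
from oracles import log_joint_density


class TestInverseChiSquare:
    def test_matches_inverse_gamma_closed_form(self):
        """Inverse-chi^2(1, r^2) is Inverse-Gamma(1/2, r^2/2); 1/g ~ chi2_1/r^2."""
        rng = np.random.default_rng(5)
        r_sq = 0.25
        g = tx.sample_inverse_chisq(rng, r_sq, 200_000)
        assert (1 / g).mean() == pytest.approx(1 / r_sq, rel=0.02)
        ks = stats.kstest(g, stats.invgamma(0.5, scale=r_sq / 2).cdf)
        assert ks.pvalue > 0.01


class TestFullConditionals:
    """Each Gibbs update's density must match brute-force evaluation of the
    joint at test points (grid-oracle check on a single-subject toy)."""

    @pytest.fixture()
    def state(self):
        return {
            "mu": 0.1,
            "alpha": np.array([0.15]),
            "beta": -0.2,
            "nu": 0.3,
            "eta": np.array([-0.05]),
            "sigma2": 0.3,
            "g_alpha": 0.5,
            "g_beta": 0.8,
            "g_nu": 0.2,
            "g_theta": 0.4,
        }

    @pytest.mark.parametrize("model", ["Mu", "M1", "M0"])
    def test_normal_blocks_match_joint_density(self, one_subject_data, state, model):
        priors = tx.PriorSettings()
        cond = tx.gibbs_conditionals(state, one_subject_data, priors, model)
        blocks = ["mu", "beta", "alpha"]
        if model in ("M1", "Mu"):
            blocks.append("nu")
        if model == "Mu":
            blocks.append("eta")
        for name in blocks:
            m, sd = cond[name]
            m, sd = np.atleast_1d(m)[0], np.atleast_1d(sd)[0]
            offsets = []
            for v in m + sd * np.linspace(-2, 2, 10):
                st2 = {
                    k: (np.array(val, copy=True) if isinstance(val, np.ndarray) else val)
                    for k, val in state.items()
                }
                if name in ("alpha", "eta"):
                    st2[name][0] = v
                else:
                    st2[name] = v
                delta = log_joint_density(st2, one_subject_data, priors, model)
                delta -= stats.norm.logpdf(v, m, sd)
                offsets.append(delta)
            # log joint minus log conditional must be constant in v
            assert np.ptp(offsets) < 1e-6

    def test_variance_blocks_match_joint_density(self, one_subject_data, state):
        priors = tx.PriorSettings()
        cond = tx.gibbs_conditionals(state, one_subject_data, priors, "Mu")
        for name in ("sigma2", "g_alpha", "g_beta", "g_nu", "g_theta"):
            shape, rate = cond[name]
            offsets = []
            for v in rate / (shape + 1) * np.linspace(0.5, 3, 10):
                st2 = dict(state)
                st2[name] = v
                delta = log_joint_density(st2, one_subject_data, priors, "Mu")
                delta -= stats.invgamma.logpdf(v, shape, scale=rate)
                offsets.append(delta)
            assert np.ptp(offsets) < 1e-6


class TestFit:
    def test_seed_determinism(self, mu_data_small):
        data, _ = mu_data_small
        s1 = tx.fit(data, "Mu", n_iterations=200, burn_in=50, seed=9)
        s2 = tx.fit(data, "Mu", n_iterations=200, burn_in=50, seed=9)
        np.testing.assert_array_equal(s1.theta, s2.theta)
        np.testing.assert_array_equal(s1.sigma2, s2.sigma2)

    def test_reduced_models_constrain_theta(self, mu_data_small):
        data, _ = mu_data_small
        s0 = tx.fit(data, "M0", n_iterations=150, burn_in=20, seed=1)
        assert (s0.theta == 0).all()
        s1 = tx.fit(data, "M1", n_iterations=150, burn_in=20, seed=1)
        assert np.ptp(s1.theta, axis=1) == pytest.approx(0.0, abs=1e-15)

    def test_noise_free_common_effect_concentrates(self):
        cfg = tx.GeneratorConfig(
            model="M1",
            n_subjects=20,
            n_statements_per_subject=20,
            effect_mean=0.25,
            subject_sd=0.1,
            trial_sd=1e-4,
            seed=8,
        )
        data, _ = tx.generate(cfg)
        s = tx.fit(data, "M1", n_iterations=1500, burn_in=500, seed=2)
        assert s.nu.mean() == pytest.approx(0.25, abs=1e-3)
        assert s.nu.std() < 1e-3

    def test_posterior_recovery_small(self):
        cfg = tx.GeneratorConfig(
            model="Mu",
            n_subjects=80,
            n_statements_per_subject=40,
            effect_mean=0.15,
            effect_sd=0.15,
            seed=21,
        )
        data, _ = tx.generate(cfg)
        s = tx.fit(data, "Mu", n_iterations=3000, burn_in=500, seed=22)
        for chain, truth in ((s.nu, 0.15), (s.delta, 0.15), (np.sqrt(s.sigma2), 0.5)):
            assert abs(chain.mean() - truth) < 3 * chain.std()

    def test_shrinkage_toward_group_mean(self):
        """Posterior theta means vary less than observed effects (M1 truth)."""
        for seed in range(5):
            cfg = tx.GeneratorConfig(
                model="M1",
                n_subjects=50,
                n_statements_per_subject=20,
                effect_mean=0.2,
                seed=seed,
            )
            data, _ = tx.generate(cfg)
            s = tx.fit(data, "Mu", n_iterations=1000, burn_in=200, seed=seed)
            observed = tx.individual_effects(data)["observed_effect"].to_numpy()
            assert s.theta.mean(axis=0).var() < observed.var()

    def test_prior_sampling_with_empty_likelihood(self):
        """Geweke-style check: no data -> chain reproduces the prior."""
        empty = tx.RatingDataset(
            table=pd.DataFrame(
                {"subject": [], "statement": [], "repeated": [], "truth": [], "rating": []}
            )
        )
        s = tx.fit(empty, "Mu", n_iterations=150_000, burn_in=500, seed=3)
        rng = np.random.default_rng(4)
        g_prior = tx.sample_inverse_chisq(rng, 0.25, 150_000)
        chain = s.g_theta[::20]
        ks = stats.kstest(chain, stats.invgamma(0.5, scale=0.25 / 2).cdf)
        assert ks.pvalue > 0.01
        # nu marginal: scale mixture N(0, g_nu) with sigma^2 = 1; quantile
        # noise grows in the heavy tails, so outer quantiles get more slack
        nu_prior = rng.standard_normal(150_000) * np.sqrt(g_prior)
        for q, tol in ((0.1, 0.08), (0.25, 0.04), (0.5, 0.02), (0.75, 0.04), (0.9, 0.08)):
            a, b = np.quantile(s.nu[::20], q), np.quantile(nu_prior, q)
            assert a == pytest.approx(b, abs=tol)

    def test_empty_condition_raises(self, tiny_frame):
        df = tiny_frame.copy()
        df["repeated"] = 1
        data = tx.from_frame(df, validate=False)
        with pytest.raises(tx.DataValidationError):
            tx.fit(data, "Mu", n_iterations=10, burn_in=0, seed=0)

    def test_non_finite_rating_raises(self, tiny_frame):
        df = tiny_frame.copy()
        df.loc[0, "rating"] = np.inf
        data = tx.from_frame(df, validate=False)
        with pytest.raises(tx.DataValidationError):
            tx.fit(data, "Mu", n_iterations=10, burn_in=0, seed=0)


class TestConditionalThetaMoments:
    def test_subject_without_repeated_trials_gets_group_prior(self):
        df = pd.DataFrame(
            {
                "subject": [1, 1, 2, 2],
                "statement": [1, 2, 3, 4],
                "repeated": [1, 0, 0, 0],
                "truth": [1, 0, 1, 0],
                "rating": [0.5, 0.1, -0.2, 0.3],
            }
        )
        data = tx.from_frame(df, validate=False)
        samples = make_dummy_samples(
            np.zeros((3, 2)),
            nu=np.full(3, 0.2),
            g_theta=np.full(3, 0.16),
            sigma2=np.full(3, 1.0),
        )
        means, sds = tx.conditional_theta_moments(samples, data)
        np.testing.assert_allclose(means[:, 1], 0.2)
        np.testing.assert_allclose(sds[:, 1], 0.4)

    def test_one_observation_matches_conjugate_formula(self):
        df = pd.DataFrame(
            {
                "subject": [1, 1],
                "statement": [1, 2],
                "repeated": [1, 0],
                "truth": [0, 0],
                "rating": [0.6, 0.0],
            }
        )
        data = tx.from_frame(df, validate=False)
        nu, g_t, sig2 = 0.1, 0.25, 0.5
        samples = make_dummy_samples(
            np.zeros((2, 1)),
            nu=np.full(2, nu),
            g_theta=np.full(2, g_t),
            sigma2=np.full(2, sig2),
        )
        means, sds = tx.conditional_theta_moments(samples, data)
        prec = 1 / sig2 + 1 / (g_t * sig2)
        expected_mean = (0.6 / sig2 + nu / (g_t * sig2)) / prec
        assert means[0, 0] == pytest.approx(expected_mean)
        assert sds[0, 0] == pytest.approx(1 / np.sqrt(prec))

    def test_complete_pooling_limit(self, mu_fit_small, mu_data_small):
        data, _ = mu_data_small
        pinched = make_dummy_samples(
            mu_fit_small.theta[:5],
            nu=np.full(5, 0.15),
            g_theta=np.full(5, 1e-12),
            sigma2=np.full(5, 0.25),
        )
        means, _ = tx.conditional_theta_moments(pinched, data)
        np.testing.assert_allclose(means, 0.15, atol=1e-6)


class TestDiagnostics:
    def _samples_from_chain(self, chain, I=2):
        n = len(chain)
        return make_dummy_samples(
            np.tile(chain[:, None], (1, I)), nu=chain, g_theta=np.ones(n)
        )

    def test_white_noise_has_no_autocorrelation(self):
        rng = np.random.default_rng(0)
        s = self._samples_from_chain(rng.standard_normal(20_000))
        report = tx.diagnostics(s, parameters=["nu"])
        assert abs(report["nu"]["acf"][0]) < 0.05
        assert report["nu"]["ess"] > 10_000

    def test_constant_chain_flagged_degenerate(self):
        s = self._samples_from_chain(np.full(500, 1.3))
        report = tx.diagnostics(s, parameters=["nu"])
        assert report["nu"]["degenerate"]
        assert report["nu"]["ess"] is None

    def test_ar1_chain_lag_one(self):
        rng = np.random.default_rng(1)
        n = 50_000
        chain = np.empty(n)
        chain[0] = 0.0
        eps = rng.standard_normal(n)
        for i in range(1, n):
            chain[i] = 0.5 * chain[i - 1] + eps[i]
        report = tx.diagnostics(self._samples_from_chain(chain), parameters=["nu"])
        assert report["nu"]["acf"][0] == pytest.approx(0.5, abs=0.05)
        # AR(1) with rho=0.5 has ESS = n * (1-rho)/(1+rho) = n/3
        assert report["nu"]["ess"] == pytest.approx(n / 3, rel=0.15)

    def test_theta_subset_and_min_draws(self, mu_fit_small):
        report = tx.diagnostics(mu_fit_small, theta_subset=(1, 2))
        assert "theta_1" in report and report["theta_1"]["ess"] > 100
        with pytest.raises(ValueError):
            short = make_dummy_samples(np.zeros((50, 1)))
            tx.diagnostics(short, parameters=["nu"])


def test_draw_export_round_trip(mu_fit_small, tmp_path):
    frame = mu_fit_small.to_frame()
    path = tmp_path / "draws.csv"
    frame.to_csv(path, index=False)
    back = pd.read_csv(path)
    assert list(back.columns) == list(frame.columns)
    np.testing.assert_allclose(back["nu"], mu_fit_small.nu)
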