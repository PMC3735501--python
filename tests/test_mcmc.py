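import numpy as np
import pytest

from oligopbmc.hier_model import (
    DesignMatrices,
    ObservedData,
    PriorSpec,
    build_design,
    extract_observations,
)
from oligopbmc.mcmc import (
    MCMCConfig,
    check_convergence,
    psrf,
    run_chains,
)
from oligopbmc.study_data import IncubationCondition, StudyDesign, WellMeasurement
from oligopbmc.synthetic_data import GenerativeParams, simulate_dataset


def fixed_effects_design(y: np.ndarray, cond_of_well: np.ndarray, labels: list[str]):
    """A fixed-effects-only design (no horses)."""
    n, p = len(y), len(labels)
    X = np.zeros((n, p))
    X[np.arange(n), cond_of_well] = 1.0
    return DesignMatrices(
        X=X, Z=np.zeros((n, 5)), horse_index=np.zeros(n, dtype=np.intp),
        condition_labels=labels, horse_ids=[], analyte="TNFa",
    ), ObservedData(y_log=y, is_censored=np.zeros(n, dtype=bool), analyte="TNFa")


class TestPSRF:
    def test_hand_computed_example(self):
        # W = 1, B = 0 -> sqrt(((n-1)/n)) = sqrt(2/3)
        chains = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert psrf(chains) == pytest.approx(0.8165, abs=5e-5)

    def test_identically_distributed_chains_near_one(self):
        rng = np.random.default_rng(42)
        chains = rng.standard_normal((4, 10_000))
        assert psrf(chains) == pytest.approx(1.0, abs=0.02)

    def test_diverged_chains_far_above_one(self):
        rng = np.random.default_rng(0)
        chains = np.stack([rng.standard_normal(500), 100 + rng.standard_normal(500)])
        assert psrf(chains) > 10

    def test_degenerate_chains_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            psrf(np.ones((2, 10)))

    def test_single_chain_error(self):
        with pytest.raises(ValueError, match="chains"):
            psrf(np.arange(10.0)[None, :])


class TestCheckConvergence:
    def test_well_mixed_fit_passes(self, tnfa_draws):
        report = check_convergence(tnfa_draws)
        assert set(report.psrf) == set(tnfa_draws.parameter_names())
        assert report.passed
        assert max(report.psrf.values()) <= 1.1

    def test_stuck_chain_named(self, tnfa_draws):
        import copy

        broken = copy.deepcopy(tnfa_draws)
        broken.beta[0, :, 0] = broken.beta[0, :, 0] + 50.0  # wreck one chain
        report = check_convergence(broken)
        assert not report.passed
        bad_param = f"beta[{broken.condition_labels[0]}]"
        assert bad_param in report.failing()

    def test_single_chain_rejected(self, tnfa_draws):
        import copy

        solo = copy.deepcopy(tnfa_draws)
        solo.beta = solo.beta[:1]
        solo.sigma2 = solo.sigma2[:1]
        solo.Sigma_b = solo.Sigma_b[:1]
        with pytest.raises(ValueError, match="2 chains"):
            check_convergence(solo)


class TestConfig:
    def test_full_protocol_defaults(self):
        cfg = MCMCConfig()
        assert (cfg.n_chains, cfg.n_iterations, cfg.thin) == (4, 1_000_000, 50)
        assert cfg.burn_in_fraction == 0.5
        assert cfg.n_saved_per_chain == 10_000

    def test_scaled_down_profile(self):
        cfg = MCMCConfig(scaled_down=True)
        assert (cfg.n_iterations, cfg.thin) == (20_000, 10)
        assert cfg.n_saved_per_chain == 1000

    def test_zero_draws_after_burn_in_rejected(self):
        with pytest.raises(ValueError, match="burn-in"):
            MCMCConfig(n_iterations=0, thin=50, burn_in_fraction=0.5)


class TestSamplerCorrectness:
    def test_conjugate_posterior_oracle(self):
        """Fixed effects, known variance: draws match the closed-form
        normal posterior within Monte-Carlo error."""
        rng = np.random.default_rng(7)
        labels = ["a", "b", "c"]
        true_beta = np.array([1.0, 3.0, -2.0])
        sigma2 = 0.49
        cond = np.repeat([0, 1, 2], 12)
        y = true_beta[cond] + np.sqrt(sigma2) * rng.standard_normal(len(cond))
        design, data = fixed_effects_design(y, cond, labels)
        priors = PriorSpec()
        config = MCMCConfig(n_chains=4, n_iterations=20_000, thin=10, seed=5)
        draws = run_chains(design, data, priors, config,
                           random_effects=False, sigma2_fixed=sigma2)
        # closed-form conjugate posterior per cell
        for j, lab in enumerate(labels):
            nj = (cond == j).sum()
            prec = nj / sigma2 + priors.beta_sd ** -2
            mean = (y[cond == j].sum() / sigma2) / prec
            sd = prec ** -0.5
            sample = draws.beta_draws(lab)
            mcse = sd / np.sqrt(sample.size)  # draws are exact-conditional
            assert abs(sample.mean() - mean) < 3 * mcse
            assert sample.std(ddof=1) == pytest.approx(sd, rel=0.05)

    def test_prior_sampling_with_empty_data(self):
        """No wells: beta margins must reproduce the Normal(0, 100) prior."""
        design, data = fixed_effects_design(
            np.empty(0), np.empty(0, dtype=int), ["a"]
        )
        config = MCMCConfig(n_chains=2, n_iterations=4000, thin=1, seed=3)
        draws = run_chains(design, data, PriorSpec(), config, random_effects=False)
        sample = draws.beta_draws("a")
        assert abs(sample.mean()) < 3 * 100 / np.sqrt(sample.size)
        assert sample.std(ddof=1) == pytest.approx(100.0, rel=0.1)

    def test_seed_determinism(self, catalogue, cytokine_wells):
        dm = build_design(cytokine_wells, catalogue, analyte="IL10")
        data = extract_observations(cytokine_wells, "IL10")
        cfg = MCMCConfig(n_chains=2, n_iterations=500, thin=5, seed=9)
        a = run_chains(dm, data, PriorSpec(), cfg)
        b = run_chains(dm, data, PriorSpec(), cfg)
        np.testing.assert_array_equal(a.beta, b.beta)
        np.testing.assert_array_equal(a.sigma2, b.sigma2)
        np.testing.assert_array_equal(a.Sigma_b, b.Sigma_b)

    def test_censored_model_matches_grid_integration_oracle(self):
        """Left-censored wells with unknown variance: the augmented Gibbs
        sampler agrees with a brute-force 2-D grid integration of the exact
        censored-likelihood posterior."""
        from scipy.stats import invgamma, norm

        blank = IncubationCondition(label="blank", arm="blank")
        design_s = StudyDesign(
            horses={f"H{i}": "oligosaccharide" for i in range(12)},
            conditions=[blank],
        )
        mu = float(np.log(15.0))  # just below the 15.625 pg/ml limit
        params = GenerativeParams(
            beta={("blank", "TNFa"): mu, ("blank", "IL10"): np.log(1000.0)},
            sigma=0.3, Sigma_b=np.zeros((5, 5)), seed=2,
        )
        wells = [w for w in simulate_dataset(design_s, params)
                 if w.analyte == "TNFa"]
        assert 0.2 < np.mean([w.below_detection for w in wells]) < 0.9
        dm = build_design(wells, [blank])
        data = extract_observations(wells, "TNFa")

        # oracle: joint posterior of (beta, sigma2) on a dense grid
        y_unc = data.y_log[~data.is_censored]
        n_cens = int(data.is_censored.sum())
        bound = float(np.log(15.625))
        beta_grid = np.linspace(mu - 1.5, mu + 1.5, 801)
        log_s2 = np.linspace(np.log(0.002), np.log(3.0), 601)
        s2_grid = np.exp(log_s2)
        B, S2 = np.meshgrid(beta_grid, s2_grid, indexing="ij")
        loglik = (
            -0.5 * y_unc.size * np.log(2 * np.pi * S2)
            - ((y_unc[None, None, :] - B[..., None]) ** 2).sum(-1) / (2 * S2)
            + n_cens * norm.logcdf((bound - B) / np.sqrt(S2))
        )
        log_post = (
            loglik
            + norm.logpdf(B, 0, 100)
            + invgamma.logpdf(S2, 2.0001, scale=1.0001)
            + np.log(S2)  # Jacobian of the log-spaced sigma2 grid
        )
        w = np.exp(log_post - log_post.max())
        w /= w.sum()
        oracle_mean = float((w * B).sum())
        oracle_sd = float(np.sqrt((w * (B - oracle_mean) ** 2).sum()))

        cfg = MCMCConfig(n_chains=2, n_iterations=8000, thin=4, seed=1)
        draws = run_chains(dm, data, PriorSpec(), cfg, random_effects=False)
        sample = draws.beta_draws("blank")
        assert abs(sample.mean() - oracle_mean) < 0.02
        assert sample.std(ddof=1) == pytest.approx(oracle_sd, rel=0.05)
        # and the naive average of reported values is biased upward
        naive = np.mean(np.log([w_.value for w_ in wells]))
        assert naive > oracle_mean + 0.05

    def test_initialisation_insensitivity(self, catalogue, cytokine_wells):
        """Different master seeds (hence different overdispersed starts)
        agree on posterior means within Monte-Carlo error."""
        dm = build_design(cytokine_wells, catalogue, analyte="TNFa")
        data = extract_observations(cytokine_wells, "TNFa")
        cfg_a = MCMCConfig(n_chains=2, n_iterations=8000, thin=4, seed=100)
        cfg_b = MCMCConfig(n_chains=2, n_iterations=8000, thin=4, seed=200)
        a = run_chains(dm, data, PriorSpec(), cfg_a)
        b = run_chains(dm, data, PriorSpec(), cfg_b)
        ma = a.beta.reshape(-1, a.beta.shape[-1]).mean(axis=0)
        mb = b.beta.reshape(-1, b.beta.shape[-1]).mean(axis=0)
        assert np.max(np.abs(ma - mb)) < 0.15

    def test_no_horses_with_random_effects_rejected(self):
        design, data = fixed_effects_design(np.zeros(3), np.zeros(3, dtype=int), ["a"])
        with pytest.raises(ValueError, match="horses"):
            run_chains(design, data, PriorSpec(), MCMCConfig(scaled_down=True))


class TestPosteriorDrawsContainer:
    def test_saved_draw_count_matches_config(self, tnfa_draws):
        cfg = tnfa_draws.config
        assert tnfa_draws.n_saved == cfg.n_saved_per_chain
        assert tnfa_draws.n_chains == cfg.n_chains
        assert np.all(np.isfinite(tnfa_draws.beta))

    def test_parameter_registry_lookup(self, tnfa_draws):
        names = tnfa_draws.parameter_names()
        assert "sigma2" in names and "Sigma_b[intercept,intercept]" in names
        for name in names:
            arr = tnfa_draws.get(name)
            assert arr.shape == (tnfa_draws.n_chains, tnfa_draws.n_saved)
        with pytest.raises(KeyError):
            tnfa_draws.get("beta[nonexistent]")

    def test_save_load_round_trip(self, tnfa_draws, tmp_path):
        path = tmp_path / "draws.npz"
        tnfa_draws.save(path)
        from oligopbmc.mcmc import PosteriorDraws

        back = PosteriorDraws.load(path)
        np.testing.assert_array_equal(back.beta, tnfa_draws.beta)
        assert back.condition_labels == tnfa_draws.condition_labels
        assert back.config.seed == tnfa_draws.config.seed
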