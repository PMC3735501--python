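import numpy as np
import pytest

from oligopbmc import (
    MCMCConfig,
    PriorSpec,
    build_design,
    default_condition_catalogue,
    default_generative_params,
    default_study_design,
    extract_observations,
    run_chains,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def catalogue():
    return default_condition_catalogue()


@pytest.fixture(scope="session")
def design():
    return default_study_design()


@pytest.fixture(scope="session")
def gen_params():
    return default_generative_params(seed=20130722)


@pytest.fixture(scope="session")
def cytokine_wells(design, gen_params):
    return simulate_dataset(design, gen_params)


@pytest.fixture(scope="session")
def tnfa_draws(design, catalogue, cytokine_wells):
    """A modest TNF-alpha fit shared by inference-level tests."""
    dm = build_design(cytokine_wells, catalogue, analyte="TNFa")
    data = extract_observations(cytokine_wells, "TNFa")
    config = MCMCConfig(n_chains=2, n_iterations=4000, thin=4, seed=11)
    return run_chains(dm, data, PriorSpec(), config)


def make_draws(beta_by_condition, analyte="TNFa", n_chains=2, n=200, rng=None):
    """Hand-built PosteriorDraws with given per-condition log-scale draws.

    ``beta_by_condition`` maps label -> scalar (degenerate draws) or array of
    length n_chains * n.
    """
    from oligopbmc.mcmc import PosteriorDraws

    labels = list(beta_by_condition)
    cols = []
    for lab in labels:
        v = np.asarray(beta_by_condition[lab], dtype=float)
        if v.ndim == 0:
            v = np.full(n_chains * n, float(v))
        cols.append(v.reshape(n_chains, n))
    beta = np.stack(cols, axis=-1)
    return PosteriorDraws(
        beta=beta,
        sigma2=np.full((n_chains, n), 0.1),
        Sigma_b=None,
        condition_labels=labels,
        analyte=analyte,
        config=MCMCConfig(n_chains=n_chains, n_iterations=n, thin=1, seed=0),
        sigma2_fixed=False,
    )
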