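import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from phenogp.genomics import filter_snps, relationship_matrices
from phenogp.simulate import SimConfig, simulate_panel_genotypes, simulate_trait


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        seed=42,
        n_snps=600,
        group_sizes=(12, 12, 12, 20),
        n_commercial=24,
        sigma_a2=0.5,
        sigma_d2=0.1,
        sigma_e2=0.4,
    )


@pytest.fixture(scope="session")
def small_panel(small_config):
    """Filtered synthetic panel: 80 hybrids x ~600 SNPs."""
    return filter_snps(simulate_panel_genotypes(small_config))


@pytest.fixture(scope="session")
def small_rel(small_panel):
    return relationship_matrices(small_panel)


@pytest.fixture(scope="session")
def small_trait(small_panel, small_config):
    obs, truth = simulate_trait(small_panel, small_config)
    y = obs[obs["environment"] == "env0"]["value"].to_numpy()
    return y, truth


def medium_setup(seed, sigma_a2=0.5, sigma_d2=0.1, sigma_e2=0.4, n_snps=2000, n_env=1, rho=0.8):
    """N=300 panel with a trait; used by recovery and acceptance tests."""
    cfg = SimConfig(
        seed=seed,
        n_snps=n_snps,
        group_sizes=(50, 50, 50, 94),
        n_commercial=56,
        sigma_a2=sigma_a2,
        sigma_d2=sigma_d2,
        sigma_e2=sigma_e2,
        n_environments=n_env,
        env_genetic_correlation=rho,
    )
    panel = filter_snps(simulate_panel_genotypes(cfg))
    rel = relationship_matrices(panel)
    obs, truth = simulate_trait(panel, cfg)
    return panel, rel, obs, truth
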