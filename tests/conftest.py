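import numpy as np
import pytest

from regnetdriver.synthetic_data import DriverSpec, SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=42,
        n_chromosomes=2,
        chrom_length=5_000_000,
        n_genes=80,
        n_enhancers=60,
        n_tumor_samples=40,
        n_normal_samples=12,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    """A small null cohort (no implanted drivers) shared across tests."""
    return simulate_all(small_config)


@pytest.fixture(scope="session")
def driver_sim():
    """A cohort with one implanted driver of each mechanism."""
    cfg = SimulationConfig(
        seed=7,
        n_chromosomes=2,
        chrom_length=5_000_000,
        n_genes=80,
        n_enhancers=60,
        n_tumor_samples=50,
        n_normal_samples=12,
        implanted_drivers=[
            DriverSpec("hotspot-SNV", penetrance=0.2),
            DriverSpec("recurrent-SV", penetrance=0.4),
            DriverSpec("hyper-meth", penetrance=0.4, effect_size=0.5),
        ],
    )
    return cfg, simulate_all(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
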