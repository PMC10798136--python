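import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated dataset shared by read-level tests."""
    from mscout.simulate import SimConfig, simulate_genome, simulate_reads

    cfg = SimConfig(
        seed=11,
        autosome_length=3000,
        n_autosomal_loci=2,
        m_locus_length=2000,
        planted_orf_length=600,
        depth=20.0,
    )
    genome = simulate_genome(cfg)
    male = simulate_reads(genome, cfg, "male")
    female = simulate_reads(genome, cfg, "female")
    return cfg, genome, male, female


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
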