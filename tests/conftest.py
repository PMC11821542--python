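import numpy as np
import pytest

from anchorpgs import synthetic_admix as sim


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small admixed cohort with truth-track ancestry, shared across tests."""
    cfg = sim.SimulationConfig(
        n_individuals=40,
        n_variants=60,
        n_causal=10,
        seed=99,
        fst=0.15,
        theta_distribution=("uniform", 0.2, 0.8),
        chrom_length_bp=50_000_000,
    )
    freqs = sim.draw_ancestral_frequencies(cfg.n_variants, cfg.fst, seed=cfg.seed)
    cohort = sim.simulate_admixed_genomes(cfg, freqs)
    return cfg, freqs, cohort
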