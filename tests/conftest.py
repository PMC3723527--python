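import pytest

from exonsplice.synthdata import SimConfig, simulate


@pytest.fixture(scope="session")
def noise_free_sim():
    """Small cohort in the noise-free limit: planted effects appear exactly."""
    cfg = SimConfig(n_genes=30, noise_sd=0.0, effect_log2=1.3,
                    affinity_sd=0.3, event_fraction=0.4,
                    gene_level_confounder_fraction=0.1, seed=11)
    return simulate(cfg)


@pytest.fixture(scope="session")
def strong_sim():
    """Strong effects over realistic noise; the recovery workhorse."""
    cfg = SimConfig(n_genes=60, noise_sd=0.25, effect_log2=2.0,
                    nmd_event_fraction=0.3, truncation_event_fraction=0.2,
                    seed=5)
    return simulate(cfg)


@pytest.fixture(scope="session")
def paired_sim():
    """Three-state paired cohort (control / case / post-treatment)."""
    cfg = SimConfig(n_genes=60, paired_followup=True, nmd_event_fraction=0.4,
                    seed=7)
    return simulate(cfg)
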