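import pytest

from mitobook import simulate as sim


@pytest.fixture(scope="session")
def small_params() -> sim.SimParams:
    """A compact but fully featured synthetic experiment configuration."""
    return sim.SimParams(
        n_contigs=2,
        contig_length=120_000,
        n_genes=12,
        lncRNA_fraction=0.25,
        n_true_sites=8,
        bookmark_fraction=0.5,
        n_artifacts=3,
        reads_per_site=200.0,
        background_rate=5e-4,
        n_replicates=2,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_experiment(small_params) -> sim.SimulatedExperiment:
    return sim.simulate_experiment(small_params)


@pytest.fixture(scope="session")
def default_experiment() -> sim.SimulatedExperiment:
    """The generator's default study conditions (shared across tests)."""
    return sim.simulate_experiment(sim.SimParams(seed=7))
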