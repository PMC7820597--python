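import pytest

from txforge import synthetic


@pytest.fixture(scope="session")
def sim_config():
    return synthetic.SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def dataset(sim_config):
    """One fully simulated experiment shared across tests (seed fixed)."""
    genome = synthetic.generate_genome(sim_config)
    truth, reference, ledger = synthetic.generate_annotation_pair(genome, sim_config)
    counts = synthetic.simulate_counts(truth, sim_config, ledger)
    transfrags = synthetic.simulate_transfrags(truth, counts, sim_config)
    return {
        "config": sim_config,
        "genome": genome,
        "truth": truth,
        "reference": reference,
        "ledger": ledger,
        "counts": counts,
        "transfrags": transfrags,
    }
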