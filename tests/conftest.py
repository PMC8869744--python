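import pytest

from cernapipe.synthetic import SimConfig, emit_coding_scores, generate_annotation, simulate_counts


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def sim_dataset(sim_config):
    """One fully generated synthetic dataset shared across tests."""
    ann, seqs, truth = generate_annotation(sim_config)
    matrices = simulate_counts(truth, sim_config)
    scores = emit_coding_scores(truth)
    return {
        "config": sim_config,
        "annotation": ann,
        "sequences": seqs,
        "truth": truth,
        "matrices": matrices,
        "scores": scores,
    }
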