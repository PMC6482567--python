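import numpy as np
import pytest

from famevol import simulate


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_family():
    """Four duplicate pairs at moderate divergence plus two singletons."""
    cfg = simulate.SimulationConfig(
        seed=11, codon_length=300,
        duplication_events=[("P01", 0.2, 0.3), ("P02", 0.5, 0.3),
                            ("P03", 0.8, 0.5), ("P04", 1.1, 0.2)],
        n_singletons=2)
    seqs, truth = simulate.simulate_family(cfg)
    return seqs, truth
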