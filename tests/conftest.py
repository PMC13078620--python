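import numpy as np
import pytest

from isorhythm import (
    Circuit,
    Forcing,
    IntegrationConfig,
    complete_digraph,
    to_adjacency,
)


@pytest.fixture
def fast_config():
    """Short, coarse integration for structural tests (not accuracy checks)."""
    return IntegrationConfig(dt=2e-3, duration=6.0, transient=2.0, seed=0)


@pytest.fixture
def five_node_circuit():
    """A fixed all-to-all circuit with heterogeneous frequencies."""
    rng = np.random.default_rng(11)
    return Circuit(
        n_oscillators=5,
        adjacency=to_adjacency(complete_digraph(5)),
        natural_frequencies=rng.normal(4.0 * np.pi, np.pi, 5),
        coupling=2.0,
    )


@pytest.fixture
def resonant_forcing():
    return Forcing(tempo=2.0, relative_strength=1.0)
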