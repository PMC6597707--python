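import numpy as np
import pytest

from ethmig import explosion, synthetic
from ethmig.units import ethanol_geometry


@pytest.fixture(scope="session")
def geometry():
    return ethanol_geometry()


@pytest.fixture(scope="session")
def triple_template():
    """Momenta of one concerted triple-coincidence event in the order
    (H+, H2O+, C2H3+), used to build rotated momentum-conserving events."""
    ev = explosion.simulate_concerted("TRIPLE", seed=0)
    order = [ev.species.index(s) for s in ("H+", "H2O+", "C2H3+")]
    return ev.momenta_au[order]


@pytest.fixture(scope="session")
def event_stream():
    """One default-condition synthetic pump-probe stream, shared by the
    pipeline-level tests (generation is the expensive step)."""
    config = synthetic.GeneratorConfig()
    hits, truth = synthetic.generate_event_stream(config, seed=1)
    return config, hits, truth


@pytest.fixture(scope="session")
def gated_stream(event_stream):
    from ethmig import coincidence

    config, hits, truth = event_stream
    events, stats = coincidence.assign_channels(hits)
    return config, truth, events, stats


def random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)
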