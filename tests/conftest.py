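import logging

import numpy as np
import pytest

from ineuron import morphology as M
from ineuron import synthetic as S

logging.getLogger("ineuron").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def simple_neurite():
    """Straight 25 µm neurite along x from the origin."""
    nodes = np.array([[0.0, 0, 0], [10.0, 0, 0], [25.0, 0, 0]])
    return M.Neurite(nodes, np.array([-1, 0, 1]))


@pytest.fixture
def random_trees(rng):
    """20 generated morphologies with their generator truth records."""
    out = []
    for i in range(20):
        m, truth = S.generate_morphology(S.MorphGenParams(), 14, rng,
                                         cell_id=f"tree{i}")
        out.append((m, truth))
    return out


def random_rotation(rng):
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    return q * np.sign(np.diag(r))


def transformed(m, rotation, translation):
    """Apply a rigid transform to a morphology."""
    neurites = [M.Neurite(nr.nodes @ rotation.T + translation, nr.parents,
                          nr.radii) for nr in m.neurites]
    return M.NeuronMorphology(m.cell_id, rotation @ m.soma_centroid
                              + translation, neurites, dict(m.metadata))
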