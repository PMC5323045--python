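import numpy as np
import pytest

from stgmorph.geometry import NeuronGeometry, SkeletonNode
from stgmorph.synthetic import SyntheticNeuronSpec, generate_neuron


def build_tree(points, parents, radii=None, **kwargs):
    """Build a geometry from parallel lists (1-based implicit ids)."""
    radii = radii or [None] * len(points)
    nodes = [
        SkeletonNode(i + 1, np.asarray(p, dtype=float), radii[i], parents[i])
        for i, p in enumerate(points)
    ]
    kwargs.setdefault("merge_zero_edges", False)
    return NeuronGeometry(nodes, **kwargs)


@pytest.fixture
def straight_chain():
    """Soma -> two collinear nodes along x (total cable 20 µm)."""
    return build_tree([(0, 0, 0), (10, 0, 0), (20, 0, 0)], [None, 1, 2])


@pytest.fixture
def y_tree():
    """Soma -> stem -> bifurcation with two tips."""
    return build_tree(
        [(0, 0, 0), (10, 0, 0), (20, 5, 0), (20, -5, 0)],
        [None, 1, 2, 2],
    )


@pytest.fixture(scope="session")
def default_neuron():
    """Mid-sized synthetic neuron with radii (shared across tests)."""
    spec = SyntheticNeuronSpec(seed=101, radius_noise_sigma=0.0)
    return generate_neuron(spec)


@pytest.fixture(scope="session")
def tiled_neuron():
    """Tightly tiled neuron: tip dispersion well below tile spacing."""
    spec = SyntheticNeuronSpec(
        seed=55, field_dispersion=15.0, tile_spacing=150.0, subtree_layout="tiled-grid"
    )
    return generate_neuron(spec)


@pytest.fixture(scope="session")
def multi_axon_neuron():
    spec = SyntheticNeuronSpec(seed=77, n_axons=3, n_subtrees=8, primary_length=400.0)
    return generate_neuron(spec)
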