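import numpy as np
import pytest

from molimage.graphs import AttributeVocabulary, MolecularGraph
from molimage.synth import SynthConfig, generate_dataset


@pytest.fixture
def vocab():
    return AttributeVocabulary((10,), (4,))


@pytest.fixture
def triangle():
    """3-cycle with distinct atom and bond types."""
    return MolecularGraph(
        node_attrs=[[1], [2], [3]],
        edge_index=[[0, 1], [1, 0], [1, 2], [2, 1], [2, 0], [0, 2]],
        edge_attrs=[[0], [0], [1], [1], [2], [2]],
        molecule_id="tri")


def make_chain(n: int, atom: int = 1, bond: int = 0) -> MolecularGraph:
    arcs, attrs = [], []
    for i in range(n - 1):
        arcs += [[i, i + 1], [i + 1, i]]
        attrs += [[bond], [bond]]
    if not arcs:
        arcs = np.zeros((0, 2), dtype=int)
        attrs = np.zeros((0, 1), dtype=int)
    return MolecularGraph([[atom]] * n, arcs, attrs, f"chain{n}")


@pytest.fixture(scope="session")
def small_dataset():
    """40 molecules x 2 views at 16 px — enough to exercise training paths."""
    return generate_dataset(SynthConfig(
        n_molecules=40, views_per_molecule=2, signal_strength=0.9,
        image_size=16, seed=3))


def rel_err(a: float, b: float) -> float:
    return abs(a - b) / max(1e-12, abs(a), abs(b))


def check_gradients(loss_fn, params, n_coords=3, h=1e-5, tol=1e-4, rng=None):
    """Compare analytic gradients with central finite differences.

    ``loss_fn`` must rebuild the graph and return the loss Tensor each call.
    """
    from molimage.nn import numeric_gradient

    rng = rng or np.random.default_rng(0)
    loss = loss_fn()
    for p in params.values():
        p.grad = None
    loss.backward()
    coords = [(k, int(rng.integers(p.data.size)))
              for k, p in params.items() for _ in range(n_coords)]
    num = numeric_gradient(lambda: float(loss_fn().data), params, h=h,
                           coords=coords)
    worst = 0.0
    for (k, i), g_num in num.items():
        g_ana = 0.0 if params[k].grad is None else params[k].grad.ravel()[i]
        denom = max(abs(g_num), abs(g_ana), 1e-6)
        worst = max(worst, abs(g_ana - g_num) / denom)
    assert worst < tol, f"max gradient relative error {worst}"
    return worst
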