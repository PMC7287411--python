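import numpy as np
import pytest

from rapidcns.simulate import default_fixture_config, make_fixture_suite, oryza_tree, simulate_blocks


@pytest.fixture(scope="session")
def tree():
    return oryza_tree()


@pytest.fixture(scope="session")
def fixture_suite(tmp_path_factory):
    """Small deterministic fixture suite shared across tests (60 blocks, 0.3 Mb)."""
    out = tmp_path_factory.mktemp("fixture")
    paths = make_fixture_suite(out, seed=42, n_blocks=60)
    return paths


@pytest.fixture(scope="session")
def simulated_fixture():
    """Blocks + truth + genes for the same layout, held in memory."""
    cfg = default_fixture_config(seed=42, n_blocks=60)
    blocks, truth, genes = simulate_blocks(cfg)
    return cfg, blocks, truth, genes


def brute_force_parsimony(tree, column):
    """Exhaustive minimum substitutions over all internal-node labelings.

    ``column`` maps species -> base index 0..3, with absent species omitted.
    Absent leaves are free (they can always copy their parent at zero cost),
    so this equals parsimony on the induced subtree.
    """
    internals = [i for i in range(tree.n_nodes) if not tree.is_leaf[i]]
    pos = {n: k for k, n in enumerate(internals)}
    m = len(internals)
    assign = np.indices((4,) * m).reshape(m, -1).T  # (4^m, m)
    cost = np.zeros(assign.shape[0], dtype=np.int64)
    for i in internals:
        p = tree.parent[i]
        if p >= 0:
            cost += assign[:, pos[i]] != assign[:, pos[p]]
    for i in range(tree.n_nodes):
        if tree.is_leaf[i]:
            sp = tree.node_leaf[i]
            if sp in column:
                cost += assign[:, pos[tree.parent[i]]] != column[sp]
    return int(cost.min())
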