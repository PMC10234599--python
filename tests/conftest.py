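import numpy as np
import pytest
from skbio import TreeNode

from strainshare import PipelineConfig


@pytest.fixture
def config():
    return PipelineConfig()


def random_tree(n_leaves: int, rng: np.random.Generator) -> TreeNode:
    """Random binary topology with positive branch lengths (0.05..1)."""
    nodes = [TreeNode(name=f"L{i}", length=float(rng.uniform(0.05, 1.0)))
             for i in range(n_leaves)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = TreeNode(length=float(rng.uniform(0.05, 1.0)), children=[left, right])
        nodes.append(parent)
    root = TreeNode(children=nodes)
    return root


def brute_force_patristic(tree: TreeNode) -> tuple[list[str], np.ndarray]:
    """Path-sum patristic distances computed edge-by-edge, independent of any
    distance-matrix helper: sum branch lengths on the two root paths minus
    twice the shared prefix."""
    tips = list(tree.tips())
    names = [t.name for t in tips]
    paths = []
    for t in tips:
        path = []
        node = t
        while node.parent is not None:
            path.append(node)
            node = node.parent
        paths.append(list(reversed(path)))  # root -> tip
    n = len(tips)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            k = 0
            while k < min(len(paths[i]), len(paths[j])) and paths[i][k] is paths[j][k]:
                k += 1
            d = sum(nd.length or 0.0 for nd in paths[i][k:])
            d += sum(nd.length or 0.0 for nd in paths[j][k:])
            D[i, j] = D[j, i] = d
    return names, D
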