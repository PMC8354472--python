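import numpy as np
import pytest

from iesevo.trees import Tree, paramecium_species_tree


@pytest.fixture(scope="session")
def species_tree() -> Tree:
    return paramecium_species_tree()


@pytest.fixture(scope="session")
def quartet() -> Tree:
    return Tree.from_newick("((a:0.3,b:0.2):0.4,(c:0.5,d:0.1):0.6);")


def random_binary_tree(rng: np.random.Generator, n_tips: int) -> Tree:
    """Random rooted binary tree with exponential branch lengths."""
    tree = Tree()
    root = tree.add_node(None)
    leaves = [root]
    while len(leaves) < n_tips:
        pick = leaves.pop(rng.integers(len(leaves)))
        for _ in range(2):
            leaves.append(tree.add_node(pick, float(rng.exponential(0.4))
                                        + 1e-3))
    for i, leaf in enumerate(leaves):
        tree.nodes[leaf].name = f"t{i}"
    return tree
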