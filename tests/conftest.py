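import numpy as np
import pytest

from msyphylo import MutationTree, TreeNode, VariantMatrix
from msyphylo.classify import default_hierarchy


@pytest.fixture(scope="session")
def hierarchy():
    return default_hierarchy()


@pytest.fixture
def rng():
    return np.random.default_rng(20150624)


def make_tree(spec, mutations=None, ages=None):
    """Build a MutationTree from a nested (label, [children]) spec.

    ``mutations`` maps node label -> iterable of site names; ``ages`` maps
    label -> years.
    """
    mutations = mutations or {}
    ages = ages or {}

    def build(s):
        if isinstance(s, str):
            node = TreeNode(label=s)
        else:
            label, children = s
            node = TreeNode(label=label)
            for c in children:
                node.add_child(build(c))
        node.mutations = set(mutations.get(node.label, ()))
        node.age = ages.get(node.label)
        return node

    return MutationTree(build(spec))


def random_binary_matrix(rng, n_samples, n_sites, missing_prob=0.0):
    """A random *compatible* matrix: derived sets drawn from the clades of
    a random topology, so a perfect phylogeny always exists."""
    # random laminar family via a random tree over samples
    samples = [f"s{i}" for i in range(n_samples)]
    clades = [frozenset([s]) for s in samples]
    pool = list(clades)
    while len(pool) > 1:
        i, j = rng.choice(len(pool), size=2, replace=False)
        merged = pool[i] | pool[j]
        pool = [c for k, c in enumerate(pool) if k not in (i, j)] + [merged]
        clades.append(merged)
    usable = [c for c in clades if 0 < len(c) < n_samples]
    rows = []
    names = []
    for m in range(n_sites):
        clade = usable[rng.integers(len(usable))]
        row = np.array(
            [1 if s in clade else 0 for s in samples], dtype=np.int8
        )
        if missing_prob > 0:
            mask = rng.random(n_samples) < missing_prob
            row[mask] = -1
        rows.append(row)
        names.append(f"m{m}")
    return VariantMatrix(
        names, list(range(1, n_sites + 1)), samples, np.array(rows)
    )
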