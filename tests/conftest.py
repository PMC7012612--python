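"""Shared fixtures and tree-construction helpers."""

from __future__ import annotations

import numpy as np
import pytest

import rerscan as rs
from rerscan.trees import Node, PhyloTree


def random_binary_tree(
    n_tips: int, rng: np.random.Generator, min_len: float = 0.01, max_len: float = 0.5
) -> PhyloTree:
    """Grow a random rooted binary tree by repeated tip splitting."""
    labels = [f"t{i:02d}" for i in range(n_tips)]
    root = Node()
    a, b = Node(labels[0]), Node(labels[1])
    root.add_child(a)
    root.add_child(b)
    leaves = [a, b]
    for label in labels[2:]:
        target = leaves[rng.integers(len(leaves))]
        left = Node(target.name)
        right = Node(label)
        target.name = None
        target.add_child(left)
        target.add_child(right)
        leaves.remove(target)
        leaves.extend([left, right])
    tree = PhyloTree(root)
    for node in tree.iter_nodes():
        if node is not tree.root:
            node.length = float(rng.uniform(min_len, max_len))
    return tree


@pytest.fixture(scope="session")
def master61() -> PhyloTree:
    """The 61-species analysis tree (printed fixture minus cape golden mole)."""
    return rs.default_master()


@pytest.fixture(scope="session")
def full_fixture_tree() -> PhyloTree:
    return rs.load_fixture_tree("mammal61")


@pytest.fixture(scope="session")
def small_planted_dataset(master61):
    """A compact planted study shared by association/enrichment/model tests."""
    spec = rs.SyntheticSpec(n_genes=150, seed=5, master=master61)
    return rs.generate_dataset(spec, n_sets=20, set_size=10)


@pytest.fixture(scope="session")
def small_planted_fit(small_planted_dataset):
    d = small_planted_dataset
    model = rs.RERScan(
        gene_trees=d.genes,
        traits=d.traits,
        gene_sets=d.collection,
        master=d.master,
    )
    return model.fit(n_permulations=50, seed=3)
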