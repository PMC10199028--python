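"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from multifreq import MultilayerNetwork, Partition


def random_multilayer(
    seed: int, n_layers: int = 3, n_nodes: int = 5, density: float = 1.0
) -> MultilayerNetwork:
    """Random fully-weighted (or sparse) multilayer network."""
    rng = np.random.default_rng(seed)
    intra, inter = {}, {}
    for h in range(n_layers):
        w = rng.uniform(0.0, 1.0, size=(n_nodes, n_nodes))
        w *= rng.random(size=w.shape) < density
        w = np.triu(w, k=1)
        intra[h] = w + w.T
        for k in range(h + 1, n_layers):
            b = rng.uniform(0.0, 1.0, size=(n_nodes, n_nodes))
            b *= rng.random(size=b.shape) < density
            inter[(h, k)] = b
    return MultilayerNetwork(
        [f"L{h}" for h in range(n_layers)], [n_nodes] * n_layers, intra, inter
    )


def set_partitions(items: list):
    """All set partitions of ``items`` (Bell-number enumeration oracle)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i, block in enumerate(smaller):
            yield smaller[:i] + [[first] + block] + smaller[i + 1:]
        yield [[first]] + smaller


def partition_labels_from_blocks(blocks: list[list[int]], n: int) -> np.ndarray:
    labels = np.empty(n, dtype=int)
    for g, block in enumerate(blocks):
        for i in block:
            labels[i] = g
    return labels


def brute_force_optimum(B: np.ndarray) -> tuple[np.ndarray, float]:
    """Exhaustive maximization of sum_ij B_ij delta(g_i, g_j)."""
    n = B.shape[0]
    best_q, best_labels = -np.inf, None
    for blocks in set_partitions(list(range(n))):
        labels = partition_labels_from_blocks(blocks, n)
        same = labels[:, None] == labels[None, :]
        q = B[same].sum()
        if q > best_q:
            best_q, best_labels = q, labels
    return best_labels, best_q


@pytest.fixture
def toy_net() -> MultilayerNetwork:
    """2 layers x 2 nodes, one intra edge (w=1, layer 0), one inter edge (w=0.5)."""
    return MultilayerNetwork(
        ["a", "b"],
        [2, 2],
        intra={0: np.array([[0.0, 1.0], [1.0, 0.0]])},
        inter={(0, 1): np.array([[0.5, 0.0], [0.0, 0.0]])},
    )


@pytest.fixture
def planted_two_cliques() -> tuple[MultilayerNetwork, Partition]:
    """Two 4-cliques per layer (2 layers), strong inter-layer edges joining
    clique A of layer 0 with clique A of layer 1 (planted cross-layer
    2-community structure)."""
    n = 8
    block = np.zeros((n, n))
    for group in (range(4), range(4, 8)):
        for i, j in itertools.combinations(group, 2):
            block[i, j] = block[j, i] = 1.0
    inter = np.zeros((n, n))
    inter[:4, :4] = 1.0
    inter[4:, 4:] = 1.0
    net = MultilayerNetwork(["x", "y"], [n, n], {0: block.copy(), 1: block.copy()},
                            {(0, 1): inter})
    labels = np.array([0] * 4 + [1] * 4 + [0] * 4 + [1] * 4)
    return net, Partition(net, labels)
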