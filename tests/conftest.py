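"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from mimevo.mk import MkModel, transition_matrix
from mimevo.trees import Phylogeny


def balanced_tree(n: int, height: float = 1.0) -> Phylogeny:
    """Fully balanced ultrametric tree on n=2^m tips, labels t0..t{n-1}."""

    def rec(labels, h):
        if len(labels) == 1:
            return f"{labels[0]}:{h}"
        half = len(labels) // 2
        return f"({rec(labels[:half], h / 2)},{rec(labels[half:], h / 2)}):{h / 2}"

    labels = [f"t{i}" for i in range(n)]
    half = n // 2
    nwk = f"({rec(labels[:half], height / 2)},{rec(labels[half:], height / 2)});"
    return Phylogeny.from_newick(nwk)


def random_tree(n_tips: int, rng: np.random.Generator) -> Phylogeny:
    """Random rooted binary tree with exponential branch lengths."""

    def rec(labels):
        if len(labels) == 1:
            return f"{labels[0]}:{rng.exponential(0.5):.6f}"
        cut = int(rng.integers(1, len(labels)))
        return (
            f"({rec(labels[:cut])},{rec(labels[cut:])}):{rng.exponential(0.5):.6f}"
        )

    labels = [f"t{i}" for i in range(n_tips)]
    perm = rng.permutation(n_tips)
    labels = [labels[i] for i in perm]
    cut = int(rng.integers(1, n_tips)) if n_tips > 1 else 1
    return Phylogeny.from_newick(f"({rec(labels[:cut])},{rec(labels[cut:])});")


def brute_force_likelihood(tree: Phylogeny, model: MkModel, traits: dict) -> float:
    """Likelihood by explicit summation over every node-state assignment.

    Independent of the pruning implementation: walks assignments of all
    nodes (tips fixed to their observed state, missing tips free) and sums
    root_prior x product of per-branch transition probabilities.
    """
    idx = tree.index()
    k = model.k
    P = {i: transition_matrix(model, idx.lengths[i]) for i in range(idx.n_nodes)}
    free_nodes = []
    fixed = {}
    for lab, i in idx.tip_index.items():
        if lab in traits and traits[lab] is not None:
            fixed[i] = int(traits[lab]) - 1
        else:
            free_nodes.append(i)
    free_nodes += [int(n) for n in idx.postorder]
    total = 0.0
    for combo in itertools.product(range(k), repeat=len(free_nodes)):
        assign = dict(fixed)
        assign.update(dict(zip(free_nodes, combo)))
        p = model.root_prior[assign[idx.root]]
        for node in range(idx.n_nodes):
            parent = idx.parent[node]
            if parent >= 0:
                p *= P[node][assign[parent], assign[node]]
        total += p
    return float(total)


def brute_force_marginals(tree: Phylogeny, model: MkModel, traits: dict) -> np.ndarray:
    """Per-node marginal posteriors by explicit enumeration (see above)."""
    idx = tree.index()
    k = model.k
    P = {i: transition_matrix(model, idx.lengths[i]) for i in range(idx.n_nodes)}
    free_nodes = []
    fixed = {}
    for lab, i in idx.tip_index.items():
        if lab in traits and traits[lab] is not None:
            fixed[i] = int(traits[lab]) - 1
        else:
            free_nodes.append(i)
    free_nodes += [int(n) for n in idx.postorder]
    acc = np.zeros((idx.n_nodes, k))
    for combo in itertools.product(range(k), repeat=len(free_nodes)):
        assign = dict(fixed)
        assign.update(dict(zip(free_nodes, combo)))
        p = model.root_prior[assign[idx.root]]
        for node in range(idx.n_nodes):
            parent = idx.parent[node]
            if parent >= 0:
                p *= P[node][assign[parent], assign[node]]
        for node, s in assign.items():
            acc[node, s] += p
    return acc / acc.sum(axis=1, keepdims=True)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
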