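"""Rooted-tree handling: Newick I/O, relative-time scaling, pruning.

A :class:`Phylogeny` wraps a dendropy tree and adds the operations the
downstream analyses need:

* node ages (distance to the tips, 0 at the present) and an ultrametricity
  check with a relative tolerance;
* the relative-time-unit (RTU) transformation — an ultrametric tree is
  rescaled so the root sits at age 1.0 and every extant tip at 0.0, which
  lets divergence times be compared without absolute calibration;
* representative pruning — reducing a densely sampled group to 3–5 terminals
  that span its deepest splits, the standard preparation for expensive
  dating-style analyses;
* a flat indexed view (parent arrays, postorder) consumed by the Mk-model
  machinery.
"""

from __future__ import annotations

import io
from typing import Dict, List, Optional, Sequence

import dendropy
import numpy as np

__all__ = ["Phylogeny", "parse_newick", "write_newick", "to_rtu", "prune_representatives"]


class TreeIndex:
    """Array view of a rooted tree for likelihood computations.

    Nodes are numbered 0..n_nodes-1 with tips first (in ``tip_labels`` order)
    and internal nodes in postorder afterwards; the root is the last node.
    """

    def __init__(self, tip_labels, parent, lengths, postorder, children):
        self.tip_labels: List[str] = tip_labels
        self.parent: np.ndarray = parent          # -1 at the root
        self.lengths: np.ndarray = lengths        # edge above each node
        self.postorder: np.ndarray = postorder    # internal nodes, tips excluded
        self.children: List[List[int]] = children
        self.n_tips = len(tip_labels)
        self.n_nodes = len(parent)
        self.root = int(postorder[-1]) if len(postorder) else 0
        self.tip_index: Dict[str, int] = {lab: i for i, lab in enumerate(tip_labels)}


class Phylogeny:
    """A rooted phylogeny with branch lengths (units arbitrary or RTU)."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise ValueError("tip labels must be unique")
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError("branch lengths must be non-negative")

    # -- construction / serialisation --------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=text, schema="newick", rooting="force-rooted",
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise ValueError(f"malformed Newick: {exc}") from exc
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "Phylogeny":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        out = io.StringIO()
        self._tree.write(
            file=out, schema="newick", suppress_rooting=True,
            real_value_format_specifier=".10g",
        )
        return out.getvalue().strip()

    def write_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    def clone(self) -> "Phylogeny":
        return Phylogeny(self._tree.clone(depth=1))

    # -- basic structure ----------------------------------------------------

    @property
    def tip_labels(self) -> List[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    def _depths(self):
        """Distance of every node from the root (root edge ignored)."""
        depths = {}
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                depths[node] = 0.0
            else:
                depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
        return depths

    @property
    def height(self) -> float:
        depths = self._depths()
        return max(depths[leaf] for leaf in self._tree.leaf_node_iter())

    def node_ages(self):
        """Map node → age (height − depth; exact zeros only if ultrametric)."""
        depths = self._depths()
        h = max(depths[leaf] for leaf in self._tree.leaf_node_iter())
        return {node: h - d for node, d in depths.items()}

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        depths = self._depths()
        tip_depths = [depths[leaf] for leaf in self._tree.leaf_node_iter()]
        h = max(tip_depths)
        if h == 0:
            return True
        return (h - min(tip_depths)) <= rel_tol * h

    def worst_offending_tip(self):
        """Tip whose root-to-tip distance deviates most from the tree height."""
        depths = self._depths()
        tips = list(self._tree.leaf_node_iter())
        h = max(depths[t] for t in tips)
        worst = min(tips, key=lambda t: depths[t])
        return worst.taxon.label, h - depths[worst]

    # -- indexed view -------------------------------------------------------

    def index(self) -> TreeIndex:
        tips = list(self._tree.leaf_node_iter())
        tip_labels = [t.taxon.label for t in tips]
        order = {node: i for i, node in enumerate(tips)}
        internal = [n for n in self._tree.postorder_node_iter() if not n.is_leaf()]
        for j, node in enumerate(internal):
            order[node] = len(tips) + j
        n = len(order)
        parent = np.full(n, -1, dtype=int)
        lengths = np.zeros(n)
        children: List[List[int]] = [[] for _ in range(n)]
        for node, i in order.items():
            if node.parent_node is not None:
                parent[i] = order[node.parent_node]
                lengths[i] = node.edge.length or 0.0
                children[order[node.parent_node]].append(i)
        postorder = np.array([order[n_] for n_ in internal], dtype=int)
        return TreeIndex(tip_labels, parent, lengths, postorder, children)

    # -- transformations ----------------------------------------------------

    def to_rtu(self) -> "Phylogeny":
        """Rescale an ultrametric tree to relative time units.

        Node ages are divided by the root age so the root sits at exactly
        1.0 and the tips at 0.0; the relative order of node ages is
        preserved. Raises on non-ultrametric input, naming the tip whose
        root-to-tip distance deviates most.
        """
        if not self.is_ultrametric():
            tip, dev = self.worst_offending_tip()
            raise ValueError(
                f"tree is not ultrametric: tip {tip!r} deviates by {dev:.6g} "
                "from the tree height"
            )
        h = self.height
        if h <= 0:
            raise ValueError("tree height must be positive")
        clone = self._tree.clone(depth=1)
        for edge in clone.preorder_edge_iter():
            if edge.length is not None:
                edge.length = edge.length / h
        root = clone.seed_node
        root.edge.length = None
        out = Phylogeny(clone)
        # snap tips exactly to age 0 by absorbing round-off into tip edges
        depths = out._depths()
        for leaf in out._tree.leaf_node_iter():
            err = 1.0 - depths[leaf]
            if leaf.edge.length is not None:
                leaf.edge.length += err
        return out

    def prune_to(self, keep: Sequence[str]) -> "Phylogeny":
        """Induced subtree on ``keep``; unary nodes suppressed, lengths summed."""
        clone = self._tree.clone(depth=1)
        taxa = set(keep)
        clone.retain_taxa_with_labels(list(taxa))
        return Phylogeny(clone)


def parse_newick(text: str) -> Phylogeny:
    return Phylogeny.from_newick(text)


def write_newick(tree: Phylogeny) -> str:
    return tree.to_newick()


def to_rtu(tree: Phylogeny) -> Phylogeny:
    return tree.to_rtu()


def _greedy_representatives(tree: Phylogeny, tips: List[str], k: int) -> List[str]:
    """Greedy deepest-split retention: start from the two tips realising the
    group's deepest divergence, then iteratively add the tip whose path to
    the already-retained subtree is longest (ties broken by label). This is
    the greedy maximiser of retained subtree length, hence of retained
    root-to-split depth."""
    if len(tips) <= k:
        return sorted(tips)
    pdm = tree._tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree._tree.taxon_namespace if t.label in set(tips)}
    labels = sorted(taxa)
    dist = {
        (a, b): pdm.patristic_distance(taxa[a], taxa[b])
        for i, a in enumerate(labels)
        for b in labels[i + 1 :]
    }

    def d(a, b):
        return dist[(a, b)] if (a, b) in dist else dist[(b, a)]

    # seed with the deepest split in the group
    best = max(((d(a, b), a, b) for (a, b) in dist), key=lambda t: (t[0], t[1], t[2]))
    retained = [best[1], best[2]]
    while len(retained) < k:
        # distance from a candidate to the retained subtree equals half of
        # max over retained pairs of (d(c,a) + d(c,b) - d(a,b)) ... use the
        # standard formula: d(c, subtree) = max over a in retained of
        # (d(c,a) - d(a, attach)) — computed via the Gromov product.
        def gain(c):
            g = min(
                0.5 * (d(c, a) + d(c, b) - d(a, b))
                for i, a in enumerate(retained)
                for b in retained[i + 1 :]
            ) if len(retained) > 1 else d(c, retained[0])
            return g

        candidates = [t for t in labels if t not in retained]
        chosen = max(candidates, key=lambda c: (gain(c), c))
        retained.append(chosen)
    return sorted(retained)


def prune_representatives(
    tree: Phylogeny,
    groups: Dict[str, str],
    k_min: int = 3,
    k_max: int = 5,
) -> Phylogeny:
    """Reduce each group (e.g. tribe) to k_min..k_max deep-split terminals.

    ``groups`` maps every tip label to a group name. Per group, between
    ``k_min`` and min(k_max, group size) tips are retained by greedy
    deepest-split selection; the result is the induced subtree with unary
    nodes suppressed (pairwise path lengths among retained tips preserved).
    """
    if not groups:
        raise ValueError("empty group map")
    tip_set = set(tree.tip_labels)
    unassigned = tip_set - set(groups)
    if unassigned:
        raise ValueError(f"tips without a group assignment: {sorted(unassigned)[:5]}")
    by_group: Dict[str, List[str]] = {}
    for tip, g in groups.items():
        if tip in tip_set:
            by_group.setdefault(g, []).append(tip)
    keep: List[str] = []
    for g, tips in sorted(by_group.items()):
        k = min(k_max, len(tips))
        k = max(k, min(k_min, len(tips)))
        keep.extend(_greedy_representatives(tree, tips, k))
    return tree.prune_to(keep)
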