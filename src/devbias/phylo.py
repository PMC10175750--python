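"""Phylogenetic relationship matrices and Grafen branch lengths."""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np


def _as_tree(tree: "dendropy.Tree | str") -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree.clone(depth=1)
    return dendropy.Tree.get(data=str(tree), schema="newick")


def grafen_branch_lengths(tree: "dendropy.Tree | str") -> dendropy.Tree:
    """Assign Grafen branch lengths to a rooted topology.

    Each node's height is its number of descendant tips minus one, scaled
    so the root has height 1; tips have height 0.  A branch's length is the
    parent height minus the child height.
    """
    t = _as_tree(tree)
    root = t.seed_node
    tips = len(root.leaf_nodes())
    if tips < 2:
        raise ValueError("need a rooted tree with at least two tips")
    if len(root.child_nodes()) < 2:
        raise ValueError("tree is not rooted (root has a single child)")
    denom = tips - 1
    for node in t.postorder_node_iter():
        n_desc = max(len(node.leaf_nodes()), 1)
        node._grafen_height = (n_desc - 1) / denom
    for node in t.preorder_node_iter():
        if node.parent_node is None:
            node.edge.length = None
        else:
            node.edge.length = node.parent_node._grafen_height - node._grafen_height
    return t


@dataclass
class RelationshipMatrix:
    """Shared root-to-MRCA path lengths among taxa (PSD by construction)."""

    taxa: list[str]
    S: np.ndarray
    branch_length_rule: str = "none"

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        n = len(self.taxa)
        if self.S.shape != (n, n):
            raise ValueError("S must be n x n for n taxa")
        if np.abs(self.S - self.S.T).max() > 1e-10:
            raise ValueError("S must be symmetric")
        w = np.linalg.eigvalsh(self.S)
        if w[0] < -1e-8 * max(w[-1], 1e-300):
            raise ValueError("S is not positive semidefinite")


def phylo_relationship_matrix(tree: "dendropy.Tree | str",
                              rule: str = "none") -> RelationshipMatrix:
    """Relationship matrix S with S[i, j] = root-to-MRCA path length.

    ``rule='grafen'`` first assigns Grafen branch lengths (unit root
    height, so the diagonal is 1); ``rule='unity'`` sets every branch
    length to one; ``rule='none'`` uses the lengths on the tree.
    """
    if rule == "grafen":
        t = grafen_branch_lengths(tree)
    else:
        t = _as_tree(tree)
        if rule == "unity":
            for edge in t.preorder_edge_iter():
                if edge.head_node.parent_node is not None:
                    edge.length = 1.0
        elif rule != "none":
            raise ValueError(f"unknown branch length rule {rule!r}")

    # depth of each node measured from the root
    for node in t.preorder_node_iter():
        if node.parent_node is None:
            node._depth = 0.0
        else:
            bl = node.edge.length
            if bl is None:
                raise ValueError("tree has missing branch lengths; apply a rule first")
            if bl < 0:
                raise ValueError("negative branch length")
            node._depth = node.parent_node._depth + bl

    leaves = list(t.leaf_node_iter())
    taxa = [lf.taxon.label if lf.taxon else f"tip_{i}" for i, lf in enumerate(leaves)]
    index = {id(lf): i for i, lf in enumerate(leaves)}
    n = len(leaves)
    s = np.zeros((n, n))
    for lf in leaves:
        s[index[id(lf)], index[id(lf)]] = lf._depth
    for node in t.postorder_internal_node_iter():
        children = node.child_nodes()
        groups = [[index[id(lf)] for lf in ch.leaf_iter()] for ch in children]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                for i in groups[a]:
                    for j in groups[b]:
                        s[i, j] = s[j, i] = node._depth
    return RelationshipMatrix(taxa=taxa, S=s, branch_length_rule=rule)


def random_cladogram(n_tips: int, seed: int | None = None) -> dendropy.Tree:
    """A random rooted binary topology (no branch lengths) on
    ``sp_1 ... sp_n``, grown by random splitting."""
    if n_tips < 2:
        raise ValueError("need at least two tips")
    rng = np.random.default_rng(seed)
    labels = [f"sp_{i + 1}" for i in range(n_tips)]
    nodes = [f"'{lab}'" for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]})"
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [merged]
    newick = nodes[0] + ";"
    return dendropy.Tree.get(data=newick, schema="newick")
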