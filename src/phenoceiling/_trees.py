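"""Internal helpers for extracting Brownian-motion covariance structure
from dendropy trees.

The phylogenetic variance-covariance matrix of tip values under Brownian
motion has entries equal to the root-to-MRCA path length of each tip pair,
with tip depths on the diagonal.
"""

from __future__ import annotations

import numpy as np
import dendropy

__all__ = ["tip_labels", "brownian_vcv", "is_ultrametric"]


def tip_labels(tree: dendropy.Tree) -> list[str]:
    """Taxon labels of the tree's leaves, in leaf-iteration order."""
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def brownian_vcv(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Brownian-motion variance-covariance matrix of the tree's tips.

    Returns ``(labels, V)`` where ``V[i, j]`` is the shared root-to-MRCA
    path length of tips i and j (their depth on the diagonal), in the
    tree's branch-length units.
    """
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    n = len(leaves)
    index = {id(lf): i for i, lf in enumerate(leaves)}

    # root-to-node depth for every node
    depth: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        edge = node.edge.length or 0.0
        parent = node.parent_node
        depth[id(node)] = edge + (depth[id(parent)] if parent is not None else 0.0)

    V = np.zeros((n, n))
    # postorder: collect descendant-tip index sets; cross-child pairs share
    # the internal node as MRCA
    tipsets: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[id(node)]
            tipsets[id(node)] = np.array([i], dtype=np.intp)
            V[i, i] = depth[id(node)]
            continue
        child_sets = [tipsets.pop(id(c)) for c in node.child_nodes()]
        d = depth[id(node)]
        for a in range(len(child_sets)):
            for b in range(a + 1, len(child_sets)):
                ia, ib = child_sets[a], child_sets[b]
                V[np.ix_(ia, ib)] = d
                V[np.ix_(ib, ia)] = d
        tipsets[id(node)] = np.concatenate(child_sets)
    return labels, V


def is_ultrametric(tree: dendropy.Tree, rel_tol: float = 1e-6) -> bool:
    """True if all root-to-tip distances agree to relative tolerance."""
    _, V = brownian_vcv(tree)
    depths = np.diag(V)
    span = depths.max() - depths.min()
    return bool(span <= rel_tol * max(depths.max(), 1e-300))
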