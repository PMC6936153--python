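"""Neighbor-joining tree construction, midpoint rooting and node depths.

The genome tree is built from the Dice distance matrix with the classic
Saitou-Nei neighbor-joining algorithm and midpoint rooted.  Node *depth* is
the cumulative branch length from the root; the lineage classification
selects clades by a minimum depth, so deeper nodes group more closely
related genomes.

Determinism: the distance matrix is always fed with lexicographically
sorted genome IDs, so tie-breaking in the join criterion is reproducible
across platforms.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

__all__ = [
    "neighbor_joining",
    "midpoint_root",
    "annotate_depths",
    "build_tree",
    "rooted_clades",
    "write_newick",
    "read_newick",
    "depth_table",
]


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei NJ on a symmetric distance matrix (>= 3 taxa).

    Negative branch lengths (possible on non-additive input) are clamped to
    zero.  Input IDs are sorted before joining so that output is
    deterministic.
    """
    if dm.shape[0] < 3:
        raise ValueError(f"neighbor joining needs >= 3 taxa, got {dm.shape[0]}")
    ids = sorted(dm.ids)
    dm = dm.filter(ids)
    if not np.allclose(dm.data, dm.data.T):
        raise ValueError("distance matrix is not symmetric")
    return nj(dm, neg_as_zero=True)


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root at the midpoint of the longest tip-to-tip path.

    The two root-adjacent branches sum to the length of the original edge
    the midpoint falls on.  A tree whose branch lengths are all zero is
    rooted at an arbitrary edge (skbio picks deterministically).
    """
    tips = list(tree.tips())
    if len(tips) == 2:
        half = sum((t.length or 0.0) for t in tips) / 2.0
        root = TreeNode(name=None)
        root.extend([TreeNode(name=t.name, length=half) for t in tips])
        return root
    rooted = tree.root_at_midpoint(reset=True)
    for node in rooted.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return rooted


def annotate_depths(tree: TreeNode) -> TreeNode:
    """Assign ``node.depth`` (root-path branch-length sum) to every node.

    Also names unnamed internal nodes ``N0, N1, ...`` in preorder so that
    robustness and lineage tables can refer to them.
    """
    counter = 0
    for node in tree.preorder():
        if node.is_root():
            node.depth = 0.0
        else:
            node.depth = node.parent.depth + (node.length or 0.0)
        if not node.is_tip() and not node.name:
            node.name = f"N{counter}"
        counter += 1
    return tree


def build_tree(dm: DistanceMatrix) -> TreeNode:
    """NJ + midpoint rooting + depth annotation in one call."""
    return annotate_depths(midpoint_root(neighbor_joining(dm)))


def rooted_clades(tree: TreeNode) -> set[frozenset]:
    """The leaf-label set of every node (tips included) of a rooted tree."""
    out: set[frozenset] = set()
    for node in tree.postorder():
        if node.is_tip():
            node._leafset = frozenset([node.name])
        else:
            s = frozenset().union(*(c._leafset for c in node.children))
            node._leafset = s
        out.add(node._leafset)
    return out


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def depth_table(tree: TreeNode):
    """Per-node TSV-ready rows: ``node_id, depth, n_leaves``."""
    import pandas as pd

    rows = []
    for node in tree.preorder():
        n_leaves = node.count(tips=True) or 1
        rows.append((node.name, getattr(node, "depth", float("nan")), n_leaves))
    return pd.DataFrame(rows, columns=["node_id", "depth", "n_leaves"])
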