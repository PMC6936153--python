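"""Lineage extraction from the rooted genome tree, calibration, robustness.

A *lineage* is a maximal monophyletic clade whose defining node satisfies a
per-level rule: node depth (root-path branch length) at least ``min_depth``
and at least ``min_size`` member genomes.  Maximality — no ancestor also
satisfies the rule — makes the lineages of one level pairwise disjoint;
because deeper cutoffs select descendant nodes, lineages across levels are
nested or disjoint.

Depth cutoffs are calibrated by scanning a grid and scoring each candidate
partition against a reference taxonomy with the (plain) Rand index.
Robustness of the tree nodes is quantified by removing the hits of a random
fraction of proteins, rebuilding the tree, and counting how often each
original clade reappears.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .distance import bitscore_sums, dice_matrix
from .hits import HitTable
from .tree import annotate_depths, build_tree, rooted_clades

__all__ = [
    "LineageRule",
    "LineagePartition",
    "DEFAULT_RULES",
    "extract_lineages",
    "rand_index",
    "calibrate_cutoff",
    "resample_robustness",
    "sensitivity_sweep",
]


@dataclass(frozen=True)
class LineageRule:
    """Per-level clade-selection rule."""

    level: int
    min_depth: float
    min_size: int

    def __post_init__(self) -> None:
        if self.min_depth <= 0:
            raise ValueError("min_depth must be > 0")
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")


#: Published defaults: level 1 ~ family (depth 0.0014, >=20 genomes),
#: level 2 ~ subfamily (0.0056, >=3), level 3 ~ genus (0.0189, >=3).
DEFAULT_RULES: tuple[LineageRule, ...] = (
    LineageRule(1, 0.0014, 20),
    LineageRule(2, 0.0056, 3),
    LineageRule(3, 0.0189, 3),
)


@dataclass
class LineagePartition:
    """Disjoint lineages of one level plus the unassigned remainder."""

    level: int
    lineages: dict[str, tuple[str, frozenset]] = field(default_factory=dict)
    unassigned: frozenset = frozenset()

    def as_labels(self) -> dict[str, str]:
        """``genome_id -> lineage_id`` over assigned genomes only."""
        return {g: lid for lid, (_, members) in self.lineages.items() for g in members}

    @property
    def n_assigned(self) -> int:
        return sum(len(m) for _, m in self.lineages.values())


def extract_lineages(tree: TreeNode, rule: LineageRule) -> LineagePartition:
    """Maximal qualifying clades under ``rule``.

    The tree must carry ``depth`` annotations (see
    :func:`gluvab.tree.annotate_depths`).  A node defines a lineage iff its
    depth and leaf count meet the rule and no ancestor does; descending
    stops at the first qualifying node, so lineages are disjoint.
    """
    rooted_clades(tree)  # caches node._leafset
    lineages: dict[str, tuple[str, frozenset]] = {}
    assigned: set = set()
    stack = [tree]
    idx = 0
    while stack:
        node = stack.pop()
        depth = getattr(node, "depth", None)
        if depth is None:
            raise ValueError("tree nodes lack depth annotations; call annotate_depths first")
        members = node._leafset
        if depth >= rule.min_depth and len(members) >= rule.min_size:
            idx += 1
            lineages[f"L{rule.level}_{idx:03d}"] = (node.name or "", members)
            assigned.update(members)
            continue
        stack.extend(reversed(node.children))
    all_leaves = tree._leafset
    return LineagePartition(rule.level, lineages, frozenset(all_leaves - assigned))


def rand_index(
    p1: Mapping[str, str], p2: Mapping[str, str], *, adjusted: bool = False
) -> float:
    """(Adjusted) Rand index of two partitions given as element -> label maps.

    Restricted to elements present in both; fewer than two common elements
    is undefined and raises.  The plain index is the fraction of element
    pairs on which the partitions agree (co-clustered in both or separated
    in both).
    """
    common = sorted(set(p1) & set(p2))
    n = len(common)
    if n < 2:
        raise ValueError(f"Rand index undefined for {n} common element(s)")
    cont: Counter[tuple[str, str]] = Counter((p1[e], p2[e]) for e in common)
    a_sums: Counter[str] = Counter()
    b_sums: Counter[str] = Counter()
    for (la, lb), c in cont.items():
        a_sums[la] += c
        b_sums[lb] += c
    sum_ij = sum(math.comb(c, 2) for c in cont.values())
    sum_a = sum(math.comb(c, 2) for c in a_sums.values())
    sum_b = sum(math.comb(c, 2) for c in b_sums.values())
    pairs = math.comb(n, 2)
    if adjusted:
        expected = sum_a * sum_b / pairs
        max_index = (sum_a + sum_b) / 2
        if max_index == expected:
            return 1.0
        return (sum_ij - expected) / (max_index - expected)
    agree = pairs + 2 * sum_ij - sum_a - sum_b  # a + d
    return agree / pairs


def calibrate_cutoff(
    tree: TreeNode,
    reference: Mapping[str, str],
    min_size: int = 3,
    lo: float = 0.0001,
    hi: float = 0.2,
    step: float = 0.0001,
) -> tuple[float, pd.DataFrame]:
    """Scan depth cutoffs and score each against a reference taxonomy.

    ``reference`` maps genome IDs to taxon labels at one rank; unlabeled or
    unassigned genomes are excluded from each cutoff's Rand computation.
    Returns the argmax cutoff (ties: smallest) and the full score table
    (``cutoff, n_lineages, n_assigned, rand_index``); cutoffs where fewer
    than two labeled genomes are assigned score NaN.
    """
    if len(reference) == 0:
        raise ValueError("reference taxonomy has no labeled genomes")
    n_points = int(math.floor((hi - lo) / step + 1e-9)) + 1
    rows = []
    for i in range(n_points):
        cutoff = lo + i * step
        part = extract_lineages(tree, LineageRule(0, cutoff, min_size))
        labels = part.as_labels()
        common = set(labels) & set(reference)
        if len(common) < 2:
            score = float("nan")
        else:
            score = rand_index({g: labels[g] for g in common}, reference)
        rows.append((cutoff, len(part.lineages), part.n_assigned, score))
    table = pd.DataFrame(rows, columns=["cutoff", "n_lineages", "n_assigned", "rand_index"])
    if table["rand_index"].isna().all():
        raise ValueError("no cutoff assigned >= 2 labeled genomes; cannot calibrate")
    best = float(table.loc[table["rand_index"].idxmax(), "cutoff"])
    return best, table


def _resampled_tree(
    hit_table: HitTable,
    drop: set[str],
    ids: Sequence[str],
) -> TreeNode | None:
    """Tree rebuilt after removing all hits touching ``drop`` proteins.

    Returns None when some genome loses every self-hit (AA = 0), signalling
    the caller to redraw.
    """
    d = hit_table.df
    keep = ~(d["query"].isin(drop) | d["subject"].isin(drop))
    sub = HitTable(d[keep], hit_table.protein_to_genome, hit_table.protein_counts)
    try:
        sums = bitscore_sums(sub)
        dm = dice_matrix(sums, ids=list(ids))
    except ValueError:
        return None
    return build_tree(dm)


def resample_robustness(
    hit_table: HitTable,
    protein_ids: Sequence[str],
    tree: TreeNode,
    frac: float = 0.05,
    iterations: int = 100,
    seed: int = 0,
) -> dict[str, float]:
    """Node recovery frequencies under random protein removal.

    Per iteration, ``frac`` of all protein IDs are drawn without
    replacement and every hit whose query or subject was drawn is removed
    (dropping f of the proteins removes about 2f of the matches); the Dice
    matrix and midpoint-rooted tree are then rebuilt.  A node of the
    original tree is recovered iff its exact leaf-label set occurs as a
    clade of the resampled tree.  Iterations in which a genome loses all
    self-hits are redrawn from a fresh substream.
    """
    if not (0.0 < frac < 1.0):
        raise ValueError(f"frac must be in (0, 1), got {frac}")
    protein_ids = sorted(protein_ids)
    k = int(frac * len(protein_ids))
    annotate_depths(tree)
    rooted_clades(tree)
    node_sets = {n.name: n._leafset for n in tree.traverse()}
    ids = sorted(n.name for n in tree.tips())
    recovered: Counter[str] = Counter()
    for it in range(iterations):
        for attempt in range(100):
            rng = np.random.default_rng([seed % (2**31), it, attempt])
            drop = set(rng.choice(protein_ids, size=k, replace=False)) if k else set()
            new_tree = _resampled_tree(hit_table, drop, ids)
            if new_tree is not None:
                break
        else:
            raise RuntimeError(f"iteration {it}: could not draw a resample with all AA > 0")
        new_clades = rooted_clades(new_tree)
        for name, leafset in node_sets.items():
            if leafset in new_clades:
                recovered[name] += 1
    return {name: recovered[name] / iterations for name in node_sets}


def sensitivity_sweep(
    hit_table: HitTable,
    protein_ids: Sequence[str],
    tree: TreeNode,
    frac_list: Iterable[float] = (0.01, 0.05, 0.10, 0.20),
    iterations: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Recovery per node for several removal fractions.

    One row per original-tree node: ``node_id, depth, height, n_leaves``
    plus a ``recovery_<pct>`` column per fraction.  Height is the maximum
    branch-length sum from the node down to any of its tips.
    """
    annotate_depths(tree)
    heights: dict[str, float] = {}
    for node in tree.postorder():
        if node.is_tip():
            heights[node.name] = 0.0
            node._height = 0.0
        else:
            h = max(c._height + (c.length or 0.0) for c in node.children)
            heights[node.name] = h
            node._height = h
    rooted_clades(tree)
    rows = {
        n.name: {
            "node_id": n.name,
            "depth": n.depth,
            "height": heights[n.name],
            "n_leaves": len(n._leafset),
        }
        for n in tree.traverse()
    }
    for j, frac in enumerate(frac_list):
        freq = resample_robustness(
            hit_table, protein_ids, tree, frac=frac, iterations=iterations, seed=seed + j
        )
        col = f"recovery_{round(100 * frac):d}"
        for name, f in freq.items():
            rows[name][col] = f
    return pd.DataFrame(list(rows.values()))
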