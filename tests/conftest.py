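"""Shared fixtures: the default synthetic community and derived artifacts."""

import numpy as np
import pytest

from gluvab.distance import dice_from_hits
from gluvab.hits import PROFILES, HitTable
from gluvab.synth import generate_community
from gluvab.tree import build_tree


@pytest.fixture(scope="session")
def bundle():
    return generate_community()


@pytest.fixture(scope="session")
def hit_table(bundle):
    return bundle.hit_table()


@pytest.fixture(scope="session")
def dice(bundle, hit_table):
    return dice_from_hits(hit_table, ids=bundle.tree_genomes)


@pytest.fixture(scope="session")
def community_tree(dice):
    return build_tree(dice)


@pytest.fixture(scope="session")
def marker_table(bundle):
    return (
        HitTable(bundle.marker_hits)
        .filter(PROFILES["marker_search"])
        .with_genomes(bundle.protein_map, subjects_are_proteins=False)
    )


@pytest.fixture(scope="session")
def tree_protein_ids(bundle):
    viral = set(bundle.tree_genomes)
    return sorted(p for p, g in bundle.protein_map.items() if g in viral)


def random_additive_tree(rng: np.random.Generator, n_taxa: int):
    """Random binary tree with positive branch lengths, plus its path metric.

    Built by sequential random attachment; used as the independent oracle
    for neighbor joining (an additive matrix determines its tree uniquely).
    """
    from skbio import TreeNode

    names = [f"t{i}" for i in range(n_taxa)]
    root = TreeNode(name=None)
    a = TreeNode(name=names[0], length=float(rng.uniform(0.1, 1.0)))
    b = TreeNode(name=names[1], length=float(rng.uniform(0.1, 1.0)))
    root.extend([a, b])
    tips = [a, b]
    for name in names[2:]:
        target = tips[int(rng.integers(len(tips)))]
        # split target's edge and hang the new tip off the split point
        parent = target.parent
        split = TreeNode(name=None, length=float(target.length) * float(rng.uniform(0.2, 0.8)))
        target.length = float(target.length) - split.length
        parent.remove(target)
        split.append(target)
        new_tip = TreeNode(name=name, length=float(rng.uniform(0.1, 1.0)))
        split.append(new_tip)
        parent.append(split)
        tips.append(new_tip)
    dm = root.tip_tip_distances()
    return root, dm
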