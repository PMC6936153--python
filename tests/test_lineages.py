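"""Lineage extraction, Rand index, calibration and robustness resampling."""

import io
import itertools
import math

import numpy as np
import pytest
from skbio import TreeNode

from gluvab.lineages import (
    LineageRule,
    calibrate_cutoff,
    extract_lineages,
    rand_index,
    resample_robustness,
    sensitivity_sweep,
)
from gluvab.tree import annotate_depths


def _two_clade_tree(n_per_clade=20, split_depth=0.5, tip_extra=0.5):
    """Ultrametric: root -> two clades at ``split_depth`` -> combs of tips."""
    def comb(prefix, n):
        # ladder of zero-length internal edges keeps the tree binary
        node = TreeNode(name=None, length=split_depth)
        current = node
        for i in range(n - 1):
            tip = TreeNode(name=f"{prefix}{i}", length=tip_extra)
            if i == n - 2:
                last = TreeNode(name=f"{prefix}{i + 1}", length=tip_extra)
                current.extend([tip, last])
            else:
                nxt = TreeNode(name=None, length=0.0)
                current.extend([tip, nxt])
                current = nxt
        return node

    root = TreeNode(name=None)
    root.extend([comb("a", n_per_clade), comb("b", n_per_clade)])
    return annotate_depths(root)


class TestExtractLineages:
    def test_two_planted_clades(self):
        tree = _two_clade_tree()
        part = extract_lineages(tree, LineageRule(1, 0.0014, 20))
        assert len(part.lineages) == 2
        sizes = sorted(len(m) for _, m in part.lineages.values())
        assert sizes == [20, 20]
        assert not part.unassigned

    def test_min_size_above_clades(self):
        tree = _two_clade_tree()
        part = extract_lineages(tree, LineageRule(1, 0.0014, 21))
        assert len(part.lineages) == 0
        assert len(part.unassigned) == 40

    def test_cutoff_above_max_depth(self):
        tree = _two_clade_tree()
        max_depth = max(x.depth for x in tree.tips())
        part = extract_lineages(tree, LineageRule(1, max_depth + 1, 1))
        assert not part.lineages and len(part.unassigned) == 40

    def test_members_equal_defining_node_leafsets(self, community_tree, bundle):
        for rule in bundle.suggested_rules:
            part = extract_lineages(community_tree, rule)
            nodes = {n.name: n for n in community_tree.traverse()}
            for lid, (node_id, members) in part.lineages.items():
                leafset = frozenset(x.name for x in nodes[node_id].tips())
                assert members == leafset

    def test_oracle_agreement_random_trees(self):
        """Exhaustive node-scan oracle on 100 random rooted trees."""
        from conftest import random_additive_tree

        rng = np.random.default_rng(11)
        for _ in range(100):
            tree, _ = random_additive_tree(rng, int(rng.integers(4, 15)))
            annotate_depths(tree)
            cutoff = float(rng.uniform(0.1, 1.5))
            min_size = int(rng.integers(1, 4))
            part = extract_lineages(tree, LineageRule(1, cutoff, min_size))
            # oracle: nodes qualifying with no qualifying ancestor
            expected = []
            for node in tree.traverse():
                leaves = frozenset(x.name for x in node.tips()) or frozenset([node.name])
                if node.depth >= cutoff and len(leaves) >= min_size:
                    anc_ok = any(
                        a.depth >= cutoff
                        and len(frozenset(x.name for x in a.tips()) or {a.name}) >= min_size
                        for a in node.ancestors()
                    )
                    if not anc_ok:
                        expected.append(leaves)
            got = sorted(m for _, m in part.lineages.values())
            assert sorted(expected) == got
            # disjointness
            for m1, m2 in itertools.combinations(got, 2):
                assert not (m1 & m2)

    def test_nestedness_across_levels(self, community_tree, bundle):
        parts = [extract_lineages(community_tree, r) for r in bundle.suggested_rules]
        for shallow, deep in ((0, 1), (1, 2)):
            for _, deep_members in parts[deep].lineages.values():
                for _, shallow_members in parts[shallow].lineages.values():
                    inter = deep_members & shallow_members
                    assert not inter or deep_members <= shallow_members

    def test_looser_rule_never_unassigns(self, community_tree):
        base = extract_lineages(community_tree, LineageRule(1, 0.05, 4))
        lower_depth = extract_lineages(community_tree, LineageRule(1, 0.01, 4))
        lower_size = extract_lineages(community_tree, LineageRule(1, 0.05, 2))
        assert lower_depth.n_assigned >= base.n_assigned
        assert lower_size.n_assigned >= base.n_assigned


def brute_force_rand(p1, p2):
    common = sorted(set(p1) & set(p2))
    agree = total = 0
    for a, b in itertools.combinations(common, 2):
        total += 1
        agree += (p1[a] == p1[b]) == (p2[a] == p2[b])
    return agree, total


class TestRandIndex:
    def test_identical_partitions(self):
        p = {"a": "x", "b": "x", "c": "y"}
        assert rand_index(p, dict(p)) == 1.0

    def test_hand_computed_two_thirds(self):
        p1 = {"a": 1, "b": 1, "c": 2}
        p2 = {"a": 1, "b": 2, "c": 3}
        assert rand_index(p1, p2) == pytest.approx(2 / 3)

    def test_all_singletons(self):
        p = {c: c for c in "abcde"}
        assert rand_index(p, dict(p)) == 1.0

    def test_too_few_common(self):
        with pytest.raises(ValueError):
            rand_index({"a": 1}, {"a": 1})

    def test_pair_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            n = int(rng.integers(2, 25))
            elems = [f"e{i}" for i in range(n)]
            p1 = {e: int(rng.integers(1, 5)) for e in elems}
            p2 = {e: int(rng.integers(1, 5)) for e in elems}
            agree, total = brute_force_rand(p1, p2)
            # exact rational comparison
            assert rand_index(p1, p2) == agree / total

    def test_matches_sklearn(self):
        from sklearn.metrics import rand_score

        rng = np.random.default_rng(6)
        for _ in range(50):
            n = int(rng.integers(5, 40))
            l1 = rng.integers(0, 6, size=n)
            l2 = rng.integers(0, 6, size=n)
            mine = rand_index(
                {i: int(v) for i, v in enumerate(l1)},
                {i: int(v) for i, v in enumerate(l2)},
            )
            assert mine == pytest.approx(rand_score(l1, l2), abs=1e-12)

    def test_adjusted_matches_sklearn(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(5, 40))
            l1 = rng.integers(0, 5, size=n)
            l2 = rng.integers(0, 5, size=n)
            mine = rand_index(
                {i: int(v) for i, v in enumerate(l1)},
                {i: int(v) for i, v in enumerate(l2)},
                adjusted=True,
            )
            assert mine == pytest.approx(adjusted_rand_score(l1, l2), abs=1e-12)


class TestCalibration:
    def test_planted_truth_reaches_rand_one(self, community_tree, bundle):
        reference = bundle.truth_labels(1)
        best, table = calibrate_cutoff(
            community_tree, reference, min_size=2, lo=0.02, hi=0.0699, step=0.0001
        )
        best_score = table.loc[table["cutoff"].sub(best).abs().idxmin(), "rand_index"]
        assert best_score == 1.0

    def test_grid_row_count(self, community_tree, bundle):
        _, table = calibrate_cutoff(
            community_tree, bundle.truth_labels(1), min_size=2, lo=0.01, hi=0.05, step=0.001
        )
        assert len(table) == math.floor((0.05 - 0.01) / 0.001) + 1

    def test_degenerate_single_taxon_reference(self, community_tree, bundle):
        # all labeled genomes share one taxon and sit inside one clade: any
        # cutoff keeping them co-clustered maximises the Rand index at 1.0
        reference = {
            g: "everything" for g, lab in bundle.truth_labels(1).items() if lab == "l1_1"
        }
        best, table = calibrate_cutoff(
            community_tree, reference, min_size=2, lo=0.0005, hi=0.01, step=0.0005
        )
        row = table.loc[table["cutoff"].sub(best).abs().idxmin()]
        assert row["rand_index"] == 1.0

    def test_empty_reference_error(self, community_tree):
        with pytest.raises(ValueError):
            calibrate_cutoff(community_tree, {})


class TestRobustness:
    def test_tiny_frac_full_recovery(self, bundle, hit_table, community_tree, tree_protein_ids):
        freq = resample_robustness(
            hit_table, tree_protein_ids, community_tree,
            frac=1e-6, iterations=3, seed=0,
        )
        assert all(v == 1.0 for v in freq.values())

    def test_leaves_always_recovered(self, bundle, hit_table, community_tree, tree_protein_ids):
        freq = resample_robustness(
            hit_table, tree_protein_ids, community_tree,
            frac=0.05, iterations=5, seed=0,
        )
        for tip in community_tree.tips():
            assert freq[tip.name] == 1.0

    def test_invalid_frac(self, hit_table, community_tree, tree_protein_ids):
        for bad in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                resample_robustness(hit_table, tree_protein_ids, community_tree, frac=bad)

    def test_sweep_schema(self, hit_table, community_tree, tree_protein_ids):
        table = sensitivity_sweep(
            hit_table, tree_protein_ids, community_tree,
            frac_list=(0.05,), iterations=2, seed=0,
        )
        n_nodes = sum(1 for _ in community_tree.traverse())
        assert len(table) == n_nodes
        assert {"node_id", "depth", "height", "n_leaves", "recovery_5"} <= set(table.columns)
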