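"""Abundance aggregation, prevalence, rarefaction and OG pan-genomes."""

import numpy as np
import pandas as pd
import pytest

from gluvab.lineages import LineagePartition
from gluvab.profile import (
    UNASSIGNED,
    lineage_abundance,
    og_prevalence,
    prevalence,
    rarefaction,
    read_counts,
)


def _partition(groups: dict, unassigned=()):
    return LineagePartition(
        1,
        {lid: ("", frozenset(members)) for lid, members in groups.items()},
        frozenset(unassigned),
    )


class TestAbundance:
    def test_single_lineage_sums_to_hundred(self):
        counts = pd.DataFrame({"x": [30], "y": [70]}, index=["s1"])
        ab = lineage_abundance(counts, _partition({"L": {"x", "y"}}))
        assert ab.loc["s1", "L"] == pytest.approx(100.0)
        assert ab.loc["s1", UNASSIGNED] == 0.0

    def test_unassigned_bucket(self):
        counts = pd.DataFrame({"x": [30], "y": [70]}, index=["s1"])
        ab = lineage_abundance(counts, _partition({"L": {"x"}}, unassigned={"y"}))
        assert ab.loc["s1", "L"] == pytest.approx(30.0)
        assert ab.loc["s1", UNASSIGNED] == pytest.approx(70.0)

    def test_empty_partition_all_unassigned(self):
        counts = pd.DataFrame({"x": [10], "y": [90]}, index=["s1"])
        ab = lineage_abundance(counts, _partition({}, unassigned={"x", "y"}))
        assert ab.loc["s1", UNASSIGNED] == pytest.approx(100.0)

    def test_rows_close_to_hundred(self, bundle, community_tree):
        from gluvab.lineages import extract_lineages

        part = extract_lineages(community_tree, bundle.suggested_rules[0])
        counts = read_counts_df(bundle)
        ab = lineage_abundance(counts, part)
        assert np.allclose(ab.sum(axis=1), 100.0, atol=1e-9)

    def test_zero_total_sample_warns(self):
        counts = pd.DataFrame({"x": [0, 5]}, index=["empty", "ok"])
        with pytest.warns(UserWarning, match="zero mapped"):
            ab = lineage_abundance(counts, _partition({"L": {"x"}}))
        assert ab.loc["empty"].sum() == 0.0


def read_counts_df(bundle):
    wide = bundle.counts.pivot_table(
        index="sample", columns="genome_id", values="reads", fill_value=0
    )
    return wide.astype(int)


class TestPrevalence:
    def test_unlabeled_excluded_from_denominator(self):
        part = _partition({"L": {f"g{i}" for i in range(10)}})
        meta = {f"g{i}": "Proteobacteria" for i in range(5)}  # 5 unlabeled
        out = prevalence(part, meta)
        row = out[(out.lineage == "L") & (out.label == "Proteobacteria")]
        assert row["pct"].iloc[0] == pytest.approx(100.0)

    def test_uniform_label(self):
        part = _partition({"L": {"a", "b", "c"}})
        out = prevalence(part, {"a": "aquatic", "b": "aquatic", "c": "aquatic"})
        assert out["pct"].tolist() == [pytest.approx(100.0)]

    def test_rare_labels_merged_into_other(self):
        members = {f"g{i}" for i in range(200)}
        meta = {g: "common" for g in members}
        meta["g0"] = "rare"  # 0.5% < 1%
        out = prevalence(_partition({"L": members}), meta)
        assert set(out["label"]) == {"common", "other"}

    def test_percentages_sum_to_hundred(self, bundle, community_tree):
        from gluvab.lineages import extract_lineages

        part = extract_lineages(community_tree, bundle.suggested_rules[0])
        meta = bundle.truth.set_index("genome_id")["host_phylum"].dropna().to_dict()
        meta = {g: v for g, v in meta.items() if v}
        out = prevalence(part, meta, min_frac=0.0)
        for lid, grp in out.groupby("lineage"):
            assert grp["pct"].sum() == pytest.approx(100.0)

    def test_planted_single_host_lineages_pure(self, bundle, community_tree):
        from gluvab.lineages import extract_lineages

        part = extract_lineages(community_tree, bundle.suggested_rules[0])
        meta = {g: v for g, v in
                bundle.truth.set_index("genome_id")["host_phylum"].dropna().items() if v}
        out = prevalence(part, meta)
        # each level-1 lineage was planted with exactly one host phylum
        for lid, grp in out.groupby("lineage"):
            assert len(grp) == 1 and grp["pct"].iloc[0] == pytest.approx(100.0)


class TestRarefaction:
    def test_full_depth_equals_true_count(self):
        ecos = {f"g{i}": "aquatic" for i in range(10)}
        lin = {f"g{i}": f"L{i % 3}" for i in range(10)}
        out = rarefaction(ecos, lin, grid=[10], draws=5, seed=0)
        assert out["mean"].iloc[0] == 3.0 and out["sd"].iloc[0] == 0.0

    def test_single_draw_with_unassigned(self):
        ecos = {"a": "x", "b": "x"}
        lin = {"a": "L1"}  # b unassigned
        out = rarefaction(ecos, lin, grid=[1], draws=400, seed=1)
        assert 0.0 < out["mean"].iloc[0] < 1.0

    def test_curves_nondecreasing(self, bundle, community_tree):
        from gluvab.lineages import extract_lineages

        part = extract_lineages(community_tree, bundle.suggested_rules[0])
        truth = bundle.truth[bundle.truth.role == "tree"].set_index("genome_id")
        ecos = {g: e for g, e in truth["ecosystem"].items() if e}
        out = rarefaction(ecos, part.as_labels(), grid=[1, 2, 5, 10, 50], draws=50, seed=2)
        for eco, grp in out.groupby("ecosystem"):
            means = grp.sort_values("n")["mean"].tolist()
            assert means == sorted(means)

    def test_draws_validation(self):
        with pytest.raises(ValueError):
            rarefaction({"a": "x"}, {}, grid=[1], draws=0)


class TestOgPrevalence:
    def _setup(self, og_spread):
        """og_spread: {og: {lineage: n_genomes_detected}}"""
        part_groups, og_map, pmap = {}, {}, {}
        for lid in {l for spread in og_spread.values() for l in spread}:
            part_groups[lid] = {f"{lid}_g{i}" for i in range(5)}
        for og, spread in og_spread.items():
            for lid, n in spread.items():
                for i in range(n):
                    pid = f"{og}_{lid}_p{i}"
                    og_map[pid] = og
                    pmap[pid] = f"{lid}_g{i}"
        for lid, members in part_groups.items():
            for g in members:
                pmap.setdefault(f"{g}_self", g)
        return og_map, pmap, _partition(part_groups)

    def test_three_members_one_lineage_not_promiscuous(self):
        og_map, pmap, part = self._setup({"OG1": {"A": 3}})
        out = og_prevalence(og_map, pmap, part)
        assert out["lineage"].tolist() == ["A"]
        assert not out["promiscuous"].any()

    def test_three_lineages_promiscuous(self):
        og_map, pmap, part = self._setup({"OG1": {"A": 3, "B": 4, "C": 3}})
        out = og_prevalence(og_map, pmap, part)
        assert out["promiscuous"].all() and len(out) == 3

    def test_two_members_everywhere_absent(self):
        og_map, pmap, part = self._setup({"OG1": {"A": 2, "B": 2, "C": 2}})
        out = og_prevalence(og_map, pmap, part)
        assert out.empty

    def test_unclassified_proteins_tallied(self):
        og_map = {"p1": "OG1"}
        pmap = {"p1": "mystery_genome"}
        out = og_prevalence(og_map, pmap, _partition({"A": {"a1"}}))
        assert out.attrs["n_skipped"] == 1

    def test_planted_promiscuous_slots(self, bundle, community_tree):
        from gluvab.lineages import extract_lineages

        part = extract_lineages(community_tree, bundle.suggested_rules[0])
        out = og_prevalence(bundle.og_membership, bundle.protein_map, part)
        shared = {og for og in out.attrs["promiscuous_ogs"]}
        # the generator plants shared OG slots across all level-1 lineages
        expected = {f"OG_shared_{k + 1}" for k in range(bundle.spec.n_promiscuous_slots)}
        assert shared == expected
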