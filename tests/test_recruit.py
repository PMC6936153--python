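"""Viral recruitment: AVQ scoring, two recruitment rounds, completeness."""

import pandas as pd
import pytest

from gluvab.hits import HIT_COLUMNS, PROFILES, HitTable
from gluvab.recruit import (
    detect_terminal_overlap,
    prune_marker_db,
    recruit_round1,
    recruit_round2,
    score_avq,
    tag_completeness,
)


def _table(rows):
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def _row(q, s, ident=50.0, length=100, evalue=1e-10, bitscore=100.0):
    return [q, s, ident, length, 10, 0, 1, length, 1, length, evalue, bitscore]


class TestMarkerPruning:
    def test_decoy_markers_removed(self):
        markers = {f"m{i}": 1.0 for i in range(100)}
        decoy = HitTable(_table([_row("euk_1", f"m{i}") for i in range(10)]))
        assert len(prune_marker_db(markers, decoy)) == 90

    def test_no_decoys_identity(self):
        markers = {"m1": 0.5, "m2": 1.0}
        assert prune_marker_db(markers, HitTable(_table([]))) == markers

    def test_all_pruned_warns(self):
        markers = {"m1": 1.0}
        decoy = HitTable(_table([_row("e_1", "m1")]))
        with pytest.warns(UserWarning):
            assert prune_marker_db(markers, decoy) == {}


class TestAvq:
    def test_unit_quotients_pass_round1(self):
        markers = {f"m{i}": 1.0 for i in range(5)}
        hits = HitTable(_table([_row(f"g_{i}", f"m{i}") for i in range(5)]))
        pct, avq = score_avq("g", hits, markers, n_proteins=10)
        assert (pct, avq) == (50.0, 5.0)
        assert recruit_round1({"g": (pct, avq)}) == {"g"}

    def test_fractional_quotients_fail_avq(self):
        vqs = [1.0, 1.0, 1.0, 0.9, 0.8]
        markers = {f"m{i}": vq for i, vq in enumerate(vqs)}
        hits = HitTable(_table([_row(f"g_{i}", f"m{i}") for i in range(5)]))
        pct, avq = score_avq("g", hits, markers, n_proteins=10)
        assert pct == 50.0 and avq == pytest.approx(4.7)
        assert recruit_round1({"g": (pct, avq)}) == set()

    def test_best_hit_by_bitscore(self):
        markers = {"good": 1.0, "bad": 0.1}
        hits = HitTable(
            _table([_row("g_1", "bad", bitscore=80), _row("g_1", "good", bitscore=120)])
        )
        _, avq = score_avq("g", hits, markers, n_proteins=2)
        assert avq == 1.0

    def test_no_hits(self):
        assert score_avq("g", HitTable(_table([])), {"m": 1.0}, 4) == (0.0, 0.0)

    def test_zero_proteins_error(self):
        with pytest.raises(ValueError):
            score_avq("g", HitTable(_table([])), {}, 0)

    def test_round1_boundary_inclusive(self):
        assert recruit_round1({"g": (20.0, 5.0)}) == {"g"}
        assert recruit_round1({}) == set()

    def test_raising_cutoffs_never_grows_set(self):
        scores = {f"g{i}": (float(10 + 5 * i), float(i)) for i in range(10)}
        base = recruit_round1(scores, 20, 3)
        assert recruit_round1(scores, 30, 3) <= base
        assert recruit_round1(scores, 20, 5) <= base


def _indexed(rows, pmap):
    return HitTable(_table(rows)).with_genomes(pmap)


class TestRound2:
    def _pmap(self, cand_n=10):
        pmap = {f"c_{i}": "cand" for i in range(1, cand_n + 1)}
        pmap.update({f"x_{i}": "X" for i in range(1, 6)})
        pmap.update({f"y_{i}": "Y" for i in range(1, 6)})
        return pmap

    def test_two_matches_insufficient(self):
        ht = _indexed([_row(f"c_{i}", f"x_{i}") for i in (1, 2)], self._pmap())
        assert recruit_round2(ht, {"X", "Y"}) == {}

    def test_three_matches_recruit(self):
        ht = _indexed([_row(f"c_{i}", f"x_{i}") for i in (1, 2, 3)], self._pmap())
        assert recruit_round2(ht, {"X", "Y"}) == {"cand": "X"}

    def test_split_across_anchors_fails(self):
        rows = [_row("c_1", "x_1"), _row("c_2", "x_2"), _row("c_3", "y_1"), _row("c_4", "y_2")]
        assert recruit_round2(_indexed(rows, self._pmap()), {"X", "Y"}) == {}

    def test_round1_members_not_candidates(self, bundle, hit_table):
        r1 = set(bundle.tree_genomes[:5])
        r2 = recruit_round2(hit_table, r1)
        assert not (set(r2) & r1)

    def test_rounds_disjoint_on_fixture(self, bundle, hit_table, marker_table):
        from gluvab.recruit import prune_marker_db

        markers = prune_marker_db(
            bundle.marker_db,
            HitTable(bundle.euk_decoy_marker_hits).filter(PROFILES["marker_search"]),
        )
        counts = {g: n for g, n in marker_table.protein_counts.items()}
        scores = {g: score_avq(g, marker_table, markers, counts[g]) for g in sorted(counts)}
        r1 = recruit_round1(scores)
        r2 = recruit_round2(hit_table, r1)
        assert not (r1 & set(r2))
        universe = set(bundle.protein_map.values())
        assert (r1 | set(r2)) <= universe


class TestCompleteness:
    def _pmap(self):
        pmap = {f"a_{i}": "A" for i in range(1, 11)}
        pmap.update({f"b_{i}": "B" for i in range(1, 11)})
        return pmap

    def test_seventy_percent_and_length(self):
        rows = [_row(f"a_{i}", f"b_{i}") for i in range(1, 8)]  # 7 of 10
        ht = _indexed(rows, self._pmap())
        assert tag_completeness({"A"}, ht, {"B": 12_000}) == {"B": "nearly_complete"}
        assert tag_completeness({"A"}, ht, {"B": 8_000}) == {"B": "partial"}

    def test_below_coverage(self):
        rows = [_row(f"a_{i}", f"b_{i}") for i in range(1, 7)]  # 6 of 10
        ht = _indexed(rows, self._pmap())
        assert tag_completeness({"A"}, ht, {"B": 12_000}) == {"B": "partial"}

    def test_missing_length_error(self):
        ht = _indexed([_row(f"a_{i}", f"b_{i}") for i in range(1, 8)], self._pmap())
        with pytest.raises(KeyError):
            tag_completeness({"A"}, ht, {})


class TestTerminalOverlap:
    def test_planted_repeat(self):
        import numpy as np

        rng = np.random.default_rng(7)
        core = "".join(rng.choice(list("ACGT"), size=2000))
        seq = core + core[:25]
        circ, ov = detect_terminal_overlap(seq)
        assert circ and ov == 25

    def test_random_sequence_linear(self):
        import numpy as np

        rng = np.random.default_rng(8)
        seq = "".join(rng.choice(list("ACGT"), size=5000))
        circ, _ = detect_terminal_overlap(seq)
        assert not circ

    def test_homopolymer_degenerate(self):
        circ, ov = detect_terminal_overlap("A" * 100)
        assert circ and ov == 99

    def test_short_sequence_warns(self):
        with pytest.warns(UserWarning):
            assert detect_terminal_overlap("ACGT" * 10, min_overlap=20) == (False, 0)
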