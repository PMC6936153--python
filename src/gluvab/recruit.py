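"""Recruitment of bona fide prokaryotic-virus sequences and completeness tags.

A sequence is considered a bona fide prokaryotic virus when its proteins
carry a strong signal against a database of viral-marker orthologous groups.
Each marker group has a *viral quotient* (VQ) in [0, 1]: the fraction of its
occurrences found in viral rather than cellular genomes.  Summing the VQ of
each protein's best marker hit gives the genome's *added viral quotient*
(AVQ).

Recruitment proceeds in two automatic rounds:

* round 1 — sequences with >= 20% of proteins matching markers and AVQ >= 5;
* round 2 — remaining sequences for which >= 20% of proteins best-map to a
  single round-1 genome, with at least three distinct protein matches.

Completeness: a sequence >= 10 kbp covering >= 70% of the proteins of some
complete genome is tagged nearly complete; exact terminal repeats flag
putative circular (complete) sequences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .hits import HitTable

__all__ = [
    "read_marker_db",
    "prune_marker_db",
    "score_avq",
    "recruit_round1",
    "recruit_round2",
    "tag_completeness",
    "detect_terminal_overlap",
    "RecruitmentReport",
    "build_report",
]


def read_marker_db(path: str | Path) -> dict[str, float]:
    """Read a marker database TSV ``marker_id<TAB>viral_quotient``."""
    db: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            marker, vq = parts[0], float(parts[1])
            if not (0.0 <= vq <= 1.0):
                raise ValueError(f"{path}:{lineno}: viral quotient {vq} outside [0, 1]")
            db[marker] = vq
    return db


def prune_marker_db(markers: Mapping[str, float], decoy_hits: HitTable) -> dict[str, float]:
    """Drop every marker matched by a decoy (eukaryotic-virus) protein.

    ``decoy_hits`` must already be filtered with the ``marker_search``
    profile; any marker appearing as a subject is excluded from AVQ scoring.
    """
    tainted = set(decoy_hits.df["subject"].unique())
    pruned = {m: vq for m, vq in markers.items() if m not in tainted}
    if not pruned and markers:
        warnings.warn("all markers were pruned by decoy hits; AVQ scores will be zero")
    return pruned


def _best_marker_hits(marker_hits: HitTable, markers: Mapping[str, float]) -> pd.DataFrame:
    """Best (highest-bitscore) marker hit per query protein.

    Hits to markers absent from ``markers`` (e.g. pruned ones) are ignored.
    Ties on bitscore break by lowest e-value, then lexicographic marker ID.
    """
    d = marker_hits.df
    d = d[d["subject"].isin(markers.keys())]
    if d.empty:
        return d
    d = d.sort_values(
        ["query", "bitscore", "evalue", "subject"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    return d.drop_duplicates("query", keep="first")


def score_avq(
    genome_id: str,
    marker_hits: HitTable,
    markers: Mapping[str, float],
    n_proteins: int,
) -> tuple[float, float]:
    """Return ``(pct_matched, avq)`` for one genome.

    ``marker_hits`` holds this genome's protein-vs-marker hits (already
    filtered with the ``marker_search`` profile, and with ``qgenome``
    attached if the table mixes genomes).  ``pct_matched`` is the percentage
    of the genome's ``n_proteins`` with at least one marker hit; ``avq`` sums
    the viral quotient of each matched protein's best hit.
    """
    if n_proteins < 1:
        raise ValueError(f"genome {genome_id!r}: n_proteins must be >= 1, got {n_proteins}")
    d = marker_hits.df
    if "qgenome" in d.columns:
        d = d[d["qgenome"] == genome_id]
    best = _best_marker_hits(HitTable(d), markers)
    if len(best) == 0:
        return 0.0, 0.0
    avq = float(sum(markers[m] for m in best["subject"]))
    pct = 100.0 * len(best) / n_proteins
    return pct, avq


def recruit_round1(
    scores: Mapping[str, tuple[float, float]],
    min_pct: float = 20.0,
    min_avq: float = 5.0,
) -> set[str]:
    """Genomes whose ``(pct_matched, avq)`` meet both inclusive cutoffs."""
    return {g for g, (pct, avq) in scores.items() if pct >= min_pct and avq >= min_avq}


def recruit_round2(
    candidate_hits: HitTable,
    round1: set[str],
    min_pct: float = 20.0,
    min_matches: int = 3,
) -> dict[str, str]:
    """Homology linkage of unrecruited candidates to round-1 genomes.

    ``candidate_hits`` are candidate-protein vs round-1-protein hits filtered
    with the ``standard`` profile and genome-indexed.  A candidate is
    recruited iff some single round-1 genome receives best hits from
    >= ``min_pct`` percent of its proteins (distinct proteins, not hit rows)
    and from >= ``min_matches`` distinct proteins.  Returns
    ``{candidate: anchor}``; the anchor is the qualifying genome with the
    most matched proteins (ties: highest summed bitscore, then lexicographic
    genome ID).
    """
    d = candidate_hits.df
    d = d[~d["qgenome"].isin(round1) & d["sgenome"].isin(round1)]
    out: dict[str, str] = {}
    if d.empty:
        return out
    # Best hit per (candidate protein, round-1 genome): a protein counts once
    # per potential anchor.
    per_anchor = (
        d.groupby(["qgenome", "sgenome"])
        .agg(n_prot=("query", "nunique"), bs=("bitscore", "sum"))
        .reset_index()
    )
    counts = candidate_hits.protein_counts
    for cand, grp in per_anchor.groupby("qgenome"):
        n_total = counts.get(cand)
        if n_total is None:
            raise KeyError(f"no protein count for candidate genome {cand!r}")
        ok = grp[(100.0 * grp["n_prot"] / n_total >= min_pct) & (grp["n_prot"] >= min_matches)]
        if ok.empty:
            continue
        ok = ok.sort_values(
            ["n_prot", "bs", "sgenome"], ascending=[False, False, True], kind="mergesort"
        )
        out[str(cand)] = str(ok.iloc[0]["sgenome"])
    return out


def tag_completeness(
    complete_ids: set[str],
    cross_hits: HitTable,
    lengths: Mapping[str, int],
    min_coverage: float = 70.0,
    min_length: int = 10_000,
) -> dict[str, str]:
    """Label non-complete genomes ``nearly_complete`` or ``partial``.

    ``cross_hits`` are complete-genome proteins (queries) vs candidate
    proteins (subjects), filtered with the ``standard`` profile and
    genome-indexed.  Candidate B is nearly complete iff some complete genome
    A has >= ``min_coverage`` percent of its proteins with a hit into B and
    B is at least ``min_length`` bp long.
    """
    d = cross_hits.df
    d = d[d["qgenome"].isin(complete_ids) & ~d["sgenome"].isin(complete_ids)]
    labels: dict[str, str] = {}
    counts = cross_hits.protein_counts
    candidates = set(d["sgenome"].unique())
    for cand in candidates:
        if cand not in lengths:
            raise KeyError(f"no sequence length for candidate genome {cand!r}")
    cov = (
        d.groupby(["sgenome", "qgenome"])["query"].nunique().reset_index(name="n_cov")
    )
    for _, row in cov.iterrows():
        a, b = row["qgenome"], row["sgenome"]
        n_a = counts.get(a)
        if n_a is None:
            raise KeyError(f"no protein count for complete genome {a!r}")
        if 100.0 * row["n_cov"] / n_a >= min_coverage and lengths[b] >= min_length:
            labels[str(b)] = "nearly_complete"
    for cand in candidates:
        labels.setdefault(str(cand), "partial")
    return labels


def detect_terminal_overlap(seq: str, min_overlap: int = 20) -> tuple[bool, int]:
    """Exact terminal-repeat detection for circularity.

    Returns ``(circular, overlap_len)`` where ``overlap_len`` is the longest
    proper prefix of ``seq`` that is also a suffix; circular iff that length
    is >= ``min_overlap``.  Degenerate case: a homopolymer of length n has
    overlap n - 1.  Sequences of length <= 2 * min_overlap give
    ``(False, 0)`` with a warning.
    """
    n = len(seq)
    if n <= 2 * min_overlap:
        warnings.warn(
            f"sequence of length {n} too short for terminal-overlap detection "
            f"(need > {2 * min_overlap})"
        )
        return False, 0
    # KMP failure function: pi[-1] = longest proper border of seq.
    pi = [0] * n
    k = 0
    for i in range(1, n):
        while k and seq[i] != seq[k]:
            k = pi[k - 1]
        if seq[i] == seq[k]:
            k += 1
        pi[i] = k
    overlap = pi[-1]
    return overlap >= min_overlap, overlap


# Completeness labels reserved for externally flagged sequences (manual
# curation, third-party viral predictors); the automatic rounds never emit
# them but report merging keeps them intact.
RESERVED_ROUNDS = ("manual", "external")


@dataclass
class RecruitmentReport:
    """Per-genome recruitment and completeness summary."""

    rows: pd.DataFrame = field(default_factory=pd.DataFrame)

    COLUMNS = (
        "genome_id",
        "pct_matched_markers",
        "avq",
        "recruited_round",
        "round2_anchor",
        "completeness",
        "circular",
    )

    def to_tsv(self, path: str | Path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)

    @property
    def recruited(self) -> set[str]:
        r = self.rows
        return set(r.loc[r["recruited_round"].isin(["1", "2"]), "genome_id"])


def build_report(
    scores: Mapping[str, tuple[float, float]],
    round1: set[str],
    round2: Mapping[str, str],
    completeness: Mapping[str, str],
    circular: Mapping[str, bool],
) -> RecruitmentReport:
    """Assemble the per-genome report from the stage outputs."""
    rows = []
    for g in sorted(scores):
        pct, avq = scores[g]
        if g in round1:
            rnd, anchor = "1", ""
        elif g in round2:
            rnd, anchor = "2", round2[g]
        else:
            rnd, anchor = "none", ""
        comp = completeness.get(g, "complete" if circular.get(g, False) else "partial")
        rows.append((g, pct, avq, rnd, anchor, comp, bool(circular.get(g, False))))
    return RecruitmentReport(pd.DataFrame(rows, columns=list(RecruitmentReport.COLUMNS)))
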