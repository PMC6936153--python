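"""Lineage expansion by closest-relative identification (CRI).

Sequences too short or too redundant for the phylogenomic tree inherit the
lineage of their closest classified relative.  The closest relative is the
classified genome with the highest percentage of matched protein-encoding
genes (PEGs), with average amino acid identity (AAI) breaking ties; a match
must reach AAI >= 50% and matched PEGs >= 70%.  Such assignments are
tentative, so output rows are flagged ``method=CRI``.

Percentages are computed over the query's proteins: queries are typically
genome fragments, so demanding coverage of the full-length relative would
reject nearly everything.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .hits import HitTable

__all__ = ["CRIMatch", "compute_aai", "assign_closest_relative", "expand_lineages"]

MIN_AAI = 50.0
MIN_PCT_PEGS = 70.0


@dataclass(frozen=True)
class CRIMatch:
    """Accepted closest-relative match for one query sequence."""

    query: str
    relative: str
    aai: float
    pct_matched_pegs: float
    n_matches: int
    lineages: dict[str, str]  # level name -> inherited lineage ID


def _best_hits(hits: HitTable, query: str, subject: str) -> pd.DataFrame:
    d = hits.df
    d = d[(d["qgenome"] == query) & (d["sgenome"] == subject)]
    if d.empty:
        return d
    d = d.sort_values(
        ["query", "bitscore", "evalue", "subject"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    return d.drop_duplicates("query", keep="first")


def compute_aai(hits: HitTable, query: str, subject: str, *, length_weighted: bool = False) -> tuple[float, float]:
    """``(aai, pct_matched_pegs)`` of ``query`` against ``subject``.

    Per query protein the best (highest-bitscore) hit into the subject is
    kept; AAI is the unweighted mean of those hits' percent identities
    (optionally alignment-length weighted) and the matched-PEG percentage is
    over the query's total protein count.  ``(0, 0)`` when there are no
    hits.
    """
    n_query = hits.protein_counts.get(query)
    if not n_query:
        raise ValueError(f"query genome {query!r} has no proteins on record")
    best = _best_hits(hits, query, subject)
    if best.empty:
        return 0.0, 0.0
    if length_weighted:
        aai = float((best["pident"] * best["length"]).sum() / best["length"].sum())
    else:
        aai = float(best["pident"].mean())
    pct = 100.0 * len(best) / n_query
    return aai, pct


def assign_closest_relative(
    query: str,
    candidates: Mapping[str, Mapping[str, str]],
    hits: HitTable,
    min_aai: float = MIN_AAI,
    min_pct: float = MIN_PCT_PEGS,
) -> CRIMatch | None:
    """Pick the closest classified relative of ``query``, or None.

    ``candidates`` maps classified genome IDs to their per-level lineage
    assignments (e.g. ``{"level1": "L1_001", ...}``; levels where the
    relative itself is unassigned are simply absent).  Ordering among
    qualifying candidates: highest matched-PEG percentage, then highest
    AAI, then lexicographic candidate ID.
    """
    d = hits.df
    reachable = set(d.loc[d["qgenome"] == query, "sgenome"].unique()) & set(candidates)
    scored = []
    for cand in sorted(reachable):
        if cand == query:
            continue
        best = _best_hits(hits, query, cand)
        if best.empty:
            continue
        aai = float(best["pident"].mean())
        n_query = hits.protein_counts.get(query)
        if not n_query:
            raise ValueError(f"query genome {query!r} has no proteins on record")
        pct = 100.0 * len(best) / n_query
        if aai >= min_aai and pct >= min_pct:
            scored.append((-pct, -aai, cand, len(best)))
    if not scored:
        return None
    scored.sort()
    neg_pct, neg_aai, cand, n_matches = scored[0]
    return CRIMatch(
        query=query,
        relative=cand,
        aai=-neg_aai,
        pct_matched_pegs=-neg_pct,
        n_matches=n_matches,
        lineages=dict(candidates[cand]),
    )


def expand_lineages(
    queries: Sequence[str],
    candidates: Mapping[str, Mapping[str, str]],
    hits: HitTable,
    min_aai: float = MIN_AAI,
    min_pct: float = MIN_PCT_PEGS,
) -> pd.DataFrame:
    """CRI over many queries; tree-derived assignments are never altered.

    Returns one row per query: ``genome_id, cr_id, cr_hits,
    cr_pct_matched, aai, level1..level3, method`` (empty strings where
    unassigned; ``method`` is ``CRI`` or ``unassigned``).
    """
    rows = []
    for q in sorted(queries):
        m = assign_closest_relative(q, candidates, hits, min_aai=min_aai, min_pct=min_pct)
        if m is None:
            rows.append((q, "", 0, 0.0, 0.0, "", "", "", "unassigned"))
        else:
            rows.append(
                (
                    q,
                    m.relative,
                    m.n_matches,
                    m.pct_matched_pegs,
                    m.aai,
                    m.lineages.get("level1", ""),
                    m.lineages.get("level2", ""),
                    m.lineages.get("level3", ""),
                    "CRI",
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "genome_id",
            "cr_id",
            "cr_hits",
            "cr_pct_matched",
            "aai",
            "level1",
            "level2",
            "level3",
            "method",
        ],
    )
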