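"""Dice genome distances from all-vs-all protein homology.

For genomes A and B, let AB be the summed bitscore of all valid hits of A's
proteins against B's proteins, and AA, BB the corresponding self sums.  The
Dice distance is

    D_AB = 1 - 2*AB / (AA + BB)

so genomes sharing many high-scoring homologs approach 0 and genomes with
disjoint proteomes are exactly 1.  Non-homologous proteins contribute to AA
and BB only, which penalises gene content differences.  Since the raw AB sum
is directional, the matrix is symmetrised with numerator AB + BA (equal to
2*AB for a symmetric search), which neighbor joining requires.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .hits import HitTable

__all__ = ["bitscore_sums", "dice_matrix", "dice_from_hits", "write_tsv", "write_phylip"]


def bitscore_sums(hit_table: HitTable, *, best_hsp_only: bool = False) -> pd.Series:
    """Summed bitscores per ordered genome pair.

    Returns a Series indexed by ``(qgenome, sgenome)``.  Multiple rows for
    the same protein pair (multiple HSPs) are summed by default;
    ``best_hsp_only`` keeps only the highest-scoring row per protein pair,
    for sensitivity analysis.

    Raises
    ------
    ValueError
        If any genome in the table has a zero self sum (AA = 0), which
        indicates the search is missing self-hits.
    """
    d = hit_table.df
    if "qgenome" not in d.columns or "sgenome" not in d.columns:
        raise ValueError("hit table is not genome-indexed; call HitTable.with_genomes first")
    if best_hsp_only:
        d = d.sort_values("bitscore", ascending=False, kind="mergesort").drop_duplicates(
            ["query", "subject"], keep="first"
        )
    sums = d.groupby(["qgenome", "sgenome"])["bitscore"].sum()
    genomes = sorted(set(d["qgenome"]) | set(d["sgenome"]))
    missing_self = [g for g in genomes if sums.get((g, g), 0.0) <= 0.0]
    if missing_self:
        raise ValueError(
            "zero self-homology sum (AA = 0) for genomes: " + ", ".join(missing_self[:10])
        )
    return sums


def dice_matrix(sums: pd.Series, ids: list[str] | None = None) -> DistanceMatrix:
    """Build the symmetric Dice distance matrix from pair bitscore sums.

    ``ids`` fixes the genome set and output order (lexicographic by
    default).  Pairs with no hits get distance exactly 1; values are clamped
    into [0, 1] since AB + BA can marginally exceed AA + BB under asymmetric
    scoring.
    """
    if ids is None:
        ids = sorted({g for pair in sums.index for g in pair})
    else:
        ids = list(ids)
    n = len(ids)
    pos = {g: i for i, g in enumerate(ids)}
    self_sum = np.empty(n)
    for g in ids:
        aa = sums.get((g, g), 0.0)
        if aa <= 0.0:
            raise ValueError(f"genome {g!r} has non-positive self sum AA={aa}")
        self_sum[pos[g]] = aa
    cross = np.zeros((n, n))
    for (qa, sb), bs in sums.items():
        i, j = pos.get(qa), pos.get(sb)
        if i is None or j is None or i == j:
            continue
        cross[i, j] += bs
    with np.errstate(invalid="ignore"):
        num = cross + cross.T
        den = self_sum[:, None] + self_sum[None, :]
        dist = 1.0 - num / den
    np.clip(dist, 0.0, 1.0, out=dist)
    np.fill_diagonal(dist, 0.0)
    return DistanceMatrix(dist, ids)


def dice_from_hits(hit_table: HitTable, ids: list[str] | None = None, **kw) -> DistanceMatrix:
    """Convenience: :func:`bitscore_sums` then :func:`dice_matrix`."""
    return dice_matrix(bitscore_sums(hit_table, **kw), ids)


def write_tsv(dm: DistanceMatrix, path: str | Path) -> None:
    """Square matrix with genome-ID header row and column."""
    pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(path, sep="\t")


def write_phylip(dm: DistanceMatrix, path: str | Path) -> None:
    """PHYLIP square (lower+upper) distance format."""
    with open(path, "w") as fh:
        fh.write(f"{dm.shape[0]}\n")
        for gid, row in zip(dm.ids, dm.data):
            fh.write(gid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def read_tsv(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.values, [str(i) for i in df.index])
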