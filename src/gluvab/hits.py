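"""Reading and filtering of tabular protein-homology hits.

Hits arrive in the 12-column tab-separated layout produced by BLAST and
DIAMOND (``outfmt 6``): query, subject, percent identity, alignment length,
mismatches, gap opens, qstart, qend, sstart, send, e-value, bitscore.
The pipeline consumes these files as-is; it never runs the search itself.

A :class:`HitTable` couples the filtered hit rows with the protein-to-genome
mapping needed by every genome-level operation downstream (distance sums,
recruitment, AAI).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

__all__ = [
    "FilterProfile",
    "HitTable",
    "PROFILES",
    "parse_hit_table",
    "read_fasta",
    "read_protein_map",
    "HIT_COLUMNS",
]

HIT_COLUMNS = [
    "query",
    "subject",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


@dataclass(frozen=True)
class FilterProfile:
    """Inclusive thresholds applied to every hit row.

    A hit is retained iff identity >= ``min_identity``, bitscore >=
    ``min_bitscore``, alignment length >= ``min_aln_length`` and e-value <=
    ``max_evalue``.
    """

    min_identity: float = 30.0
    min_bitscore: float = 30.0
    min_aln_length: int = 30
    max_evalue: float = 0.01

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_identity <= 100.0):
            raise ValueError(f"min_identity must be in [0, 100], got {self.min_identity}")
        for name in ("min_bitscore", "min_aln_length", "max_evalue"):
            v = getattr(self, name)
            if v != v or v in (float("inf"), float("-inf")):
                raise ValueError(f"{name} must be finite, got {v}")


#: Built-in profiles. ``standard`` is used for the all-vs-all, completeness and
#: closest-relative searches; ``marker_search`` (higher bitscore floor) for
#: searches against the viral-marker orthologous groups.
PROFILES: dict[str, FilterProfile] = {
    "standard": FilterProfile(30.0, 30.0, 30, 0.01),
    "marker_search": FilterProfile(30.0, 50.0, 30, 0.01),
}


@dataclass
class HitTable:
    """Filtered homology hits plus genome indexing.

    Attributes
    ----------
    df :
        Hit rows (columns :data:`HIT_COLUMNS`), already filtered.
    protein_to_genome :
        Maps protein IDs to their genome of origin.  May be empty when the
        subjects are marker groups rather than proteins.
    protein_counts :
        Number of predicted proteins per genome; derived from the full
        protein map, not from the hits (a genome may have proteins with no
        hits at all).
    """

    df: pd.DataFrame
    protein_to_genome: Mapping[str, str] = field(default_factory=dict)
    protein_counts: Mapping[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    def filter(self, profile: FilterProfile) -> "HitTable":
        """Return a new table with ``profile`` applied (idempotent)."""
        d = self.df
        keep = (
            (d["pident"] >= profile.min_identity)
            & (d["bitscore"] >= profile.min_bitscore)
            & (d["length"] >= profile.min_aln_length)
            & (d["evalue"] <= profile.max_evalue)
        )
        return HitTable(d[keep].reset_index(drop=True), self.protein_to_genome, self.protein_counts)

    def with_genomes(
        self,
        protein_to_genome: Mapping[str, str],
        *,
        subjects_are_proteins: bool = True,
    ) -> "HitTable":
        """Attach genome-of-origin columns ``qgenome``/``sgenome``.

        Raises
        ------
        KeyError
            If any referenced protein ID has no genome mapping.
        """
        df = self.df.copy()
        missing: set[str] = set()
        qg = df["query"].map(protein_to_genome)
        missing.update(df.loc[qg.isna(), "query"])
        df["qgenome"] = qg
        if subjects_are_proteins:
            sg = df["subject"].map(protein_to_genome)
            missing.update(df.loc[sg.isna(), "subject"])
            df["sgenome"] = sg
        if missing:
            raise KeyError(
                "no genome mapping for protein IDs: " + ", ".join(sorted(missing)[:20])
            )
        counts = Counter(protein_to_genome.values())
        return HitTable(df, dict(protein_to_genome), dict(counts))


def parse_hit_table(path: str | Path, profile: FilterProfile | None = None) -> HitTable:
    """Read a 12-column tabular hit file and apply ``profile``.

    Self-hits (query == subject) are retained: the Dice distance needs the
    self-homology sums AA and BB.  Rows with fewer than 12 columns, or with
    non-numeric values in numeric columns, are hard errors naming the line.
    """
    path = Path(path)
    rows: list[list] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ValueError(
                    f"{path}:{lineno}: expected >=12 tab-separated columns, got {len(parts)}"
                )
            try:
                rows.append(
                    [
                        parts[0],
                        parts[1],
                        float(parts[2]),
                        int(parts[3]),
                        int(parts[4]),
                        int(parts[5]),
                        int(parts[6]),
                        int(parts[7]),
                        int(parts[8]),
                        int(parts[9]),
                        float(parts[10]),
                        float(parts[11]),
                    ]
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from None
    df = pd.DataFrame(rows, columns=HIT_COLUMNS)
    if df.empty:
        df = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
            HIT_COLUMNS,
            [object, object, float, int, int, int, int, int, int, int, float, float],
        )})
    table = HitTable(df)
    if profile is not None:
        table = table.filter(profile)
    return table


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{record_id: sequence}``.

    Duplicate IDs and empty sequences are hard errors.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA ID {rec.id!r} in {path}")
        seq = str(rec.seq)
        if not rec.id or not seq:
            raise ValueError(f"empty ID or sequence in {path}")
        records[rec.id] = seq
    return records


def read_protein_map(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV ``protein_id<TAB>genome_id``.

    Duplicate protein IDs are hard errors (a protein belongs to exactly one
    genome).
    """
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            prot, genome = parts
            if prot in mapping:
                raise ValueError(f"{path}:{lineno}: duplicate protein ID {prot!r}")
            mapping[prot] = genome
    return mapping


def infer_protein_map(protein_ids: Iterable[str]) -> dict[str, str]:
    """Fallback mapping for ``genomeID_N``-suffixed protein IDs.

    Follows the gene-caller convention of appending ``_<index>`` to the
    contig ID.  Emits a warning because explicit maps are preferred.
    """
    warnings.warn(
        "inferring genome of origin from 'genomeID_N' protein-ID suffixes; "
        "supply an explicit protein map when possible",
        stacklevel=2,
    )
    mapping: dict[str, str] = {}
    for pid in protein_ids:
        genome, sep, idx = pid.rpartition("_")
        if not sep or not idx.isdigit():
            raise ValueError(f"protein ID {pid!r} does not follow the genomeID_N convention")
        mapping[pid] = genome
    return mapping
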