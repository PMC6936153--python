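"""Ecological profiling of lineages: abundance, prevalence, rarefaction, OGs.

Per-sample lineage abundance sums the relative abundances (percent of
mapped reads) of member sequences; whatever is not assigned to a lineage
falls into an explicit ``unassigned`` bucket so each sample row closes to
100%.  Prevalence summarises metadata labels (host taxon, ecosystem)
within each lineage over annotated members only.  Rarefaction estimates,
per ecosystem, how many distinct lineages a random sample of n genomes
touches.  Orthologous-group (OG) prevalence counts an OG in a lineage's
pan-genome when it is detected in at least three member genomes; OGs in
three or more level-1 pan-genomes are flagged promiscuous.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .lineages import LineagePartition

__all__ = [
    "read_counts",
    "lineage_abundance",
    "prevalence",
    "rarefaction",
    "og_prevalence",
]

UNASSIGNED = "unassigned"


def read_counts(path) -> pd.DataFrame:
    """Long-format counts TSV ``sample<TAB>genome_id<TAB>reads`` -> wide table."""
    long = pd.read_csv(
        path, sep="\t", names=["sample", "genome_id", "reads"], comment="#", header=None
    )
    wide = long.pivot_table(index="sample", columns="genome_id", values="reads", fill_value=0)
    return wide.astype(int)


def lineage_abundance(counts: pd.DataFrame, partition: LineagePartition) -> pd.DataFrame:
    """Relative abundance (%) per sample x lineage, plus ``unassigned``.

    ``counts`` is samples x genomes (mapped reads).  Each genome's relative
    abundance is 100 * count / total mapped reads in the sample; lineage
    abundance sums members; genomes in no lineage contribute to
    ``unassigned``.  A sample with zero total yields a zero row with a
    warning.
    """
    labels = partition.as_labels()
    lineage_ids = sorted(partition.lineages)
    totals = counts.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"samples with zero mapped reads: {list(counts.index[zero])}")
    out = pd.DataFrame(0.0, index=counts.index, columns=lineage_ids + [UNASSIGNED])
    safe_tot = totals.replace(0, 1)
    rel = 100.0 * counts.div(safe_tot, axis=0)
    for genome in counts.columns:
        out[labels.get(genome, UNASSIGNED)] += rel[genome]
    out.loc[zero] = 0.0
    return out


def prevalence(
    partition: LineagePartition,
    metadata: Mapping[str, str],
    min_frac: float = 1.0,
) -> pd.DataFrame:
    """Percentage of each metadata label among annotated lineage members.

    ``metadata`` maps genome IDs to a label for one attribute (host phylum,
    ecosystem, ...); members without the attribute are excluded from the
    denominator.  Labels below ``min_frac`` percent within a lineage are
    merged into ``other``.  Long format: ``lineage, label, pct, n``.
    """
    rows = []
    for lid in sorted(partition.lineages):
        _, members = partition.lineages[lid]
        labeled = [metadata[g] for g in members if metadata.get(g) not in (None, "")]
        if not labeled:
            continue
        n = len(labeled)
        merged: dict[str, int] = {}
        for label, c in pd.Series(labeled).value_counts().items():
            pct = 100.0 * c / n
            if pct < min_frac:
                merged["other"] = merged.get("other", 0) + int(c)
            else:
                merged[str(label)] = int(c)
        for label in sorted(merged):
            rows.append((lid, label, 100.0 * merged[label] / n, merged[label]))
    return pd.DataFrame(rows, columns=["lineage", "label", "pct", "n"])


def rarefaction(
    ecosystems: Mapping[str, str],
    lineage_of: Mapping[str, str],
    grid: Sequence[int],
    draws: int = 25,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean distinct-lineage count vs number of genomes sampled per ecosystem.

    ``ecosystems`` maps genome IDs to ecosystem labels (the sampling pools);
    ``lineage_of`` maps assigned genomes to lineage IDs — unassigned genomes
    are still sampled but contribute no lineage.  Sampling is uniform
    without replacement, ``draws`` times per grid point, with n capped at
    the pool size.  Output: ``ecosystem, n, mean, sd``.
    """
    if draws < 1:
        raise ValueError("draws must be >= 1")
    rng = np.random.default_rng(seed)
    pools: dict[str, list[str]] = {}
    for g in sorted(ecosystems):
        pools.setdefault(ecosystems[g], []).append(g)
    rows = []
    for eco in sorted(pools):
        pool = pools[eco]
        if not pool:
            warnings.warn(f"ecosystem {eco!r} has no genomes; skipped")
            continue
        for n in grid:
            n_eff = min(int(n), len(pool))
            if n_eff < 1:
                continue
            vals = []
            for _ in range(draws):
                picked = rng.choice(pool, size=n_eff, replace=False)
                vals.append(len({lineage_of[g] for g in picked if g in lineage_of}))
            rows.append((eco, n_eff, float(np.mean(vals)), float(np.std(vals, ddof=0))))
    return pd.DataFrame(rows, columns=["ecosystem", "n", "mean", "sd"])


def og_prevalence(
    og_membership: Mapping[str, str],
    protein_to_genome: Mapping[str, str],
    partition: LineagePartition,
    min_members: int = 3,
) -> pd.DataFrame:
    """OG pan-genome membership per level-1 lineage and promiscuity flag.

    ``og_membership`` maps protein IDs to OG IDs.  An OG belongs to a
    lineage's pan-genome iff detected in at least ``min_members`` distinct
    member genomes; it is *promiscuous* iff it belongs to the pan-genome of
    three or more lineages.  Proteins of unclassified genomes are ignored
    (their count is reported as a DataFrame attribute ``n_skipped``).
    Output: ``og, lineage, n_genomes, promiscuous``.
    """
    genome_lineage = partition.as_labels()
    per: dict[tuple[str, str], set[str]] = {}
    skipped = 0
    for prot in sorted(og_membership):
        og = og_membership[prot]
        genome = protein_to_genome.get(prot)
        lid = genome_lineage.get(genome) if genome else None
        if lid is None:
            skipped += 1
            continue
        per.setdefault((og, lid), set()).add(genome)
    rows = [
        (og, lid, len(genomes))
        for (og, lid), genomes in sorted(per.items())
        if len(genomes) >= min_members
    ]
    df = pd.DataFrame(rows, columns=["og", "lineage", "n_genomes"])
    pan_counts = df.groupby("og")["lineage"].nunique() if not df.empty else pd.Series(dtype=int)
    promiscuous = set(pan_counts[pan_counts >= 3].index)
    df["promiscuous"] = df["og"].isin(promiscuous) if not df.empty else pd.Series(dtype=bool)
    df.attrs["n_skipped"] = skipped
    df.attrs["promiscuous_ogs"] = sorted(promiscuous)
    return df
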