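"""Seeded synthetic viral communities with planted lineage structure.

The pipeline consumes tabular homology hits, marker tables, metadata and
read counts — so the generator synthesises those directly instead of
simulating sequence evolution and running an aligner.  Homologous protein
pairs receive a percent identity drawn from the band that corresponds to
the planted relationship of their genomes, and a bitscore that is a
monotone function of identity times alignment length
(``round(2 * length * identity / 100)``); only monotonicity matters to the
Dice ordering, so the constant is arbitrary.

Planted structure (defaults):

* three level-1 lineages, disjoint proteomes (Dice distance exactly 1
  between them);
* two level-2 sublineages per level-1 lineage, sharing half of their
  protein slots at 43-47% identity;
* two level-3 groups per level-2 sublineage, sharing 80% of their slots at
  63-67% identity;
* 2-3 genomes per level-3 group, sharing all slots on an identity ladder
  inside 86-92%.

The identity bands are strictly ordered, which guarantees that the Dice
matrix is block-structured and that the node-depth bands of the resulting
midpoint-rooted tree are separable; the rules returned in
``bundle.suggested_rules`` put each level's cutoff between two bands.

Decoy proteomes mirror the recruitment benchmark: "eukaryotic-virus"
decoys hit a designated marker subset (exercising marker pruning) and
"cellular" decoys carry near-zero marker signal (exercising precision).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .hits import HIT_COLUMNS, HitTable
from .lineages import LineageRule

__all__ = ["FixtureSpec", "CommunityBundle", "generate_community", "generate_decoys", "write_bundle"]

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_NT = np.array(list("ACGT"))


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the planted community.

    Identity bands are percentages; ``level3_identity`` applies within
    level-3 groups, ``level2_identity`` across level-3 groups of the same
    level-2 sublineage, ``level1_identity`` across level-2 sublineages of
    the same level-1 lineage.  Bands must be strictly ordered
    (level3 > level2 > level1) so the planted clades are separable.
    """

    n_level1: int = 3
    n_level2_per_level1: int = 2
    n_level3_per_level2: int = 2
    genomes_per_level3: tuple[int, int] = (2, 3)
    proteins_per_genome: tuple[int, int] = (12, 12)
    level3_identity: tuple[float, float] = (86.0, 92.0)
    level2_identity: tuple[float, float] = (63.0, 67.0)
    level1_identity: tuple[float, float] = (43.0, 47.0)
    level2_shared: float = 0.8
    level1_shared: float = 0.5
    marker_fraction: float = 0.6
    round2_fraction: float = 0.3
    n_markers: int = 40
    n_decoy_markers: int = 5
    n_lowvq_markers: int = 5
    n_eukaryotic_decoys: int = 3
    n_cellular_decoys: int = 5
    decoy_proteins: int = 20
    fragment_fraction: float = 0.2
    fragment_retain: tuple[float, float] = (0.7, 0.9)
    complete_fraction: float = 0.6
    circular_fraction: float = 0.2
    n_promiscuous_slots: int = 3
    n_samples: int = 4
    read_log_mean: float = 4.0
    read_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        bands = [self.level1_identity, self.level2_identity, self.level3_identity]
        for lo, hi in bands:
            if not (0.0 <= lo <= hi <= 100.0):
                raise ValueError(f"identity band ({lo}, {hi}) outside [0, 100]")
        if not (
            self.level3_identity[0] > self.level2_identity[1] > self.level2_identity[0]
            > self.level1_identity[1]
        ):
            raise ValueError(
                "identity bands must be separable: level3 > level2 > level1 strictly"
            )


_ECOSYSTEMS = ("aquatic", "human_gut", "soil", "wastewater")
_PHYLA = ("Proteobacteria", "Firmicutes", "Actinobacteria", "Bacteroidetes", "Cyanobacteria")


@dataclass
class CommunityBundle:
    """Everything the pipeline stages consume, plus the planted truth."""

    spec: FixtureSpec
    genomes: dict[str, str]                 # nucleotide sequences
    proteins: dict[str, str]                # amino-acid sequences
    protein_map: dict[str, str]             # protein -> genome (incl. decoys, fragments)
    lengths: dict[str, int]                 # genome -> bp
    hits: pd.DataFrame                      # all-vs-all, tree genomes only
    marker_db: dict[str, float]
    marker_hits: pd.DataFrame               # viral + cellular-decoy proteins vs markers
    euk_decoy_marker_hits: pd.DataFrame     # for marker pruning
    fragment_hits: pd.DataFrame             # fragment proteins vs tree genomes
    counts: pd.DataFrame                    # long: sample, genome_id, reads
    og_membership: dict[str, str]           # protein -> OG
    truth: pd.DataFrame                     # per-genome planted annotations
    suggested_rules: tuple[LineageRule, ...] = field(default_factory=tuple)

    @property
    def tree_genomes(self) -> list[str]:
        t = self.truth
        return sorted(t.loc[t["role"] == "tree", "genome_id"])

    @property
    def viral_genomes(self) -> list[str]:
        t = self.truth
        return sorted(t.loc[t["role"].isin(["tree", "fragment"]), "genome_id"])

    @property
    def decoy_genomes(self) -> list[str]:
        t = self.truth
        return sorted(t.loc[t["role"].isin(["eukaryotic_decoy", "cellular_decoy"]), "genome_id"])

    def hit_table(self) -> HitTable:
        return HitTable(self.hits).with_genomes(self.protein_map)

    def truth_labels(self, level: int, roles: tuple[str, ...] = ("tree",)) -> dict[str, str]:
        t = self.truth[self.truth["role"].isin(roles)]
        col = f"level{level}"
        return {r["genome_id"]: r[col] for _, r in t.iterrows() if r[col]}


def _rand_seq(rng: np.random.Generator, alphabet: np.ndarray, n: int) -> str:
    return "".join(rng.choice(alphabet, size=n))


def _hit_row(query, subject, ident, length, evalue, bitscore):
    mism = int(round(length * (100.0 - ident) / 100.0))
    return [query, subject, round(float(ident), 2), int(length), mism, 0,
            1, int(length), 1, int(length), float(evalue), float(bitscore)]


def _homology_rows(qprot, sprot, ident, length):
    """Symmetric pair of hit rows for two homologous proteins."""
    bs = round(2 * length * ident / 100.0)
    ev = 10.0 ** (-min(bs / 5.0, 180.0))
    return [
        _hit_row(qprot, sprot, ident, length, ev, bs),
        _hit_row(sprot, qprot, ident, length, ev, bs),
    ]


def generate_decoys(spec: FixtureSpec, marker_ids: list[str]) -> dict:
    """Decoy proteomes and their marker hits.

    ``marker_ids`` is the full marker list; the last
    ``n_decoy_markers + n_lowvq_markers`` entries are the designated
    eukaryotic-decoy subset and the low-viral-quotient subset respectively.
    """
    rng = np.random.default_rng([spec.seed % (2**31), 101])
    n_clean = spec.n_markers - spec.n_decoy_markers - spec.n_lowvq_markers
    decoy_markers = marker_ids[n_clean:n_clean + spec.n_decoy_markers]
    lowvq_markers = marker_ids[n_clean + spec.n_decoy_markers:]

    protein_map: dict[str, str] = {}
    proteins: dict[str, str] = {}
    lengths: dict[str, int] = {}
    euk_rows: list[list] = []
    cell_rows: list[list] = []
    truth_rows: list[dict] = []

    for i in range(spec.n_eukaryotic_decoys):
        g = f"eukvir_{i + 1:02d}"
        plen = 0
        for k in range(spec.decoy_proteins):
            pid = f"{g}_{k + 1}"
            protein_map[pid] = g
            l = int(rng.integers(150, 401))
            proteins[pid] = _rand_seq(rng, _AA, l)
            plen += l
            if decoy_markers and rng.random() < 0.5:
                m = decoy_markers[int(rng.integers(len(decoy_markers)))]
                euk_rows.append(_hit_row(pid, m, rng.uniform(40, 70), l, 1e-20,
                                         round(rng.uniform(60, 150))))
        lengths[g] = plen * 3 + 2000
        truth_rows.append({"genome_id": g, "role": "eukaryotic_decoy"})

    for i in range(spec.n_cellular_decoys):
        g = f"cell_{i + 1:02d}"
        plen = 0
        for k in range(spec.decoy_proteins):
            pid = f"{g}_{k + 1}"
            protein_map[pid] = g
            l = int(rng.integers(150, 401))
            proteins[pid] = _rand_seq(rng, _AA, l)
            plen += l
            # A single weak hit to a low-VQ marker: passes the search filter
            # but contributes almost nothing to the AVQ.
            if k == 0 and lowvq_markers:
                m = lowvq_markers[int(rng.integers(len(lowvq_markers)))]
                cell_rows.append(_hit_row(pid, m, rng.uniform(30, 40), l, 1e-5,
                                          round(rng.uniform(55, 70))))
        lengths[g] = plen * 3 + 2000
        truth_rows.append({"genome_id": g, "role": "cellular_decoy"})

    return {
        "protein_map": protein_map,
        "proteins": proteins,
        "lengths": lengths,
        "euk_marker_hits": pd.DataFrame(euk_rows, columns=HIT_COLUMNS),
        "cell_marker_hits": pd.DataFrame(cell_rows, columns=HIT_COLUMNS),
        "truth_rows": truth_rows,
    }


def generate_community(spec: FixtureSpec | None = None) -> CommunityBundle:
    """Build the full synthetic bundle; same seed -> byte-identical outputs."""
    spec = spec or FixtureSpec()
    root_seed = spec.seed % (2**31)
    rng_struct = np.random.default_rng([root_seed, 1])
    rng_ident = np.random.default_rng([root_seed, 2])
    rng_seq = np.random.default_rng([root_seed, 3])
    rng_marker = np.random.default_rng([root_seed, 4])
    rng_meta = np.random.default_rng([root_seed, 5])
    rng_counts = np.random.default_rng([root_seed, 6])
    rng_frag = np.random.default_rng([root_seed, 7])

    pmin, pmax = spec.proteins_per_genome
    # Slot pools: one per level-1 lineage; slot lengths are shared by every
    # genome of the lineage so self-sums stay comparable.
    slot_len = {
        l1: rng_struct.integers(150, 401, size=pmax)
        for l1 in range(1, spec.n_level1 + 1)
    }

    genome_info: list[dict] = []
    for l1 in range(1, spec.n_level1 + 1):
        for l2 in range(1, spec.n_level2_per_level1 + 1):
            for l3 in range(1, spec.n_level3_per_level2 + 1):
                size = int(rng_struct.integers(spec.genomes_per_level3[0],
                                               spec.genomes_per_level3[1] + 1))
                for gi in range(size):
                    gid = f"vir_{l1}_{l2}_{l3}_{gi + 1}"
                    genome_info.append(
                        {
                            "genome_id": gid,
                            "l1": l1, "l2": l2, "l3": l3, "rank": gi,
                            "n_proteins": int(rng_struct.integers(pmin, pmax + 1)),
                        }
                    )

    protein_map: dict[str, str] = {}
    proteins: dict[str, str] = {}
    genomes: dict[str, str] = {}
    lengths: dict[str, int] = {}
    for g in genome_info:
        gid, l1 = g["genome_id"], g["l1"]
        plen = 0
        for k in range(g["n_proteins"]):
            pid = f"{gid}_{k + 1}"
            protein_map[pid] = gid
            l = int(slot_len[l1][k])
            proteins[pid] = _rand_seq(rng_seq, _AA, l)
            plen += l
        circular = bool(rng_seq.random() < spec.circular_fraction)
        core = _rand_seq(rng_seq, _NT, plen * 3 + 2000)
        seq = core + core[:30] if circular else core
        genomes[gid] = seq
        lengths[gid] = len(seq)
        g["circular"] = circular

    # --- all-vs-all homology hits (tree genomes only) ---
    hit_rows: list[list] = []
    for g in genome_info:  # self-hits
        gid, l1 = g["genome_id"], g["l1"]
        for k in range(g["n_proteins"]):
            l = int(slot_len[l1][k])
            hit_rows.append(_hit_row(f"{gid}_{k + 1}", f"{gid}_{k + 1}", 100.0, l,
                                     10.0 ** (-min(2 * l / 5.0, 180.0)), 2 * l))

    def _pair_identity(a: dict, b: dict) -> tuple[float, int] | None:
        """(identity, n_shared_slots) for two genomes, or None if disjoint."""
        if a["l1"] != b["l1"]:
            return None
        if a["l2"] != b["l2"]:
            lo, hi = spec.level1_identity
            shared = round(spec.level1_shared * pmax)
            return float(rng_ident.uniform(lo, hi)), shared
        if a["l3"] != b["l3"]:
            lo, hi = spec.level2_identity
            shared = round(spec.level2_shared * pmax)
            return float(rng_ident.uniform(lo, hi)), shared
        # Same level-3 group: identity ladder so within-group topology is a
        # stable caterpillar, not a noise-driven star.
        lo, hi = spec.level3_identity
        group = [x for x in genome_info
                 if (x["l1"], x["l2"], x["l3"]) == (a["l1"], a["l2"], a["l3"])]
        size = len(group)
        delta = (hi - lo) / max(1, size - 1)
        j = max(a["rank"], b["rank"])
        ident = hi - delta * j + float(rng_ident.uniform(-0.3, 0.3))
        return min(ident, 100.0), pmax

    for i, a in enumerate(genome_info):
        for b in genome_info[i + 1:]:
            rel = _pair_identity(a, b)
            if rel is None:
                continue
            ident, shared = rel
            n_shared = min(shared, a["n_proteins"], b["n_proteins"])
            for k in range(n_shared):
                l = int(slot_len[a["l1"]][k])
                slot_ident = min(100.0, ident + float(rng_ident.uniform(-0.2, 0.2)))
                hit_rows.extend(
                    _homology_rows(f"{a['genome_id']}_{k + 1}", f"{b['genome_id']}_{k + 1}",
                                   slot_ident, l)
                )
    hits = pd.DataFrame(hit_rows, columns=HIT_COLUMNS)

    # --- markers and marker hits ---
    n_clean = spec.n_markers - spec.n_decoy_markers - spec.n_lowvq_markers
    if n_clean < 1:
        raise ValueError("n_markers must exceed the decoy and low-VQ subsets")
    marker_ids = [f"pVOG_{i + 1:04d}" for i in range(spec.n_markers)]
    marker_db = {}
    for i, m in enumerate(marker_ids):
        if i < n_clean:
            marker_db[m] = 1.0
        elif i < n_clean + spec.n_decoy_markers:
            marker_db[m] = 0.9
        else:
            marker_db[m] = 0.05
    clean_markers = marker_ids[:n_clean]

    # Suppress marker signal for at most one genome per level-3 group: these
    # fail round 1 and must be rescued by homology linkage in round 2.
    suppressed: set[str] = set()
    groups: dict[tuple, list[dict]] = {}
    for g in genome_info:
        groups.setdefault((g["l1"], g["l2"], g["l3"]), []).append(g)
    for key in sorted(groups):
        members = groups[key]
        if len(members) > 1 and rng_marker.random() < spec.round2_fraction:
            suppressed.add(members[int(rng_marker.integers(len(members)))]["genome_id"])

    marker_rows: list[list] = []
    for g in genome_info:
        gid = g["genome_id"]
        if gid in suppressed:
            continue
        n_hit = max(1, round(spec.marker_fraction * g["n_proteins"]))
        for k in range(n_hit):
            pid = f"{gid}_{k + 1}"
            l = int(slot_len[g["l1"]][k])
            m = clean_markers[int(rng_marker.integers(len(clean_markers)))]
            marker_rows.append(_hit_row(pid, m, rng_marker.uniform(40, 80), l, 1e-20,
                                        round(rng_marker.uniform(100, 180))))
            if rng_marker.random() < 0.3:  # weaker secondary hit
                m2 = clean_markers[int(rng_marker.integers(len(clean_markers)))]
                marker_rows.append(_hit_row(pid, m2, rng_marker.uniform(35, 60), l, 1e-10,
                                            round(rng_marker.uniform(55, 95))))

    decoys = generate_decoys(spec, marker_ids)
    protein_map.update(decoys["protein_map"])
    proteins.update(decoys["proteins"])
    lengths.update(decoys["lengths"])
    marker_hits = pd.DataFrame(
        marker_rows + decoys["cell_marker_hits"].values.tolist(), columns=HIT_COLUMNS
    )

    # --- fragments for closest-relative identification ---
    frag_rows: list[list] = []
    frag_truth: list[dict] = []
    lo_r, hi_r = spec.fragment_retain
    for g in genome_info:
        if rng_frag.random() >= spec.fragment_fraction:
            continue
        src = g["genome_id"]
        fid = f"frag_{src}"
        n_keep = max(2, int(round(float(rng_frag.uniform(lo_r, hi_r)) * g["n_proteins"])))
        kept = sorted(rng_frag.choice(g["n_proteins"], size=n_keep, replace=False))
        plen = 0
        for k in kept:
            pid = f"{fid}_{int(k) + 1}"
            protein_map[pid] = fid
            l = int(slot_len[g["l1"]][k])
            proteins[pid] = proteins[f"{src}_{int(k) + 1}"]
            plen += l
            # high-identity hits back to the source genome's slot ...
            ident = float(rng_frag.uniform(95, 99))
            bs = round(2 * l * ident / 100.0)
            frag_rows.append(_hit_row(pid, f"{src}_{int(k) + 1}", ident, l,
                                      10.0 ** (-min(bs / 5.0, 180.0)), bs))
            # ... and band-identity hits to the other members of its group
            for other in groups[(g["l1"], g["l2"], g["l3"])]:
                if other["genome_id"] == src or k >= other["n_proteins"]:
                    continue
                oid = float(rng_frag.uniform(*spec.level3_identity))
                obs = round(2 * l * oid / 100.0)
                frag_rows.append(_hit_row(pid, f"{other['genome_id']}_{int(k) + 1}", oid, l,
                                          10.0 ** (-min(obs / 5.0, 180.0)), obs))
        genomes[fid] = _rand_seq(rng_frag, _NT, plen * 3 + 500)
        lengths[fid] = plen * 3 + 500
        frag_truth.append(
            {
                "genome_id": fid, "role": "fragment", "source": src,
                "level1": f"l1_{g['l1']}",
                "level2": f"l1_{g['l1']}.l2_{g['l2']}",
                "level3": f"l1_{g['l1']}.l2_{g['l2']}.l3_{g['l3']}",
                "n_proteins": n_keep, "length": lengths[fid],
            }
        )
    fragment_hits = pd.DataFrame(frag_rows, columns=HIT_COLUMNS)

    # --- metadata, counts, OGs, truth ---
    home_eco = {l1: _ECOSYSTEMS[(l1 - 1) % len(_ECOSYSTEMS)]
                for l1 in range(1, spec.n_level1 + 1)}
    host_phylum = {l1: _PHYLA[(l1 - 1) % len(_PHYLA)]
                   for l1 in range(1, spec.n_level1 + 1)}
    truth_rows: list[dict] = []
    for g in genome_info:
        gid, l1 = g["genome_id"], g["l1"]
        eco = home_eco[l1]
        if rng_meta.random() > 0.8:
            others = [e for e in _ECOSYSTEMS if e != eco]
            eco = others[int(rng_meta.integers(len(others)))]
        truth_rows.append(
            {
                "genome_id": gid, "role": "tree",
                "level1": f"l1_{l1}",
                "level2": f"l1_{l1}.l2_{g['l2']}",
                "level3": f"l1_{l1}.l2_{g['l2']}.l3_{g['l3']}",
                "host_phylum": host_phylum[l1],
                "host_genus": f"Genus_{l1}_{g['l2']}_{g['l3']}",
                "ecosystem": eco,
                "complete": bool(rng_meta.random() < spec.complete_fraction),
                "circular": g["circular"],
                "suppressed_markers": g["genome_id"] in suppressed,
                "n_proteins": g["n_proteins"],
                "length": lengths[gid],
            }
        )
    truth_rows.extend(frag_truth)
    truth_rows.extend(decoys["truth_rows"])
    truth = pd.DataFrame(truth_rows).fillna("")

    count_rows: list[tuple] = []
    sample_eco = [_ECOSYSTEMS[i % len(_ECOSYSTEMS)] for i in range(spec.n_samples)]
    countable = [r for r in truth_rows if r.get("role") in ("tree", "fragment")]
    for si in range(spec.n_samples):
        sample = f"S{si + 1}"
        for r in countable:
            base = float(rng_counts.lognormal(spec.read_log_mean, spec.read_log_sd))
            gid = r["genome_id"]
            eco = r.get("ecosystem") or ""
            if eco == sample_eco[si]:
                base *= 10.0
            count_rows.append((sample, gid, int(base)))
    counts = pd.DataFrame(count_rows, columns=["sample", "genome_id", "reads"])

    og_membership: dict[str, str] = {}
    for g in genome_info:
        gid, l1 = g["genome_id"], g["l1"]
        for k in range(g["n_proteins"]):
            pid = f"{gid}_{k + 1}"
            if k < spec.n_promiscuous_slots:
                og_membership[pid] = f"OG_shared_{k + 1}"
            else:
                og_membership[pid] = f"OG_{l1}_{k + 1}"

    min_l1 = min(
        sum(len(groups[k]) for k in groups if k[0] == l1)
        for l1 in range(1, spec.n_level1 + 1)
    )
    rules = (
        LineageRule(1, 0.05, max(2, min(4, min_l1))),
        LineageRule(2, 0.18, 2),
        LineageRule(3, 0.35, 2),
    )

    return CommunityBundle(
        spec=spec,
        genomes=genomes,
        proteins=proteins,
        protein_map=protein_map,
        lengths=lengths,
        hits=hits,
        marker_db=marker_db,
        marker_hits=marker_hits,
        euk_decoy_marker_hits=decoys["euk_marker_hits"],
        fragment_hits=fragment_hits,
        counts=counts,
        og_membership=og_membership,
        truth=truth,
        suggested_rules=rules,
    )


def _write_fasta(records: dict[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for rid in sorted(records):
            fh.write(f">{rid}\n")
            seq = records[rid]
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def _write_hits(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def write_bundle(bundle: CommunityBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the bundle as plain-text files; returns ``{name: path}``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def reg(name: str, fname: str) -> Path:
        paths[name] = out / fname
        return paths[name]

    _write_fasta(bundle.genomes, reg("genomes", "genomes.fna"))
    _write_fasta(bundle.proteins, reg("proteins", "proteins.faa"))
    with open(reg("protein_map", "protein_map.tsv"), "w") as fh:
        for pid in sorted(bundle.protein_map):
            fh.write(f"{pid}\t{bundle.protein_map[pid]}\n")
    with open(reg("lengths", "lengths.tsv"), "w") as fh:
        for gid in sorted(bundle.lengths):
            fh.write(f"{gid}\t{bundle.lengths[gid]}\n")
    _write_hits(bundle.hits, reg("hits", "all_vs_all.tsv"))
    _write_hits(bundle.marker_hits, reg("marker_hits", "marker_hits.tsv"))
    _write_hits(bundle.euk_decoy_marker_hits, reg("euk_decoy_marker_hits", "euk_decoy_marker_hits.tsv"))
    _write_hits(bundle.fragment_hits, reg("fragment_hits", "fragment_hits.tsv"))
    with open(reg("marker_db", "markers.tsv"), "w") as fh:
        for m in sorted(bundle.marker_db):
            fh.write(f"{m}\t{bundle.marker_db[m]}\n")
    bundle.counts.to_csv(reg("counts", "counts.tsv"), sep="\t", header=False, index=False)
    with open(reg("og_membership", "og_membership.tsv"), "w") as fh:
        for pid in sorted(bundle.og_membership):
            fh.write(f"{pid}\t{bundle.og_membership[pid]}\n")
    bundle.truth.to_csv(reg("truth", "truth.tsv"), sep="\t", index=False)
    with open(reg("rules", "rules.tsv"), "w") as fh:
        for r in bundle.suggested_rules:
            fh.write(f"{r.level}\t{r.min_depth}\t{r.min_size}\n")
    return paths
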