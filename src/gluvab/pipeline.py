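"""End-to-end orchestration: recruit -> dice -> tree -> lineages -> expand -> profile.

A run is configured by a TOML file (see :class:`RunConfig`); every stage
writes plain-text artifacts into the output directory and records them in a
manifest with SHA-256 checksums.  Stage outputs are pure functions of the
declared inputs and seeds, so rerunning with an unchanged config and inputs
reproduces byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .distance import dice_from_hits, write_phylip, write_tsv
from .expand import expand_lineages
from .hits import FilterProfile, HitTable, parse_hit_table, read_protein_map
from .lineages import (
    LineageRule,
    extract_lineages,
    resample_robustness,
)
from .profile import lineage_abundance, og_prevalence, prevalence, rarefaction, read_counts
from .recruit import (
    build_report,
    prune_marker_db,
    read_marker_db,
    recruit_round1,
    recruit_round2,
    score_avq,
    tag_completeness,
)
from .tree import build_tree, depth_table, write_newick

__all__ = ["RunConfig", "run_pipeline"]

_DEFAULT_RULES = [[1, 0.0014, 20], [2, 0.0056, 3], [3, 0.0189, 3]]


@dataclass
class RunConfig:
    """Parsed run configuration.

    Every published threshold is exposed: hit filters (30/30/30/0.01;
    marker search bitscore 50), recruitment (20% matched, AVQ 5; round 2
    20%/3), completeness (70% coverage, 10 kbp), lineage rules
    (0.0014/20, 0.0056/3, 0.0189/3), closest-relative cutoffs (AAI 50%,
    matched PEGs 70%) and robustness resampling (5%, 100 iterations).
    """

    inputs: dict = field(default_factory=dict)   # name -> path
    out_dir: Path = Path("gluvab_out")
    standard: FilterProfile = field(default_factory=lambda: FilterProfile(30, 30, 30, 0.01))
    marker_search: FilterProfile = field(default_factory=lambda: FilterProfile(30, 50, 30, 0.01))
    min_pct: float = 20.0
    min_avq: float = 5.0
    r2_min_pct: float = 20.0
    r2_min_matches: int = 3
    completeness_min_coverage: float = 70.0
    completeness_min_length: int = 10_000
    rules: list[LineageRule] = field(
        default_factory=lambda: [LineageRule(*r) for r in _DEFAULT_RULES]
    )
    expand_min_aai: float = 50.0
    expand_min_pct: float = 70.0
    robustness_frac: float = 0.05
    robustness_iterations: int = 100
    rarefaction_draws: int = 25
    og_min_members: int = 3
    seed: int = 0
    stages: dict = field(
        default_factory=lambda: {
            "recruit": True, "dice": True, "tree": True, "lineages": True,
            "robustness": False, "expand": True, "profile": True,
        }
    )

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        cfg = cls()
        cfg.inputs = {k: str(v) for k, v in raw.get("input", {}).items()}
        out = raw.get("output", {}).get("dir")
        if out:
            cfg.out_dir = Path(out)
        filt = raw.get("filters", {})
        if "standard" in filt:
            cfg.standard = FilterProfile(**filt["standard"])
        if "marker_search" in filt:
            cfg.marker_search = FilterProfile(**filt["marker_search"])
        rec = raw.get("recruit", {})
        for k in ("min_pct", "min_avq", "r2_min_pct", "r2_min_matches"):
            if k in rec:
                setattr(cfg, k, rec[k])
        comp = raw.get("completeness", {})
        cfg.completeness_min_coverage = comp.get("min_coverage", cfg.completeness_min_coverage)
        cfg.completeness_min_length = comp.get("min_length", cfg.completeness_min_length)
        lin = raw.get("lineages", {})
        if "rules" in lin:
            cfg.rules = [LineageRule(int(l), float(d), int(s)) for l, d, s in lin["rules"]]
        exp = raw.get("expand", {})
        cfg.expand_min_aai = exp.get("min_aai", cfg.expand_min_aai)
        cfg.expand_min_pct = exp.get("min_pct", cfg.expand_min_pct)
        rob = raw.get("robustness", {})
        cfg.robustness_frac = rob.get("frac", cfg.robustness_frac)
        cfg.robustness_iterations = rob.get("iterations", cfg.robustness_iterations)
        prof = raw.get("profile", {})
        cfg.rarefaction_draws = prof.get("rarefaction_draws", cfg.rarefaction_draws)
        cfg.og_min_members = prof.get("og_min_members", cfg.og_min_members)
        cfg.seed = int(raw.get("seed", cfg.seed))
        cfg.stages.update(raw.get("stages", {}))
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "inputs": self.inputs,
                "standard": vars(self.standard),
                "marker_search": vars(self.marker_search),
                "recruit": [self.min_pct, self.min_avq, self.r2_min_pct, self.r2_min_matches],
                "completeness": [self.completeness_min_coverage, self.completeness_min_length],
                "rules": [[r.level, r.min_depth, r.min_size] for r in self.rules],
                "expand": [self.expand_min_aai, self.expand_min_pct],
                "robustness": [self.robustness_frac, self.robustness_iterations],
                "profile": [self.rarefaction_draws, self.og_min_members],
                "seed": self.seed,
                "stages": self.stages,
            },
            sort_keys=True,
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, cfg: RunConfig):
        self.cfg = cfg
        self.entries: list[dict] = []
        self.header = f"# gluvab {__version__} {cfg.config_hash()}\n"

    def add(self, stage: str, name: str, path: Path) -> None:
        self.entries.append(
            {"stage": stage, "name": name, "path": path.name, "sha256": _sha256(path)}
        )

    def write_tsv(self, stage: str, name: str, df: pd.DataFrame, path: Path, **kw) -> None:
        with open(path, "w") as fh:
            fh.write(self.header)
            df.to_csv(fh, sep="\t", index=kw.pop("index", False), **kw)
        self.add(stage, name, path)

    def dump(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"version": __version__, "config_hash": self.cfg.config_hash(),
                 "artifacts": self.entries},
                fh, indent=2, sort_keys=True,
            )
            fh.write("\n")


def _read_lengths(path: str | Path) -> dict[str, int]:
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            gid, ln = line.split("\t")
            out[gid] = int(ln)
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns the manifest dict.

    A failing stage aborts with the stage named; partial outputs stay in
    place under a ``failed/<stage>`` marker file.
    """
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_dir = out / "failed"
    if failed_dir.exists():
        for f in failed_dir.iterdir():
            f.unlink()
        failed_dir.rmdir()
    manifest = _Manifest(cfg)

    required = {"hits", "protein_map"}
    if cfg.stages.get("recruit"):
        required |= {"marker_hits", "markers", "lengths"}
    if cfg.stages.get("expand"):
        required |= {"fragment_hits"}
    if cfg.stages.get("profile"):
        required |= {"counts", "metadata"}
    for name in sorted(required):
        p = cfg.inputs.get(name)
        if not p or not Path(p).exists():
            raise FileNotFoundError(f"required input {name!r} missing or not found: {p}")

    stage = "load"
    try:
        protein_map = read_protein_map(cfg.inputs["protein_map"])
        hits = parse_hit_table(cfg.inputs["hits"], cfg.standard).with_genomes(protein_map)
        lengths = _read_lengths(cfg.inputs["lengths"]) if "lengths" in cfg.inputs else {}
        metadata = (
            pd.read_csv(cfg.inputs["metadata"], sep="\t", comment="#").set_index("genome_id")
            if "metadata" in cfg.inputs
            else pd.DataFrame()
        )

        recruited: set[str] | None = None
        if cfg.stages.get("recruit"):
            stage = "recruit"
            markers = read_marker_db(cfg.inputs["markers"])
            marker_hits = parse_hit_table(
                cfg.inputs["marker_hits"], cfg.marker_search
            ).with_genomes(protein_map, subjects_are_proteins=False)
            if "decoy_marker_hits" in cfg.inputs:
                decoy_hits = parse_hit_table(cfg.inputs["decoy_marker_hits"], cfg.marker_search)
                markers = prune_marker_db(markers, decoy_hits)
            counts_by_genome = hits.protein_counts
            scores = {
                g: score_avq(g, marker_hits, markers, n)
                for g, n in sorted(counts_by_genome.items())
            }
            r1 = recruit_round1(scores, cfg.min_pct, cfg.min_avq)
            r2 = recruit_round2(hits, r1, cfg.r2_min_pct, cfg.r2_min_matches)
            complete_ids = (
                set(metadata.index[metadata.get("complete", pd.Series(dtype=bool)) == True])  # noqa: E712
                if not metadata.empty
                else set()
            )
            comp = (
                tag_completeness(
                    complete_ids, hits, lengths,
                    cfg.completeness_min_coverage, cfg.completeness_min_length,
                )
                if complete_ids
                else {}
            )
            for g in complete_ids:
                comp[g] = "complete"
            report = build_report(scores, r1, r2, comp, {})
            manifest.write_tsv("recruit", "recruitment_report", report.rows, out / "recruitment.tsv")
            recruited = r1 | set(r2)

        stage = "dice"
        in_hits = set(hits.df["qgenome"]) | set(hits.df["sgenome"])
        tree_ids = sorted(in_hits if recruited is None else (in_hits & recruited))
        if cfg.stages.get("dice") or cfg.stages.get("tree") or cfg.stages.get("lineages"):
            dm = dice_from_hits(
                HitTable(
                    hits.df[hits.df["qgenome"].isin(tree_ids) & hits.df["sgenome"].isin(tree_ids)],
                    hits.protein_to_genome,
                    hits.protein_counts,
                ),
                ids=tree_ids,
            )
            if cfg.stages.get("dice"):
                write_tsv(dm, out / "dice_matrix.tsv")
                manifest.add("dice", "dice_matrix", out / "dice_matrix.tsv")
                write_phylip(dm, out / "dice_matrix.phylip")
                manifest.add("dice", "dice_matrix_phylip", out / "dice_matrix.phylip")

        tree = None
        if cfg.stages.get("tree") or cfg.stages.get("lineages"):
            stage = "tree"
            tree = build_tree(dm)
            write_newick(tree, out / "tree.nwk")
            manifest.add("tree", "tree_newick", out / "tree.nwk")
            manifest.write_tsv("tree", "node_depths", depth_table(tree), out / "node_depths.tsv")

        partitions = {}
        if cfg.stages.get("lineages"):
            stage = "lineages"
            for rule in cfg.rules:
                partitions[rule.level] = extract_lineages(tree, rule)
            rows = []
            for gid in tree_ids:
                rows.append(
                    [gid]
                    + [partitions[r.level].as_labels().get(gid, "") for r in cfg.rules]
                )
            lineage_df = pd.DataFrame(
                rows, columns=["genome_id"] + [f"level{r.level}" for r in cfg.rules]
            )
            manifest.write_tsv("lineages", "lineage_partition", lineage_df, out / "lineages.tsv")

        if cfg.stages.get("robustness"):
            stage = "robustness"
            prot_ids = sorted(p for p, g in protein_map.items() if g in set(tree_ids))
            freq = resample_robustness(
                hits, prot_ids, tree,
                frac=cfg.robustness_frac, iterations=cfg.robustness_iterations, seed=cfg.seed,
            )
            dt = depth_table(tree)
            dt["recovery"] = dt["node_id"].map(freq)
            manifest.write_tsv("robustness", "node_recovery", dt, out / "robustness.tsv")

        expanded = None
        if cfg.stages.get("expand"):
            stage = "expand"
            frag_hits = parse_hit_table(cfg.inputs["fragment_hits"], cfg.standard).with_genomes(
                protein_map
            )
            queries = sorted(set(frag_hits.df["qgenome"]) - set(tree_ids))
            cands = {
                gid: {
                    f"level{lvl}": part.as_labels()[gid]
                    for lvl, part in partitions.items()
                    if gid in part.as_labels()
                }
                for gid in tree_ids
            }
            expanded = expand_lineages(
                queries, cands, frag_hits, min_aai=cfg.expand_min_aai, min_pct=cfg.expand_min_pct
            )
            manifest.write_tsv("expand", "cri_assignments", expanded, out / "expanded.tsv")

        if cfg.stages.get("profile"):
            stage = "profile"
            counts = read_counts(cfg.inputs["counts"])
            level1 = partitions.get(1)
            ab = lineage_abundance(counts, level1)
            manifest.write_tsv("profile", "lineage_abundance", ab, out / "abundance.tsv", index=True)
            def _labels(col: str) -> dict[str, str]:
                s = metadata[col].dropna()
                return {str(g): str(v) for g, v in s.items() if str(v)}

            for attr in ("host_phylum", "ecosystem"):
                if attr in metadata.columns:
                    prev = prevalence(level1, _labels(attr))
                    manifest.write_tsv("profile", f"prevalence_{attr}", prev,
                                       out / f"prevalence_{attr}.tsv")
            if "ecosystem" in metadata.columns:
                lin_of = level1.as_labels()
                ecos = _labels("ecosystem")
                pool_max = max(
                    pd.Series(ecos).value_counts().max(), 1
                )
                grid = sorted({n for n in (1, 2, 5, 10, 20, pool_max) if n <= pool_max})
                rf = rarefaction(ecos, lin_of, grid, draws=cfg.rarefaction_draws, seed=cfg.seed)
                manifest.write_tsv("profile", "rarefaction", rf, out / "rarefaction.tsv")
            if "og_membership" in cfg.inputs and Path(cfg.inputs["og_membership"]).exists():
                og_map = read_protein_map(cfg.inputs["og_membership"])
                og = og_prevalence(og_map, protein_map, level1, cfg.og_min_members)
                manifest.write_tsv("profile", "og_prevalence", og, out / "og_prevalence.tsv")
    except Exception as exc:
        (out / "failed").mkdir(exist_ok=True)
        (out / "failed" / stage).touch()
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest.dump(out / "manifest.json")
    result = {"version": __version__, "config_hash": cfg.config_hash(),
              "artifacts": manifest.entries}
    return result
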