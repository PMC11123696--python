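"""Funnel orchestration: shape screen -> drug-like filter -> docking-score
consensus -> pose criteria, with per-stage bookkeeping and artifacts.

Docking itself is consumed, never invoked: the pipeline ingests pose SDF
files and per-program score tables, so any engine's output can be plugged in
through those two formats.  Stage outputs are written as TSV/plain text and
content-hashed into the summary so a rerun with the same config and seed is
byte-identical and auditable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from . import druglike_filter, mol_model, pose_criteria, shape_screen, synthetic_data
from .interaction_profile import GeometryParams, ResidueRef, detect_interactions, read_pdb
from .pose_criteria import CriteriaConfig, ScoreTable, SelectionReport

__all__ = [
    "ConfigError",
    "DataError",
    "PipelineConfig",
    "run_pipeline",
    "simulate_study",
]


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


class DataError(ValueError):
    """Unreadable or inconsistent input data."""


@dataclass
class PipelineConfig:
    query_sdf: str
    library_sdf: str
    receptor_pdb: str
    poses: Dict[str, str]  # program name -> pose SDF
    score_tables: List[str]  # two TSV paths
    out_dir: str
    seed: int = 0
    shape_top_n: Optional[int] = None
    shape_top_fraction: Optional[float] = None
    docking_top_n: int = 25
    max_lipinski_violations: int = 3
    criteria: Dict[str, int] = field(default_factory=dict)
    site: Optional[List[str]] = None  # entries like "F95:A"; default: all residues

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text())
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        missing = [
            f
            for f in ("query_sdf", "library_sdf", "receptor_pdb", "poses", "score_tables", "out_dir")
            if f not in raw
        ]
        if missing:
            raise ConfigError(f"missing config fields: {missing}")
        cfg = cls(**raw)
        cfg.validate(base=Path(path).parent)
        return cfg

    def validate(self, base: Optional[Path] = None) -> None:
        base = base or Path(".")

        def resolve(p: str) -> str:
            q = Path(p)
            return str(q if q.is_absolute() else base / q)

        self.query_sdf = resolve(self.query_sdf)
        self.library_sdf = resolve(self.library_sdf)
        self.receptor_pdb = resolve(self.receptor_pdb)
        self.poses = {k: resolve(v) for k, v in self.poses.items()}
        self.score_tables = [resolve(p) for p in self.score_tables]
        self.out_dir = resolve(self.out_dir)
        for name in ("query_sdf", "library_sdf", "receptor_pdb"):
            if not Path(getattr(self, name)).exists():
                raise ConfigError(f"{name}: path does not exist: {getattr(self, name)}")
        for prog, p in self.poses.items():
            if not Path(p).exists():
                raise ConfigError(f"poses[{prog}]: path does not exist: {p}")
        if len(self.score_tables) != 2:
            raise ConfigError("exactly two score tables are required")
        for p in self.score_tables:
            if not Path(p).exists():
                raise ConfigError(f"score table does not exist: {p}")
        if len(self.poses) != 2:
            raise ConfigError("exactly two pose files (one per program) are required")

    def criteria_config(self) -> CriteriaConfig:
        return CriteriaConfig(**self.criteria) if self.criteria else CriteriaConfig()

    def site_refs(self, protein) -> Optional[List[ResidueRef]]:
        if self.site is None:
            return None
        refs = []
        for entry in self.site:
            label, _, chain = entry.partition(":")
            refs.append(ResidueRef(chain or "A", label[0], int(label[1:])))
        return refs


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> SelectionReport:
    """Execute the funnel; returns the stage report and writes artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: List[Path] = []

    # stage 1: shape screen
    try:
        query_confs = mol_model.read_sdf(config.query_sdf)
        library_confs = mol_model.read_sdf(config.library_sdf)
    except mol_model.SdfError as exc:
        raise DataError(f"shape_screen inputs: {exc}") from exc
    if not query_confs:
        raise DataError("query SDF contains no records")
    query = query_confs[0]
    library = mol_model.group_by_compound(library_confs)
    n_library = len(library)
    hits = shape_screen.screen(
        query,
        library,
        top_n=config.shape_top_n,
        top_fraction=config.shape_top_fraction,
    )
    survivors1 = [h.compound_id for h in hits]
    p = out / "shape_hits.tsv"
    with p.open("w") as fh:
        fh.write("compound\tconformer\tshape_tanimoto\trank\n")
        for h in hits:
            fh.write(f"{h.compound_id}\t{h.conformer_id}\t{h.score:.6f}\t{h.rank}\n")
    artifacts.append(p)

    # stage 2: drug-like filter
    ruleset = druglike_filter.RuleSet(max_lipinski_violations=config.max_lipinski_violations)
    pairs = []
    for cid in survivors1:
        mol = library[cid][0].molecule
        pairs.append((mol, mol_model.compute_properties(mol)))
    retained, verdicts, _ = druglike_filter.apply_filter(pairs, ruleset)
    survivors2 = [m.id for m in retained]
    p = out / "filter_verdicts.tsv"
    with p.open("w") as fh:
        fh.write("compound\tlipinski_violations\talerts\taggregator\tpass\n")
        for v in verdicts:
            fh.write(
                f"{v.compound_id}\t{v.lipinski_violations}\t"
                f"{';'.join(v.alert_hits) or '-'}\t{int(v.aggregator)}\t{int(v.overall_pass)}\n"
            )
    artifacts.append(p)

    # stage 3: per-program top-N + consensus union
    tables = [pose_criteria.read_score_table(p) for p in config.score_tables]
    survivor_set = set(survivors2)
    tops: List[List[str]] = []
    for table in tables:
        restricted = ScoreTable(
            program=table.program,
            orientation=table.orientation,
            scores={k: v for k, v in table.scores.items() if k in survivor_set},
        )
        n_eff = min(config.docking_top_n, len(restricted.scores))
        tops.append(pose_criteria.select_top(restricted, n_eff))
    union, overlap = pose_criteria.consensus_union(tops[0], tops[1])
    p = out / "consensus.tsv"
    with p.open("w") as fh:
        fh.write("compound\tin_" + tables[0].program + "\tin_" + tables[1].program + "\n")
        for cid in union:
            fh.write(f"{cid}\t{int(cid in tops[0])}\t{int(cid in tops[1])}\n")
    artifacts.append(p)

    # stage 4: interaction profiling + visual-inspection criteria
    protein = read_pdb(config.receptor_pdb)
    site = config.site_refs(protein)
    crit_cfg = config.criteria_config()
    pose_sets: Dict[str, Dict[str, mol_model.Conformer]] = {}
    for prog, path in config.poses.items():
        confs = mol_model.read_sdf(path)
        pose_sets[prog] = {c.compound_id: c for c in confs}
    rows = []
    final: List[str] = []
    for cid in union:
        passes = []
        for prog in sorted(pose_sets):
            pose = pose_sets[prog].get(cid)
            if pose is None:
                passes.append(False)
                rows.append((cid, prog, 0, "", 0))
                continue
            profile = detect_interactions(protein, pose, site=site)
            verdict = pose_criteria.evaluate_criteria(profile, crit_cfg, site=site)
            passes.append(verdict.overall_pass)
            rows.append(
                (
                    cid,
                    prog,
                    verdict.n_interactions,
                    ";".join(verdict.key_residues),
                    int(verdict.overall_pass),
                )
            )
        if all(passes):
            final.append(cid)
    p = out / "criteria_verdicts.tsv"
    with p.open("w") as fh:
        fh.write("compound\tprogram\tn_interactions\tkey_residues\tpass\n")
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")
    artifacts.append(p)

    # funnel summary
    report = SelectionReport()
    report.add_stage("shape_screen", n_library, len(survivors1))
    report.add_stage("druglike_filter", len(survivors1), len(survivors2))
    report.add_stage("docking_consensus", len(survivors2), len(union))
    report.add_stage("visual_criteria", len(union), len(final))
    report.overlaps[f"{tables[0].program}&{tables[1].program}"] = overlap
    report.final_selection = final
    p = out / "funnel_summary.tsv"
    p.write_text(report.to_text())
    artifacts.append(p)

    manifest = {
        "seed": config.seed,
        "artifacts": {a.name: _sha256(a) for a in artifacts},
        "final_selection": final,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return report


# --------------------------------------------------------------------------
# End-to-end synthetic study
# --------------------------------------------------------------------------

_STRONG_SPEC = [
    synthetic_data.PlantSpec("A", "F88", "HD"),
    synthetic_data.PlantSpec("A", "F95", "HD"),
    synthetic_data.PlantSpec("A", "M105", "HD"),
    synthetic_data.PlantSpec("A", "I310", "HD"),
    synthetic_data.PlantSpec("A", "D92", "HB"),
    synthetic_data.PlantSpec("A", "K110", "HB"),
]
_MEDIUM_SPEC = [
    synthetic_data.PlantSpec("A", "F95", "HD"),
    synthetic_data.PlantSpec("A", "D92", "HB"),
]
_WEAK_SPEC = [synthetic_data.PlantSpec("A", "F95", "HD")]


def simulate_study(
    seed: int,
    n_compounds: int,
    out_dir,
    shape_top_fraction: float = 0.5,
    docking_top_n: int = 6,
    overlap_k: int = 2,
    conformers: Tuple[int, int] = (1, 3),
) -> Path:
    """Generate a complete synthetic study and its pipeline config.

    Writes query/library SDF, the pocket PDB, two pose SDFs with planted
    interaction profiles (a seeded mix of criteria-passing and failing
    poses), two score tables with a controlled top-N overlap, and a
    ``config.yml`` ready for :func:`run_pipeline`.  Returns the config path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    lib_confs, _ = synthetic_data.gen_library(
        synthetic_data.GeneratorConfig(
            seed=seed, n_compounds=n_compounds, conformers=conformers
        )
    )
    mol_model.write_sdf(lib_confs, out / "library.sdf")
    query_confs, _ = synthetic_data.gen_library(
        synthetic_data.GeneratorConfig(seed=seed + 1000, n_compounds=1, conformers=(1, 1))
    )
    query = query_confs[0]
    query.molecule.id = "QUERY"
    mol_model.write_sdf([query], out / "query.sdf")

    pocket = synthetic_data.gen_pocket()
    synthetic_data.write_pocket_pdb(pocket, out / "pocket.pdb")

    ids = sorted({c.compound_id for c in lib_confs})
    table_a, table_b = synthetic_data.gen_score_tables(
        ids, n_top=docking_top_n, overlap_k=overlap_k, seed=seed + 1
    )
    pose_criteria.write_score_table(table_a, out / "scores_a.tsv")
    pose_criteria.write_score_table(table_b, out / "scores_b.tsv")

    pose_files = {}
    for prog in (table_a.program, table_b.program):
        poses = []
        for cid in ids:
            u = rng.random()
            spec = _STRONG_SPEC if u < 0.45 else (_MEDIUM_SPEC if u < 0.7 else _WEAK_SPEC)
            pose, _ = synthetic_data.plant_pose(pocket, spec, ligand_id=cid)
            poses.append(pose)
        fname = f"poses_{prog.replace('-', '_')}.sdf"
        mol_model.write_sdf(poses, out / fname)
        pose_files[prog] = fname

    config = {
        "seed": int(seed),
        "query_sdf": "query.sdf",
        "library_sdf": "library.sdf",
        "receptor_pdb": "pocket.pdb",
        "poses": pose_files,
        "score_tables": ["scores_a.tsv", "scores_b.tsv"],
        "out_dir": "results",
        "shape_top_fraction": float(shape_top_fraction),
        "docking_top_n": int(docking_top_n),
    }
    cfg_path = out / "config.yml"
    cfg_path.write_text(yaml.safe_dump(config, sort_keys=True))
    return cfg_path
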