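"""Visual-inspection acceptance criteria, top-N consensus and funnel math.

A docked pose is accepted when its interaction profile (i) makes at least
six interactions with binding-site residues, (ii) touches at least four
"key" residues with the interaction type required for each (hydrophobic for
the aromatic/aliphatic wall residues, H-bond or salt bridge for the acidic
anchor, H-bond or hydrophobic for the tyrosine contributed by the adjacent
subunit), and (iii) makes at least one additional polar interaction
(H-bond, ionic or cation-pi) beyond the ones consuming key slots.  A strict
alternative reading of (iii) — the polar partner must not be a key residue
at all — is available via configuration.

Consensus selection takes the union of the top-N compounds from two
independent scoring programs; funnel bookkeeping reports per-stage percent
reductions at one decimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

from .interaction_profile import InteractionProfile, InteractionRecord, ResidueRef

__all__ = [
    "KeySlot",
    "KeyResidueSpec",
    "default_key_spec",
    "CriteriaConfig",
    "CriteriaVerdict",
    "ScoreTable",
    "evaluate_criteria",
    "select_top",
    "consensus_union",
    "stage_reduction",
    "StageRecord",
    "SelectionReport",
    "read_score_table",
    "write_score_table",
]

POLAR_TYPES = frozenset({"HB", "SB", "PICAT"})
AROMATIC_CODES = frozenset({"F", "Y", "W", "H"})


@dataclass(frozen=True)
class KeySlot:
    """Allowed interaction types for one key residue."""

    types: FrozenSet[str]
    adjacent: bool = False  # must come from a chain other than the primary


KeyResidueSpec = Dict[str, KeySlot]


def default_key_spec(pipi_counts_hydrophobic: bool = True) -> KeyResidueSpec:
    """Key residues of the allosteric pocket and their qualifying types.

    With ``pipi_counts_hydrophobic`` (default), pi-stacking satisfies the
    hydrophobic slot of aromatic key residues, since profiles routinely mix
    HD and pi-pi contacts at the same phenylalanine/tyrosine.
    """
    hydrophobic = ["F88", "F95", "F103", "M105", "F108", "Y295", "I310"]
    spec: KeyResidueSpec = {}
    for label in hydrophobic:
        types = {"HD"}
        if pipi_counts_hydrophobic and label[0] in AROMATIC_CODES:
            types.add("PIPI")
        spec[label] = KeySlot(frozenset(types))
    spec["D92"] = KeySlot(frozenset({"HB", "SB"}))
    spec["Y298"] = KeySlot(frozenset({"HB", "HD"}), adjacent=True)
    return spec


@dataclass
class CriteriaConfig:
    min_total_interactions: int = 6
    min_key_residues: int = 4
    min_extra_polar: int = 1
    polar_types: FrozenSet[str] = POLAR_TYPES
    key_spec: KeyResidueSpec = field(default_factory=default_key_spec)
    strict_other_residue: bool = False
    primary_chain: str = "A"

    def __post_init__(self) -> None:
        if min(self.min_total_interactions, self.min_key_residues, self.min_extra_polar) < 0:
            raise ValueError("criteria minima must be non-negative")
        if not self.key_spec:
            raise ValueError("key residue specification must be non-empty")


@dataclass
class CriteriaVerdict:
    pose_id: str
    crit_total: bool
    crit_key: bool
    crit_extra_polar: bool
    n_interactions: int
    key_residues: List[str]
    extra_polar_records: List[InteractionRecord]

    @property
    def overall_pass(self) -> bool:
        return self.crit_total and self.crit_key and self.crit_extra_polar


def _slot_satisfied(rec: InteractionRecord, label: str, slot: KeySlot, primary: str) -> bool:
    if rec.residue.label != label or rec.type not in slot.types:
        return False
    if slot.adjacent and rec.residue.chain == primary:
        return False
    return True


def evaluate_criteria(
    profile: InteractionProfile,
    config: Optional[CriteriaConfig] = None,
    site: Optional[Sequence[ResidueRef]] = None,
) -> CriteriaVerdict:
    """Apply the three pose-acceptance criteria to an interaction profile.

    When ``site`` is given, every key residue label must be resolvable in it
    (configuration error otherwise).  Criterion (i) counts distinct
    (chain, residue, type) records; (ii) counts distinct key residues with a
    qualifying record; (iii) requires a polar record not consumed by a key
    slot (or, in strict mode, on a residue outside the key list).
    """
    config = config or CriteriaConfig()
    if site is not None:
        site_labels = {ref.label for ref in site}
        missing = [k for k in config.key_spec if k not in site_labels]
        if missing:
            raise ValueError(f"key residues absent from site definition: {missing}")

    distinct = {(r.residue.chain, r.residue.label, r.type) for r in profile.records}
    n_inter = len(distinct)

    satisfied: List[str] = []
    consumed: Set[Tuple[str, str, str]] = set()
    for label, slot in config.key_spec.items():
        hit = False
        for rec in profile.records:
            if _slot_satisfied(rec, label, slot, config.primary_chain):
                hit = True
                consumed.add((rec.residue.chain, rec.residue.label, rec.type))
        if hit:
            satisfied.append(label)

    extras: List[InteractionRecord] = []
    seen: Set[Tuple[str, str, str]] = set()
    for rec in profile.records:
        if rec.type not in config.polar_types:
            continue
        key = (rec.residue.chain, rec.residue.label, rec.type)
        if key in seen:
            continue
        if config.strict_other_residue:
            if rec.residue.label in config.key_spec:
                continue
        elif key in consumed:
            continue
        seen.add(key)
        extras.append(rec)

    return CriteriaVerdict(
        pose_id=profile.pose_id,
        crit_total=n_inter >= config.min_total_interactions,
        crit_key=len(satisfied) >= config.min_key_residues,
        crit_extra_polar=len(extras) >= config.min_extra_polar,
        n_interactions=n_inter,
        key_residues=sorted(satisfied),
        extra_polar_records=extras,
    )


# --------------------------------------------------------------------------
# Score tables and consensus
# --------------------------------------------------------------------------


@dataclass
class ScoreTable:
    program: str
    orientation: str  # "higher" or "lower" is better
    scores: Dict[str, float]

    def __post_init__(self) -> None:
        if self.orientation not in ("higher", "lower"):
            raise ValueError("orientation must be 'higher' or 'lower'")
        for cid, s in self.scores.items():
            if not math.isfinite(s):
                raise ValueError(f"non-finite score for {cid}")


def select_top(table: ScoreTable, n: int) -> List[str]:
    """Top-n compound ids by declared orientation, lexicographic tie-break."""
    if n > len(table.scores):
        raise ValueError(f"requested top {n} from table of {len(table.scores)}")
    sign = -1.0 if table.orientation == "higher" else 1.0
    ordered = sorted(table.scores, key=lambda cid: (sign * table.scores[cid], cid))
    return ordered[:n]


def consensus_union(list_a: Sequence[str], list_b: Sequence[str]) -> Tuple[List[str], int]:
    """Union of two selections (A's order, then B's novel ids) + overlap size."""
    seen = set(list_a)
    union = list(list_a) + [cid for cid in list_b if cid not in seen]
    overlap = len(seen & set(list_b))
    return union, overlap


def stage_reduction(before: int, after: int) -> float:
    """Percent reduction 100*(before-after)/before, one decimal."""
    if before <= 0:
        raise ValueError("before must be positive")
    if not 0 <= after <= before:
        raise ValueError("after must be in [0, before]")
    return round(100.0 * (before - after) / before, 1)


@dataclass
class StageRecord:
    name: str
    before: int
    after: int

    @property
    def reduction_percent(self) -> float:
        return stage_reduction(self.before, self.after)


@dataclass
class SelectionReport:
    stages: List[StageRecord] = field(default_factory=list)
    overlaps: Dict[str, int] = field(default_factory=dict)
    final_selection: List[str] = field(default_factory=list)
    manual_review_flags: List[str] = field(
        default_factory=lambda: [
            "shape complementarity with the binding site",
            "reproducibility of the best-scoring pose",
            "absence of steric strain in the pose",
        ]
    )

    def add_stage(self, name: str, before: int, after: int) -> StageRecord:
        if after > before:
            raise ValueError(f"stage {name}: after ({after}) exceeds before ({before})")
        rec = StageRecord(name, before, after)
        self.stages.append(rec)
        return rec

    def to_text(self) -> str:
        lines = ["stage\tbefore\tafter\treduction_%"]
        for s in self.stages:
            lines.append(f"{s.name}\t{s.before}\t{s.after}\t{s.reduction_percent}")
        for name, k in self.overlaps.items():
            lines.append(f"# overlap {name}: {k}")
        if self.final_selection:
            lines.append("# final selection: " + ", ".join(self.final_selection))
        lines.append(
            "# manual review (not auto-decided): " + "; ".join(self.manual_review_flags)
        )
        return "\n".join(lines) + "\n"


def read_score_table(path) -> ScoreTable:
    """Read a TSV with columns program, orientation, compound, score."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"compound": str})
    required = {"program", "orientation", "compound", "score"}
    if not required <= set(df.columns):
        raise ValueError(f"score table missing columns {required - set(df.columns)}")
    programs = df["program"].unique()
    orientations = df["orientation"].unique()
    if len(programs) != 1 or len(orientations) != 1:
        raise ValueError("score table must contain one program/orientation")
    return ScoreTable(
        program=str(programs[0]),
        orientation=str(orientations[0]),
        scores=dict(zip(df["compound"], df["score"].astype(float))),
    )


def write_score_table(table: ScoreTable, path) -> None:
    import pandas as pd

    rows = [
        {"program": table.program, "orientation": table.orientation, "compound": cid, "score": s}
        for cid, s in sorted(table.scores.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
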