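"""Drug-likeness rule engine.

A configurable "blockbuster"-style filter: hard numeric ranges over the
property profile, a Lipinski rule-of-five secondary filter relaxed to allow
a configurable number of violations (default 3), SMARTS structural alerts
for protein-reactive / redox-cycling / chelating groups, and an
exact-structure aggregator blacklist.  The shipped numeric defaults are this
package's own choices (documented in the ruleset below and overridable in
config); they make no claim of reproducing any vendor's proprietary
thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from rdkit import Chem

from .mol_model import Molecule, PropertyProfile

__all__ = [
    "RuleSet",
    "RuleVerdict",
    "FilterReport",
    "DEFAULT_ALERTS",
    "DEFAULT_AGGREGATORS",
    "lipinski_violations",
    "match_alerts",
    "is_aggregator",
    "apply_filter",
]

#: named SMARTS patterns for reactive/undesirable groups
DEFAULT_ALERTS: List[Tuple[str, str]] = [
    ("acyl_halide", "[CX3](=O)[F,Cl,Br,I]"),
    ("aldehyde", "[CX3H1](=O)[#6,#1]"),
    ("epoxide", "[OX2r3]1[#6r3][#6r3]1"),
    ("michael_acceptor", "[CX3]=[CX3][CX3]=[OX1]"),
    ("quinone", "O=C1C=CC(=O)C=C1"),
    ("ortho_quinone", "O=C1C(=O)C=CC=C1"),
    ("hydroxamic_acid_chelator", "[CX3](=O)[NX3][OX2H1]"),
]

#: small illustrative exact-structure aggregator list (known promiscuous
#: colloidal aggregators); matching is by canonical-SMILES identity
DEFAULT_AGGREGATORS: List[str] = [
    "Oc1ccc(/C=C/c2cc(O)cc(O)c2)cc1",  # resveratrol
    "O=c1c(O)c(-c2ccc(O)c(O)c2)oc2cc(O)cc(O)c12",  # quercetin
    "O=C(O)c1cc(O)c(O)c(O)c1",  # gallic acid
]


@dataclass
class RuleSet:
    """Named numeric ranges plus alert and aggregator configuration.

    ``ranges`` maps a PropertyProfile field name to an inclusive
    (lower, upper) interval; ``None`` means unbounded on that side.
    """

    ranges: Dict[str, Tuple[Optional[float], Optional[float]]] = field(
        default_factory=lambda: {
            "mw": (130.0, 781.0),
            "clogp": (None, 6.85),
            "hbd": (None, 6),
            "hba": (None, 10),
            "rotatable": (None, 14),
            "ring_systems": (None, 6),
            "chiral_centers": (None, 10),
            "tpsa": (None, 205.0),
        }
    )
    max_lipinski_violations: int = 3
    alerts: List[Tuple[str, str]] = field(default_factory=lambda: list(DEFAULT_ALERTS))
    aggregators: List[str] = field(default_factory=lambda: list(DEFAULT_AGGREGATORS))

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.ranges.items():
            if lo is not None and hi is not None and lo > hi:
                raise ValueError(f"range for {name} has lower > upper")
        if not 0 <= self.max_lipinski_violations <= 4:
            raise ValueError("max_lipinski_violations must be in [0, 4]")
        self._compiled = []
        for name, smarts in self.alerts:
            patt = Chem.MolFromSmarts(smarts)
            if patt is None:
                raise ValueError(f"malformed alert SMARTS for {name!r}: {smarts!r}")
            self._compiled.append((name, patt))
        self._agg_canonical = set()
        for smi in self.aggregators:
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                raise ValueError(f"malformed aggregator SMILES: {smi!r}")
            self._agg_canonical.add(Chem.MolToSmiles(mol))


@dataclass
class RuleVerdict:
    compound_id: str
    rule_outcomes: Dict[str, Tuple[bool, float]]
    lipinski_violations: int
    alert_hits: List[str]
    aggregator: bool
    overall_pass: bool


@dataclass
class FilterReport:
    before: int
    after: int

    @property
    def reduction_percent(self) -> float:
        return round(100.0 * (self.before - self.after) / self.before, 1)


def lipinski_violations(p: PropertyProfile) -> int:
    """Rule-of-five violation count: MW>500, clogP>5, HBD>5, HBA>10."""
    return sum(
        [p.mw > 500.0, p.clogp > 5.0, p.hbd > 5, p.hba > 10]
    )


def match_alerts(m: Molecule, ruleset: Optional[RuleSet] = None) -> List[str]:
    """Names of alert substructures present in the molecule."""
    ruleset = ruleset or RuleSet()
    mol = m.to_rdkit()
    return [name for name, patt in ruleset._compiled if mol.HasSubstructMatch(patt)]


def is_aggregator(m: Molecule, ruleset: Optional[RuleSet] = None) -> bool:
    ruleset = ruleset or RuleSet()
    return Chem.MolToSmiles(m.to_rdkit()) in ruleset._agg_canonical


def _check_ranges(
    profile: PropertyProfile, ruleset: RuleSet
) -> Dict[str, Tuple[bool, float]]:
    out: Dict[str, Tuple[bool, float]] = {}
    for name, (lo, hi) in ruleset.ranges.items():
        value = float(getattr(profile, name))
        ok = (lo is None or value >= lo) and (hi is None or value <= hi)
        out[name] = (ok, value)
    return out


def evaluate_compound(
    m: Molecule, profile: PropertyProfile, ruleset: Optional[RuleSet] = None
) -> RuleVerdict:
    """Full verdict for one compound: ranges, Lipinski count, alerts."""
    ruleset = ruleset or RuleSet()
    outcomes = _check_ranges(profile, ruleset)
    violations = lipinski_violations(profile)
    hits = match_alerts(m, ruleset)
    agg = is_aggregator(m, ruleset)
    overall = (
        all(ok for ok, _ in outcomes.values())
        and violations <= ruleset.max_lipinski_violations
        and not hits
        and not agg
    )
    return RuleVerdict(
        compound_id=m.id,
        rule_outcomes=outcomes,
        lipinski_violations=violations,
        alert_hits=hits,
        aggregator=agg,
        overall_pass=overall,
    )


def apply_filter(
    compounds: Sequence[Tuple[Molecule, PropertyProfile]],
    ruleset: Optional[RuleSet] = None,
) -> Tuple[List[Molecule], List[RuleVerdict], FilterReport]:
    """Filter compounds; returns (retained, per-compound verdicts, report)."""
    ruleset = ruleset or RuleSet()
    verdicts = [evaluate_compound(m, p, ruleset) for m, p in compounds]
    retained = [m for (m, _), v in zip(compounds, verdicts) if v.overall_pass]
    report = FilterReport(before=len(compounds), after=len(retained))
    return retained, verdicts, report
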