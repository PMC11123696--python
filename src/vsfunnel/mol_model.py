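"""Chemical data model and property calculators.

Small molecules are represented by a light-weight :class:`Molecule` graph
(element, formal charge, aromatic flag, implicit hydrogen count per atom;
bond orders 1/2/3/aromatic) plus :class:`Conformer` objects that carry
heavy-atom 3D coordinates in Angstrom.  RDKit does the heavy lifting for
SMILES parsing/writing, SDF V2000 I/O and the fragment/atom-contribution
descriptors (TPSA, Crippen clogP); the molecular-formula arithmetic and the
counting conventions used by the drug-likeness rules are defined here so the
conventions are explicit and testable.

Conventions
-----------
* HBD: number of N/O atoms bearing at least one hydrogen.
* HBA: number of N plus O atoms (Lipinski count).
* Rotatable bond: non-ring single bond between two heavy atoms that each
  have heavy-atom degree >= 2, excluding amide C-N bonds.
* Hydrogens are implicit throughout; conformers store heavy atoms only.
  Polar hydrogens needed for H-bond angle checks may ride along as optional
  extra positions on a pose conformer.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "ATOMIC_WEIGHTS",
    "MolecularFormula",
    "parse_formula",
    "molecular_weight",
    "Molecule",
    "Conformer",
    "PropertyProfile",
    "parse_smiles",
    "write_smiles",
    "compute_properties",
    "read_sdf",
    "write_sdf",
    "read_smiles_file",
    "group_by_compound",
    "FormulaError",
    "SmilesError",
    "SdfError",
]


class FormulaError(ValueError):
    """Malformed or unsupported molecular formula."""


class SmilesError(ValueError):
    """Unparseable SMILES input."""


class SdfError(ValueError):
    """Malformed SDF record."""


#: IUPAC conventional atomic weights (g/mol), abridged to the elements that
#: occur in drug-like small molecules.
ATOMIC_WEIGHTS: Dict[str, float] = {
    "H": 1.008,
    "B": 10.81,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "Na": 22.990,
    "Mg": 24.305,
    "Si": 28.085,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "K": 39.098,
    "Ca": 40.078,
    "Br": 79.904,
    "I": 126.904,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class MolecularFormula(Dict[str, int]):
    """Element -> count mapping; only positive counts are stored."""

    def __init__(self, counts: Optional[Dict[str, int]] = None):
        super().__init__()
        for el, n in (counts or {}).items():
            if el not in ATOMIC_WEIGHTS:
                raise FormulaError(f"unknown element symbol {el!r}")
            if n < 0:
                raise FormulaError(f"negative count for {el}")
            if n > 0:
                self[el] = int(n)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self)
        for el, n in other.items():
            merged[el] = merged.get(el, 0) + n
        return MolecularFormula(merged)


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-notation formula such as ``C25H26O6``.

    Raises :class:`FormulaError` naming the offending token for unknown
    element symbols or malformed counts.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula")
    text = text.strip()
    counts: Dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if not m or not m.group(1):
            raise FormulaError(f"malformed formula at {text[pos:]!r}")
        el, digits = m.group(1), m.group(2)
        if el not in ATOMIC_WEIGHTS:
            raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return MolecularFormula(counts)


def molecular_weight(f: MolecularFormula) -> float:
    """Molecular weight in g/mol from conventional atomic weights."""
    return float(sum(n * ATOMIC_WEIGHTS[el] for el, n in f.items()))


# --------------------------------------------------------------------------
# Molecule graph
# --------------------------------------------------------------------------

#: bond order encoding: 1, 2, 3 or the string "ar" for aromatic bonds
BondOrder = object

_ORDER_TO_RDKIT = {
    1: Chem.BondType.SINGLE,
    2: Chem.BondType.DOUBLE,
    3: Chem.BondType.TRIPLE,
    "ar": Chem.BondType.AROMATIC,
}
_RDKIT_TO_ORDER = {v: k for k, v in _ORDER_TO_RDKIT.items()}


@dataclass
class Molecule:
    """Heavy-atom chemical graph.

    atoms: list of (element, formal_charge, aromatic, implicit_h) tuples.
    bonds: list of ((i, j), order) with order in {1, 2, 3, "ar"}.
    """

    id: str
    atoms: List[Tuple[str, int, bool, int]]
    bonds: List[Tuple[Tuple[int, int], object]]
    _rdmol: Optional[Chem.Mol] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for (i, j), order in self.bonds:
            if i == j:
                raise ValueError(f"self-bond on atom {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) out of range for {n} atoms")
            if order not in _ORDER_TO_RDKIT:
                raise ValueError(f"unsupported bond order {order!r}")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def neighbors(self, idx: int) -> List[int]:
        out = []
        for (i, j), _ in self.bonds:
            if i == idx:
                out.append(j)
            elif j == idx:
                out.append(i)
        return out

    def heavy_degree(self, idx: int) -> int:
        return len(self.neighbors(idx))

    # -- RDKit bridge ------------------------------------------------------
    def to_rdkit(self) -> Chem.Mol:
        if self._rdmol is not None:
            return self._rdmol
        rw = Chem.RWMol()
        for el, charge, aromatic, hs in self.atoms:
            a = Chem.Atom(el)
            a.SetFormalCharge(int(charge))
            a.SetIsAromatic(bool(aromatic))
            a.SetNumExplicitHs(int(hs))
            a.SetNoImplicit(True)
            rw.AddAtom(a)
        for (i, j), order in self.bonds:
            rw.AddBond(int(i), int(j), _ORDER_TO_RDKIT[order])
            if order == "ar":
                rw.GetBondBetweenAtoms(int(i), int(j)).SetIsAromatic(True)
        mol = rw.GetMol()
        try:
            Chem.SanitizeMol(mol)
        except Exception:
            Chem.SanitizeMol(
                mol, Chem.SanitizeFlags.SANITIZE_ALL ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE
            )
        mol.SetProp("_Name", self.id)
        self._rdmol = mol
        return mol

    @classmethod
    def from_rdkit(cls, mol: Chem.Mol, mol_id: Optional[str] = None) -> "Molecule":
        mol = Chem.RemoveHs(mol)
        atoms = [
            (
                a.GetSymbol(),
                a.GetFormalCharge(),
                a.GetIsAromatic(),
                a.GetTotalNumHs(),
            )
            for a in mol.GetAtoms()
        ]
        bonds = []
        for b in mol.GetBonds():
            order = _RDKIT_TO_ORDER.get(b.GetBondType())
            if order is None:
                order = 1
            bonds.append(((b.GetBeginAtomIdx(), b.GetEndAtomIdx()), order))
        name = mol_id
        if name is None:
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        out = cls(id=name, atoms=atoms, bonds=bonds)
        out._rdmol = mol
        return out

    def heavy_atom_multiset(self) -> Dict[str, int]:
        counts: Dict[str, int] = {}
        for el, *_ in self.atoms:
            counts[el] = counts.get(el, 0) + 1
        return counts


def parse_smiles(text: str, mol_id: str = "") -> Molecule:
    """Parse a SMILES string into a :class:`Molecule`.

    Aromaticity is perceived for standard rings and implicit hydrogen counts
    are assigned by default valence.  Raises :class:`SmilesError` on
    unbalanced rings/parentheses or valence violations.
    """
    if not isinstance(text, str) or not text.strip():
        raise SmilesError("empty SMILES")
    mol = Chem.MolFromSmiles(text.strip())
    if mol is None:
        raise SmilesError(f"cannot parse SMILES {text!r}")
    return Molecule.from_rdkit(mol, mol_id or text.strip())


def write_smiles(m: Molecule) -> str:
    return Chem.MolToSmiles(m.to_rdkit())


@dataclass
class Conformer:
    """Heavy-atom 3D coordinates (Angstrom) for one conformation.

    ``polar_h`` optionally lists explicit polar-hydrogen positions as
    (heavy_atom_index, xyz) pairs; H-bond detection falls back to a
    distance-only rule when they are absent.
    """

    molecule: Molecule
    coords: np.ndarray
    conformer_id: str = "0"
    polar_h: List[Tuple[int, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if self.coords.shape[0] != self.molecule.n_atoms:
            raise ValueError(
                f"{self.coords.shape[0]} coordinates for "
                f"{self.molecule.n_atoms} heavy atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @property
    def elements(self) -> List[str]:
        return [a[0] for a in self.molecule.atoms]

    @property
    def compound_id(self) -> str:
        return self.molecule.id


# --------------------------------------------------------------------------
# Property profile
# --------------------------------------------------------------------------


@dataclass
class PropertyProfile:
    mw: float
    hbd: int
    hba: int
    rotatable: int
    rigid: int
    chiral_centers: int
    ring_systems: int
    carbon_count: int
    heteroatom_count: int
    tpsa: float
    clogp: float


def _is_amide_cn(mol: Chem.Mol, bond: Chem.Bond) -> bool:
    a, b = bond.GetBeginAtom(), bond.GetEndAtom()
    for c, n in ((a, b), (b, a)):
        if c.GetSymbol() == "C" and n.GetSymbol() == "N":
            for nb in c.GetBonds():
                other = nb.GetOtherAtom(c)
                if other.GetSymbol() == "O" and nb.GetBondType() == Chem.BondType.DOUBLE:
                    return True
    return False


def count_rotatable_bonds(m: Molecule) -> int:
    """Non-ring single bonds between heavy atoms of degree >= 2, minus amides."""
    mol = m.to_rdkit()
    ri = mol.GetRingInfo()
    n = 0
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE:
            continue
        if ri.NumBondRings(bond.GetIdx()):
            continue
        if bond.GetBeginAtom().GetDegree() < 2 or bond.GetEndAtom().GetDegree() < 2:
            continue
        if _is_amide_cn(mol, bond):
            continue
        n += 1
    return n


def count_ring_systems(m: Molecule) -> int:
    """Number of fused ring systems (rings sharing an atom are one system)."""
    mol = m.to_rdkit()
    rings = [set(r) for r in mol.GetRingInfo().AtomRings()]
    systems: List[set] = []
    for ring in rings:
        merged = ring
        keep = []
        for sys_ in systems:
            if sys_ & merged:
                merged = merged | sys_
            else:
                keep.append(sys_)
        keep.append(merged)
        systems = keep
    return len(systems)


def compute_properties(m: Molecule) -> PropertyProfile:
    """Physicochemical + topological profile used by the drug-likeness rules.

    clogP is RDKit's Crippen atom-contribution estimate and is not expected
    to match vendor-computed values; TPSA is the Ertl fragment-contribution
    sum.
    """
    if m.n_atoms == 0:
        return PropertyProfile(0.0, 0, 0, 0, 0, 0, 0, 0, 0, 0.0, 0.0)
    mol = m.to_rdkit()
    hbd = sum(
        1
        for a in mol.GetAtoms()
        if a.GetSymbol() in ("N", "O") and a.GetTotalNumHs() >= 1
    )
    hba = sum(1 for a in mol.GetAtoms() if a.GetSymbol() in ("N", "O"))
    rotatable = count_rotatable_bonds(m)
    heavy_bonds = mol.GetNumBonds()
    chiral = len(
        Chem.FindMolChiralCenters(
            mol, includeUnassigned=True, useLegacyImplementation=False
        )
    )
    carbons = sum(1 for a in mol.GetAtoms() if a.GetSymbol() == "C")
    hetero = mol.GetNumHeavyAtoms() - carbons
    return PropertyProfile(
        mw=float(Descriptors.MolWt(mol)),
        hbd=hbd,
        hba=hba,
        rotatable=rotatable,
        rigid=heavy_bonds - rotatable,
        chiral_centers=chiral,
        ring_systems=count_ring_systems(m),
        carbon_count=carbons,
        heteroatom_count=hetero,
        tpsa=float(rdMolDescriptors.CalcTPSA(mol)),
        clogp=float(Crippen.MolLogP(mol)),
    )


# --------------------------------------------------------------------------
# File I/O
# --------------------------------------------------------------------------


def read_sdf(path) -> List[Conformer]:
    """Read a (multi-record) V2000 SDF into a list of conformers.

    Records sharing a title are conformers of one compound and get conformer
    ids 0, 1, 2, ... in file order.  Explicit hydrogens on N/O are captured
    as polar-hydrogen positions; all other hydrogens are dropped.
    """
    path = str(path)
    supplier = Chem.SDMolSupplier(path, removeHs=False, sanitize=True)
    confs: List[Conformer] = []
    seen: Dict[str, int] = {}
    for idx, mol in enumerate(supplier):
        if mol is None:
            raise SdfError(f"malformed SDF record #{idx} in {path}")
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{idx}"
        if not name:
            name = f"mol{idx}"
        conf = mol.GetConformer()
        heavy_idx = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
        remap = {old: new for new, old in enumerate(heavy_idx)}
        coords = np.array([list(conf.GetAtomPosition(i)) for i in heavy_idx])
        polar_h: List[Tuple[int, np.ndarray]] = []
        for a in mol.GetAtoms():
            if a.GetAtomicNum() != 1:
                continue
            for nb in a.GetNeighbors():
                if nb.GetSymbol() in ("N", "O"):
                    polar_h.append(
                        (remap[nb.GetIdx()], np.array(list(conf.GetAtomPosition(a.GetIdx()))))
                    )
        molecule = Molecule.from_rdkit(mol, name)
        k = seen.get(name, 0)
        seen[name] = k + 1
        confs.append(
            Conformer(molecule=molecule, coords=coords, conformer_id=str(k), polar_h=polar_h)
        )
    return confs


def write_sdf(confs: Sequence[Conformer], path) -> None:
    """Write conformers as a multi-record V2000 SDF (heavy atoms only)."""
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(True)
    try:
        for conf in confs:
            mol = Chem.Mol(conf.molecule.to_rdkit())
            rdconf = Chem.Conformer(mol.GetNumAtoms())
            for i, xyz in enumerate(conf.coords):
                rdconf.SetAtomPosition(i, [float(x) for x in xyz])
            mol.RemoveAllConformers()
            mol.AddConformer(rdconf, assignId=True)
            mol.SetProp("_Name", conf.molecule.id)
            mol.SetProp("conformer_id", str(conf.conformer_id))
            writer.write(mol)
    finally:
        writer.close()


def read_smiles_file(path) -> List[Molecule]:
    """One SMILES per line, optional whitespace-separated id."""
    out: List[Molecule] = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        smiles = parts[0]
        mol_id = parts[1] if len(parts) > 1 else f"line{ln}"
        try:
            out.append(parse_smiles(smiles, mol_id))
        except SmilesError as exc:
            raise SmilesError(f"line {ln}: {exc}") from exc
    return out


def group_by_compound(confs: Iterable[Conformer]) -> Dict[str, List[Conformer]]:
    """Group conformers by compound id, preserving encounter order."""
    groups: Dict[str, List[Conformer]] = {}
    for c in confs:
        groups.setdefault(c.compound_id, []).append(c)
    return groups
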