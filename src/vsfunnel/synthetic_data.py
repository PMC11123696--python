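"""Seeded generators for every input the screening funnel consumes.

Real screens of this kind run on commercial conformer databases, a crystal
receptor structure and poses from commercial docking engines.  This module
replaces those inputs with fully deterministic synthetic stand-ins:

* ``gen_library`` — drug-like small molecules assembled from a fragment
  grammar, with multi-conformer 3D geometries (up to 50 per compound,
  matching typical conformer-library preparation) and optional planted
  drug-likeness violations with ground-truth labels;
* ``gen_pocket`` — a trimeric-pocket-like receptor fragment: pseudo
  side-chain geometries for the named binding-site residues on chains
  A/B/C arranged around a central cavity;
* ``plant_pose`` — ligand poses with interactions planted inside the
  detector thresholds by a stated margin (and decoy contacts outside by the
  same margin), emitted together with the ground-truth record list;
* ``gen_score_tables`` — paired docking-style score tables with a
  controlled overlap between the two programs' top-N lists;
* ``fixtures`` — packaged machine-readable transcriptions of the published
  property table and per-residue interaction grids used as worked examples.

All randomness flows from a single seed; identical seeds give byte-identical
SDF/PDB/TSV output.  The pocket geometry is detector-facing realism only —
no folds, no energetics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib.resources import files
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem

from .interaction_profile import (
    AROMATIC_RINGS,
    CHARGED_GROUPS,
    HYDROPHOBIC_ATOMS,
    ONE_TO_THREE,
    SIDECHAIN_ACCEPTORS,
    SIDECHAIN_DONORS,
    GeometryParams,
    InteractionProfile,
    InteractionRecord,
    ProteinStructure,
    Residue,
    ResidueRef,
    detect_interactions,
)
from .mol_model import Conformer, Molecule
from .pose_criteria import ScoreTable

__all__ = [
    "GeneratorConfig",
    "gen_library",
    "gen_pocket",
    "write_pocket_pdb",
    "PlantSpec",
    "plant_pose",
    "gen_score_tables",
    "fixtures",
    "table_properties",
    "table_interactions",
    "fixture_profile",
    "DEFAULT_POCKET_SPEC",
]


# --------------------------------------------------------------------------
# Ligand library generator
# --------------------------------------------------------------------------

_SCAFFOLDS = [
    "c1ccccc1",
    "c1ccncc1",
    "c1ccc2ccccc2c1",
    "C1CCNCC1",
    "c1ccc2[nH]ccc2c1",
    "C1CCOC1",
    "c1ccsc1",
    "C1CCCCC1",
    "c1cnc2ccccc2c1",
]
_SUBSTITUENTS = [
    "C",
    "CC",
    "O",
    "OC",
    "N",
    "F",
    "Cl",
    "NC(C)=O",
    "C(=O)OC",
    "CO",
    "C(F)(F)F",
    "CCN(C)C",
    "S(C)(=O)=O",
]
# guaranteed rule-of-range violator: >14 rotatable bonds and large MW
_VIOLATION_TAIL = "C" * 20
_FALLBACK_CLEAN = "Cc1ccc2ccccc2c1"  # 2-methylnaphthalene


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic library.

    ``conformers`` is the inclusive (min, max) range of conformations drawn
    per compound — up to 50, as in typical multi-conformer database
    preparation.  ``violation_rate`` is the fraction of compounds given a
    planted drug-likeness violation (ground truth returned alongside).
    """

    seed: int = 0
    n_compounds: int = 20
    conformers: Tuple[int, int] = (1, 50)
    violation_rate: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.conformers
        if not (1 <= lo <= hi <= 50):
            raise ValueError("conformers range must satisfy 1 <= min <= max <= 50")
        if not 0.0 <= self.violation_rate <= 1.0:
            raise ValueError("violation_rate must be in [0, 1]")
        if self.n_compounds < 1:
            raise ValueError("n_compounds must be positive")


def _attach(core: Chem.Mol, frag: Chem.Mol, rng: np.random.Generator) -> Optional[Chem.Mol]:
    n_core = core.GetNumAtoms()
    combined = Chem.RWMol(Chem.CombineMols(core, frag))
    core_sites = [
        a.GetIdx()
        for a in combined.GetAtoms()
        if a.GetIdx() < n_core and a.GetTotalNumHs() >= 1
    ]
    frag_sites = [
        a.GetIdx()
        for a in combined.GetAtoms()
        if a.GetIdx() >= n_core and a.GetTotalNumHs() >= 1
    ]
    if not core_sites or not frag_sites:
        return None
    i = int(rng.choice(core_sites))
    j = int(rng.choice(frag_sites))
    combined.AddBond(i, j, Chem.BondType.SINGLE)
    mol = combined.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return mol


def _assemble_molecule(rng: np.random.Generator, violate: bool) -> Chem.Mol:
    from .druglike_filter import RuleSet, evaluate_compound
    from .mol_model import compute_properties

    ruleset = RuleSet()
    for _ in range(30):
        mol = Chem.MolFromSmiles(_SCAFFOLDS[int(rng.integers(len(_SCAFFOLDS)))])
        n_extra = int(rng.integers(1, 5))
        ok = True
        for _ in range(n_extra):
            frag = Chem.MolFromSmiles(_SUBSTITUENTS[int(rng.integers(len(_SUBSTITUENTS)))])
            nxt = _attach(mol, frag, rng)
            if nxt is None:
                ok = False
                break
            mol = nxt
        if not ok:
            continue
        if violate:
            tail = Chem.MolFromSmiles(_VIOLATION_TAIL)
            nxt = _attach(mol, tail, rng)
            if nxt is None:
                continue
            mol = nxt
        m = Molecule.from_rdkit(mol)
        verdict = evaluate_compound(m, compute_properties(m), ruleset)
        if verdict.overall_pass != violate:
            return mol
    # deterministic fallbacks that satisfy the requested label
    smi = _FALLBACK_CLEAN if not violate else _FALLBACK_CLEAN + _VIOLATION_TAIL
    return Chem.MolFromSmiles(smi)


def _embed(mol: Chem.Mol, n_confs: int, seed: int) -> Chem.Mol:
    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    ids = AllChem.EmbedMultipleConfs(molh, numConfs=n_confs, params=params)
    if len(ids) == 0:
        params.useRandomCoords = True
        ids = AllChem.EmbedMultipleConfs(molh, numConfs=n_confs, params=params)
    if len(ids) == 0:
        raise RuntimeError("conformer embedding failed")
    return Chem.RemoveHs(molh)


def gen_library(
    config: GeneratorConfig,
) -> Tuple[List[Conformer], Dict[str, bool]]:
    """Generate a multi-conformer compound library.

    Returns (conformers in file order, compound id -> planted-violation
    flag).  Deterministic for a fixed config.
    """
    rng = np.random.default_rng(config.seed)
    confs: List[Conformer] = []
    truth: Dict[str, bool] = {}
    for idx in range(config.n_compounds):
        cid = f"CMP{idx:04d}"
        violate = bool(rng.random() < config.violation_rate)
        rdmol = _assemble_molecule(rng, violate)
        lo, hi = config.conformers
        n_confs = int(rng.integers(lo, hi + 1))
        embed_seed = int(rng.integers(1, 2**31 - 1))
        mol3d = _embed(rdmol, n_confs, embed_seed)
        molecule = Molecule.from_rdkit(mol3d, cid)
        heavy = [a.GetIdx() for a in mol3d.GetAtoms() if a.GetAtomicNum() > 1]
        for j, conf in enumerate(mol3d.GetConformers()):
            coords = np.array([list(conf.GetAtomPosition(i)) for i in heavy])
            confs.append(Conformer(molecule=molecule, coords=coords, conformer_id=str(j)))
        truth[cid] = violate
    return confs, truth


# --------------------------------------------------------------------------
# Pocket generator
# --------------------------------------------------------------------------

_BACKBONE = [("N", (-0.6, 1.35, 0.0)), ("CA", (0.0, 0.0, 0.0)),
             ("C", (-0.6, -1.35, 0.0)), ("O", (-1.75, -1.7, 0.0))]

# aromatic rings face the cavity (+x is inward; ring planes are y-z), so
# that stacking partners placed along the ring normal head into the pocket
_PHE_RING = [
    ("CG", (3.4, -1.39, 0.0)),
    ("CD1", (3.4, -0.695, 1.204)),
    ("CE1", (3.4, 0.695, 1.204)),
    ("CZ", (3.4, 1.39, 0.0)),
    ("CE2", (3.4, 0.695, -1.204)),
    ("CD2", (3.4, -0.695, -1.204)),
]

_SIDECHAINS: Dict[str, List[Tuple[str, Tuple[float, float, float]]]] = {
    "GLY": [],
    "ALA": [("CB", (1.5, 0.0, 0.0))],
    "VAL": [("CB", (1.5, 0, 0)), ("CG1", (2.3, 1.2, 0)), ("CG2", (2.3, -1.2, 0))],
    "ILE": [("CB", (1.5, 0, 0)), ("CG1", (2.3, 1.2, 0)), ("CG2", (2.3, -1.2, 0)),
            ("CD1", (3.7, 1.3, 0))],
    "LEU": [("CB", (1.5, 0, 0)), ("CG", (2.9, 0.3, 0)), ("CD1", (3.6, 1.5, 0)),
            ("CD2", (3.6, -0.9, 0))],
    "MET": [("CB", (1.5, 0, 0)), ("CG", (2.9, 0.4, 0)), ("SD", (4.25, -0.3, 0)),
            ("CE", (5.65, 0.4, 0))],
    "PRO": [("CB", (1.45, 0.7, 0)), ("CG", (2.6, -0.1, 0)), ("CD", (1.9, -1.4, 0))],
    "SER": [("CB", (1.5, 0, 0)), ("OG", (2.2, 1.2, 0))],
    "THR": [("CB", (1.5, 0, 0)), ("OG1", (2.2, 1.2, 0)), ("CG2", (2.3, -1.2, 0))],
    "CYS": [("CB", (1.5, 0, 0)), ("SG", (2.9, 0.5, 0))],
    "LYS": [("CB", (1.5, 0, 0)), ("CG", (2.9, 0.4, 0)), ("CD", (4.3, -0.3, 0)),
            ("CE", (5.7, 0.3, 0)), ("NZ", (7.0, -0.4, 0))],
    "ARG": [("CB", (1.5, 0, 0)), ("CG", (2.9, 0.4, 0)), ("CD", (4.3, -0.3, 0)),
            ("NE", (5.6, 0.3, 0)), ("CZ", (6.9, 0.0, 0)), ("NH1", (7.6, 1.1, 0)),
            ("NH2", (7.6, -1.1, 0))],
    "ASP": [("CB", (1.5, 0, 0)), ("CG", (2.9, 0.3, 0)), ("OD1", (3.6, 1.35, 0)),
            ("OD2", (3.55, -0.85, 0))],
    "GLU": [("CB", (1.5, 0, 0)), ("CG", (2.9, 0.4, 0)), ("CD", (4.3, -0.2, 0)),
            ("OE1", (5.0, 0.85, 0)), ("OE2", (4.95, -1.35, 0))],
    "ASN": [("CB", (1.5, 0, 0)), ("CG", (2.9, 0.3, 0)), ("OD1", (3.6, 1.35, 0)),
            ("ND2", (3.55, -0.85, 0))],
    "GLN": [("CB", (1.5, 0, 0)), ("CG", (2.9, 0.4, 0)), ("CD", (4.3, -0.2, 0)),
            ("OE1", (5.0, 0.85, 0)), ("NE2", (4.95, -1.35, 0))],
    "HIS": [("CB", (1.5, 0, 0)), ("CG", (3.2, -1.17, 0)), ("ND1", (3.2, -0.36, 1.11)),
            ("CE1", (3.2, 0.95, 0.69)), ("NE2", (3.2, 0.95, -0.69)),
            ("CD2", (3.2, -0.36, -1.11))],
    "PHE": [("CB", (1.5, 0.0, 0.0))] + _PHE_RING,
    "TYR": [("CB", (1.5, 0.0, 0.0))] + _PHE_RING + [("OH", (3.4, 2.76, 0.0))],
    "TRP": [("CB", (1.5, 0, 0)), ("CG", (3.6, -1.9, 2.2)), ("CD1", (3.6, -0.9, 3.2)),
            ("NE1", (3.6, 0.4, 2.7)), ("CE2", (3.6, 0.0, 1.39)), ("CD2", (3.6, -1.2, 0.695)),
            ("CE3", (3.6, -1.2, -0.695)), ("CZ3", (3.6, 0.0, -1.39)),
            ("CH2", (3.6, 1.2, -0.695)), ("CZ2", (3.6, 1.2, 0.695))],
}

#: binding-site residue inventory with subunit letters, as displayed in the
#: per-residue interaction grids (one-letter code + author numbering)
DEFAULT_POCKET_SPEC: List[Tuple[str, str]] = [
    ("A", "F88"), ("A", "A91"), ("A", "D92"), ("A", "Y93"), ("A", "T94"),
    ("A", "F95"), ("A", "P96"), ("A", "Q98"), ("A", "F103"), ("A", "M105"),
    ("A", "F108"), ("A", "K110"), ("A", "W167"), ("A", "Y291"), ("A", "F293"),
    ("A", "Y295"), ("A", "A296"), ("A", "K297"), ("A", "Y298"), ("A", "I310"),
    ("A", "V312"),
    ("B", "F95"), ("B", "P96"), ("B", "Q98"), ("B", "W167"), ("B", "F293"),
    ("B", "Y295"), ("B", "A296"), ("B", "Y298"),
    ("C", "F95"), ("C", "P96"), ("C", "Q98"),
]


def _fibonacci_directions(n: int) -> np.ndarray:
    """n well-spread unit vectors (golden-angle spiral on the sphere)."""
    k = np.arange(n)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def _orientation_frame(inward: np.ndarray) -> np.ndarray:
    e1 = inward / np.linalg.norm(inward)
    helper = np.array([0.0, 0.0, 1.0]) if abs(e1[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e2 = helper - np.dot(helper, e1) * e1
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    return np.stack([e1, e2, e3], axis=1)  # columns


def gen_pocket(
    spec: Optional[Sequence[Tuple[str, str]]] = None,
    radius: float = 16.0,
) -> ProteinStructure:
    """Arrange pseudo-residues around a central cavity at the origin.

    ``spec`` lists (chain, label) pairs such as ("A", "F95"); side chains
    point toward the cavity center.  An empty spec yields an empty
    structure; unknown one-letter codes raise.
    """
    if spec is None:
        spec = DEFAULT_POCKET_SPEC
    spec = sorted(spec, key=lambda e: (e[0], int(e[1][1:])))
    if not spec:
        return ProteinStructure([])
    dirs = _fibonacci_directions(len(spec))
    residues: List[Residue] = []
    for (chain, label), outward in zip(spec, dirs):
        code1, number = label[0], int(label[1:])
        if code1 not in ONE_TO_THREE:
            raise ValueError(f"unknown residue code {code1!r} in {label}")
        name3 = ONE_TO_THREE[code1]
        anchor = radius * outward
        frame = _orientation_frame(-outward)
        atoms: Dict[str, np.ndarray] = {}
        for atom_name, local in _BACKBONE + _SIDECHAINS[name3]:
            atoms[atom_name] = anchor + frame @ np.asarray(local)
        residues.append(Residue(chain=chain, name=name3, number=number, atoms=atoms))
    return ProteinStructure(residues)


def write_pocket_pdb(structure: ProteinStructure, path) -> None:
    """Write the pocket as a PDB file via gemmi."""
    import gemmi

    st = gemmi.Structure()
    st.name = "synthetic pocket"
    model = gemmi.Model("1")
    chains: Dict[str, "gemmi.Chain"] = {}
    for res in structure.residues:
        chain = chains.get(res.chain)
        if chain is None:
            chain = gemmi.Chain(res.chain)
            chains[res.chain] = chain
        g_res = gemmi.Residue()
        g_res.name = res.name
        g_res.seqid = gemmi.SeqId(res.number, " ")
        for name, pos in res.atoms.items():
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(name[0])
            atom.pos = gemmi.Position(*[float(x) for x in pos])
            atom.occ = 1.0
            g_res.add_atom(atom)
        chain.add_residue(g_res)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# --------------------------------------------------------------------------
# Pose planting
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantSpec:
    """One contact to plant: residue (chain + label) and interaction type.

    ``decoy`` places the contact *outside* the threshold by the margin
    instead of inside, so it must not be detected.
    """

    chain: str
    label: str
    type: str
    decoy: bool = False


def _residue_for(pocket: ProteinStructure, spec: PlantSpec) -> Residue:
    ref = ResidueRef(spec.chain, spec.label[0], int(spec.label[1:]))
    return pocket.find(ref)


def _closest_to(center: np.ndarray, named: List[Tuple[str, np.ndarray]]) -> np.ndarray:
    return min(named, key=lambda t: np.linalg.norm(t[1] - center))[1]


def _ring_frame(res: Residue, center: np.ndarray):
    rings = AROMATIC_RINGS[res.name]
    names = max(rings, key=len)  # prefer the six-membered ring
    coords = np.array([res.atoms[n] for n in names])
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    _, _, vt = np.linalg.svd(centered)
    normal = vt[2]
    if np.dot(center - centroid, normal) < 0:
        normal = -normal
    in_plane = centered[0] - np.dot(centered[0], normal) * normal
    in_plane /= np.linalg.norm(in_plane)
    return centroid, normal, in_plane


def _benzene_atoms(centroid: np.ndarray, normal: np.ndarray, axis1: np.ndarray):
    axis2 = np.cross(normal, axis1)
    coords = [
        centroid + 1.39 * (math.cos(k * math.pi / 3) * axis1 + math.sin(k * math.pi / 3) * axis2)
        for k in range(6)
    ]
    atoms = [("C", 0, True, 1)] * 6
    bonds = [((k, (k + 1) % 6), "ar") for k in range(6)]
    return atoms, bonds, coords


def plant_pose(
    pocket: ProteinStructure,
    specs: Sequence[PlantSpec],
    margin: float = 0.4,
    params: Optional[GeometryParams] = None,
    ligand_id: str = "pose",
    check: bool = True,
) -> Tuple[Conformer, List[Tuple[str, str, str]]]:
    """Build a ligand pose realizing the requested contacts.

    Planted contacts sit inside their detection threshold by ``margin``;
    decoys sit outside by the same margin.  The ground truth — the list of
    (chain, label, type) that the default detector must find — is returned
    alongside.  When ``check`` is on, the pose is verified against the
    detector over the full pocket and an infeasible geometry (missing or
    spurious contact) raises ``ValueError`` naming the clash.
    """
    params = params or GeometryParams()
    center = np.mean([a for r in pocket.residues for a in r.atoms.values()], axis=0)
    atoms: List[Tuple[str, int, bool, int]] = []
    bonds: List[Tuple[Tuple[int, int], object]] = []
    coords: List[np.ndarray] = []
    truth: List[Tuple[str, str, str]] = []

    def _add(atom, pos):
        atoms.append(atom)
        coords.append(np.asarray(pos, dtype=float))

    for spec in specs:
        res = _residue_for(pocket, spec)
        sign = 1.0 if spec.decoy else -1.0
        if spec.type == "HD":
            named = [(n, res.atoms[n]) for n in HYDROPHOBIC_ATOMS[res.name] if n in res.atoms]
            if not named:
                raise ValueError(f"{spec.label} has no hydrophobic atoms")
            target = _closest_to(center, named)
            d = params.hydrophobic_max + sign * margin
            u = (center - target) / np.linalg.norm(center - target)
            _add(("C", 0, False, 4), target + d * u)
        elif spec.type == "HB":
            names = (
                SIDECHAIN_ACCEPTORS.get(res.name, [])
                + SIDECHAIN_DONORS.get(res.name, [])
                + ["O"]
            )
            named = [(n, res.atoms[n]) for n in names if n in res.atoms]
            target = _closest_to(center, named)
            d = params.hbond_max_no_h + sign * margin
            u = (center - target) / np.linalg.norm(center - target)
            _add(("O", 0, False, 2), target + d * u)
        elif spec.type == "SB":
            group = CHARGED_GROUPS.get(res.name)
            if group is None:
                raise ValueError(f"{spec.label} carries no charged group")
            gsign, names = group
            centroid = np.mean([res.atoms[n] for n in names if n in res.atoms], axis=0)
            d = params.saltbridge_max + sign * margin
            u = (center - centroid) / np.linalg.norm(center - centroid)
            atom = ("N", 1, False, 4) if gsign < 0 else ("O", -1, False, 1)
            _add(atom, centroid + d * u)
        elif spec.type == "PIPI":
            if res.name not in AROMATIC_RINGS:
                raise ValueError(f"{spec.label} is not aromatic")
            centroid, normal, axis1 = _ring_frame(res, center)
            # 4.5 A face-to-face, atom-eclipsed: inside the centroid cutoff
            # yet outside the 4.0 A hydrophobic cutoff atom-for-atom
            h = 4.5 if not spec.decoy else params.pipi_max_centroid + margin
            ring_atoms, ring_bonds, ring_coords = _benzene_atoms(
                centroid + h * normal, normal, axis1
            )
            offset = len(atoms)
            for a, c in zip(ring_atoms, ring_coords):
                _add(a, c)
            bonds.extend([((i + offset, j + offset), o) for (i, j), o in ring_bonds])
        elif spec.type == "PICAT":
            if res.name in AROMATIC_RINGS:
                centroid, normal, _ = _ring_frame(res, center)
                d = params.pication_max + sign * margin
                _add(("N", 1, False, 4), centroid + d * normal)
            elif res.name in CHARGED_GROUPS and CHARGED_GROUPS[res.name][0] > 0:
                _, names = CHARGED_GROUPS[res.name]
                centroid = np.mean([res.atoms[n] for n in names if n in res.atoms], axis=0)
                d = params.pication_max + sign * margin
                u = (center - centroid) / np.linalg.norm(center - centroid)
                ring_centroid = centroid + d * u
                helper = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
                axis1 = np.cross(u, helper)
                axis1 /= np.linalg.norm(axis1)
                ring_atoms, ring_bonds, ring_coords = _benzene_atoms(ring_centroid, u, axis1)
                offset = len(atoms)
                for a, c in zip(ring_atoms, ring_coords):
                    _add(a, c)
                bonds.extend([((i + offset, j + offset), o) for (i, j), o in ring_bonds])
            else:
                raise ValueError(f"{spec.label} supports no cation-pi geometry")
        else:
            raise ValueError(f"unknown interaction type {spec.type!r}")
        if not spec.decoy:
            truth.append((spec.chain, spec.label, spec.type))

    molecule = Molecule(id=ligand_id, atoms=atoms, bonds=bonds)
    pose = Conformer(molecule=molecule, coords=np.array(coords).reshape(-1, 3))

    if check and pocket.residues:
        profile = detect_interactions(pocket, pose, params)
        found = {(r.residue.chain, r.residue.label, r.type) for r in profile.records}
        expected = set(truth)
        if found != expected:
            raise ValueError(
                "infeasible plant geometry: "
                f"spurious={sorted(found - expected)} missing={sorted(expected - found)}"
            )
    return pose, truth


# --------------------------------------------------------------------------
# Score tables
# --------------------------------------------------------------------------


def gen_score_tables(
    ids: Sequence[str],
    n_top: int,
    overlap_k: int,
    seed: int = 0,
    program_a: str = "GOLD-like",
    program_b: str = "DockThor-like",
) -> Tuple[ScoreTable, ScoreTable]:
    """Two score tables whose top-``n_top`` lists share exactly ``overlap_k`` ids.

    Program A is higher-is-better (empirical docking score scale), program B
    lower-is-better (kcal/mol-like scale).
    """
    ids = list(ids)
    if not 0 <= overlap_k <= n_top:
        raise ValueError("need 0 <= overlap_k <= n_top")
    if len(ids) < 2 * n_top - overlap_k:
        raise ValueError(
            f"infeasible overlap: need at least {2 * n_top - overlap_k} ids, have {len(ids)}"
        )
    rng = np.random.default_rng(seed)
    shuffled = list(ids)
    rng.shuffle(shuffled)
    a_top = shuffled[:n_top]
    b_top = a_top[:overlap_k] + shuffled[n_top : 2 * n_top - overlap_k]

    scores_a: Dict[str, float] = {}
    top_vals = np.linspace(107.5, 86.2, num=n_top)
    for cid, v in zip(a_top, top_vals):
        scores_a[cid] = round(float(v), 3)
    rest = [cid for cid in shuffled if cid not in scores_a]
    for cid, v in zip(rest, 60.0 + 25.0 * rng.random(len(rest))):
        scores_a[cid] = round(float(v), 3)

    scores_b: Dict[str, float] = {}
    top_vals_b = np.linspace(-12.2, -10.6, num=n_top)
    for cid, v in zip(b_top, top_vals_b):
        scores_b[cid] = round(float(v), 3)
    rest_b = [cid for cid in shuffled if cid not in scores_b]
    for cid, v in zip(rest_b, -9.5 + 4.0 * rng.random(len(rest_b))):
        scores_b[cid] = round(float(v), 3)

    return (
        ScoreTable(program=program_a, orientation="higher", scores=scores_a),
        ScoreTable(program=program_b, orientation="lower", scores=scores_b),
    )


# --------------------------------------------------------------------------
# Packaged table fixtures
# --------------------------------------------------------------------------

_CELL_TYPE_MAP = {
    "HD": "HD",
    "HB": "HB",
    "HBA": "HB",  # printed as "hydrogen-bond acceptor"; an H-bond
    "SB": "SB",
    "π-π": "PIPI",
    "π-C": "PICAT",
}
_NOMINAL_GEOMETRY = {"HD": 3.6, "HB": 3.0, "SB": 4.0, "PIPI": 4.0, "PICAT": 4.5}


def _data_path(name: str):
    return files("vsfunnel.data").joinpath(name)


def table_properties() -> pd.DataFrame:
    """Published per-compound property/score table (vendor-computed values)."""
    with _data_path("table_properties.tsv").open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, sep="\t")


def table_interactions(db: Optional[str] = None) -> pd.DataFrame:
    """Published per-residue interaction grids in long form (verbatim cells)."""
    with _data_path("table_interactions.tsv").open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh, sep="\t")
    if db is not None:
        df = df[df["db"] == db].reset_index(drop=True)
    return df


def parse_cell(cell: str) -> List[str]:
    """Normalize a printed grid cell like 'HD, HB, π-π' to canonical types."""
    out = []
    for token in str(cell).split(","):
        token = token.strip().replace(" ", "")
        if not token:
            continue
        if token not in _CELL_TYPE_MAP:
            raise ValueError(f"unrecognized interaction cell token {token!r}")
        t = _CELL_TYPE_MAP[token]
        if t not in out:
            out.append(t)
    return out


def fixture_profile(compound: str, program: str) -> InteractionProfile:
    """Interaction profile of one compound/program column of the grids.

    Geometry was not printed, so records carry nominal in-threshold values.
    """
    df = table_interactions()
    rows = df[(df["compound"] == compound) & (df["program"] == program)]
    if rows.empty:
        raise KeyError(f"no fixture column for {compound}/{program}")
    profile = InteractionProfile(pose_id=f"{compound}/{program}")
    for _, row in rows.iterrows():
        label = str(row["residue"])
        ref = ResidueRef(str(row["chain"]), label[0], int(label[1:]))
        for t in parse_cell(row["cell"]):
            profile.records.append(
                InteractionRecord(
                    type=t,
                    residue=ref,
                    ligand_atoms=(0,),
                    distance=_NOMINAL_GEOMETRY[t],
                    angle=0.0 if t == "PIPI" else None,
                )
            )
    return profile


def fixtures() -> Dict[str, pd.DataFrame]:
    """All packaged table transcriptions."""
    return {"properties": table_properties(), "interactions": table_interactions()}
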