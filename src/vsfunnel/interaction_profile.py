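"""Geometric protein-ligand interaction profiling.

Detects typed contacts between a receptor structure and a docked ligand
pose with PLIP-style distance/angle rules: hydrophobic contacts (HD),
hydrogen bonds (HB), salt bridges (SB), pi-stacking (PIPI) and pi-cation
(PICAT).  Residue-level profiles mirror the per-residue interaction grids
used when inspecting poses in an allosteric binding site, with residues
labelled by one-letter code + author numbering and the subunit (chain)
letter kept alongside.

Also provides the mass-weighted RMSD between two conformations of the same
atom set (pure deviation, no superposition).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import gemmi
import numpy as np

from .mol_model import Conformer

__all__ = [
    "ProteinStructure",
    "Residue",
    "ResidueRef",
    "GeometryParams",
    "InteractionRecord",
    "InteractionProfile",
    "INTERACTION_TYPES",
    "read_pdb",
    "detect_interactions",
    "aggregate_profile",
    "profiles_to_grid",
    "grid_to_records",
    "rmsd",
]

INTERACTION_TYPES = ("HD", "HB", "SB", "PIPI", "PICAT")

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Side-chain carbons bonded only to C/H/S (hydrophobic contact atoms).
HYDROPHOBIC_ATOMS = {
    "ALA": ["CB"],
    "VAL": ["CB", "CG1", "CG2"],
    "LEU": ["CB", "CG", "CD1", "CD2"],
    "ILE": ["CB", "CG1", "CG2", "CD1"],
    "MET": ["CB", "CG", "CE"],
    "PHE": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TYR": ["CB", "CG", "CD1", "CD2", "CE1", "CE2"],
    "TRP": ["CB", "CG", "CD2", "CE3", "CZ2", "CZ3", "CH2"],
    "PRO": ["CB", "CG"],
    "THR": ["CG2"],
    "LYS": ["CB", "CG", "CD"],
    "ARG": ["CB", "CG"],
    "ASP": ["CB"],
    "GLU": ["CB", "CG"],
    "ASN": ["CB"],
    "GLN": ["CB", "CG"],
    "CYS": ["CB"],
    "HIS": ["CB"],
}

# Side-chain H-bond donors / acceptors; the backbone N (donor) and O
# (acceptor) are added for every residue.
SIDECHAIN_DONORS = {
    "SER": ["OG"], "THR": ["OG1"], "TYR": ["OH"], "LYS": ["NZ"],
    "ARG": ["NE", "NH1", "NH2"], "TRP": ["NE1"], "ASN": ["ND2"],
    "GLN": ["NE2"], "HIS": ["ND1", "NE2"], "CYS": ["SG"],
}
SIDECHAIN_ACCEPTORS = {
    "ASP": ["OD1", "OD2"], "GLU": ["OE1", "OE2"], "ASN": ["OD1"],
    "GLN": ["OE1"], "SER": ["OG"], "THR": ["OG1"], "TYR": ["OH"],
    "HIS": ["ND1", "NE2"],
}

# Charged groups at pH 7.4 (K/R positive, D/E negative, H neutral).
CHARGED_GROUPS = {
    "ASP": (-1, ["OD1", "OD2"]),
    "GLU": (-1, ["OE1", "OE2"]),
    "LYS": (+1, ["NZ"]),
    "ARG": (+1, ["CZ", "NH1", "NH2"]),
}

AROMATIC_RINGS = {
    "PHE": [["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]],
    "TYR": [["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]],
    "TRP": [
        ["CG", "CD1", "NE1", "CE2", "CD2"],
        ["CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"],
    ],
    "HIS": [["CG", "ND1", "CE1", "NE2", "CD2"]],
}


@dataclass
class Residue:
    chain: str
    name: str  # three-letter code
    number: int
    atoms: Dict[str, np.ndarray]

    @property
    def code1(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")

    @property
    def label(self) -> str:
        return f"{self.code1}{self.number}"


@dataclass(frozen=True)
class ResidueRef:
    """Residue identity as displayed in interaction grids, e.g. F95 on A."""

    chain: str
    code1: str
    number: int
    role: str = "ordinary"

    @property
    def label(self) -> str:
        return f"{self.code1}{self.number}"

    @property
    def full_label(self) -> str:
        return f"{self.label}:{self.chain}"


class ProteinStructure:
    """Chains -> residues -> atoms container with (chain, number) lookup."""

    def __init__(self, residues: Sequence[Residue]):
        self.residues: List[Residue] = list(residues)
        self._index = {(r.chain, r.number): r for r in self.residues}
        if len(self._index) != len(self.residues):
            raise ValueError("duplicate (chain, residue number) entries")

    def get(self, chain: str, number: int) -> Residue:
        return self._index[(chain, number)]

    def find(self, ref: ResidueRef) -> Residue:
        res = self._index.get((ref.chain, ref.number))
        if res is None:
            raise KeyError(f"residue {ref.full_label} not in structure")
        if res.code1 != ref.code1:
            raise KeyError(
                f"residue {ref.chain}/{ref.number} is {res.code1}, expected {ref.code1}"
            )
        return res

    def residue_refs(self) -> List[ResidueRef]:
        return [ResidueRef(r.chain, r.code1, r.number) for r in self.residues]

    @property
    def chains(self) -> List[str]:
        seen = []
        for r in self.residues:
            if r.chain not in seen:
                seen.append(r.chain)
        return seen


def read_pdb(path, include_het: bool = False) -> ProteinStructure:
    """Read ATOM records from a PDB file (first altloc; waters excluded)."""
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse PDB {path}: {exc}") from exc
    residues: List[Residue] = []
    if len(st) == 0:
        return ProteinStructure([])
    model = st[0]
    for chain in model:
        for res in chain:
            if res.is_water():
                continue
            if res.het_flag == "H" and res.name not in THREE_TO_ONE and not include_het:
                continue
            atoms: Dict[str, np.ndarray] = {}
            for atom in res:
                if atom.name in atoms:  # keep first altloc
                    continue
                atoms[atom.name] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
            residues.append(
                Residue(chain=chain.name, name=res.name, number=res.seqid.num, atoms=atoms)
            )
    return ProteinStructure(residues)


@dataclass
class GeometryParams:
    """Distance (A) / angle (deg) thresholds for each interaction type."""

    hydrophobic_max: float = 4.0
    hbond_max_no_h: float = 3.5
    hbond_max_with_h: float = 3.6
    hbond_min_angle: float = 120.0
    saltbridge_max: float = 5.5
    pipi_max_centroid: float = 5.5
    pipi_parallel_max_angle: float = 30.0
    pipi_tshape_min_angle: float = 60.0
    pipi_tshape_max_angle: float = 90.0
    pipi_max_offset: float = 2.0
    pication_max: float = 6.0

    def __post_init__(self) -> None:
        for name, v in vars(self).items():
            if v <= 0:
                raise ValueError(f"threshold {name} must be positive")


@dataclass
class InteractionRecord:
    type: str
    residue: ResidueRef
    ligand_atoms: Tuple[int, ...]
    distance: float
    angle: Optional[float] = None

    def __post_init__(self) -> None:
        if self.type not in INTERACTION_TYPES:
            raise ValueError(f"unknown interaction type {self.type!r}")
        if self.distance <= 0:
            raise ValueError("distance must be positive")


@dataclass
class InteractionProfile:
    pose_id: str
    records: List[InteractionRecord] = field(default_factory=list)

    def summary(self) -> Dict[str, List[str]]:
        """Residue full label -> sorted list of interaction types."""
        out: Dict[str, set] = {}
        for rec in self.records:
            out.setdefault(rec.residue.full_label, set()).add(rec.type)
        return {k: sorted(v) for k, v in out.items()}

    def types_at(self, label: str, chain: Optional[str] = None) -> set:
        found = set()
        for rec in self.records:
            if rec.residue.label == label and (chain is None or rec.residue.chain == chain):
                found.add(rec.type)
        return found


# --------------------------------------------------------------------------
# Ligand feature perception
# --------------------------------------------------------------------------


def _ligand_features(pose: Conformer):
    mol = pose.molecule
    apolar: List[int] = []
    donors: List[int] = []
    acceptors: List[int] = []
    cations: List[int] = []
    anions: List[int] = []
    for i, (el, charge, _arom, hs) in enumerate(mol.atoms):
        if el == "C":
            nbr_els = {mol.atoms[j][0] for j in mol.neighbors(i)}
            if nbr_els <= {"C", "S", "H"}:
                apolar.append(i)
        if el in ("N", "O"):
            if hs >= 1 and charge >= 0:
                donors.append(i)
            if charge <= 0:
                acceptors.append(i)
        if charge > 0:
            cations.append(i)
        elif charge < 0:
            anions.append(i)
    rings: List[List[int]] = []
    try:
        rd = mol.to_rdkit()
        for ring in rd.GetRingInfo().AtomRings():
            if all(rd.GetAtomWithIdx(a).GetIsAromatic() for a in ring):
                rings.append(list(ring))
    except Exception:
        rings = []
    return apolar, donors, acceptors, cations, anions, rings


def _ring_geometry(coords: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    _, _, vt = np.linalg.svd(centered)
    normal = vt[2]
    return centroid, normal / np.linalg.norm(normal)


def _plane_offset(centroid_a, normal_a, centroid_b) -> float:
    """In-plane displacement of centroid_b relative to ring A."""
    d = centroid_b - centroid_a
    along = np.dot(d, normal_a) * normal_a
    return float(np.linalg.norm(d - along))


def _interplanar_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    cosang = abs(float(np.dot(n1, n2)))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    v1, v2 = a - b, c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


# --------------------------------------------------------------------------
# Detection
# --------------------------------------------------------------------------


def detect_interactions(
    protein: ProteinStructure,
    pose: Conformer,
    params: Optional[GeometryParams] = None,
    site: Optional[Sequence[ResidueRef]] = None,
) -> InteractionProfile:
    """Evaluate every interaction-type rule for each site residue.

    One record per (residue, type) is emitted, carrying the closest
    qualifying geometry.  Detection is restricted to ``site`` residues
    (default: all residues in the structure).
    """
    params = params or GeometryParams()
    refs = list(site) if site is not None else protein.residue_refs()
    profile = InteractionProfile(pose_id=f"{pose.compound_id}/{pose.conformer_id}")
    if pose.coords.shape[0] == 0:
        return profile

    apolar, donors, acceptors, cations, anions, rings = _ligand_features(pose)
    lig = pose.coords
    h_by_donor: Dict[int, List[np.ndarray]] = {}
    for heavy_idx, hpos in pose.polar_h:
        h_by_donor.setdefault(heavy_idx, []).append(np.asarray(hpos, dtype=float))

    ring_geoms = [(_ring_geometry(lig[r]), r) for r in rings]

    for ref in refs:
        res = protein.find(ref)
        _detect_hydrophobic(profile, ref, res, lig, apolar, params)
        _detect_hbond(profile, ref, res, lig, donors, acceptors, h_by_donor, params)
        _detect_saltbridge(profile, ref, res, lig, cations, anions, params)
        _detect_pipi(profile, ref, res, ring_geoms, params)
        _detect_pication(profile, ref, res, lig, cations, ring_geoms, params)
    return profile


def _residue_coords(res: Residue, names: Iterable[str]) -> List[Tuple[str, np.ndarray]]:
    return [(n, res.atoms[n]) for n in names if n in res.atoms]


def _detect_hydrophobic(profile, ref, res, lig, apolar, params) -> None:
    atoms = _residue_coords(res, HYDROPHOBIC_ATOMS.get(res.name, []))
    if not atoms or not apolar:
        return
    best = None
    for li in apolar:
        for _, pos in atoms:
            d = float(np.linalg.norm(lig[li] - pos))
            if d <= params.hydrophobic_max and (best is None or d < best[0]):
                best = (d, li)
    if best:
        profile.records.append(
            InteractionRecord("HD", ref, (best[1],), best[0])
        )


def _detect_hbond(profile, ref, res, lig, donors, acceptors, h_by_donor, params) -> None:
    res_donors = _residue_coords(res, SIDECHAIN_DONORS.get(res.name, []) + ["N"])
    res_acceptors = _residue_coords(res, SIDECHAIN_ACCEPTORS.get(res.name, []) + ["O"])
    best = None
    # ligand donor -> residue acceptor (angle check when polar H present)
    for li in donors:
        for _, apos in res_acceptors:
            d = float(np.linalg.norm(lig[li] - apos))
            hs = h_by_donor.get(li, [])
            if hs:
                if d > params.hbond_max_with_h:
                    continue
                ang = max(_angle(lig[li], h, apos) for h in hs)
                if ang < params.hbond_min_angle:
                    continue
                cand = (d, li, ang)
            else:
                if d > params.hbond_max_no_h:
                    continue
                cand = (d, li, None)
            if best is None or cand[0] < best[0]:
                best = cand
    # ligand acceptor -> residue donor (distance-only; protein H implicit)
    for li in acceptors:
        for _, dpos in res_donors:
            d = float(np.linalg.norm(lig[li] - dpos))
            if d <= params.hbond_max_no_h and (best is None or d < best[0]):
                best = (d, li, None)
    if best:
        profile.records.append(
            InteractionRecord("HB", ref, (best[1],), best[0], angle=best[2])
        )


def _detect_saltbridge(profile, ref, res, lig, cations, anions, params) -> None:
    group = CHARGED_GROUPS.get(res.name)
    if group is None:
        return
    sign, names = group
    atoms = _residue_coords(res, names)
    if not atoms:
        return
    centroid = np.mean([pos for _, pos in atoms], axis=0)
    partners = anions if sign > 0 else cations
    best = None
    for li in partners:
        d = float(np.linalg.norm(lig[li] - centroid))
        if d <= params.saltbridge_max and (best is None or d < best[0]):
            best = (d, li)
    if best:
        profile.records.append(InteractionRecord("SB", ref, (best[1],), best[0]))


def _detect_pipi(profile, ref, res, ring_geoms, params) -> None:
    res_rings = AROMATIC_RINGS.get(res.name, [])
    best = None
    for names in res_rings:
        atoms = _residue_coords(res, names)
        if len(atoms) < len(names):
            continue
        r_centroid, r_normal = _ring_geometry(np.array([p for _, p in atoms]))
        for (l_centroid, l_normal), ring_atoms in ring_geoms:
            d = float(np.linalg.norm(l_centroid - r_centroid))
            if d > params.pipi_max_centroid:
                continue
            ang = _interplanar_angle(l_normal, r_normal)
            parallel = ang <= params.pipi_parallel_max_angle
            tshaped = params.pipi_tshape_min_angle <= ang <= params.pipi_tshape_max_angle
            if not (parallel or tshaped):
                continue
            offset = min(
                _plane_offset(r_centroid, r_normal, l_centroid),
                _plane_offset(l_centroid, l_normal, r_centroid),
            )
            if offset > params.pipi_max_offset:
                continue
            if best is None or d < best[0]:
                best = (d, tuple(ring_atoms), ang)
    if best:
        profile.records.append(
            InteractionRecord("PIPI", ref, best[1], best[0], angle=best[2])
        )


def _detect_pication(profile, ref, res, lig, cations, ring_geoms, params) -> None:
    best = None
    # ligand cation vs residue aromatic ring
    for names in AROMATIC_RINGS.get(res.name, []):
        atoms = _residue_coords(res, names)
        if len(atoms) < len(names):
            continue
        centroid, _ = _ring_geometry(np.array([p for _, p in atoms]))
        for li in cations:
            d = float(np.linalg.norm(lig[li] - centroid))
            if d <= params.pication_max and (best is None or d < best[0]):
                best = (d, (li,))
    # residue cation vs ligand aromatic ring
    group = CHARGED_GROUPS.get(res.name)
    if group is not None and group[0] > 0:
        atoms = _residue_coords(res, group[1])
        if atoms:
            centroid = np.mean([pos for _, pos in atoms], axis=0)
            for (l_centroid, _), ring_atoms in ring_geoms:
                d = float(np.linalg.norm(l_centroid - centroid))
                if d <= params.pication_max and (best is None or d < best[0]):
                    best = (d, tuple(ring_atoms))
    if best:
        profile.records.append(InteractionRecord("PICAT", ref, best[1], best[0]))


# --------------------------------------------------------------------------
# Aggregation / grids
# --------------------------------------------------------------------------


def aggregate_profile(profile: InteractionProfile) -> Dict[str, str]:
    """Per-residue grid: full residue label -> 'HB, HD'-style cell."""
    return {label: ", ".join(types) for label, types in profile.summary().items()}


def profiles_to_grid(profiles: Dict[str, InteractionProfile]):
    """Long-to-wide grid across poses: rows residues, columns pose names."""
    import pandas as pd

    rows = sorted(
        {label for p in profiles.values() for label in p.summary()},
        key=lambda s: (s.split(":")[1], int(s.split(":")[0][1:])),
    )
    data = {}
    for name, p in profiles.items():
        cells = aggregate_profile(p)
        data[name] = [cells.get(r, "") for r in rows]
    return pd.DataFrame(data, index=rows)


def grid_to_records(grid) -> List[Tuple[str, str, str]]:
    """Flatten a residue x pose grid into (pose, residue_label, type) rows."""
    out = []
    for residue_label, row in grid.iterrows():
        for pose_name, cell in row.items():
            if not cell:
                continue
            for t in str(cell).split(","):
                t = t.strip()
                if t:
                    out.append((pose_name, residue_label, t))
    return out


# --------------------------------------------------------------------------
# RMSD
# --------------------------------------------------------------------------


def rmsd(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    masses: Optional[np.ndarray] = None,
) -> float:
    """Mass-weighted RMSD sqrt(sum m_i |r_i - r'_i|^2 / sum m_i), no fitting."""
    a = np.asarray(coords_a, dtype=float).reshape(-1, 3)
    b = np.asarray(coords_b, dtype=float).reshape(-1, 3)
    if a.shape != b.shape:
        raise ValueError(f"coordinate shapes differ: {a.shape} vs {b.shape}")
    if masses is None:
        m = np.ones(a.shape[0])
    else:
        m = np.asarray(masses, dtype=float)
        if m.shape[0] != a.shape[0]:
            raise ValueError("mass count does not match atom count")
        if np.any(m <= 0):
            raise ValueError("masses must be positive")
    sq = np.sum((a - b) ** 2, axis=1)
    return float(np.sqrt(np.sum(m * sq) / np.sum(m)))
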