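import math

import numpy as np
import pytest

from vsfunnel.interaction_profile import (
    AROMATIC_RINGS,
    CHARGED_GROUPS,
    HYDROPHOBIC_ATOMS,
    SIDECHAIN_ACCEPTORS,
    SIDECHAIN_DONORS,
    GeometryParams,
    ProteinStructure,
    Residue,
    ResidueRef,
    aggregate_profile,
    detect_interactions,
    grid_to_records,
    profiles_to_grid,
    read_pdb,
    rmsd,
)
from vsfunnel.mol_model import Conformer, Molecule
from vsfunnel.synthetic_data import (
    PlantSpec,
    fixture_profile,
    gen_pocket,
    plant_pose,
    table_interactions,
    write_pocket_pdb,
)


# --------------------------------------------------------------------------
# PDB reading
# --------------------------------------------------------------------------


class TestReadPdb:
    def test_pocket_round_trip(self, pocket, tmp_path):
        path = tmp_path / "pocket.pdb"
        write_pocket_pdb(pocket, path)
        back = read_pdb(path)
        assert {(r.chain, r.number, r.name) for r in back.residues} == {
            (r.chain, r.number, r.name) for r in pocket.residues
        }
        assert back.chains == ["A", "B", "C"]

    def test_altloc_keeps_first(self, tmp_path):
        pdb = (
            "ATOM      1  N  ASER A   1      11.104   6.134  -6.504  1.00  0.00           N\n"
            "ATOM      2  N  BSER A   1      12.000   6.000  -6.000  0.50  0.00           N\n"
            "ATOM      3  CA  SER A   1      10.000   5.000  -6.000  1.00  0.00           C\n"
            "END\n"
        )
        path = tmp_path / "altloc.pdb"
        path.write_text(pdb)
        st = read_pdb(path)
        res = st.get("A", 1)
        assert set(res.atoms) == {"N", "CA"}
        assert res.atoms["N"][0] == pytest.approx(11.104)

    def test_waters_excluded(self, tmp_path):
        pdb = (
            "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "HETATM    2  O   HOH A 101       5.000   5.000   5.000  1.00  0.00           O\n"
            "END\n"
        )
        path = tmp_path / "wat.pdb"
        path.write_text(pdb)
        st = read_pdb(path)
        assert len(st.residues) == 1

    def test_unparsable_raises(self, tmp_path):
        path = tmp_path / "bad.pdb"
        path.write_text("ATOM  not a valid coordinate line at all\n")
        with pytest.raises(ValueError):
            read_pdb(path)


# --------------------------------------------------------------------------
# Detection against planted geometry and a brute-force oracle
# --------------------------------------------------------------------------


def oracle_detect(protein, pose, params):
    """Independent all-pairs enumeration applying the published thresholds.

    Plain nested loops over every (protein atom/group, ligand atom/ring)
    combination; shares only the residue chemistry tables with the detector.
    """
    found = set()
    mol = pose.molecule
    lig = pose.coords

    def neighbors_elements(i):
        return {mol.atoms[j][0] for j in mol.neighbors(i)}

    apolar = [i for i, (el, _, _, _) in enumerate(mol.atoms)
              if el == "C" and neighbors_elements(i) <= {"C", "S", "H"}]
    donors = [i for i, (el, ch, _, hs) in enumerate(mol.atoms)
              if el in ("N", "O") and hs >= 1 and ch >= 0]
    acceptors = [i for i, (el, ch, _, _) in enumerate(mol.atoms)
                 if el in ("N", "O") and ch <= 0]
    cations = [i for i, (_, ch, _, _) in enumerate(mol.atoms) if ch > 0]
    anions = [i for i, (_, ch, _, _) in enumerate(mol.atoms) if ch < 0]
    # aromatic rings: cycles of aromatic bonds (brute force over bond graph)
    rings = []
    try:
        rd = mol.to_rdkit()
        for ring in rd.GetRingInfo().AtomRings():
            if all(rd.GetAtomWithIdx(a).GetIsAromatic() for a in ring):
                rings.append(list(ring))
    except Exception:
        pass

    def ring_geom(coords):
        c = coords.mean(axis=0)
        _, _, vt = np.linalg.svd(coords - c)
        return c, vt[2] / np.linalg.norm(vt[2])

    for res in protein.residues:
        key = (res.chain, res.label)
        for li in apolar:
            for name in HYDROPHOBIC_ATOMS.get(res.name, []):
                if name in res.atoms and np.linalg.norm(lig[li] - res.atoms[name]) <= params.hydrophobic_max:
                    found.add(key + ("HD",))
        res_acc = [res.atoms[n] for n in SIDECHAIN_ACCEPTORS.get(res.name, []) + ["O"] if n in res.atoms]
        res_don = [res.atoms[n] for n in SIDECHAIN_DONORS.get(res.name, []) + ["N"] if n in res.atoms]
        for li in donors:
            for pos in res_acc:
                if np.linalg.norm(lig[li] - pos) <= params.hbond_max_no_h:
                    found.add(key + ("HB",))
        for li in acceptors:
            for pos in res_don:
                if np.linalg.norm(lig[li] - pos) <= params.hbond_max_no_h:
                    found.add(key + ("HB",))
        if res.name in CHARGED_GROUPS:
            sign, names = CHARGED_GROUPS[res.name]
            pts = [res.atoms[n] for n in names if n in res.atoms]
            if pts:
                centroid = np.mean(pts, axis=0)
                for li in (anions if sign > 0 else cations):
                    if np.linalg.norm(lig[li] - centroid) <= params.saltbridge_max:
                        found.add(key + ("SB",))
                if sign > 0:
                    for ring in rings:
                        c, _ = ring_geom(lig[ring])
                        if np.linalg.norm(c - centroid) <= params.pication_max:
                            found.add(key + ("PICAT",))
        for names in AROMATIC_RINGS.get(res.name, []):
            if not all(n in res.atoms for n in names):
                continue
            rc, rn = ring_geom(np.array([res.atoms[n] for n in names]))
            for li in cations:
                if np.linalg.norm(lig[li] - rc) <= params.pication_max:
                    found.add(key + ("PICAT",))
            for ring in rings:
                lc, ln = ring_geom(lig[ring])
                d = np.linalg.norm(lc - rc)
                if d > params.pipi_max_centroid:
                    continue
                ang = math.degrees(math.acos(min(1.0, abs(float(np.dot(ln, rn))))))
                if not (ang <= params.pipi_parallel_max_angle
                        or params.pipi_tshape_min_angle <= ang <= params.pipi_tshape_max_angle):
                    continue
                def offset(c1, n1, c2):
                    d_ = c2 - c1
                    return np.linalg.norm(d_ - np.dot(d_, n1) * n1)
                if min(offset(rc, rn, lc), offset(lc, ln, rc)) <= params.pipi_max_offset:
                    found.add(key + ("PIPI",))
    return found


MIXED_SPECS = [
    PlantSpec("A", "F95", "HD"),
    PlantSpec("A", "D92", "HB"),
    PlantSpec("A", "D92", "SB"),
    PlantSpec("A", "F103", "PIPI"),
    PlantSpec("A", "K297", "PICAT"),
    PlantSpec("B", "Y298", "HB"),
    PlantSpec("A", "I310", "HD", decoy=True),
    PlantSpec("A", "K110", "HB", decoy=True),
]


class TestDetection:
    def test_planted_hydrophobic_contact(self, pocket):
        pose, _ = plant_pose(pocket, [PlantSpec("A", "F95", "HD")])
        profile = detect_interactions(pocket, pose)
        assert {(r.residue.full_label, r.type) for r in profile.records} == {("F95:A", "HD")}
        rec = profile.records[0]
        assert rec.distance <= GeometryParams().hydrophobic_max

    def test_planted_hbond_with_explicit_hydrogen_angle(self, pocket):
        res = pocket.find(ResidueRef("A", "D", 92))
        acceptor = res.atoms["OD1"]
        center = np.zeros(3)
        u = (center - acceptor) / np.linalg.norm(acceptor)
        donor_pos = acceptor + 2.9 * u
        mol = Molecule("hb", [("O", 0, False, 1)], [])
        # near-linear D-H...A (~165 degrees) qualifies
        h_good = donor_pos - 1.0 * u * math.cos(math.radians(15.0)) + 1.0 * np.array(
            [0, 0, 1]
        ) * math.sin(math.radians(15.0))
        pose = Conformer(mol, [donor_pos], polar_h=[(0, h_good)])
        types = detect_interactions(pocket, pose).types_at("D92", "A")
        assert "HB" in types
        # H pointing away (~60 degrees) disqualifies despite the short distance
        h_bad = donor_pos + 1.0 * (acceptor - donor_pos) / np.linalg.norm(
            acceptor - donor_pos
        ) * math.cos(math.radians(120.0)) + 1.0 * np.array([0, 0, 1]) * math.sin(
            math.radians(120.0)
        )
        pose_bad = Conformer(mol, [donor_pos], polar_h=[(0, h_bad)])
        assert "HB" not in detect_interactions(pocket, pose_bad).types_at("D92", "A")

    def test_planted_mix_matches_oracle_exactly(self, pocket):
        params = GeometryParams()
        pose, truth = plant_pose(pocket, MIXED_SPECS, params=params)
        detected = {
            (r.residue.chain, r.residue.label, r.type)
            for r in detect_interactions(pocket, pose, params).records
        }
        assert detected == set(truth)  # recall and precision both 1
        assert detected == oracle_detect(pocket, pose, params)

    def test_rigid_motion_invariance(self, pocket):
        from scipy.spatial.transform import Rotation

        pose, truth = plant_pose(pocket, MIXED_SPECS)
        rot = Rotation.from_euler("xyz", [0.3, -1.0, 2.2]).as_matrix()
        shift = np.array([10.0, -5.0, 3.0])
        moved_residues = [
            Residue(r.chain, r.name, r.number, {n: p @ rot.T + shift for n, p in r.atoms.items()})
            for r in pocket.residues
        ]
        moved_pocket = ProteinStructure(moved_residues)
        moved_pose = Conformer(pose.molecule, pose.coords @ rot.T + shift)
        a = {(r.residue.chain, r.residue.label, r.type)
             for r in detect_interactions(pocket, pose).records}
        b = {(r.residue.chain, r.residue.label, r.type)
             for r in detect_interactions(moved_pocket, moved_pose).records}
        assert a == b

    def test_empty_pose_gives_empty_profile(self, pocket):
        pose, _ = plant_pose(pocket, [])
        assert detect_interactions(pocket, pose).records == []

    def test_deterministic(self, pocket):
        pose, _ = plant_pose(pocket, MIXED_SPECS)
        p1 = detect_interactions(pocket, pose)
        p2 = detect_interactions(pocket, pose)
        assert [(r.residue, r.type, r.distance) for r in p1.records] == [
            (r.residue, r.type, r.distance) for r in p2.records
        ]

    def test_site_restriction(self, pocket):
        pose, _ = plant_pose(pocket, [PlantSpec("A", "F95", "HD"), PlantSpec("A", "D92", "HB")])
        site = [ResidueRef("A", "F", 95)]
        profile = detect_interactions(pocket, pose, site=site)
        assert {r.residue.label for r in profile.records} == {"F95"}


# --------------------------------------------------------------------------
# Aggregation
# --------------------------------------------------------------------------


class TestAggregation:
    def test_empty_profile(self):
        from vsfunnel.interaction_profile import InteractionProfile

        assert aggregate_profile(InteractionProfile("x")) == {}

    def test_cell_merging(self):
        from vsfunnel.interaction_profile import InteractionProfile, InteractionRecord

        ref = ResidueRef("A", "Y", 295)
        profile = InteractionProfile(
            "x",
            [
                InteractionRecord("HD", ref, (0,), 3.5),
                InteractionRecord("HB", ref, (1,), 3.0),
            ],
        )
        assert aggregate_profile(profile) == {"Y295:A": "HB, HD"}

    def test_fixture_grid_round_trip(self):
        df = table_interactions("MEGx")
        compounds = sorted(df["compound"].unique())
        profiles = {c: fixture_profile(c, "GOLD") for c in compounds}
        grid = profiles_to_grid(profiles)
        records = {(pose, res, t) for pose, res, t in grid_to_records(grid)}
        expected = set()
        for c, p in profiles.items():
            for rec in p.records:
                expected.add((c, rec.residue.full_label, rec.type))
        assert records == expected


# --------------------------------------------------------------------------
# RMSD
# --------------------------------------------------------------------------


class TestRmsd:
    def test_identical_is_zero(self):
        a = np.random.default_rng(0).normal(size=(7, 3))
        assert rmsd(a, a) == 0.0

    def test_single_displacement(self):
        assert rmsd([[0, 0, 0]], [[2.0, 0, 0]]) == pytest.approx(2.0)

    def test_two_atoms_hand_value(self):
        a = [[0, 0, 0], [5, 0, 0]]
        b = [[1.0, 0, 0], [5, 3.0, 0]]
        assert rmsd(a, b) == pytest.approx(math.sqrt(5), abs=1e-12)

    def test_mass_weighting(self):
        a = [[0, 0, 0], [5, 0, 0]]
        b = [[1.0, 0, 0], [5, 3.0, 0]]
        # all weight on the second atom -> its displacement dominates
        assert rmsd(a, b, masses=[1e-9, 1.0]) == pytest.approx(3.0, abs=1e-3)

    def test_symmetry_and_scaling(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
        assert rmsd(a, b) == pytest.approx(rmsd(b, a), abs=1e-12)
        assert rmsd(a, a + 3 * (b - a)) == pytest.approx(3 * rmsd(a, a + (b - a)), rel=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            rmsd([[0, 0, 0]], [[0, 0, 0], [1, 1, 1]])
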