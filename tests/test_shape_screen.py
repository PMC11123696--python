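import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.spatial.transform import Rotation

from conftest import toy_conformer
from vsfunnel.shape_screen import (
    ShapeParams,
    atom_alpha,
    optimize_overlay,
    overlap_volume,
    screen,
    self_overlap,
    shape_tanimoto,
)


def gaussian_pair_density_integral(conf_a, conf_b, params, spacing=0.15, pad=4.0):
    """Grid quadrature of the product density integral (independent oracle)."""
    pts = np.vstack([conf_a.coords, conf_b.coords])
    lo, hi = pts.min(axis=0) - pad, pts.max(axis=0) + pad
    axes = [np.arange(lo[i], hi[i], spacing) for i in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    grid = np.stack([X, Y, Z], axis=-1)

    def density(conf):
        alphas = params.alphas(conf.elements)
        rho = np.zeros(X.shape)
        for xi, alpha in zip(conf.coords, alphas):
            d2 = np.sum((grid - xi) ** 2, axis=-1)
            rho += params.p * np.exp(-alpha * d2)
        return rho

    return float(np.sum(density(conf_a) * density(conf_b)) * spacing**3)


class TestAtomAlpha:
    def test_isolated_atom_integral_is_sphere_volume(self):
        # radial quadrature of p*exp(-a r^2) over R^3
        r, p = 1.7, 2.7
        alpha = atom_alpha(r, p)
        integral, _ = quad(lambda x: 4 * math.pi * x * x * p * math.exp(-alpha * x * x), 0, 50)
        assert integral == pytest.approx(4.0 / 3.0 * math.pi * r**3, rel=1e-6)

    def test_closed_form_value(self):
        # independent symbolic evaluation of pi*(3p/(4 pi r^3))^(2/3)
        import sympy

        r, p = sympy.Rational(1), sympy.Rational(27, 10)
        expected = float(sympy.pi * (3 * p / (4 * sympy.pi * r**3)) ** sympy.Rational(2, 3))
        assert atom_alpha(1.0, 2.7) == pytest.approx(expected, rel=1e-12)

    def test_monotone_decreasing_in_radius(self):
        radii = np.linspace(0.5, 3.0, 20)
        alphas = [atom_alpha(r) for r in radii]
        assert all(a > b for a, b in zip(alphas, alphas[1:]))

    def test_rejects_nonpositive_radius(self):
        with pytest.raises(ValueError):
            atom_alpha(0.0)


class TestOverlapVolume:
    def test_coincident_atoms(self):
        a = toy_conformer(["C"], [[0, 0, 0]])
        b = toy_conformer(["C"], [[0, 0, 0]])
        assert overlap_volume(a, b) == pytest.approx(self_overlap(a), rel=1e-12)

    def test_far_field_vanishes(self):
        a = toy_conformer(["C"], [[0, 0, 0]])
        b = toy_conformer(["C"], [[50.0, 0, 0]])
        assert overlap_volume(a, b) < 1e-9

    @pytest.mark.parametrize(
        "els_a,xyz_a,els_b,xyz_b",
        [
            (["C", "O"], [[0, 0, 0], [1.3, 0, 0]], ["N", "C"], [[0.4, 0.8, 0], [1.6, -0.4, 0.5]]),
            (["C"], [[0, 0, 0]], ["S"], [[1.0, 1.0, 0.5]]),
            (
                ["C", "C", "N"],
                [[0, 0, 0], [1.5, 0, 0], [2.2, 1.1, 0]],
                ["O", "C"],
                [[0.5, 0.5, 0.8], [1.8, -0.2, -0.4]],
            ),
        ],
    )
    def test_matches_grid_quadrature(self, els_a, xyz_a, els_b, xyz_b):
        params = ShapeParams()
        a = toy_conformer(els_a, xyz_a)
        b = toy_conformer(els_b, xyz_b)
        oracle = gaussian_pair_density_integral(a, b, params)
        assert overlap_volume(a, b, params) == pytest.approx(oracle, rel=0.01)

    def test_symmetry(self, asymmetric_toys):
        a, b = asymmetric_toys
        assert overlap_volume(a, b) == pytest.approx(overlap_volume(b, a), rel=1e-12)


class TestShapeTanimoto:
    @pytest.mark.parametrize(
        "vab,vaa,vbb,expected",
        [(10, 10, 10, 1.0), (0, 10, 10, 0.0), (10, 20, 30, 0.25)],
    )
    def test_values(self, vab, vaa, vbb, expected):
        assert shape_tanimoto(vab, vaa, vbb) == pytest.approx(expected)

    def test_errors(self):
        with pytest.raises(ValueError):
            shape_tanimoto(1.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            shape_tanimoto(-1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            shape_tanimoto(30.0, 10.0, 10.0)  # non-positive denominator


class TestOptimizeOverlay:
    def test_self_overlay_is_unity(self, small_library):
        confs, _ = small_library
        ov = optimize_overlay(confs[0], confs[0])
        assert ov.shape_tanimoto == pytest.approx(1.0, abs=1e-6)

    def test_rigid_motion_invariance(self, small_library):
        from vsfunnel.mol_model import Conformer

        confs, _ = small_library
        q = confs[0]
        rot = Rotation.from_euler("xyz", [0.7, -1.2, 2.1]).as_matrix()
        moved = Conformer(q.molecule, q.coords @ rot.T + np.array([4.0, -2.0, 7.0]), "m")
        ov = optimize_overlay(q, moved)
        assert ov.shape_tanimoto == pytest.approx(1.0, abs=1e-3)

    def test_beats_grid_search_oracle(self, asymmetric_toys):
        """Optimized overlay matches a 10-degree brute-force rotation grid."""
        a, b = asymmetric_toys
        params = ShapeParams()
        from vsfunnel.shape_screen import _pairwise_overlap

        aq = params.alphas(a.elements)
        ac = params.alphas(b.elements)
        cq = a.coords.mean(axis=0)
        centered = b.coords - b.coords.mean(axis=0)
        best_v, best_rot = -1.0, None
        grid = np.deg2rad(np.arange(0, 360, 10))
        betas = np.deg2rad(np.arange(0, 181, 10))
        for alpha in grid:
            for beta in betas:
                for gamma in grid:
                    rot = Rotation.from_euler("zyz", [alpha, beta, gamma]).as_matrix()
                    placed = centered @ rot.T + cq
                    v = _pairwise_overlap(a.coords, aq, placed, ac, params.p)
                    if v > best_v:
                        best_v, best_rot = v, rot
        # local polish from the grid optimum (translation + rotation)
        from scipy.optimize import minimize

        def neg(x):
            rot = Rotation.from_rotvec(x[:3]).as_matrix() @ best_rot
            placed = centered @ rot.T + cq + x[3:]
            return -_pairwise_overlap(a.coords, aq, placed, ac, params.p)

        res = minimize(neg, np.zeros(6), method="Nelder-Mead", options={"maxiter": 2000})
        oracle_v = max(best_v, -res.fun)
        ov = optimize_overlay(a, b, params)
        vaa, vbb = ov.v_aa, ov.v_bb
        st_oracle = shape_tanimoto(oracle_v, vaa, vbb)
        assert ov.shape_tanimoto == pytest.approx(st_oracle, abs=1e-3)

    def test_symmetry_of_optimized_score(self, asymmetric_toys):
        a, b = asymmetric_toys
        assert optimize_overlay(a, b).shape_tanimoto == pytest.approx(
            optimize_overlay(b, a).shape_tanimoto, abs=1e-3
        )

    def test_collinear_candidate_does_not_fail(self):
        line = toy_conformer(["C", "C", "C"], [[0, 0, 0], [1.5, 0, 0], [3.0, 0, 0]])
        ov = optimize_overlay(line, line)
        assert ov.shape_tanimoto == pytest.approx(1.0, abs=1e-6)

    def test_scores_bounded(self, small_library):
        confs, _ = small_library
        pairs = [(confs[i], confs[j]) for i, j in [(0, 3), (1, 5), (2, 7), (4, 6)]]
        for a, b in pairs:
            st = optimize_overlay(a, b).shape_tanimoto
            assert 0.0 <= st <= 1.0


class TestScreen:
    def test_query_in_library_ranks_first(self, small_library):
        from vsfunnel.mol_model import group_by_compound

        confs, _ = small_library
        library = group_by_compound(confs)
        query = library[sorted(library)[0]][0]
        hits = screen(query, library)
        assert hits[0].compound_id == query.compound_id
        assert hits[0].score == pytest.approx(1.0, abs=1e-6)
        assert [h.rank for h in hits] == list(range(1, len(hits) + 1))

    def test_duplicate_conformer_does_not_change_best(self, small_library):
        from vsfunnel.mol_model import group_by_compound

        confs, _ = small_library
        library = group_by_compound(confs)
        query = library[sorted(library)[0]][0]
        cid = sorted(library)[1]
        base = screen(query, {cid: library[cid]})[0].score
        dup = screen(query, {cid: library[cid] + [library[cid][0]]})[0].score
        assert dup == pytest.approx(base, abs=1e-9)

    def test_matches_per_conformer_maximum_oracle(self, small_library):
        from vsfunnel.mol_model import group_by_compound

        confs, _ = small_library
        library = {k: v for k, v in list(group_by_compound(confs).items())[:4]}
        query = next(iter(library.values()))[0]
        hits = screen(query, library)
        oracle = {}
        for cid, cs in library.items():
            oracle[cid] = max(optimize_overlay(query, c).shape_tanimoto for c in cs)
        expected_order = sorted(oracle, key=lambda c: (-oracle[c], c))
        assert [h.compound_id for h in hits] == expected_order
        for h in hits:
            assert h.score == pytest.approx(oracle[h.compound_id], abs=1e-9)

    def test_selection_truncates_after_ranking(self, small_library):
        from vsfunnel.mol_model import group_by_compound

        confs, _ = small_library
        library = group_by_compound(confs)
        query = next(iter(library.values()))[0]
        all_hits = screen(query, library)
        top2 = screen(query, library, top_n=2)
        assert [h.compound_id for h in top2] == [h.compound_id for h in all_hits[:2]]

    def test_empty_library_raises(self, small_library):
        confs, _ = small_library
        with pytest.raises(ValueError):
            screen(confs[0], {})
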