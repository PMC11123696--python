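"""Gaussian-volume shape overlay and Shape-Tanimoto screening.

Each heavy atom i is modelled as a spherical Gaussian density
``rho_i(x) = p * exp(-alpha_i * |x - x_i|^2)`` whose width ``alpha_i`` is
chosen so the isolated-atom integral equals the hard-sphere volume
``4/3 pi r_i^3`` for the element's van der Waals radius.  The overlap of two
molecules is the first-order (pairwise) Gaussian product integral

    V_AB = sum_ij p^2 (pi / (a_i + a_j))^{3/2} exp(-a_i a_j / (a_i + a_j) d_ij^2)

and the Shape-Tanimoto score is ``V_AB / (V_AA + V_BB - V_AB)``, which lies
in [0, 1] by the Cauchy-Schwarz inequality.  Overlays are optimized over
rigid rotation + translation from four principal-axes starting orientations,
the standard recipe for shape-only alignment.  No chemistry/"color" features
are scored — the ranking is purely geometric.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .mol_model import Conformer

logger = logging.getLogger(__name__)

__all__ = [
    "ShapeParams",
    "Overlay",
    "ShapeHit",
    "atom_alpha",
    "overlap_volume",
    "self_overlap",
    "shape_tanimoto",
    "optimize_overlay",
    "screen",
]

#: van der Waals radii (Angstrom) for the heavy atoms the screen supports.
DEFAULT_RADII: Dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "S": 1.80,
    "P": 1.80,
    "Cl": 1.75,
    "Br": 1.85,
    "I": 1.98,
}
_FALLBACK_RADIUS = 1.70


@dataclass
class ShapeParams:
    """Gaussian amplitude and per-element radii for the volume model."""

    p: float = 2.7
    radii: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RADII))

    def __post_init__(self) -> None:
        if self.p <= 1:
            raise ValueError("Gaussian amplitude p must exceed 1")
        for el, r in self.radii.items():
            if r <= 0:
                raise ValueError(f"non-positive radius for {el}")

    def alphas(self, elements: Sequence[str]) -> np.ndarray:
        return np.array(
            [atom_alpha(self.radii.get(el, _FALLBACK_RADIUS), self.p) for el in elements]
        )


def atom_alpha(radius: float, p: float = 2.7) -> float:
    """Gaussian width (1/A^2) whose isolated-atom integral is 4/3 pi r^3."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    return math.pi * (3.0 * p / (4.0 * math.pi * radius**3)) ** (2.0 / 3.0)


def _pairwise_overlap(
    coords_a: np.ndarray,
    alphas_a: np.ndarray,
    coords_b: np.ndarray,
    alphas_b: np.ndarray,
    p: float,
) -> float:
    d2 = np.sum(
        (coords_a[:, None, :] - coords_b[None, :, :]) ** 2, axis=-1
    )
    asum = alphas_a[:, None] + alphas_b[None, :]
    aprod = alphas_a[:, None] * alphas_b[None, :]
    terms = p * p * (np.pi / asum) ** 1.5 * np.exp(-(aprod / asum) * d2)
    return float(terms.sum())


def overlap_volume(a: Conformer, b: Conformer, params: Optional[ShapeParams] = None) -> float:
    """First-order pairwise Gaussian overlap volume V_AB (A^3)."""
    params = params or ShapeParams()
    return _pairwise_overlap(
        a.coords, params.alphas(a.elements), b.coords, params.alphas(b.elements), params.p
    )


def self_overlap(a: Conformer, params: Optional[ShapeParams] = None) -> float:
    return overlap_volume(a, a, params)


def shape_tanimoto(v_ab: float, v_aa: float, v_bb: float) -> float:
    """Shape-Tanimoto score V_AB / (V_AA + V_BB - V_AB), in [0, 1]."""
    if v_aa <= 0 or v_bb <= 0:
        raise ValueError("self-overlap volumes must be positive")
    if v_ab < 0:
        raise ValueError("overlap volume must be non-negative")
    denom = v_aa + v_bb - v_ab
    if denom <= 0:
        raise ValueError("non-positive Tanimoto denominator")
    st = v_ab / denom
    if 1.0 < st < 1.0 + 1e-9:  # float round-off on identical shapes
        return 1.0
    return st


@dataclass
class Overlay:
    """Optimized rigid placement of a candidate onto a query."""

    rotation: np.ndarray  # 3x3, applied about the candidate centroid
    translation: np.ndarray  # final shift (A)
    v_ab: float
    v_aa: float
    v_bb: float
    shape_tanimoto: float
    transformed_coords: np.ndarray


@dataclass
class ShapeHit:
    compound_id: str
    conformer_id: str
    score: float
    rank: int = 0


def _principal_axes(coords: np.ndarray) -> np.ndarray:
    """Right-handed principal axes (columns), largest variance first."""
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered
    w, v = np.linalg.eigh(cov)
    v = v[:, ::-1]  # descending variance
    if np.linalg.det(v) < 0:
        v[:, 2] = -v[:, 2]
    return v


_FLIPS = [
    np.diag([1.0, 1.0, 1.0]),
    np.diag([1.0, -1.0, -1.0]),
    np.diag([-1.0, 1.0, -1.0]),
    np.diag([-1.0, -1.0, 1.0]),
]


def optimize_overlay(
    query: Conformer,
    cand: Conformer,
    params: Optional[ShapeParams] = None,
    max_iter: int = 200,
) -> Overlay:
    """Locally maximize V_AB over rotation + translation of the candidate.

    The candidate is first centered on the query centroid; four proper
    principal-axes alignments seed the local search and the best converged
    placement is returned.  Degenerate inertia (collinear molecules) falls
    back to plain axis flips of the identity alignment.
    """
    params = params or ShapeParams()
    if query.coords.shape[0] == 0 or cand.coords.shape[0] == 0:
        raise ValueError("conformers must contain at least one heavy atom")

    alphas_q = params.alphas(query.elements)
    alphas_c = params.alphas(cand.elements)
    v_aa = _pairwise_overlap(query.coords, alphas_q, query.coords, alphas_q, params.p)
    v_bb = _pairwise_overlap(cand.coords, alphas_c, cand.coords, alphas_c, params.p)

    cq = query.coords.mean(axis=0)
    cc = cand.coords.mean(axis=0)
    cand_centered = cand.coords - cc

    try:
        axes_q = _principal_axes(query.coords)
        axes_c = _principal_axes(cand.coords)
        base_rots = [axes_q @ flip @ axes_c.T for flip in _FLIPS]
    except np.linalg.LinAlgError:  # pragma: no cover - eigh is robust
        base_rots = [np.eye(3) @ flip for flip in _FLIPS]

    def objective(x: np.ndarray, pre_rotated: np.ndarray) -> float:
        rot = Rotation.from_rotvec(x[:3]).as_matrix()
        placed = pre_rotated @ rot.T + cq + x[3:]
        return -_pairwise_overlap(query.coords, alphas_q, placed, alphas_c, params.p)

    best: Optional[Tuple[float, np.ndarray, np.ndarray]] = None
    for r0 in base_rots:
        pre = cand_centered @ r0.T
        res = minimize(
            objective,
            np.zeros(6),
            args=(pre,),
            method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-10},
        )
        v = -res.fun
        start_v = -objective(np.zeros(6), pre)
        if v < start_v:  # keep the start if the line search degraded it
            v, x = start_v, np.zeros(6)
        else:
            x = res.x
        rot = Rotation.from_rotvec(x[:3]).as_matrix() @ r0
        if best is None or v > best[0]:
            best = (v, rot, x[3:].copy())

    assert best is not None
    v_ab, rot, shift = best
    placed = (cand.coords - cc) @ rot.T + cq + shift
    return Overlay(
        rotation=rot,
        translation=cq + shift - cc,
        v_ab=v_ab,
        v_aa=v_aa,
        v_bb=v_bb,
        shape_tanimoto=shape_tanimoto(v_ab, v_aa, v_bb),
        transformed_coords=placed,
    )


def screen(
    query: Conformer,
    library: Dict[str, List[Conformer]],
    top_n: Optional[int] = None,
    top_fraction: Optional[float] = None,
    params: Optional[ShapeParams] = None,
) -> List[ShapeHit]:
    """Rank a conformer library against the query by best-conformer score.

    Each compound's score is the maximum Shape-Tanimoto over its conformers;
    compounds are ranked by descending score with lexicographic id
    tie-breaks, then truncated to ``top_n`` or ``ceil(top_fraction * N)``.
    """
    if not library:
        raise ValueError("empty library")
    params = params or ShapeParams()
    hits: List[ShapeHit] = []
    for cid in library:
        confs = library[cid]
        if not confs:
            logger.warning("compound %s has no conformers; skipped", cid)
            continue
        best_score, best_conf = -1.0, None
        for conf in confs:
            ov = optimize_overlay(query, conf, params)
            if ov.shape_tanimoto > best_score:
                best_score, best_conf = ov.shape_tanimoto, conf.conformer_id
        hits.append(ShapeHit(compound_id=cid, conformer_id=best_conf, score=best_score))
    hits.sort(key=lambda h: (-h.score, h.compound_id))
    for i, h in enumerate(hits, start=1):
        h.rank = i
    if top_n is not None:
        hits = hits[: int(top_n)]
    elif top_fraction is not None:
        hits = hits[: max(1, math.ceil(top_fraction * len(hits)))]
    return hits
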