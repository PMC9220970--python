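"""Coarse-grained hydrogen-bond detection from Cα geometry.

Backbone hydrogen bonds cannot be measured in a Cα-only structure, but the
regular geometry of β-sheets constrains where bonded neighbors sit. This
module uses a triangle surrogate: every three consecutive Cα atoms define a
triangle (centroid + unit normal); two triangles are declared hydrogen-bonded
when they are roughly parallel, their centroids sit at cross-strand distance,
and the displacement between them runs roughly along the normals — the
arrangement adjacent strands adopt in a sheet. Each residue can hold at most
one bond on either side of its triangle, so per-residue counts are 0, 1 or 2.

The geometric thresholds are free parameters of the detector; the defaults in
:class:`HbondCriteria` were chosen to fire on cross-strand Cα geometry at the
canonical ~4.8 Å inter-strand spacing and to stay silent within an isolated
strand or helix. They are stored inside every trained model file so that
training and inference always agree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import SscaError
from .structure_io import CaTrace

_DEGENERATE_TOL = 1e-10


class DegenerateTriangleError(SscaError):
    """Three collinear points define no triangle normal."""


@dataclass(frozen=True)
class HbondCriteria:
    """Geometric gates of the CG hydrogen-bond detector.

    dist_min/dist_max:
        Allowed centroid-centroid distance window (Å).
    normal_cos:
        Minimum |cos| between the two triangle normals (parallelism gate;
        unsigned so parallel and antiparallel sheets both qualify).
    disp_cos:
        Minimum |cos| between the centroid displacement and each normal
        (the partner must sit above/below the triangle face, not beside it).
    min_seq_sep:
        Minimum |i-j| along the sequence; closer pairs are never evaluated.
    """

    dist_min: float = 4.0
    dist_max: float = 6.0
    normal_cos: float = 0.7
    disp_cos: float = 0.5
    min_seq_sep: int = 3

    def __post_init__(self):
        if not (0 < self.dist_min < self.dist_max):
            raise SscaError("need 0 < dist_min < dist_max")
        if not (0 < self.normal_cos <= 1 and 0 < self.disp_cos <= 1):
            raise SscaError("cosine thresholds must lie in (0, 1]")
        if self.min_seq_sep < 3:
            raise SscaError("min_seq_sep must be >= 3")

    def to_dict(self) -> dict:
        return {
            "dist_min": self.dist_min,
            "dist_max": self.dist_max,
            "normal_cos": self.normal_cos,
            "disp_cos": self.disp_cos,
            "min_seq_sep": self.min_seq_sep,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HbondCriteria":
        return cls(**d)


@dataclass(frozen=True)
class ResidueTriangle:
    """Triangle on residues (i-1, i, i+1): centroid and unit normal."""

    residue_index: int
    centroid: np.ndarray
    normal: np.ndarray


def residue_triangle(p_prev, p, p_next, index: int) -> ResidueTriangle:
    """Build the triangle of residue ``index`` from its two sequence neighbors.

    The normal is the unit cross product (p - p_prev) x (p_next - p); its
    orientation therefore rotates with the chain and flips under mirroring.
    Collinear points raise :class:`DegenerateTriangleError`.
    """
    p_prev, p, p_next = (np.asarray(q, dtype=float) for q in (p_prev, p, p_next))
    n = np.cross(p - p_prev, p_next - p)
    norm = np.linalg.norm(n)
    scale = max(np.linalg.norm(p - p_prev), np.linalg.norm(p_next - p), 1.0)
    if norm <= _DEGENERATE_TOL * scale * scale:
        raise DegenerateTriangleError(f"degenerate triangle at residue {index}")
    return ResidueTriangle(
        residue_index=index,
        centroid=(p_prev + p + p_next) / 3.0,
        normal=n / norm,
    )


def chain_triangles(trace: CaTrace) -> list[ResidueTriangle]:
    """Triangles for residues 1..L-2; degenerate (collinear) positions are skipped."""
    coords = trace.coords
    out = []
    for i in range(1, len(trace) - 1):
        try:
            out.append(residue_triangle(coords[i - 1], coords[i], coords[i + 1], i))
        except DegenerateTriangleError:
            continue
    return out


def triangle_pair_bonded(
    a: ResidueTriangle, b: ResidueTriangle, criteria: HbondCriteria
) -> int | None:
    """Evaluate the bond gates for one triangle pair.

    Returns ``None`` when not bonded, else +1/-1: the side of triangle ``a``
    (along/against its normal) on which the partner sits. The test is
    symmetric in (a, b) — the displacement gate is applied to both normals —
    so bonded(a, b) iff bonded(b, a), though the reported sides may differ.
    """
    if abs(a.residue_index - b.residue_index) < criteria.min_seq_sep:
        return None
    d = b.centroid - a.centroid
    dist = float(np.linalg.norm(d))
    if not (criteria.dist_min <= dist <= criteria.dist_max):
        return None
    if abs(float(np.dot(a.normal, b.normal))) < criteria.normal_cos:
        return None
    dhat = d / dist
    cos_a = float(np.dot(dhat, a.normal))
    cos_b = float(np.dot(dhat, b.normal))
    if abs(cos_a) < criteria.disp_cos or abs(cos_b) < criteria.disp_cos:
        return None
    return 1 if cos_a >= 0 else -1


def hbond_counts(trace: CaTrace, criteria: HbondCriteria = HbondCriteria()) -> np.ndarray:
    """Per-residue CG hydrogen-bond counts for a whole chain.

    Each residue offers two binding sides (above/below its triangle). At most
    one partner occupies a side — the one with the nearest centroid, ties
    broken toward the lower partner residue index — so counts are bounded by
    2 on any input. Terminal residues (no triangle) and residues whose
    triangle is degenerate count 0.
    """
    L = len(trace)
    if L < 3:
        raise SscaError("hbond detection needs at least 3 residues")
    tris = chain_triangles(trace)
    counts = np.zeros(L, dtype=int)
    if len(tris) < 2:
        return counts

    cent = np.array([t.centroid for t in tris])
    nrm = np.array([t.normal for t in tris])
    ridx = np.array([t.residue_index for t in tris])
    T = len(tris)

    dist = cdist(cent, cent)
    sep_ok = np.abs(ridx[:, None] - ridx[None, :]) >= criteria.min_seq_sep
    in_range = (dist >= criteria.dist_min) & (dist <= criteria.dist_max)
    parallel = np.abs(nrm @ nrm.T) >= criteria.normal_cos

    disp = cent[None, :, :] - cent[:, None, :]  # disp[i, j] = c_j - c_i
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_own = np.einsum("ijk,ik->ij", disp, nrm) / dist
    disp_ok = (np.abs(cos_own) >= criteria.disp_cos) & (
        np.abs(cos_own.T) >= criteria.disp_cos
    )
    bonded = sep_ok & in_range & parallel & disp_ok

    for i in range(T):
        js = np.nonzero(bonded[i])[0]
        if js.size == 0:
            continue
        occupied = 0
        for side in (1, -1):
            side_js = js[cos_own[i, js] >= 0] if side == 1 else js[cos_own[i, js] < 0]
            if side_js.size:
                # nearest centroid wins the side (ties -> lower residue index);
                # only occupancy feeds the count, so the winner is implicit
                occupied += 1
        counts[ridx[i]] = occupied
    return counts
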