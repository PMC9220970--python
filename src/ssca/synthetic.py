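"""Labeled synthetic Cα traces: ideal helices, strands, sheets, coils, chimeras.

These generators define the study conditions under which the classifier is
trained and evaluated without any downloaded structures. Geometry uses
textbook Cα parameters: an α-helix with 1.5 Å rise, 2.3 Å radius and 100°
twist per residue; a β-strand as a planar zigzag with 3.3 Å axial step and
±0.942 Å lateral amplitude (both give a 3.8 Å consecutive Cα-Cα distance, so
no generator output ever contains a chain break). Sheets lay strands
side-by-side at the canonical ~4.8 Å spacing, stacked along the triangle
normals so the coarse-grained hydrogen-bond detector sees cross-strand
geometry, and join them with deterministic equal-chord arc loops. Coils are
seeded self-avoiding random walks biased toward expanded conformations.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.distance import cdist

from .errors import GenerationError, SscaError
from .structure_io import CaTrace, trace_from_coords

BOND_LENGTH = 3.8  # Å, consecutive Cα-Cα distance used by every generator

HELIX_RISE = 1.5
HELIX_RADIUS = 2.3
HELIX_TWIST = 100.0  # degrees per residue

STRAND_AXIAL_STEP = 3.3
STRAND_LATERAL = 0.942  # zigzag amplitude; bond = sqrt(3.3^2 + (2*0.942)^2) = 3.80 Å

SHEET_SPACING = 4.8  # Å between adjacent strands


@dataclass(frozen=True)
class TopologySpec:
    """Ordered secondary-structure segments plus assembly parameters.

    ``segments`` is a list of (kind, length) with kind in {H, E, C}. The
    sheet parameters apply when strands are assembled side-by-side (the
    dedicated sheet generator / dataset builder); segment concatenation in
    :func:`make_protein` places segments sequentially in space.
    """

    segments: tuple[tuple[str, int], ...]
    sheet_spacing: float = SHEET_SPACING
    antiparallel: bool = True
    seed: int = 0

    def __post_init__(self):
        segs = tuple((str(k), int(n)) for k, n in self.segments)
        if not segs or any(k not in "HEC" or n < 1 for k, n in segs):
            raise SscaError("segments must be (kind in {H,E,C}, length >= 1)")
        object.__setattr__(self, "segments", segs)

    @property
    def total_length(self) -> int:
        return sum(n for _, n in self.segments)

    @property
    def labels(self) -> str:
        return "".join(k * n for k, n in self.segments)


def parse_topology(text: str) -> tuple[tuple[str, int], ...]:
    """Parse a compact topology string like 'H10-C5-E8'."""
    segs = []
    for token in text.split("-"):
        m = re.fullmatch(r"([HEC])(\d+)", token.strip())
        if not m:
            raise SscaError(f"bad topology token: {token!r}")
        segs.append((m.group(1), int(m.group(2))))
    return tuple(segs)


def _helix_coords(n, rise, radius, twist, handedness) -> np.ndarray:
    i = np.arange(n)
    theta = np.deg2rad(twist) * i * handedness
    return np.column_stack([radius * np.cos(theta), radius * np.sin(theta), rise * i])


def make_helix(
    n: int,
    rise: float = HELIX_RISE,
    radius: float = HELIX_RADIUS,
    twist: float = HELIX_TWIST,
    handedness: int = 1,
) -> tuple[CaTrace, str]:
    """Ideal helical trace, all residues labeled H. handedness +1 = right-handed."""
    if n < 1:
        raise SscaError("n must be >= 1")
    return trace_from_coords(_helix_coords(n, rise, radius, twist, handedness)), "H" * n


def _strand_coords(n, axial_step, lateral, twist) -> np.ndarray:
    i = np.arange(n)
    amp = lateral * (-1.0) ** i
    angle = np.deg2rad(twist) * i
    return np.column_stack(
        [axial_step * i, -amp * np.sin(angle), amp * np.cos(angle)]
    )


def make_strand(
    n: int,
    axial_step: float = STRAND_AXIAL_STEP,
    lateral: float = STRAND_LATERAL,
    twist: float = 0.0,
) -> tuple[CaTrace, str]:
    """Extended zigzag trace, all residues labeled E.

    ``twist`` (degrees/residue) slowly rotates the zigzag plane about the
    strand axis, imitating the natural twist of β-strands; 0 gives a planar
    strand whose closed-form chord distances are 6.60 / 10.08 / 13.20 Å.
    """
    if n < 1:
        raise SscaError("n must be >= 1")
    return trace_from_coords(_strand_coords(n, axial_step, lateral, twist)), "E" * n


def _arc_points(p0: np.ndarray, p1: np.ndarray, n_inner: int, step: float, bulge: np.ndarray) -> np.ndarray:
    """``n_inner`` points on a circular arc from p0 to p1 with equal chords ``step``.

    The returned points exclude the endpoints; every consecutive pair along
    p0, arc..., p1 is exactly ``step`` apart. ``bulge`` picks the half-space
    the arc curves into. Raises when the chord is too long to bridge.
    """
    chord = float(np.linalg.norm(p1 - p0))
    n_seg = n_inner + 1
    if chord > n_seg * step - 1e-9:
        raise GenerationError("loop too short to bridge its endpoints")
    if chord < 1e-9:
        raise GenerationError("coincident loop endpoints")

    e1 = (p1 - p0) / chord
    b = bulge - np.dot(bulge, e1) * e1
    if np.linalg.norm(b) < 1e-9:
        raise GenerationError("bulge direction parallel to chord")
    e2 = b / np.linalg.norm(b)

    # per-segment turn alpha: chord = step * sin(n_seg*alpha/2) / sin(alpha/2)
    def gap(alpha):
        return step * np.sin(n_seg * alpha / 2) / np.sin(alpha / 2) - chord

    alpha = brentq(gap, 1e-9, 2 * np.pi / n_seg - 1e-9, xtol=1e-13)
    R = step / (2 * np.sin(alpha / 2))
    h = np.sqrt(max(R * R - (chord / 2) ** 2, 0.0))
    center = (p0 + p1) / 2 - h * e2

    t0 = np.arctan2(h, -chord / 2)
    t1 = np.arctan2(h, chord / 2)
    sweep = n_seg * alpha
    # choose the rotation direction that lands on p1 after the full sweep
    if abs((t0 - sweep - t1 + np.pi) % (2 * np.pi) - np.pi) < 1e-6:
        ts = t0 - alpha * np.arange(1, n_seg)
    else:
        ts = t0 + alpha * np.arange(1, n_seg)
    return center + R * (np.cos(ts)[:, None] * e1 + np.sin(ts)[:, None] * e2)


def make_sheet(
    n_strands: int = 2,
    strand_len: int = 8,
    spacing: float = SHEET_SPACING,
    antiparallel: bool = True,
    loop_len: int = 4,
) -> tuple[CaTrace, str]:
    """Multi-strand sheet joined by coil loops, labels E on strands / C on loops.

    Strands are stacked along the strand-triangle normal at the given
    spacing, so adjacent strands satisfy the CG hydrogen-bond geometry and
    interior residues of inner strands acquire bonds on both sides. Loops are
    equal-chord arcs bulging away from the sheet; the assembled trace is
    contiguous (every consecutive distance is 3.8 Å).
    """
    if n_strands < 2:
        raise SscaError("a sheet needs at least 2 strands")
    if strand_len < 3 or loop_len < 1:
        raise SscaError("need strand_len >= 3 and loop_len >= 1")

    # planar strand runs along x and zigzags in z, so its triangle normals
    # point along +-y; stacking along y puts partners where the CG hydrogen
    # bond detector expects them
    base = _strand_coords(strand_len, STRAND_AXIAL_STEP, STRAND_LATERAL, 0.0)
    strands = []
    for k in range(n_strands):
        s = base.copy()
        s[:, 1] += spacing * k
        if antiparallel and k % 2 == 1:
            s = s[::-1].copy()
        strands.append(s)

    coords = [strands[0]]
    labels = ["E" * strand_len]
    for k in range(1, n_strands):
        p0 = coords[-1][-1]
        p1 = strands[k][0]
        if antiparallel:
            # hairpin at alternating ends: bulge outward along x and out of
            # the sheet plane (z) so the wrap-around arc clears the strands
            out_x = 1.0 if k % 2 == 1 else -1.0
            bulge = np.array([out_x, 0.0, 1.0]) / np.sqrt(2.0)
        else:
            bulge = np.array([0.0, 0.0, 1.0])
        arc = _arc_points(p0, p1, loop_len, BOND_LENGTH, bulge)
        coords.append(arc)
        labels.append("C" * loop_len)
        coords.append(strands[k])
        labels.append("E" * strand_len)
    return trace_from_coords(np.vstack(coords)), "".join(labels)


def make_coil(
    n: int,
    seed: int,
    step: float = BOND_LENGTH,
    min_approach: float = 4.0,
    angle_range: tuple[float, float] = (60.0, 180.0),
    max_restarts: int = 50,
    max_step_retries: int = 60,
) -> tuple[CaTrace, str]:
    """Self-avoiding random walk, all residues labeled C.

    Steps are exactly ``step`` long; the pseudo-bond angle at each residue is
    drawn uniformly from ``angle_range`` (180° = straight continuation), with
    a uniform dihedral. Any placement bringing two non-adjacent residues
    (|i-j| >= 2) closer than ``min_approach`` is resampled; exhausted retries
    restart the walk on a fresh substream. Deterministic per seed.
    """
    if n < 1:
        raise SscaError("n must be >= 1")
    lo, hi = np.deg2rad(angle_range[0]), np.deg2rad(angle_range[1])
    for restart in range(max_restarts):
        rng = np.random.default_rng((seed, restart))
        pts = [np.zeros(3), np.array([step, 0.0, 0.0])]
        ok = True
        while ok and len(pts) < n:
            placed = False
            for _ in range(max_step_retries):
                theta = rng.uniform(lo, hi)  # bond angle at the current end point
                phi = rng.uniform(0.0, 2 * np.pi)
                u = pts[-1] - pts[-2]
                u /= np.linalg.norm(u)
                ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
                n1 = np.cross(u, ref)
                n1 /= np.linalg.norm(n1)
                n2 = np.cross(u, n1)
                direction = (
                    np.cos(np.pi - theta) * u
                    + np.sin(np.pi - theta) * (np.cos(phi) * n1 + np.sin(phi) * n2)
                )
                cand = pts[-1] + step * direction
                prior = np.array(pts[:-1])  # |i-j| >= 2 partners of the new point
                if prior.size == 0 or np.min(np.linalg.norm(prior - cand, axis=1)) >= min_approach:
                    pts.append(cand)
                    placed = True
                    break
            if not placed:
                ok = False
        if ok:
            return trace_from_coords(np.array(pts[:n])), "C" * n
    raise GenerationError("coil generation failed: could not satisfy self-avoidance")


def mirror(trace: CaTrace) -> CaTrace:
    """Reflect a trace through the xy-plane (an improper isometry)."""
    coords = trace.coords
    coords[:, 2] *= -1.0
    return trace_from_coords(coords, chain_id=trace.chain_id)


_SEGMENT_BUILDERS = {
    "H": lambda n: _helix_coords(n, HELIX_RISE, HELIX_RADIUS, HELIX_TWIST, 1),
    "E": lambda n: _strand_coords(n, STRAND_AXIAL_STEP, STRAND_LATERAL, 0.0),
}


def _random_rotation(rng) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def make_protein(spec: TopologySpec) -> tuple[CaTrace, str]:
    """Concatenate H/E/C segments with rigid placement, avoiding clashes.

    Each segment keeps its ideal internal geometry; successive segments are
    rotated and attached so the junction bond is 3.8 Å and no two residues
    with |i-j| >= 2 come closer than 3.5 Å. Deterministic per spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    placed: np.ndarray | None = None
    for seg_no, (kind, n) in enumerate(spec.segments):
        if kind in _SEGMENT_BUILDERS:
            local = _SEGMENT_BUILDERS[kind](n)
        else:
            coil_trace, _ = make_coil(n, seed=int(rng.integers(2**31)))
            local = coil_trace.coords
        local = local - local[0]
        if placed is None:
            placed = local
            continue
        attached = None
        for _ in range(300):
            R = _random_rotation(rng)
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            cand = local @ R.T + placed[-1] + BOND_LENGTH * d
            # clash check over |i-j| >= 2 pairs across the junction
            dmat = cdist(placed, cand)
            dmat[-1, 0] = np.inf  # the junction bond itself (|i-j| = 1)
            if dmat.min() >= 3.5:
                attached = cand
                break
        if attached is None:
            raise GenerationError(f"segment {seg_no}: no clash-free placement found")
        placed = np.vstack([placed, attached])
    return trace_from_coords(placed), spec.labels


# ---------------------------------------------------------------------------
# dataset builder: the corpus the classifier trains on

#: topology menu and sampling weights; E residues come almost exclusively
#: from sheets so the CG hydrogen-bond signal exists for the E class.
_DATASET_MENU = (
    ("helix", 0.20),
    ("helix_coil_helix", 0.20),
    ("sheet2", 0.175),
    ("sheet3", 0.175),
    ("coil", 0.15),
    ("helix_coil", 0.10),
)


def make_dataset(n_chains: int, seed: int) -> list[tuple[str, CaTrace, str]]:
    """Generate a labeled corpus of mixed helix/sheet/coil chains.

    Returns (name, trace, labels) triples; deterministic per seed. Chain
    kinds are drawn from a fixed menu of topologies with randomized segment
    lengths, sized so that all three classes are well represented.
    """
    rng = np.random.default_rng(seed)
    kinds = [k for k, _ in _DATASET_MENU]
    weights = np.array([w for _, w in _DATASET_MENU])
    weights = weights / weights.sum()
    out = []
    for c in range(n_chains):
        kind = rng.choice(kinds, p=weights)
        sub = int(rng.integers(2**31))
        if kind == "helix":
            trace, labels = make_helix(int(rng.integers(10, 26)))
        elif kind == "helix_coil_helix":
            spec = TopologySpec(
                segments=(
                    ("H", int(rng.integers(8, 19))),
                    ("C", int(rng.integers(4, 9))),
                    ("H", int(rng.integers(8, 19))),
                ),
                seed=sub,
            )
            trace, labels = make_protein(spec)
        elif kind == "helix_coil":
            spec = TopologySpec(
                segments=(("H", int(rng.integers(8, 19))), ("C", int(rng.integers(6, 13)))),
                seed=sub,
            )
            trace, labels = make_protein(spec)
        elif kind == "sheet2":
            trace, labels = make_sheet(2, int(rng.integers(6, 13)), antiparallel=True)
        elif kind == "sheet3":
            trace, labels = make_sheet(3, int(rng.integers(6, 13)), antiparallel=True)
        else:  # coil
            trace, labels = make_coil(int(rng.integers(15, 31)), seed=sub)
        out.append((f"synth{c:04d}", trace, labels))
    return out
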