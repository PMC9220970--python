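"""Rotation- and translation-invariant geometric features of a Cα trace.

Three feature blocks are computed over a sliding window of N residues and
concatenated into the classifier input row for the window's middle residue:

* **local** — chord distances r(i,i+2), r(i,i+4) and the chirality-signed
  r*(i,i+3) along the window. The sign of r*(i,i+3) is the sign of the triple
  product of the three consecutive pseudo-bond vectors between atoms i..i+3,
  which separates right-handed from left-handed local conformations (a mirror
  reflection flips every sign and nothing else).
* **neighbors** — for each window residue, the number of Cα atoms of the
  chain within 4.0 / 4.5 / 5.0 / 6.0 Å, excluding atoms closer than three
  positions along the sequence. Densely packed residues (regular secondary
  structure in a protein core) score high; exposed loops score low.
* **hbonds** — per-residue coarse-grained hydrogen-bond counts in {0,1,2},
  computed by :mod:`ssca.hbond` and passed in already aligned to the trace.

All blocks depend on interatomic distances and triple products only, so every
feature is invariant under rigid motion of the input coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import SscaError
from .structure_io import CaTrace

#: neighbor-count distance cutoffs in Å, ascending.
NEIGHBOR_CUTOFFS = (4.0, 4.5, 5.0, 6.0)

#: minimum |i-j| along the sequence for a neighbor to be counted.
NEIGHBOR_MIN_SEQ_SEP = 3

#: window lengths the classifier was designed around.
SUPPORTED_WINDOWS = (5, 7, 9, 11, 13)

FEATURE_BLOCKS = ("local", "neighbors", "hbonds")


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window length and enabled feature blocks."""

    n: int = 11
    feature_set: tuple[str, ...] = FEATURE_BLOCKS

    def __post_init__(self):
        if self.n not in SUPPORTED_WINDOWS:
            raise SscaError(f"window length must be one of {SUPPORTED_WINDOWS}, got {self.n}")
        fs = tuple(self.feature_set)
        if not fs or any(b not in FEATURE_BLOCKS for b in fs):
            raise SscaError(f"feature_set must be a nonempty subset of {FEATURE_BLOCKS}")
        if "local" not in fs:
            # neighbor/hbond blocks are add-ons to the local distances, never standalone
            raise SscaError("feature_set must include 'local'")
        object.__setattr__(self, "feature_set", tuple(b for b in FEATURE_BLOCKS if b in fs))

    @property
    def half(self) -> int:
        return (self.n - 1) // 2

    @property
    def width(self) -> int:
        """Feature-vector length: (3N-9) local + 4N neighbor + N hbond entries."""
        w = 3 * self.n - 9
        if "neighbors" in self.feature_set:
            w += len(NEIGHBOR_CUTOFFS) * self.n
        if "hbonds" in self.feature_set:
            w += self.n
        return w

    def feature_names(self) -> list[str]:
        names = [f"r2_{k}" for k in range(self.n - 2)]
        names += [f"r3s_{k}" for k in range(self.n - 3)]
        names += [f"r4_{k}" for k in range(self.n - 4)]
        if "neighbors" in self.feature_set:
            names += [
                f"nb_{i}_{c:g}" for i in range(self.n) for c in NEIGHBOR_CUTOFFS
            ]
        if "hbonds" in self.feature_set:
            names += [f"hb_{i}" for i in range(self.n)]
        return names


@dataclass(frozen=True)
class LocalDistanceBlock:
    """Chord distances of one window: r2 (len N-2), signed r3 (N-3), r4 (N-4)."""

    r2: np.ndarray
    r3s: np.ndarray
    r4: np.ndarray

    def flatten(self) -> np.ndarray:
        return np.concatenate([self.r2, self.r3s, self.r4])


def signed_r3(p0, p1, p2, p3) -> float:
    """Cα(i)-Cα(i+3) distance signed by the local chirality.

    The magnitude is |p3 - p0|; the sign is that of the triple product
    (v0 x v1) . v2 of the three consecutive bond vectors v_k = p_{k+1} - p_k.
    Right-handed (α-helical) conformations give +, mirror images give -.
    An exactly planar quadruplet (triple product 0) is signed +.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    v0, v1, v2 = p1 - p0, p2 - p1, p3 - p2
    triple = float(np.dot(np.cross(v0, v1), v2))
    sign = -1.0 if triple < 0 else 1.0
    return sign * float(np.linalg.norm(p3 - p0))


def local_distances(window_coords) -> LocalDistanceBlock:
    """Local-distance block of a single N-residue window (N >= 5)."""
    w = np.asarray(window_coords, dtype=float)
    if w.ndim != 2 or w.shape[1] != 3 or w.shape[0] < 5:
        raise SscaError("window too short: need at least 5 Cα positions")
    r2 = np.linalg.norm(w[2:] - w[:-2], axis=1)
    r4 = np.linalg.norm(w[4:] - w[:-4], axis=1)
    v = np.diff(w, axis=0)
    triple = np.einsum("ij,ij->i", np.cross(v[:-2], v[1:-1]), v[2:])
    signs = np.where(triple < 0, -1.0, 1.0)
    r3s = signs * np.linalg.norm(w[3:] - w[:-3], axis=1)
    return LocalDistanceBlock(r2=r2, r3s=r3s, r4=r4)


def neighbor_counts(
    trace: CaTrace | np.ndarray,
    cutoffs=NEIGHBOR_CUTOFFS,
    min_seq_sep: int = NEIGHBOR_MIN_SEQ_SEP,
) -> np.ndarray:
    """Per-residue spatial neighbor counts within each cutoff.

    Returns an (L, n_cutoffs) integer array where entry [i, c] counts residues
    j of the same trace with |i - j| >= min_seq_sep and |p_i - p_j| <= cutoffs[c].
    Counts are monotone non-decreasing along the cutoff axis by construction.
    """
    coords = trace.coords if isinstance(trace, CaTrace) else np.asarray(trace, dtype=float)
    cutoffs = tuple(cutoffs)
    if any(b <= a for a, b in zip(cutoffs, cutoffs[1:])):
        raise SscaError("cutoffs must be strictly ascending")
    L = coords.shape[0]
    d = cdist(coords, coords)
    idx = np.arange(L)
    eligible = np.abs(idx[:, None] - idx[None, :]) >= min_seq_sep
    counts = np.empty((L, len(cutoffs)), dtype=int)
    for c, cutoff in enumerate(cutoffs):
        counts[:, c] = np.sum(eligible & (d <= cutoff), axis=1)
    return counts


def featurize_chain(
    trace: CaTrace,
    hbonds: np.ndarray | None,
    cfg: WindowConfig,
    breaks: list[int] | None = None,
) -> tuple[np.ndarray, list[int]]:
    """Assemble the per-window feature matrix of a whole chain.

    Windows slide by one residue; each row describes the window whose middle
    residue index is returned in ``centers``. Windows that span a chain break
    are dropped: their local distances would measure across a physical gap.

    Parameters
    ----------
    trace:
        The chain to featurize.
    hbonds:
        Per-residue CG hydrogen-bond counts aligned to the trace; required
        iff 'hbonds' is in ``cfg.feature_set``.
    cfg:
        Window length and feature blocks.
    breaks:
        Output of :func:`ssca.structure_io.detect_chain_breaks`; ``None``
        means the chain is known to be contiguous.

    Returns
    -------
    (X, centers):
        X is (n_windows, cfg.width); centers the 0-based middle-residue
        indices. A trace shorter than N yields an empty matrix and a warning.
    """
    N = cfg.n
    L = len(trace)
    if "hbonds" in cfg.feature_set:
        if hbonds is None:
            raise SscaError("hbond counts required by the feature configuration")
        hbonds = np.asarray(hbonds, dtype=float)
        if hbonds.shape != (L,):
            raise SscaError("hbond counts not aligned to trace")
    if L < N:
        warnings.warn(f"trace of length {L} shorter than window {N}: no features")
        return np.empty((0, cfg.width)), []

    coords = trace.coords
    breaks = set(breaks or [])
    nb = neighbor_counts(trace) if "neighbors" in cfg.feature_set else None

    rows, centers = [], []
    for s in range(L - N + 1):
        # a break at i separates residues i and i+1; the window covers s..s+N-1
        if any(s <= b <= s + N - 2 for b in breaks):
            continue
        parts = [local_distances(coords[s : s + N]).flatten()]
        if nb is not None:
            parts.append(nb[s : s + N].reshape(-1).astype(float))
        if "hbonds" in cfg.feature_set:
            parts.append(hbonds[s : s + N])
        rows.append(np.concatenate(parts))
        centers.append(s + cfg.half)
    if not rows:
        return np.empty((0, cfg.width)), []
    return np.vstack(rows), centers


def features_tsv(X: np.ndarray, centers: list[int], cfg: WindowConfig) -> str:
    """Render a feature matrix as TSV with named columns (debugging/interop)."""
    header = "center\t" + "\t".join(cfg.feature_names())
    lines = [header]
    for c, row in zip(centers, X):
        lines.append(f"{c}\t" + "\t".join(f"{v:.6f}" for v in row))
    return "\n".join(lines) + "\n"
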