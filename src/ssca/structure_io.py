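"""Read Cα traces from PDB text, validate chain continuity, and handle label strings.

The only structural input representation used anywhere in the package is the
:class:`CaTrace`: the ordered alpha-carbon coordinates of a single chain.
Everything else about a deposit (side chains, other backbone atoms, ligands,
waters) is ignored at parse time.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import gemmi
import numpy as np
from Bio import SeqIO

from .errors import (
    AlignmentError,
    ChainNotFoundError,
    EmptyTraceError,
    InvalidLabelError,
    SscaError,
)

SS_ALPHABET = "HEC"

#: eight-state DSSP letters -> three states. H,G,I are helical; E,B extended;
#: turns, bends, blanks and unassigned positions collapse to coil.
DSSP_3STATE = {
    "H": "H", "G": "H", "I": "H",
    "E": "E", "B": "E",
    "T": "C", "S": "C", "C": "C", "-": "C", " ": "C",
}

#: Accepted consecutive Cα-Cα distance range (Å): admits the trans peptide
#: (~3.8 Å) and the rarer cis peptide (~2.9 Å); anything outside is a break.
BREAK_D_MIN = 2.5
BREAK_D_MAX = 4.3


@dataclass(frozen=True)
class Residue:
    """One residue of a Cα trace: PDB numbering plus the CA coordinate."""

    resseq: int
    icode: str
    coord: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.coord, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise SscaError(f"residue {self.resseq}: coordinate must be a finite 3-vector")
        object.__setattr__(self, "coord", c)


@dataclass(frozen=True)
class CaTrace:
    """Ordered Cα coordinates of one chain, in file order."""

    chain_id: str
    residues: tuple[Residue, ...]

    def __post_init__(self):
        if len(self.residues) < 1:
            raise EmptyTraceError("a trace needs at least one residue")
        object.__setattr__(self, "residues", tuple(self.residues))

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def coords(self) -> np.ndarray:
        """(L, 3) float array of Cα positions in Å."""
        return np.array([r.coord for r in self.residues], dtype=float)


@dataclass(frozen=True)
class SSAssignment:
    """Per-residue H/E/C labels aligned to a trace, with optional class probabilities."""

    labels: str
    probabilities: np.ndarray | None = field(default=None)

    def __post_init__(self):
        if len(self.labels) == 0:
            raise InvalidLabelError("empty assignment")
        bad = set(self.labels) - set(SS_ALPHABET)
        if bad:
            raise InvalidLabelError(f"labels outside H/E/C alphabet: {sorted(bad)}")
        if self.probabilities is not None:
            p = np.asarray(self.probabilities, dtype=float)
            if p.shape != (len(self.labels), 3):
                raise AlignmentError("probability array must be (L, 3)")
            object.__setattr__(self, "probabilities", p)

    def __len__(self) -> int:
        return len(self.labels)


def trace_from_coords(coords, chain_id: str = "A", start_resseq: int = 1) -> CaTrace:
    """Build a CaTrace from a bare (L, 3) coordinate array (synthetic data, tests)."""
    coords = np.asarray(coords, dtype=float)
    residues = tuple(
        Residue(resseq=start_resseq + i, icode="", coord=coords[i])
        for i in range(coords.shape[0])
    )
    return CaTrace(chain_id=chain_id, residues=residues)


def read_ca_trace(pdb_text: str, chain_id: str, model_index: int = 1) -> CaTrace:
    """Extract the Cα trace of one chain from PDB-format text.

    Only CA atoms whose element is carbon are taken (this excludes calcium
    ions, which share the atom name). HETATM CA records (e.g. selenomethionine)
    are accepted. Where a residue carries alternate locations, the highest
    occupancy wins; ties go to the record encountered first.

    Parameters
    ----------
    pdb_text:
        Contents of a PDB file (ATOM/HETATM records; other records ignored).
    chain_id:
        Chain identifier to extract.
    model_index:
        1-based model number (NMR/EM multi-model files); default 1.
    """
    if model_index < 1:
        raise SscaError("model_index is 1-based and must be >= 1")
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise EmptyTraceError("no models in PDB text")
    if model_index > len(st):
        raise SscaError(f"model {model_index} not present ({len(st)} model(s) found)")
    model = st[model_index - 1]

    chain = None
    for ch in model:
        if ch.name == chain_id:
            chain = ch
            break
    if chain is None:
        raise ChainNotFoundError(f"chain not found: {chain_id!r}")

    residues = []
    for res in chain:
        cas = [a for a in res if a.name == "CA" and a.element.name == "C"]
        if not cas:
            continue
        best = max(cas, key=lambda a: a.occ)  # max() keeps the first on ties
        residues.append(
            Residue(
                resseq=res.seqid.num,
                icode=(res.seqid.icode or "").strip(),
                coord=np.array([best.pos.x, best.pos.y, best.pos.z]),
            )
        )
    if not residues:
        raise EmptyTraceError(f"empty trace: chain {chain_id!r} has no CA atoms")
    return CaTrace(chain_id=chain_id, residues=tuple(residues))


def write_ca_pdb(trace: CaTrace, res_name: str = "ALA") -> str:
    """Serialize a trace as CA-only ATOM records (wwPDB v3.3 fixed columns)."""
    lines = []
    for i, r in enumerate(trace.residues):
        x, y, z = r.coord
        lines.append(
            f"ATOM  {i + 1:>5}  CA  {res_name:<3} {trace.chain_id[:1]}"
            f"{r.resseq:>4}{(r.icode or ' ')[:1]}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
            f" C  "
        )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def detect_chain_breaks(
    trace: CaTrace, d_min: float = BREAK_D_MIN, d_max: float = BREAK_D_MAX
) -> list[int]:
    """Indices ``i`` where the Cα(i)-Cα(i+1) distance falls outside [d_min, d_max].

    An empty list means the chain is contiguous. Raises on traces shorter
    than two residues, where contiguity is undefined.
    """
    if len(trace) < 2:
        raise SscaError("chain-break detection needs at least 2 residues")
    coords = trace.coords
    d = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    return [int(i) for i in np.nonzero((d < d_min) | (d > d_max))[0]]


def reduce_dssp_classes(eight_state: str) -> str:
    """Collapse an 8-state DSSP string to the three-state H/E/C alphabet."""
    out = []
    for ch in eight_state:
        try:
            out.append(DSSP_3STATE[ch])
        except KeyError:
            raise InvalidLabelError(f"invalid DSSP code: {ch!r}") from None
    return "".join(out)


def write_assignment(trace: CaTrace, assignment: SSAssignment, format: str = "plain") -> str:
    """Render an assignment as a plain H/E/C string or a per-residue TSV table."""
    if len(trace) != len(assignment):
        raise AlignmentError(
            f"alignment error: trace has {len(trace)} residues, labels {len(assignment)}"
        )
    if format == "plain":
        return assignment.labels
    if format == "tsv":
        rows = ["chain\tresseq\ticode\tss\tpH\tpE\tpC"]
        for i, r in enumerate(trace.residues):
            if assignment.probabilities is not None:
                ph, pe, pc = (f"{v:.6f}" for v in assignment.probabilities[i])
            else:
                ph = pe = pc = ""
            rows.append(
                f"{trace.chain_id}\t{r.resseq}\t{r.icode}\t{assignment.labels[i]}\t{ph}\t{pe}\t{pc}"
            )
        return "\n".join(rows) + "\n"
    raise SscaError(f"unknown format: {format!r}")


def read_label_file(text: str) -> dict[str, str]:
    """Parse a FASTA-like label file: '>' headers, one H/E/C (or DSSP) string each."""
    records = {}
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        records[rec.id] = str(rec.seq)
    if not records:
        raise SscaError("no label records found")
    return records


def write_label_file(entries: dict[str, str]) -> str:
    """Serialize {name: label-string} as FASTA-like text."""
    return "".join(f">{name}\n{labels}\n" for name, labels in entries.items())
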