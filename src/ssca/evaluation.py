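"""Q3 accuracy, confusion matrices and per-protein accuracy histograms.

Q3 is the fraction of residues whose three-state label matches the
reference. The aggregate Q3 over a set of chains is residue-weighted
(total correct / total residues); per-chain values are kept separately
for histogramming.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, SscaError
from .structure_io import SSAssignment

CLASS_ORDER = "HEC"


def _as_string(x) -> str:
    return x.labels if isinstance(x, SSAssignment) else str(x)


def _paired(pred, truth) -> tuple[str, str]:
    p, t = _as_string(pred), _as_string(truth)
    if len(p) == 0 or len(t) == 0:
        raise AlignmentError("empty assignment")
    if len(p) != len(t):
        raise AlignmentError(f"alignment error: lengths {len(p)} vs {len(t)}")
    return p, t


def q3(pred, truth) -> float:
    """Fraction of positions where prediction and reference agree."""
    p, t = _paired(pred, truth)
    return sum(a == b for a, b in zip(p, t)) / len(p)


def confusion_counts(pred, truth) -> np.ndarray:
    """3x3 integer counts; rows = true H,E,C, columns = predicted."""
    p, t = _paired(pred, truth)
    idx = {c: k for k, c in enumerate(CLASS_ORDER)}
    m = np.zeros((3, 3), dtype=int)
    for a, b in zip(t, p):
        m[idx[a], idx[b]] += 1
    return m


def confusion(pred, truth) -> np.ndarray:
    """Row-normalized confusion matrix in percent.

    entry[t][p] = 100 * #(truth=t, pred=p) / #(truth=t). A true class absent
    from the reference yields an undefined (NaN) row.
    """
    m = confusion_counts(pred, truth).astype(float)
    totals = m.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * m / totals
    pct[totals[:, 0] == 0] = np.nan
    return pct


def q3_histogram(per_protein_q3, bin_width: float = 2.5) -> np.ndarray:
    """Histogram of per-chain Q3 over [0, 100] percent.

    Bins are left-open/right-closed, so a chain at exactly 95.0% falls in the
    92.5-95.0 bin; 0% falls in the first bin. Counts sum to the number of
    chains.
    """
    values = np.asarray(per_protein_q3, dtype=float)
    if values.size and (values.min() < 0 or values.max() > 1):
        raise SscaError("per-protein Q3 values must lie in [0, 1]")
    n_bins = int(round(100.0 / bin_width))
    counts = np.zeros(n_bins, dtype=int)
    for v in values * 100.0:
        k = int(np.ceil(v / bin_width)) - 1 if v > 0 else 0
        counts[min(max(k, 0), n_bins - 1)] += 1
    return counts


@dataclass(frozen=True)
class EvalReport:
    """Aggregate evaluation over a set of chains."""

    q3: float
    confusion: np.ndarray  # row-normalized percent
    per_protein_q3: list[float]
    n_perfect: int


def evaluate(pairs) -> EvalReport:
    """Build an EvalReport from (prediction, truth) pairs, one per chain."""
    pairs = list(pairs)
    if not pairs:
        raise SscaError("nothing to evaluate")
    total = np.zeros((3, 3), dtype=int)
    per_chain = []
    for pred, truth in pairs:
        total += confusion_counts(pred, truth)
        per_chain.append(q3(pred, truth))
    grand = total.sum()
    totals = total.sum(axis=1, keepdims=True).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * total / totals
    pct[totals[:, 0] == 0] = np.nan
    return EvalReport(
        q3=float(np.trace(total)) / grand,
        confusion=pct,
        per_protein_q3=per_chain,
        n_perfect=sum(1 for v in per_chain if v == 1.0),
    )


def confusion_tsv(matrix: np.ndarray) -> str:
    lines = ["true\\pred\tH\tE\tC"]
    for k, row_label in enumerate(CLASS_ORDER):
        cells = ["" if np.isnan(v) else f"{v:.3f}" for v in matrix[k]]
        lines.append(f"{row_label}\t" + "\t".join(cells))
    return "\n".join(lines) + "\n"


def histogram_tsv(counts: np.ndarray, bin_width: float = 2.5) -> str:
    lines = ["bin_start\tcount"]
    for k, c in enumerate(counts):
        lines.append(f"{k * bin_width:g}\t{int(c)}")
    return "\n".join(lines) + "\n"


def report_text(report: EvalReport) -> str:
    """Human-readable summary used by the CLI."""
    return (
        f"q3\t{report.q3:.6f}\n"
        f"n_chains\t{len(report.per_protein_q3)}\n"
        f"n_perfect\t{report.n_perfect}\n"
    )
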