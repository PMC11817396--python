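"""Decoupling and stability metrics on inferred connectomes.

Stability is summarized by the largest eigenvalues of the graph Laplacian
(the rates at which non-uniform biomarker patterns relax under diffusion);
decoupling is read off the early-minus-late adjacency difference matrix:
its largest upper-triangle cells are the candidate decoupled region pairs,
scored against a known perturbation by precision (fraction of the top-K
cells touching a perturbed region) and recall (fraction of perturbed
regions touched by at least one cell).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import CondynError, InvalidAdjacencyError
from .synthetic import DecouplingGroundTruth

__all__ = [
    "DecouplingReport",
    "top_k_eigenvalues",
    "adjacency_difference",
    "top_k_cells",
    "decoupling_precision_recall",
    "decoupling_report",
]


@dataclass
class DecouplingReport:
    """Early-minus-late difference analysis with optional ground-truth scores."""

    difference: np.ndarray
    top_cells: list[tuple[int, int]]
    precision: float | None = None
    recall: float | None = None

    @property
    def k(self) -> int:
        return len(self.top_cells)


def top_k_eigenvalues(L, k: int) -> np.ndarray:
    """The k largest Laplacian eigenvalues, descending."""
    L = np.asarray(L, dtype=float)
    n = L.shape[0]
    if k > n:
        raise CondynError(f"k={k} exceeds matrix size {n}")
    w = np.linalg.eigvalsh(L)
    return w[::-1][:k]


def adjacency_difference(A_early, A_late, labels_early=None, labels_late=None) -> np.ndarray:
    """Element-wise early minus late adjacency.

    Negative cells (strengthened connections) are retained; they are
    reported but rank below positive cells when selecting decoupled pairs.
    """
    A_early = np.asarray(A_early, dtype=float)
    A_late = np.asarray(A_late, dtype=float)
    if A_early.shape != A_late.shape:
        raise CondynError("adjacency shapes differ")
    if labels_early is not None and labels_late is not None and list(labels_early) != list(labels_late):
        raise CondynError("region labels differ between the two adjacencies")
    for A in (A_early, A_late):
        if np.abs(A - A.T).max() > 1e-8 * max(1.0, np.abs(A).max()):
            raise InvalidAdjacencyError("input adjacency is not symmetric")
    return A_early - A_late


def top_k_cells(D, k: int) -> list[tuple[int, int]]:
    """The K largest upper-triangle cells of a symmetric difference matrix.

    Returned as (i, j) with i < j, sorted by descending value; exact ties
    break in (i, j) lexicographic order.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    if k > iu.size:
        raise CondynError(f"k={k} exceeds the {iu.size} upper-triangle cells")
    vals = D[iu, ju]
    order = np.lexsort((ju, iu, -vals))
    return [(int(iu[m]), int(ju[m])) for m in order[:k]]


def decoupling_precision_recall(cells, truth: DecouplingGroundTruth) -> tuple[float, float]:
    """Score predicted cells against the perturbed row/column index set.

    A cell (i, j) is a true positive iff i or j is a perturbed index (the
    injected decay removes weight from whole rows/columns).  Precision is
    TP / K; recall is the fraction of perturbed indices touched by at
    least one predicted cell.
    """
    cells = list(cells)
    if not cells:
        raise CondynError("no predicted cells")
    truth_idx = truth.perturbed_indices
    if not truth_idx:
        raise CondynError("empty ground-truth index set")
    tp = sum(1 for i, j in cells if i in truth_idx or j in truth_idx)
    touched = {m for cell in cells for m in cell if m in truth_idx}
    return tp / len(cells), len(touched) / len(truth_idx)


def decoupling_report(A_early, A_late, k: int = 10,
                      truth: DecouplingGroundTruth | None = None) -> DecouplingReport:
    """Full early/late decoupling analysis, optionally scored against truth."""
    D = adjacency_difference(A_early, A_late)
    cells = top_k_cells(D, k)
    precision = recall = None
    if truth is not None:
        precision, recall = decoupling_precision_recall(cells, truth)
    return DecouplingReport(D, cells, precision, recall)
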