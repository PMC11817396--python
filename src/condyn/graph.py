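"""Latent-vector parameterization of connectome adjacencies and graph Laplacians.

A connectome is modeled as an undirected weighted graph on N brain regions.
The latent parameterization maps a strictly positive vector phi to the
rank-one adjacency A = phi phi' with the diagonal removed, and to the
graph Laplacian L = Diag(A 1) - A.  This Laplacian always annihilates the
constant vector (L 1 = 0) and is positive semidefinite, so it generates a
mass-conserving diffusion on the graph.

The Rayleigh quotient phi' L phi / phi' phi, with phi itself as the trial
vector, serves as a cheap rank-one approximation of a Laplacian eigenvalue;
it admits the closed form

    lambda_bar = [ (1'phi)(1'phi^3) - ||phi||^4 ] / ||phi||^2
               = sum_{i<j} phi_i phi_j (phi_i - phi_j)^2 / phi'phi,

which avoids forming the N x N matrix entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidAdjacencyError, InvalidLatentError

__all__ = [
    "as_latent",
    "adjacency_from_latent",
    "laplacian_from_adjacency",
    "validate_laplacian",
    "rayleigh_ritz_value",
    "estimate_adjacency",
    "LaplacianDiagnostics",
]

#: default absolute tolerances (scaled by matrix magnitude where noted)
SYMMETRY_TOL = 1e-10
ROW_SUM_TOL = 1e-9
PSD_TOL = 1e-9


def as_latent(phi) -> np.ndarray:
    """Validate and return ``phi`` as a float array on log-normal support.

    Raises
    ------
    InvalidLatentError
        If ``phi`` is not a 1-D vector of length >= 2 with strictly
        positive finite entries.
    """
    phi = np.asarray(phi, dtype=float)
    if phi.ndim != 1 or phi.size < 2:
        raise InvalidLatentError(f"latent must be a 1-D vector of length >= 2, got shape {phi.shape}")
    if not np.all(np.isfinite(phi)):
        raise InvalidLatentError("latent contains non-finite entries")
    if np.any(phi <= 0):
        raise InvalidLatentError("latent entries must be strictly positive")
    return phi


def adjacency_from_latent(phi) -> np.ndarray:
    """Rank-one adjacency A = phi phi' with the diagonal zeroed."""
    phi = as_latent(phi)
    A = np.outer(phi, phi)
    np.fill_diagonal(A, 0.0)
    return A


def _check_adjacency(A, tol: float = 1e-8) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise InvalidAdjacencyError(f"adjacency must be square, got shape {A.shape}")
    if not np.all(np.isfinite(A)):
        raise InvalidAdjacencyError("adjacency contains non-finite entries")
    scale = max(1.0, float(np.abs(A).max()))
    if np.abs(A - A.T).max() > tol * scale:
        raise InvalidAdjacencyError("adjacency is not symmetric within tolerance")
    return A


def laplacian_from_adjacency(A, tol: float = 1e-8) -> np.ndarray:
    """Graph Laplacian L = Diag(A 1) - A from a symmetric adjacency."""
    A = _check_adjacency(A, tol=tol)
    return np.diag(A.sum(axis=1)) - A


@dataclass(frozen=True)
class LaplacianDiagnostics:
    """Structural diagnostics of a candidate graph Laplacian."""

    symmetry_defect: float
    max_abs_row_sum: float
    min_eigenvalue: float
    passed: bool


def validate_laplacian(L) -> LaplacianDiagnostics:
    """Check the defining properties of a graph Laplacian.

    Reports the symmetry defect, the largest |row sum| (should be 0: the
    constant vector is in the kernel) and the smallest eigenvalue (should
    be >= 0).  Tolerances scale with the magnitude of ``L`` so the checks
    stay meaningful for strongly weighted graphs.
    """
    L = np.asarray(L, dtype=float)
    if L.ndim != 2 or L.shape[0] != L.shape[1]:
        raise InvalidAdjacencyError(f"Laplacian must be square, got shape {L.shape}")
    scale = max(1.0, float(np.abs(L).max()))
    sym = float(np.abs(L - L.T).max())
    row = float(np.abs(L.sum(axis=1)).max())
    min_eig = float(np.linalg.eigvalsh((L + L.T) / 2.0)[0])
    passed = (
        sym <= SYMMETRY_TOL * scale
        and row <= ROW_SUM_TOL * scale
        and min_eig >= -PSD_TOL * scale
    )
    return LaplacianDiagnostics(sym, row, min_eig, passed)


def rayleigh_ritz_value(phi) -> float:
    """Rank-one eigenvalue approximation phi'L(phi)phi / phi'phi in closed form.

    Equals sum_{i<j} phi_i phi_j (phi_i - phi_j)^2 / phi'phi, evaluated in
    O(N) via power sums.  Nonnegative; zero exactly when phi is constant
    (phi is then the kernel vector of its own Laplacian).
    """
    phi = as_latent(phi)
    q = float(phi @ phi)
    num = float(phi.sum() * (phi**3).sum()) - q * q
    val = num / q
    return max(val, 0.0)


def estimate_adjacency(samples) -> np.ndarray:
    """Posterior-mean adjacency: average of normalized outer products.

    ``samples`` is a sequence of latent vectors (or an M x N array).  The
    estimate is (1/M) sum_k phi_k phi_k' / (phi_k'phi_k) with the diagonal
    zeroed afterwards, so it satisfies the adjacency invariants
    (self-loops are undefined for a connectome).
    """
    Phi = np.atleast_2d(np.asarray(samples, dtype=float))
    if Phi.shape[0] == 0:
        raise InvalidLatentError("need at least one latent sample")
    for row in Phi:
        as_latent(row)
    q = np.einsum("kn,kn->k", Phi, Phi)
    A = np.einsum("ki,kj->ij", Phi / q[:, None], Phi) / Phi.shape[0]
    np.fill_diagonal(A, 0.0)
    return A
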