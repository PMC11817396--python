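"""Network diffusion dynamics on a graph Laplacian.

Within a time window the regional biomarker vector x(t) obeys the linear
system

    dx/dt = -beta L x + s(t),      x(0) = x0,

where beta > 0 is a diffusivity (1/time), L the window's graph Laplacian,
and s(t) a source term describing accumulation/clearance/propagation
mechanisms: zero, linear s(t) = r t, or exponential s(t) = a (e^{xi t} - 1).

Solvers
-------
solve_exact
    Spectral solution e^{-t beta L} x0 of the homogeneous system.
solve_rank1
    Rank-one decoder solution e^{-t beta lambda_bar} (phi'x0 / phi'phi) phi
    using the latent vector's own Rayleigh quotient as the eigenvalue.
solve_linear_source / solve_exponential_source
    Inhomogeneous solutions where the diagonal eigenvalue matrix inside the
    source integral is approximated by the largest eigenvalue lambda_1
    (scalar quadrature; exact when x0 and the source amplitude live in the
    lambda_1 eigenspace).
ode_oracle
    Adaptive Runge-Kutta reference integrator used to cross-check every
    closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .exceptions import CondynError
from .graph import adjacency_from_latent, as_latent, laplacian_from_adjacency, rayleigh_ritz_value

__all__ = [
    "Source",
    "solve_exact",
    "solve_rank1",
    "projected_observable",
    "solve_linear_source",
    "solve_exponential_source",
    "ode_oracle",
]


@dataclass(frozen=True)
class Source:
    """Accumulation/clearance/propagation source term s(t).

    kind is one of {"zero", "linear", "exponential"}; fields unused by the
    kind are ignored.  r and a may be scalars (broadcast) or length-N
    vectors.
    """

    kind: str = "zero"
    r: np.ndarray | float | None = None
    a: np.ndarray | float | None = None
    xi: float = 0.0

    def __post_init__(self):
        if self.kind not in ("zero", "linear", "exponential"):
            raise ValueError(f"unknown source kind {self.kind!r}")

    @classmethod
    def zero(cls) -> "Source":
        return cls(kind="zero")

    @classmethod
    def linear(cls, r) -> "Source":
        return cls(kind="linear", r=r)

    @classmethod
    def exponential(cls, a, xi: float) -> "Source":
        return cls(kind="exponential", a=a, xi=float(xi))

    def __call__(self, t: float, n: int) -> np.ndarray:
        """Evaluate s(t) as a length-n vector."""
        if self.kind == "zero":
            return np.zeros(n)
        if self.kind == "linear":
            return np.broadcast_to(np.asarray(self.r, dtype=float), (n,)) * t
        return np.broadcast_to(np.asarray(self.a, dtype=float), (n,)) * (np.expm1(self.xi * t))


def _check_system(L, x0, beta, t):
    L = np.asarray(L, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    if L.ndim != 2 or L.shape[0] != L.shape[1]:
        raise CondynError(f"Laplacian must be square, got {L.shape}")
    if x0.shape != (L.shape[0],):
        raise CondynError(f"x0 shape {x0.shape} does not match Laplacian {L.shape}")
    if beta <= 0:
        raise CondynError("beta must be positive")
    if t < 0:
        raise CondynError("t must be nonnegative")
    return L, x0


def solve_exact(L, x0, beta: float, t: float) -> np.ndarray:
    """Homogeneous solution e^{-t beta L} x0 via full eigendecomposition.

    Conserves total mass 1'x because the constant vector is in the kernel
    of a symmetric Laplacian.
    """
    L, x0 = _check_system(L, x0, beta, t)
    w, U = np.linalg.eigh(L)
    return U @ (np.exp(-t * beta * w) * (U.T @ x0))


def solve_rank1(phi, x0, beta: float, t: float) -> np.ndarray:
    """Rank-one decoder solution e^{-t beta lambda_bar}(phi'x0/phi'phi) phi."""
    phi = as_latent(phi)
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != phi.shape:
        raise CondynError(f"x0 shape {x0.shape} does not match latent {phi.shape}")
    lam = rayleigh_ritz_value(phi)
    coeff = float(phi @ x0) / float(phi @ phi)
    return np.exp(-t * beta * lam) * coeff * phi


def projected_observable(phi, x0, beta: float, t: float) -> float:
    """Projection x0'x(t) = e^{-t beta lambda_bar}(phi'x0)^2 / phi'phi.

    Computed as x0 . solve_rank1(...) so the identity with the rank-one
    trajectory holds on the same floating-point path.
    """
    x0 = np.asarray(x0, dtype=float)
    return float(x0 @ solve_rank1(phi, x0, beta, t))


def _top_eigenvalue(w) -> float:
    return float(w[-1])


def solve_linear_source(L, x0, beta: float, r, t: float) -> np.ndarray:
    """Solution of dx/dt = -beta L x + r t with the scalar lambda_1 quadrature.

    The source integral e^{-t beta L} int_0^t e^{tau beta L} r tau d tau is
    approximated by replacing the eigenvalue matrix with the largest
    eigenvalue lambda_1, giving x(t) = e^{-t beta L}(x0 + g(t) r) with

        g(t) = t e^{beta t lambda_1}/(beta lambda_1)
               - (e^{beta t lambda_1} - 1)/(beta lambda_1)^2.

    Exact when x0 and r lie in the lambda_1 eigenspace; g(0) = 0 so
    x(0) = x0 always.
    """
    L, x0 = _check_system(L, x0, beta, t)
    w, U = np.linalg.eigh(L)
    lam1 = _top_eigenvalue(w)
    if lam1 <= 1e-12:
        raise CondynError("largest eigenvalue is zero (empty graph); use the zero-source solver")
    r = np.broadcast_to(np.asarray(r, dtype=float), x0.shape)
    bl = beta * lam1
    g = t * np.exp(bl * t) / bl - np.expm1(bl * t) / bl**2
    y = x0 + g * r
    return U @ (np.exp(-t * beta * w) * (U.T @ y))


def solve_exponential_source(L, x0, beta: float, a, xi: float, t: float) -> np.ndarray:
    """Solution of dx/dt = -beta L x + a(e^{xi t}-1), lambda_1 quadrature.

    x(t) = e^{-t beta L}(x0 + h(t) a) with

        h(t) = (e^{t(beta lambda_1 + xi)} - 1)/(beta lambda_1 + xi)
               - (e^{beta t lambda_1} - 1)/(beta lambda_1).
    """
    L, x0 = _check_system(L, x0, beta, t)
    w, U = np.linalg.eigh(L)
    lam1 = _top_eigenvalue(w)
    if lam1 <= 1e-12:
        raise CondynError("largest eigenvalue is zero (empty graph); use the zero-source solver")
    bl = beta * lam1
    if abs(bl + xi) < 1e-12:
        raise CondynError("beta*lambda_1 + xi = 0: removable singularity not implemented")
    a = np.broadcast_to(np.asarray(a, dtype=float), x0.shape)
    h = np.expm1((bl + xi) * t) / (bl + xi) - np.expm1(bl * t) / bl
    y = x0 + h * a
    return U @ (np.exp(-t * beta * w) * (U.T @ y))


def ode_oracle(L, x0, beta: float, t: float, source: Source | None = None,
               rtol: float = 1e-9, atol: float = 1e-9) -> np.ndarray:
    """Adaptive Runge-Kutta reference solution of dx/dt = -beta L x + s(t)."""
    L, x0 = _check_system(L, x0, beta, t)
    if t == 0:
        return x0.copy()
    source = source or Source.zero()
    n = x0.size

    def rhs(tau, x):
        return -beta * (L @ x) + source(tau, n)

    sol = solve_ivp(rhs, (0.0, t), x0, method="DOP853", rtol=rtol, atol=atol, t_eval=[t])
    if not sol.success:
        raise CondynError(f"ODE integration failed: {sol.message}")
    return sol.y[:, -1]


def rank1_laplacian(phi) -> np.ndarray:
    """Convenience: Laplacian of the rank-one adjacency built from phi."""
    return laplacian_from_adjacency(adjacency_from_latent(phi))
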