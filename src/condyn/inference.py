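"""Variational inference of a window's connectome distribution.

The latent connectome of a short time window is parameterized by a positive
vector phi with log phi ~ N(nu, Psi Psi'), Psi lower triangular with a fixed
positive diagonal (so the Cholesky factor is unconstrained in its strict
lower triangle).  Samples are drawn by the reparameterization
log phi = nu + Psi delta, delta ~ N(0, I).

The decoder reconstructs each later observation x_t from the window's first
observation x0 through the rank-one diffusion solution

    f(t) = e^{-t beta lambda_bar(phi)} (phi'x0 / phi'phi) phi,

and the encoder adds a soft least-squares constraint derived from the
uniqueness condition of the initial value problem: the observed projection
y_t = x0'x_t should match (phi'x_t)^2 / phi'phi.  The training objective is
the negative evidence lower bound

    loss = (1/M) sum_k sum_t [ ||x_t - f_k(t)||^2 + w ||y_t - c_k(x_t)||^2 ] / ns^2
           + KL( N(nu, Psi Psi') || N(0, Sigma) ),

minimized over (nu, strict lower triangle of Psi) by Adam with fresh Monte
Carlo samples each epoch.  Gradients are computed analytically (the model
is small and closed-form); they are checked against finite differences in
the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .exceptions import CondynError, DivergenceError, InsufficientDataError
from .graph import as_latent, estimate_adjacency, laplacian_from_adjacency
from .synthetic import BiomarkerSeries

__all__ = [
    "PriorSpec",
    "VariationalPosterior",
    "TrainingConfig",
    "WindowData",
    "WindowFit",
    "sample_latent",
    "constraint_target",
    "constraint_prediction",
    "kl_term",
    "reconstruction_loss",
    "elbo",
    "fit_window",
    "split_windows",
    "infer_dynamics",
]


# ---------------------------------------------------------------------------
# types


@dataclass
class PriorSpec:
    """Gaussian prior N(0, sigma) on log phi."""

    sigma: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.sigma, dtype=float)
        if s.ndim != 2 or s.shape[0] != s.shape[1]:
            raise CondynError("prior covariance must be square")
        if np.abs(s - s.T).max() > 1e-10 * max(1.0, np.abs(s).max()):
            raise CondynError("prior covariance must be symmetric")
        self.sigma = s

    @classmethod
    def identity(cls, n: int) -> "PriorSpec":
        return cls(np.eye(n))

    @classmethod
    def from_cohort(cls, cohort: list[BiomarkerSeries], ridge: float = 1e-3) -> "PriorSpec":
        """Empirical covariance of log baseline biomarkers across subjects, ridged to PD."""
        base = np.stack([s.values[0] for s in cohort])
        if np.any(base <= 0):
            raise CondynError("baseline biomarkers must be positive to take logs")
        cov = np.cov(np.log(base), rowvar=False)
        cov = np.atleast_2d(cov)
        return cls(cov + ridge * np.eye(cov.shape[0]))


@dataclass
class VariationalPosterior:
    """Posterior N(nu, Psi Psi') on log phi; Psi = strict_lower + c I."""

    nu: np.ndarray
    psi_offdiag: np.ndarray
    diag_const: float = 0.1

    def __post_init__(self):
        self.nu = np.asarray(self.nu, dtype=float)
        self.psi_offdiag = np.asarray(self.psi_offdiag, dtype=float)
        n = self.nu.size
        if self.psi_offdiag.shape != (n, n):
            raise CondynError("psi_offdiag must be N x N")
        if self.diag_const <= 0:
            raise CondynError("diag_const must be positive")
        # keep only the strict lower triangle
        self.psi_offdiag = np.tril(self.psi_offdiag, k=-1)

    @property
    def n(self) -> int:
        return self.nu.size

    def cholesky(self) -> np.ndarray:
        return self.psi_offdiag + self.diag_const * np.eye(self.n)

    def covariance(self) -> np.ndarray:
        psi = self.cholesky()
        return psi @ psi.T

    @classmethod
    def initialize(cls, mean_biomarker: np.ndarray, diag_const: float = 0.1) -> "VariationalPosterior":
        """nu = log of the unit-normalized mean biomarker vector; Psi off-diagonal zero."""
        m = np.asarray(mean_biomarker, dtype=float)
        m = np.clip(m, 1e-8, None)
        m = m / np.linalg.norm(m)
        return cls(np.log(m), np.zeros((m.size, m.size)), diag_const)


@dataclass(frozen=True)
class TrainingConfig:
    """Hyper-parameters of a window fit."""

    epochs: int = 300
    samples_per_epoch: int = 100
    learning_rate: float = 0.01
    beta: float = 1.0                 # diffusivity used by the decoder
    diag_const: float = 0.1           # fixed Cholesky diagonal of Psi
    constraint_enabled: bool = True
    constraint_weight: float = 1.0
    noise_scale: float = 1.0          # assumed observation sd; scales both residuals
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 0 or self.samples_per_epoch < 1:
            raise CondynError("epochs must be >= 0 and samples_per_epoch >= 1")
        for name in ("learning_rate", "beta", "diag_const", "noise_scale"):
            if getattr(self, name) <= 0:
                raise CondynError(f"{name} must be positive")
        if self.constraint_weight < 0:
            raise CondynError("constraint_weight must be nonnegative")


@dataclass
class WindowData:
    """One subject's observations inside a window: x0 plus later (t, x_t) pairs."""

    x0: np.ndarray
    pairs: list[tuple[float, np.ndarray]]
    subject_id: str = ""

    def __post_init__(self):
        self.x0 = np.asarray(self.x0, dtype=float)
        self.pairs = [(float(t), np.asarray(x, dtype=float)) for t, x in self.pairs]
        if not self.pairs:
            raise CondynError("window needs at least one (t, x_t) pair")
        ts = [t for t, _ in self.pairs]
        if any(t <= 0 for t in ts) or any(b <= a for a, b in zip(ts, ts[1:])):
            raise CondynError("pair times must be strictly increasing and > 0")
        for _, x in self.pairs:
            if x.shape != self.x0.shape:
                raise CondynError("all observations must share the region dimension")


@dataclass
class WindowFit:
    """Result of fitting one window: posterior plus derived point estimates."""

    posterior: VariationalPosterior
    adjacency: np.ndarray
    laplacian: np.ndarray
    trace: pd.DataFrame


# ---------------------------------------------------------------------------
# elementary operations


def sample_latent(q: VariationalPosterior, delta) -> np.ndarray:
    """Reparameterized sample phi = exp(nu + Psi delta); delta may be (N,) or (M, N)."""
    delta = np.asarray(delta, dtype=float)
    if not np.all(np.isfinite(delta)):
        raise CondynError("delta contains non-finite entries")
    psi = q.cholesky()
    if delta.ndim == 1:
        return np.exp(q.nu + psi @ delta)
    return np.exp(q.nu[None, :] + delta @ psi.T)


def constraint_target(x0, xt) -> float:
    """Observed projection y_t = x0'x_t."""
    x0 = np.asarray(x0, dtype=float)
    xt = np.asarray(xt, dtype=float)
    if x0.shape != xt.shape:
        raise CondynError("x0 and x_t must have the same length")
    return float(x0 @ xt)


def constraint_prediction(phi, xt) -> float:
    """Model-side projection (phi'x_t)^2 / phi'phi (exponential-free)."""
    phi = as_latent(phi)
    xt = np.asarray(xt, dtype=float)
    if xt.shape != phi.shape:
        raise CondynError("phi and x_t must have the same length")
    return float(phi @ xt) ** 2 / float(phi @ phi)


def kl_term(q: VariationalPosterior, prior: PriorSpec) -> float:
    """Closed-form KL( N(nu, Psi Psi') || N(0, Sigma) ).

    Full Gaussian KL including the log-determinant constants; with the
    fixed Cholesky diagonal the log det of the posterior covariance is a
    constant 2 N log c, so gradients agree with the constant-free surrogate.
    """
    n = q.n
    if prior.sigma.shape != (n, n):
        raise CondynError("prior dimension mismatch")
    try:
        cf = cho_factor(prior.sigma, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - scipy raises LinAlgError
        raise CondynError("prior covariance is not positive definite") from exc
    psi = q.cholesky()
    sinv_psi = cho_solve(cf, psi)
    trace = float(np.sum(psi * sinv_psi))
    quad = float(q.nu @ cho_solve(cf, q.nu))
    logdet_sigma = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    # log det(Psi Psi') = 2 sum log diag(Psi); the diagonal is the constant c
    logdet_post = 2.0 * n * math.log(q.diag_const)
    return 0.5 * (trace + quad + logdet_sigma - logdet_post - n)


# ---------------------------------------------------------------------------
# loss and analytic gradients


def _stack_pairs(windows: list[WindowData]):
    """Flatten pooled windows into (X0, XT, TT) arrays, one row per pair."""
    X0, XT, TT = [], [], []
    for w in windows:
        for t, xt in w.pairs:
            X0.append(w.x0)
            XT.append(xt)
            TT.append(t)
    return np.asarray(X0), np.asarray(XT), np.asarray(TT)


def _loss_and_grad_phi(Phi, X0, XT, TT, beta, w_con, ns2, want_grad=True):
    """Monte-Carlo reconstruction loss and its gradient w.r.t. each phi sample.

    Phi: (M, N) positive samples; X0, XT: (P, N); TT: (P,).
    Returns (recon_loss, grad (M, N) or None).  The loss is averaged over
    samples and summed over pairs.
    """
    M, N = Phi.shape
    q = np.einsum("mn,mn->m", Phi, Phi)                    # (M,)
    p1 = Phi.sum(axis=1)
    p3 = (Phi**3).sum(axis=1)
    num = p1 * p3 - q * q
    lam = np.maximum(num / q, 0.0)                         # (M,) Rayleigh value

    S = Phi @ X0.T                                         # (M, P) phi'x0
    U = Phi @ XT.T                                         # (M, P) phi'xt
    E = np.exp(-beta * TT[None, :] * lam[:, None])         # (M, P)
    C = S / q[:, None]                                     # (M, P)
    F = (E * C)[:, :, None] * Phi[:, None, :]              # (M, P, N)
    R = XT[None, :, :] - F                                 # residuals
    regression = float(np.einsum("mpn,mpn->", R, R)) / ns2 / M

    Y = np.einsum("pn,pn->p", X0, XT)                      # (P,) observed projections
    pred = U * U / q[:, None]
    res = Y[None, :] - pred                                # (M, P)
    loss = regression + w_con * float(np.einsum("mp,mp->", res, res)) / ns2 / M

    if not want_grad:
        return loss, None, regression

    # d lambda / d phi
    dlam = (p3[:, None] + 3.0 * Phi**2 * p1[:, None] - 4.0 * q[:, None] * Phi) / q[:, None] \
        - num[:, None] * 2.0 * Phi / (q * q)[:, None]
    dlam[num < 0.0, :] = 0.0  # clamped branch of max(lambda, 0)

    D = np.einsum("mpn,mn->mp", R, Phi)                    # R . phi per pair
    g = dlam * ((-beta * TT[None, :]) * E * C * D).sum(axis=1)[:, None]
    W2 = E * D
    g += (W2 @ X0) / q[:, None] - 2.0 * (W2 * S).sum(axis=1)[:, None] * Phi / (q * q)[:, None]
    g += np.einsum("mp,mpn->mn", E * C, R)
    g *= -2.0 / ns2

    if w_con > 0:
        gc = ((res * U) @ XT) / q[:, None] - (res * U * U).sum(axis=1)[:, None] * Phi / (q * q)[:, None]
        g += (-4.0 * w_con / ns2) * gc

    g /= M
    return loss, g, regression


def reconstruction_loss(window: WindowData, phi_samples, cfg: TrainingConfig) -> float:
    """Decoder + soft-constraint loss for one window, averaged over samples.

    (1/M) sum_k sum_t [ ||x_t - f_k(t)||^2 + w ||y_t - (phi_k'x_t)^2/phi_k'phi_k||^2 ] / ns^2
    with w = constraint_weight (0 when the constraint is disabled).
    """
    Phi = np.atleast_2d(np.asarray(phi_samples, dtype=float))
    if Phi.shape[0] == 0:
        raise CondynError("need at least one latent sample")
    X0, XT, TT = _stack_pairs([window])
    w_con = cfg.constraint_weight if cfg.constraint_enabled else 0.0
    loss, _, _ = _loss_and_grad_phi(Phi, X0, XT, TT, cfg.beta, w_con, cfg.noise_scale**2,
                                    want_grad=False)
    return loss


def elbo(window: WindowData, q: VariationalPosterior, prior: PriorSpec,
         cfg: TrainingConfig, delta_batch) -> float:
    """Evidence lower bound estimate -reconstruction_loss - KL for given deltas."""
    Phi = sample_latent(q, np.atleast_2d(np.asarray(delta_batch, dtype=float)))
    X0, XT, TT = _stack_pairs([window])
    w_con = cfg.constraint_weight if cfg.constraint_enabled else 0.0
    loss, _, _ = _loss_and_grad_phi(Phi, X0, XT, TT, cfg.beta, w_con, cfg.noise_scale**2,
                                    want_grad=False)
    return -loss - kl_term(q, prior)


# ---------------------------------------------------------------------------
# training


class _Adam:
    """Minimal adaptive-moment optimizer over a list of arrays."""

    def __init__(self, shapes, lr, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, grads):
        self.t += 1
        out = []
        for i, g in enumerate(grads):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            out.append(self.lr * mhat / (np.sqrt(vhat) + self.eps))
        return out


def fit_window(windows: list[WindowData] | WindowData, prior: PriorSpec,
               cfg: TrainingConfig) -> tuple[VariationalPosterior, pd.DataFrame]:
    """Maximize the ELBO pooled over subjects' windows; deterministic given seed.

    Returns the fitted posterior and a per-epoch trace with columns
    (epoch, reconstruction, kl).  The pooled objective is the sum of the
    per-window reconstruction losses plus a single KL term (the posterior
    is shared across the pooled windows).
    """
    if isinstance(windows, WindowData):
        windows = [windows]
    if not windows:
        raise CondynError("need at least one window")
    n = windows[0].x0.size
    if any(w.x0.size != n for w in windows):
        raise CondynError("all windows must share the region dimension")

    X0, XT, TT = _stack_pairs(windows)
    mean_vec = np.concatenate([X0, XT]).mean(axis=0)
    q = VariationalPosterior.initialize(mean_vec, cfg.diag_const)
    if prior.sigma.shape != (n, n):
        raise CondynError("prior dimension mismatch")

    cf = cho_factor(prior.sigma, lower=True)
    w_con = cfg.constraint_weight if cfg.constraint_enabled else 0.0
    ns2 = cfg.noise_scale**2
    lower_mask = np.tril(np.ones((n, n)), k=-1)

    rng = np.random.default_rng(cfg.seed)
    opt = _Adam([(n,), (n, n)], cfg.learning_rate)
    rows = []
    nu = q.nu.copy()
    psi_off = q.psi_offdiag.copy()
    for epoch in range(cfg.epochs):
        psi = psi_off + cfg.diag_const * np.eye(n)
        delta = rng.standard_normal((cfg.samples_per_epoch, n))
        Phi = np.exp(nu[None, :] + delta @ psi.T)
        recon, g_phi, regression = _loss_and_grad_phi(Phi, X0, XT, TT, cfg.beta, w_con, ns2)
        q_now = VariationalPosterior(nu.copy(), psi_off.copy(), cfg.diag_const)
        kl = kl_term(q_now, prior)
        if not np.isfinite(recon) or not np.isfinite(kl):
            raise DivergenceError(epoch)
        rows.append((epoch, recon, regression, kl))
        gp = Phi * g_phi                                     # chain through exp
        g_nu = gp.sum(axis=0) + cho_solve(cf, nu)
        g_psi = (gp.T @ delta) * lower_mask + cho_solve(cf, psi) * lower_mask
        step_nu, step_psi = opt.step([g_nu, g_psi])
        nu -= step_nu
        psi_off -= step_psi
    q = VariationalPosterior(nu, psi_off, cfg.diag_const)
    trace = pd.DataFrame(rows, columns=["epoch", "reconstruction", "regression", "kl"])
    return q, trace


def split_windows(series: BiomarkerSeries) -> tuple[WindowData, WindowData]:
    """Divide one subject's observations evenly into early and late windows.

    Observations are sorted by time; the first ceil(T/2) form the early
    window, the rest the late window.  Within each window, the earliest
    observation becomes x0 and times are re-zeroed relative to it.
    """
    order = np.argsort(series.times)
    times = series.times[order]
    values = series.values[order]
    T = times.size
    if T < 4:
        raise InsufficientDataError(f"need >= 4 observations to split, got {T}")
    n_early = math.ceil(T / 2)

    def build(ts, vs):
        t0 = ts[0]
        return WindowData(vs[0], [(t - t0, v) for t, v in zip(ts[1:], vs[1:])],
                          subject_id=series.subject_id)

    return build(times[:n_early], values[:n_early]), build(times[n_early:], values[n_early:])


def infer_dynamics(cohort: list[BiomarkerSeries], prior: PriorSpec | None,
                   cfg: TrainingConfig, n_windows: int = 2,
                   pool_subjects: bool = True) -> list[WindowFit]:
    """Fit the sequence of window posteriors for a cohort.

    Each subject's series is split into early/late windows; windows are
    pooled by position across subjects and each pooled set is fitted with
    its own seed stream.  Returns one WindowFit (posterior, estimated
    adjacency via M posterior samples, Laplacian, loss trace) per window.
    """
    if not cohort:
        raise CondynError("cohort is empty")
    if n_windows != 2:
        raise CondynError("only the early/late two-window design is implemented")
    n = cohort[0].n_regions
    if any(s.n_regions != n for s in cohort):
        raise CondynError("cohort regions are inconsistent")
    if prior is None:
        prior = PriorSpec.identity(n)

    split = [split_windows(s) for s in cohort]
    pooled = [[pair[w] for pair in split] for w in range(2)]

    seeds = np.random.SeedSequence(cfg.seed).generate_state(2 * len(pooled))
    fits = []
    for w, windows in enumerate(pooled):
        wcfg = replace(cfg, seed=int(seeds[2 * w] % (2**31)))
        if not pool_subjects:
            raise CondynError("per-subject fitting not implemented; pool_subjects must be True")
        post, trace = fit_window(windows, prior, wcfg)
        rng = np.random.default_rng(int(seeds[2 * w + 1] % (2**31)))
        delta = rng.standard_normal((cfg.samples_per_epoch, n))
        Phi = sample_latent(post, delta)
        A = estimate_adjacency(Phi)
        L = laplacian_from_adjacency(A)
        fits.append(WindowFit(post, A, L, trace))
    return fits
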