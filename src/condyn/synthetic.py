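"""Synthetic longitudinal biomarker cohorts with known ground truth.

Two dataset families are generated, emulating amyloid (4-region) and tau
(82-region) PET summary data:

* amyloid-like cohorts: flat noisy trajectories for healthy-young subjects
  (stable physiological homeostasis) and noisy logistic curves for
  pathological subjects (sigmoidal biomarker accumulation);
* a tau "decoupling" cohort: trajectories are solutions of the network
  diffusion system under an adjacency that loses weight linearly in time
  on a chosen set of rows/columns, A(t) = A0 - rate*t on those cells
  (clipped at zero), plus additive Gaussian observation noise.  The
  perturbed index set and rate are returned as ground truth so that
  decoupling detection can be scored.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .diffusion import solve_exact
from .graph import laplacian_from_adjacency

__all__ = [
    "BiomarkerSeries",
    "DecouplingGroundTruth",
    "make_healthy_av45",
    "make_pathological_av45",
    "make_base_adjacency",
    "make_decoupling_dataset",
    "perturbed_adjacency",
    "perturbed_cell_mask",
    "default_region_labels",
]

STAGES = ("H", "MCI", "AD")

#: default logistic curve b + c/(1+exp(-k(t-t0))) on the unit interval
DEFAULT_LOGISTIC = {"b": 1.0, "c": 0.5, "k": 6.0, "t0": 0.5}

#: staggered per-region onsets for the default 4-region pathological cohort;
#: regions become abnormal in sequence, so the regional pattern rotates early
#: and settles once every region saturates
DEFAULT_ONSETS = (0.1, 0.2, 0.3, 0.4)

AV45_REGIONS = ["hippocampus", "ventricles", "entorhinal", "others"]


def default_region_labels(n: int) -> list[str]:
    if n == 4:
        return list(AV45_REGIONS)
    return [f"R{i:02d}" for i in range(n)]


@dataclass
class BiomarkerSeries:
    """One subject's longitudinal regional biomarker observations."""

    subject_id: str
    stage: str
    times: np.ndarray          # (T,), strictly increasing
    values: np.ndarray         # (T, N)
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {self.stage!r}")
        if self.times.ndim != 1 or self.times.size < 2:
            raise ValueError("need at least 2 timepoints")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.values.ndim != 2 or self.values.shape[0] != self.times.size:
            raise ValueError(f"values shape {self.values.shape} inconsistent with times")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")
        if not self.region_labels:
            self.region_labels = default_region_labels(self.values.shape[1])
        elif len(self.region_labels) != self.values.shape[1]:
            raise ValueError("region_labels length does not match values")

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass
class DecouplingGroundTruth:
    """Which rows/columns of the base adjacency decay, and how fast."""

    perturbed_indices: frozenset[int]
    rate: float
    A0: np.ndarray

    def __post_init__(self):
        self.perturbed_indices = frozenset(int(i) for i in self.perturbed_indices)
        n = self.A0.shape[0]
        if any(i < 0 or i >= n for i in self.perturbed_indices):
            raise ValueError("perturbed index out of range")
        if self.rate <= 0:
            raise ValueError("rate must be positive")


def make_healthy_av45(n_subjects: int, times, baseline=None, noise_sd: float = 0.05,
                      seed: int = 0) -> list[BiomarkerSeries]:
    """Flat noisy curves: baseline + iid Gaussian noise per observation."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    times = np.asarray(times, dtype=float)
    baseline = np.asarray(baseline if baseline is not None else [1.0, 1.0, 1.0, 1.0], dtype=float)
    rng = np.random.default_rng(seed)
    labels = default_region_labels(baseline.size)
    out = []
    for s in range(n_subjects):
        vals = baseline[None, :] + rng.normal(0.0, noise_sd, size=(times.size, baseline.size))
        out.append(BiomarkerSeries(f"H{s:03d}", "H", times, vals, list(labels)))
    return out


def make_pathological_av45(n_subjects: int, times, logistic_params=None,
                           noise_sd: float = 0.05, stage: str = "AD",
                           seed: int = 0) -> list[BiomarkerSeries]:
    """Noisy logistic accumulation curves b + c/(1+e^{-k(t-t0)}) per region.

    ``logistic_params`` is a list of one dict per region with keys
    {b, c, k, t0}; a single dict is broadcast to 4 regions.  Noiseless
    curves are monotone nondecreasing (c >= 0, k > 0 enforced).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    times = np.asarray(times, dtype=float)
    if logistic_params is None:
        logistic_params = [dict(DEFAULT_LOGISTIC, t0=t0) for t0 in DEFAULT_ONSETS]
    elif isinstance(logistic_params, dict):
        logistic_params = [dict(logistic_params) for _ in range(4)]
    for p in logistic_params:
        if p["c"] < 0 or p["k"] <= 0:
            raise ValueError("logistic params require c >= 0 and k > 0")
    n_regions = len(logistic_params)
    curves = np.stack(
        [p["b"] + p["c"] / (1.0 + np.exp(-p["k"] * (times - p["t0"]))) for p in logistic_params],
        axis=1,
    )  # (T, N)
    rng = np.random.default_rng(seed)
    labels = default_region_labels(n_regions)
    out = []
    for s in range(n_subjects):
        vals = curves + rng.normal(0.0, noise_sd, size=curves.shape)
        out.append(BiomarkerSeries(f"{stage}{s:03d}", stage, times, vals, list(labels)))
    return out


def make_base_adjacency(n_regions: int = 82, density: float = 1.0, seed: int = 0,
                        sigma: float = 0.5) -> np.ndarray:
    """Random base connectome: normalized outer product of a positive vector.

    u ~ log-normal(0, sigma^2); A0 = u u' / (u'u) with zero diagonal,
    optionally sparsified to the requested edge density (symmetric pairs
    dropped at random).
    """
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    u = rng.lognormal(0.0, sigma, n_regions)
    A = np.outer(u, u) / float(u @ u)
    np.fill_diagonal(A, 0.0)
    if density < 1.0:
        iu, ju = np.triu_indices(n_regions, k=1)
        keep = rng.random(iu.size) < density
        A[iu[~keep], ju[~keep]] = 0.0
        A[ju[~keep], iu[~keep]] = 0.0
    return A


def perturbed_adjacency(A0: np.ndarray, indices, rate: float, t: float) -> np.ndarray:
    """A(t): subtract rate*t from every cell in the given rows/columns, clip at 0."""
    A = np.array(A0, dtype=float, copy=True)
    idx = sorted(int(i) for i in indices)
    if idx:
        A[idx, :] -= rate * t
        A[:, idx] -= rate * t
        # cells where a perturbed row meets a perturbed column were hit twice
        A[np.ix_(idx, idx)] += rate * t
        np.clip(A, 0.0, None, out=A)
    np.fill_diagonal(A, 0.0)
    return A


def perturbed_cell_mask(n: int, indices) -> np.ndarray:
    """Boolean mask of off-diagonal cells lying in the perturbed rows/columns."""
    idx = [int(i) for i in indices]
    mask = np.zeros((n, n), dtype=bool)
    mask[idx, :] = True
    mask[:, idx] = True
    np.fill_diagonal(mask, False)
    return mask


def make_decoupling_dataset(A0: np.ndarray | None = None,
                            perturbed_indices=(0, 1, 13),
                            rate: float = 0.02,
                            beta: float = 1.0,
                            times=(0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0),
                            n_subjects: int = 20,
                            noise_sd: float = 0.02,
                            x0_jitter: float = 0.2,
                            n_regions: int = 82,
                            seed: int = 0) -> tuple[list[BiomarkerSeries], DecouplingGroundTruth]:
    """Tau-like cohort from diffusion under a decaying adjacency.

    Each subject starts from x0 = 1 + Uniform(0, x0_jitter) per region and is
    observed at the given times in [0, 1]; the observation at time t is the
    exact diffusion solution under L(A(t)) plus Gaussian noise.  The default
    perturbation removes 0.02 per unit time from rows/columns {0, 1, 13}
    (0-based), mirroring a three-region atrophy scenario.
    """
    rng = np.random.default_rng(seed)
    if A0 is None:
        A0 = make_base_adjacency(n_regions, seed=rng.integers(2**31))
    n = A0.shape[0]
    times = np.asarray(times, dtype=float)
    if times.min() < 0 or times.max() > 1:
        raise ValueError("times must lie in [0, 1]")
    truth = DecouplingGroundTruth(frozenset(perturbed_indices), rate, A0)
    idx = sorted(truth.perturbed_indices)
    if idx:
        mask = perturbed_cell_mask(n, idx)
        if rate * times.max() > A0[mask].min():
            warnings.warn("perturbation exceeds smallest perturbed cell; clipping at zero is active",
                          stacklevel=2)
    laplacians = {float(t): laplacian_from_adjacency(perturbed_adjacency(A0, idx, rate, t))
                  for t in times}
    labels = default_region_labels(n)
    out = []
    for s in range(n_subjects):
        x0 = 1.0 + rng.uniform(0.0, x0_jitter, n)
        vals = np.empty((times.size, n))
        for j, t in enumerate(times):
            x = solve_exact(laplacians[float(t)], x0, beta, float(t))
            vals[j] = x + rng.normal(0.0, noise_sd, n)
        out.append(BiomarkerSeries(f"S{s:03d}", "AD", times, vals, list(labels)))
    return out, truth
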