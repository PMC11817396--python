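"""File formats: long biomarker CSV, labeled TSV matrices, posterior JSON, YAML config.

Biomarker cohorts travel as long-format CSV with columns
(subject_id, stage, time, region, value); matrices as TSV with a header
row and a first column of region labels; posteriors and reports as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import CondynError, InvalidAdjacencyError
from .inference import TrainingConfig, VariationalPosterior
from .synthetic import STAGES, BiomarkerSeries

__all__ = [
    "read_biomarkers",
    "write_biomarkers",
    "read_matrix",
    "write_matrix",
    "write_posterior",
    "read_posterior",
    "load_config",
    "RunConfig",
]

LONG_COLUMNS = ["subject_id", "stage", "time", "region", "value"]


def write_biomarkers(path, cohort: list[BiomarkerSeries]) -> None:
    """Serialize a cohort to long-format CSV."""
    rows = []
    for s in cohort:
        for ti, t in enumerate(s.times):
            for rj, region in enumerate(s.region_labels):
                rows.append((s.subject_id, s.stage, float(t), region, float(s.values[ti, rj])))
    pd.DataFrame(rows, columns=LONG_COLUMNS).to_csv(path, index=False)


def read_biomarkers(path) -> list[BiomarkerSeries]:
    """Parse and validate a long-format biomarker CSV into per-subject series."""
    df = pd.read_csv(path)
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise CondynError(f"missing columns {missing}; expected header {LONG_COLUMNS}")
    bad_stage = ~df["stage"].isin(STAGES)
    if bad_stage.any():
        row = int(df.index[bad_stage][0]) + 2  # header + 1-based
        raise CondynError(
            f"unknown stage {df.loc[df.index[bad_stage][0], 'stage']!r} at row {row}; "
            f"allowed stages are {set(STAGES)}"
        )
    dup = df.duplicated(subset=["subject_id", "time", "region"])
    if dup.any():
        row = int(df.index[dup][0]) + 2
        raise CondynError(f"duplicate (subject, time, region) at row {row}")

    regions = list(dict.fromkeys(df["region"]))
    out = []
    for sid, g in df.groupby("subject_id", sort=True):
        if set(g["region"]) != set(regions):
            raise CondynError(f"subject {sid} does not cover all regions {regions}")
        pivot = g.pivot(index="time", columns="region", values="value")
        if pivot.isna().any().any():
            t = pivot.index[pivot.isna().any(axis=1)][0]
            raise CondynError(f"subject {sid} is missing a region value at time {t}")
        pivot = pivot.sort_index()[regions]
        stage = g["stage"].iloc[0]
        out.append(BiomarkerSeries(str(sid), str(stage), pivot.index.to_numpy(),
                                   pivot.to_numpy(), list(regions)))
    return out


def write_matrix(path, values, labels) -> None:
    """Labeled square matrix as TSV (header row, first column of labels)."""
    values = np.asarray(values, dtype=float)
    pd.DataFrame(values, index=list(labels), columns=list(labels)).to_csv(path, sep="\t")


def read_matrix(path, check_symmetric: bool = True) -> tuple[np.ndarray, list[str]]:
    """Read a labeled TSV matrix; reject asymmetric payloads when requested."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise CondynError(f"matrix in {path} is not square: {df.shape}")
    values = df.to_numpy(dtype=float)
    if check_symmetric and np.abs(values - values.T).max() > 1e-8 * max(1.0, np.abs(values).max()):
        raise InvalidAdjacencyError(f"matrix in {path} is not symmetric within 1e-8")
    return values, [str(c) for c in df.columns]


def write_posterior(path, q: VariationalPosterior, regions, beta: float, seed: int) -> None:
    """Posterior as JSON: regions, nu, row-major lower-triangle of Psi, constants."""
    n = q.n
    iu, ju = np.tril_indices(n, k=-1)
    payload = {
        "regions": list(regions),
        "nu": q.nu.tolist(),
        "psi_offdiag": q.psi_offdiag[iu, ju].tolist(),
        "diag_const": q.diag_const,
        "beta": beta,
        "seed": seed,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_posterior(path) -> tuple[VariationalPosterior, list[str], float, int]:
    payload = json.loads(Path(path).read_text())
    regions = payload["regions"]
    n = len(regions)
    psi = np.zeros((n, n))
    iu, ju = np.tril_indices(n, k=-1)
    psi[iu, ju] = payload["psi_offdiag"]
    q = VariationalPosterior(np.asarray(payload["nu"], dtype=float), psi,
                             float(payload["diag_const"]))
    return q, regions, float(payload["beta"]), int(payload["seed"])


@dataclasses.dataclass
class RunConfig:
    """YAML-loadable run configuration mirroring the CLI flags."""

    family: str = "tau-decoupling"
    n_regions: int = 82
    n_subjects: int = 20
    seed: int = 0
    k: int = 10
    top_eigenvalues: int = 3
    output_dir: str = "."
    training: TrainingConfig = dataclasses.field(default_factory=TrainingConfig)


def load_config(path) -> RunConfig:
    """Load a YAML config, rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise CondynError("config must be a YAML mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise CondynError(f"unknown config keys: {sorted(unknown)}")
    training = raw.pop("training", None)
    cfg = RunConfig(**raw)
    if training is not None:
        tknown = {f.name for f in dataclasses.fields(TrainingConfig)}
        tunknown = set(training) - tknown
        if tunknown:
            raise CondynError(f"unknown training config keys: {sorted(tunknown)}")
        cfg.training = TrainingConfig(**training)
    return cfg
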