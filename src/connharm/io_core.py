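"""Readers, writers and validation for connectomes, manifests and metric tables.

File dialects
-------------
* Connectomes: headerless delimited text (TSV by default), row ``i`` = node
  ``i``; node order is fixed by the AAL-90 parcellation list shipped as a
  package resource.  Values are serialized at 8 significant digits.
* Cohort manifests: CSV with header ``subject_id,site,age,sex,group`` and an
  optional ``matrix_path`` column.
* Global-metric tables: long-format CSV with one row per
  (subject, stage, metric).
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import importlib.resources
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "WeightedConnectome",
    "ConnectomeError",
    "ManifestError",
    "METRICS",
    "STAGES",
    "SEX_LEVELS",
    "GROUP_LEVELS",
    "MATRIX_SIGNIFICANT_DIGITS",
    "DEFAULT_EDGE_THRESHOLD",
    "aal90_labels",
    "binary_topology",
    "validate_weights",
    "read_connectome",
    "write_connectome",
    "read_manifest",
    "write_manifest",
    "read_metric_table",
    "write_metric_table",
    "load_config",
    "RunRecord",
    "get_logger",
]

#: Names of the five global network metrics, in reporting order.
METRICS = (
    "global_efficiency",
    "clustering_coefficient",
    "modularity",
    "small_worldness",
    "density",
)

#: Harmonization stages a metric table row may be tagged with.
STAGES = ("unharmonized", "matrix_harmonized", "parameter_harmonized")

SEX_LEVELS = ("M", "F")
GROUP_LEVELS = ("mTBI", "OI")

MATRIX_SIGNIFICANT_DIGITS = 8
#: Absolute FA threshold applied when raw connectomes were built: nonzero
#: unharmonized edge weights are never below this value.
DEFAULT_EDGE_THRESHOLD = 0.10

_SYMMETRY_TOL = 1e-8

_REQUIRED_MANIFEST_COLUMNS = ("subject_id", "site", "age", "sex", "group")


class ConnectomeError(ValueError):
    """Invalid connectome matrix (shape, symmetry, sign or diagonal)."""


class ManifestError(ValueError):
    """Invalid cohort manifest (duplicates, vocabulary, bounds)."""


@dataclasses.dataclass
class WeightedConnectome:
    """One subject's symmetric, non-negative edge-weight matrix.

    ``weights[i, j]`` is the mean-FA weight of the edge between nodes ``i``
    and ``j`` (0 where no connection exists); the diagonal is zero.
    """

    subject_id: str
    weights: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def topology(self) -> np.ndarray:
        """Binary topology ``B`` (1 where an edge is present)."""
        return binary_topology(self.weights)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))


def binary_topology(weights: np.ndarray) -> np.ndarray:
    return (np.asarray(weights) > 0).astype(np.int8)


def aal90_labels() -> list[str]:
    """Node labels of the AAL-90 parcellation, in matrix row order."""
    text = (
        importlib.resources.files("connharm.data")
        .joinpath("aal90_labels.txt")
        .read_text()
    )
    labels = [line.strip() for line in text.splitlines() if line.strip()]
    if len(labels) != 90:  # pragma: no cover - packaging guard
        raise RuntimeError("AAL-90 resource is corrupt")
    return labels


def validate_weights(
    weights: np.ndarray,
    *,
    threshold: float | None = None,
    n_nodes: int | None = None,
) -> np.ndarray:
    """Validate a weight matrix against the connectome invariants.

    Parameters
    ----------
    threshold:
        If given, additionally require every nonzero weight to be at least
        this value (the absolute FA threshold of unharmonized input).
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ConnectomeError(f"weight matrix must be square, got {w.shape}")
    if n_nodes is not None and w.shape[0] != n_nodes:
        raise ConnectomeError(
            f"expected {n_nodes}x{n_nodes} matrix, got {w.shape[0]}x{w.shape[1]}"
        )
    if not np.all(np.isfinite(w)):
        raise ConnectomeError("non-finite weight")
    asym = np.max(np.abs(w - w.T)) if w.size else 0.0
    if asym > _SYMMETRY_TOL:
        raise ConnectomeError(f"asymmetry {asym:.3g} exceeds tolerance {_SYMMETRY_TOL}")
    w = (w + w.T) / 2.0
    if np.any(np.diag(w) != 0):
        raise ConnectomeError("nonzero diagonal")
    if np.any(w < 0):
        raise ConnectomeError("negative weight")
    if threshold is not None:
        nz = w[w > 0]
        if nz.size and nz.min() < threshold - 1e-12:
            raise ConnectomeError(
                f"nonzero weight {nz.min():.4g} below threshold {threshold}"
            )
    return w


def read_connectome(
    path: str | Path,
    n_nodes: int = 90,
    *,
    subject_id: str | None = None,
    delimiter: str | None = None,
    threshold: float | None = None,
) -> WeightedConnectome:
    """Read a delimited ``n_nodes`` x ``n_nodes`` matrix file.

    Whitespace/tab and comma delimiters are both accepted.  The matrix is
    symmetrized by averaging only if the maximum asymmetry is within 1e-8;
    larger asymmetries are an error.
    """
    path = Path(path)
    try:
        if delimiter is None:
            head = path.open().readline()
            delimiter = "," if ("," in head) else None
        w = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    except ValueError as exc:
        raise ConnectomeError(f"{path}: non-numeric cell ({exc})") from exc
    if w.shape != (n_nodes, n_nodes):
        raise ConnectomeError(
            f"{path}: dimension mismatch, expected {n_nodes}x{n_nodes}, got {w.shape}"
        )
    w = validate_weights(w, threshold=threshold)
    return WeightedConnectome(subject_id or path.stem, w)


def write_connectome(
    path: str | Path, connectome: WeightedConnectome | np.ndarray
) -> Path:
    """Write a connectome as headerless TSV at 8 significant digits."""
    w = connectome.weights if isinstance(connectome, WeightedConnectome) else connectome
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, np.asarray(w), fmt=f"%.{MATRIX_SIGNIFICANT_DIGITS}g", delimiter="\t")
    return path


def read_manifest(
    path: str | Path,
    *,
    age_bounds: tuple[float, float] = (0.0, 120.0),
    min_sites: int = 2,
    min_per_site: int = 3,
    n_nodes: int | None = None,
) -> pd.DataFrame:
    """Read and validate a cohort manifest CSV.

    Returns the manifest sorted by ``subject_id`` (deterministic row order).
    When ``n_nodes`` is given and the manifest carries ``matrix_path``
    entries, each referenced matrix is checked to parse at that size.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str, "site": str})
    return validate_manifest(
        df,
        age_bounds=age_bounds,
        min_sites=min_sites,
        min_per_site=min_per_site,
        n_nodes=n_nodes,
        base_dir=path.parent,
    )


def validate_manifest(
    df: pd.DataFrame,
    *,
    age_bounds: tuple[float, float] = (0.0, 120.0),
    min_sites: int = 2,
    min_per_site: int = 3,
    n_nodes: int | None = None,
    base_dir: Path | None = None,
) -> pd.DataFrame:
    missing = [c for c in _REQUIRED_MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"missing manifest columns: {missing}")
    if df["subject_id"].duplicated().any():
        dups = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ManifestError(f"duplicate subject_id: {dups}")
    bad_sex = set(df["sex"]) - set(SEX_LEVELS)
    if bad_sex:
        raise ManifestError(f"unknown sex categories: {sorted(bad_sex)}")
    bad_group = set(df["group"]) - set(GROUP_LEVELS)
    if bad_group:
        raise ManifestError(f"unknown group categories: {sorted(bad_group)}")
    ages = df["age"].astype(float)
    lo, hi = age_bounds
    if ((ages < lo) | (ages > hi)).any():
        raise ManifestError(f"age outside configured bounds {age_bounds}")
    counts = df["site"].value_counts()
    if len(counts) < min_sites:
        raise ManifestError(f"need >= {min_sites} distinct sites, got {len(counts)}")
    small = counts[counts < min_per_site]
    if len(small):
        raise ManifestError(
            f"sites with fewer than {min_per_site} subjects: {dict(small)}"
        )
    if n_nodes is not None and "matrix_path" in df.columns:
        for _, row in df.iterrows():
            p = Path(row["matrix_path"])
            if base_dir is not None and not p.is_absolute():
                p = base_dir / p
            read_connectome(p, n_nodes, subject_id=row["subject_id"])
    return df.sort_values("subject_id", kind="stable").reset_index(drop=True)


def write_manifest(path: str | Path, df: pd.DataFrame) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def write_metric_table(path: str | Path, table: pd.DataFrame) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


def read_metric_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str, "site": str})
    required = {"subject_id", "site", "stage", "metric", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ManifestError(f"metric table missing columns: {sorted(missing)}")
    bad = set(df["metric"]) - set(METRICS)
    if bad:
        raise ManifestError(f"unknown metric names: {sorted(bad)}")
    bad = set(df["stage"]) - set(STAGES)
    if bad:
        raise ManifestError(f"unknown stages: {sorted(bad)}")
    if not np.isfinite(df["value"].to_numpy(dtype=float)).all():
        raise ManifestError("non-finite metric value")
    return df


def load_config(path: str | Path) -> dict:
    """Load a YAML configuration file into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: top-level YAML must be a mapping")
    return cfg


@dataclasses.dataclass
class RunRecord:
    """Deterministic record of one pipeline run (seed, settings, counters)."""

    command: str
    seed: int | None
    settings: Mapping = dataclasses.field(default_factory=dict)
    counters: dict = dataclasses.field(default_factory=dict)
    timestamp: str = dataclasses.field(
        default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat()
    )

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)
        return path


def get_logger(name: str = "connharm", level: str | int = "INFO") -> logging.Logger:
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(level)
    return logger
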