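"""The two harmonization strategies, end to end.

*Matrix harmonization*: vectorize each subject's lower triangle into an
edge-feature table (4,005 features for 90 nodes), harmonize edge weights with
ComBat (empirical Bayes on, covariates preserved), reconstruct the symmetric
matrices, restore each subject's original binary topology by masking, then
compute the global network metrics.

*Parameter harmonization*: compute the global metrics on unharmonized
matrices first, then harmonize each metric in its own single-feature ComBat
model with empirical Bayes off (features < subjects).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from . import combat, graph_metrics
from .graph_metrics import MetricSettings
from .io_core import METRICS, WeightedConnectome
from .synthetic import Cohort

__all__ = [
    "vectorize_lower_triangle",
    "reconstruct_matrix",
    "apply_topology_mask",
    "edge_feature_table",
    "covariate_design",
    "compute_metric_table",
    "run_matrix_harmonization",
    "run_parameter_harmonization",
]


def n_edge_features(n_nodes: int) -> int:
    return n_nodes * (n_nodes - 1) // 2


def lower_triangle_index(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """(row, col) of the lower-triangle features in their fixed order.

    Row-major over ``i > j``: (1,0), (2,0), (2,1), (3,0), ...  This order is
    the bijection between feature columns and unordered node pairs.
    """
    return np.tril_indices(n_nodes, -1)


def vectorize_lower_triangle(W: np.ndarray) -> np.ndarray:
    """Extract the lower-triangle weights as a deterministic feature vector."""
    w = np.asarray(W, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"expected square matrix, got {w.shape}")
    if np.max(np.abs(w - w.T)) > 1e-8:
        raise ValueError("asymmetric input: lower-triangle extraction is lossy")
    return w[lower_triangle_index(w.shape[0])]


def reconstruct_matrix(row: np.ndarray, n_nodes: int) -> np.ndarray:
    """Inverse of :func:`vectorize_lower_triangle` (symmetric, zero diagonal)."""
    row = np.asarray(row, dtype=float)
    expected = n_edge_features(n_nodes)
    if row.shape != (expected,):
        raise ValueError(f"expected {expected} features for n={n_nodes}, got {row.shape}")
    w = np.zeros((n_nodes, n_nodes))
    w[lower_triangle_index(n_nodes)] = row
    return w + w.T


def apply_topology_mask(
    W_harm: np.ndarray, B_orig: np.ndarray, clamp: bool = True
) -> tuple[np.ndarray, int]:
    """Restore the pre-harmonization topology and zero spurious negatives.

    Multiplies the harmonized matrix elementwise by the subject's original
    binary topology (harmonization pushes many originally-zero weights
    negative; those must return to 0 before graph analysis).  Residual
    negative values at originally-present edges are clamped to 0 when
    ``clamp`` is true; the count of such events is returned.
    """
    w = np.asarray(W_harm, dtype=float)
    b = np.asarray(B_orig)
    if w.shape != b.shape:
        raise ValueError(f"shape mismatch: {w.shape} vs {b.shape}")
    out = w * (b > 0)
    n_clamped = 0
    neg = out < 0
    if neg.any():
        if clamp:
            n_clamped = int(np.count_nonzero(np.triu(neg, 1)))
            out[neg] = 0.0
        else:
            raise ValueError(
                f"{int(np.count_nonzero(np.triu(neg, 1)))} negative weights at "
                "originally-present edges and clamping disabled"
            )
    return out, n_clamped


def covariate_design(manifest: pd.DataFrame) -> np.ndarray:
    """Biological covariates to preserve: group (mTBI=1), age, sex (M=1)."""
    return np.column_stack(
        [
            (manifest["group"] == "mTBI").to_numpy(dtype=float),
            manifest["age"].to_numpy(dtype=float),
            (manifest["sex"] == "M").to_numpy(dtype=float),
        ]
    )


def edge_feature_table(cohort: Cohort) -> tuple[np.ndarray, list[str]]:
    """Stack vectorized lower triangles into a features x subjects array."""
    subjects = cohort.manifest["subject_id"].tolist()
    feats = np.stack(
        [vectorize_lower_triangle(cohort.connectomes[s].weights) for s in subjects],
        axis=1,
    )
    return feats, subjects


def compute_metric_table(
    cohort: Cohort,
    settings: MetricSettings | None = None,
    seed: int = 0,
    stage: str = "unharmonized",
    connectomes: Mapping[str, WeightedConnectome] | None = None,
) -> pd.DataFrame:
    """Per-subject global metrics as a long-format table tagged by stage.

    Per-subject seeds are spawned deterministically from ``seed`` in manifest
    (subject-id) order, so results do not depend on chunking or parallelism.
    """
    settings = settings or MetricSettings()
    conns = connectomes if connectomes is not None else cohort.connectomes
    manifest = cohort.manifest
    child_seeds = np.random.SeedSequence(seed).generate_state(len(manifest)) % (2**31)
    rows = []
    for k, (_, info) in enumerate(manifest.iterrows()):
        subject = info["subject_id"]
        gm = graph_metrics.compute_all(
            conns[subject].weights, settings, seed=int(child_seeds[k])
        )
        for metric, value in gm.as_dict().items():
            rows.append(
                {
                    "subject_id": subject,
                    "site": info["site"],
                    "age": info["age"],
                    "sex": info["sex"],
                    "group": info["group"],
                    "stage": stage,
                    "metric": metric,
                    "value": value,
                }
            )
    return pd.DataFrame(rows)


def run_matrix_harmonization(
    cohort: Cohort,
    settings: MetricSettings | None = None,
    seed: int = 0,
    *,
    eb: bool = True,
    clamp: bool = True,
    return_matrices: bool = False,
):
    """Matrix-harmonization pipeline: ComBat on edge weights, then metrics.

    Returns ``(metric_table, run_log)``; with ``return_matrices=True`` also
    the harmonized, masked connectomes.  The run log records the number of
    clamped negative present-edge weights and of all-zero edge features that
    bypassed harmonization.
    """
    manifest = cohort.manifest
    if manifest["site"].nunique() < 2:
        raise ValueError("matrix harmonization needs >= 2 sites")
    feats, subjects = edge_feature_table(cohort)
    x = covariate_design(manifest)
    model = combat.fit(feats, manifest["site"].to_numpy(), x, eb=eb)
    harmonized = combat.transform(model, feats, manifest["site"].to_numpy(), x)

    n_nodes = cohort.connectomes[subjects[0]].n_nodes
    masked: dict[str, WeightedConnectome] = {}
    total_clamped = 0
    for k, subject in enumerate(subjects):
        w_harm = reconstruct_matrix(harmonized[:, k], n_nodes)
        b_orig = cohort.connectomes[subject].topology
        w_masked, n_clamped = apply_topology_mask(w_harm, b_orig, clamp=clamp)
        total_clamped += n_clamped
        masked[subject] = WeightedConnectome(subject, w_masked)

    table = compute_metric_table(
        cohort, settings, seed=seed, stage="matrix_harmonized", connectomes=masked
    )
    run_log = {
        "stage": "matrix_harmonized",
        "eb": eb,
        "n_features": int(feats.shape[0]),
        "n_excluded_zero_variance": int((~model.retained).sum()),
        "n_clamped_negative_present_edges": total_clamped,
        "seed": seed,
    }
    if return_matrices:
        return table, run_log, masked
    return table, run_log


def run_parameter_harmonization(
    unharmonized: pd.DataFrame,
    manifest: pd.DataFrame,
    *,
    eb: bool = False,
) -> pd.DataFrame:
    """Harmonize each already-computed global metric in its own model.

    Empirical Bayes is off by default: each model has a single feature, so
    there is nothing to borrow strength across.  A site with zero variance in
    some metric is surfaced as an error by the harmonization model.
    """
    manifest = manifest.sort_values("subject_id", kind="stable")
    order = manifest["subject_id"].tolist()
    x = covariate_design(manifest)
    batch = manifest["site"].to_numpy()
    out_rows = []
    for metric in METRICS:
        sub = unharmonized[unharmonized["metric"] == metric].set_index("subject_id")
        missing = set(order) - set(sub.index)
        if missing:
            raise ValueError(f"metric {metric!r} missing for subjects {sorted(missing)[:5]}")
        values = sub.loc[order, "value"].to_numpy(dtype=float)[None, :]
        harmonized = combat.harmonize(values, batch, x, eb=eb)[0]
        for subject, value in zip(order, harmonized):
            info = sub.loc[subject]
            out_rows.append(
                {
                    "subject_id": subject,
                    "site": info["site"],
                    "age": info["age"],
                    "sex": info["sex"],
                    "group": info["group"],
                    "stage": "parameter_harmonized",
                    "metric": metric,
                    "value": float(value),
                }
            )
    return pd.DataFrame(out_rows)
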