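"""Synthetic multi-site cohorts of weighted FA connectomes.

The generator emulates the structure of a six-scanner pediatric cohort:
unequal site sizes (120/114/28/20/57/145 by default), ages 8.00-16.99 years,
~60% male, ~64% mTBI, sparse FA-weighted 90-node connectomes with per-site
additive (location) and multiplicative (scale) scanner effects, per-site
topology variability, and a positive linear age effect on connection
strength.

Generative model, subject ``j`` at site ``i``, node pair ``e``::

    present_ije = backbone_e XOR Bernoulli(flip_i)
    w_ije = clip[thr, 1]( mu_e + beta_age * (age_ij - age_mid)
                          + beta_sex * male_ij + beta_group * mtbi_ij
                          + u_ij + gamma_i + delta_i * eps_ije ),
    u ~ N(0, subject_sd^2),  eps ~ N(0, noise_sd^2)

with ``mu_e ~ N(weight_mean, weight_sd^2)`` drawn once per edge and shared by
all subjects, and absent edges exactly 0.  ``gamma_i`` / ``delta_i`` are the
additive and multiplicative scanner effects that ComBat's location/scale
model targets; ``flip_i`` is a per-site edge-flip probability that makes
network topology (hence density) differ by scanner; ``u_ij`` is a global
per-subject FA offset (individual differences beyond age/sex/group) that
keeps age correlations of strength-driven metrics at a realistic magnitude
(~0.4 rather than ~1, since edge noise averages out over thousands of
edges).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import (
    DEFAULT_EDGE_THRESHOLD,
    WeightedConnectome,
    write_connectome,
    write_manifest,
)

__all__ = [
    "TABLE1_SITE_SIZES",
    "SimulationConfig",
    "GroundTruth",
    "Cohort",
    "ConfigError",
    "generate_cohort",
    "inject_site_effects",
    "scaled_site_spec",
    "null_config",
    "save_cohort",
]

#: Per-scanner sample sizes of the cohort being emulated (total 484).
TABLE1_SITE_SIZES: dict[str, int] = {
    "Calgary": 120,
    "Edmonton": 114,
    "Montreal1": 28,
    "Montreal2": 20,
    "Ottawa": 57,
    "Vancouver": 145,
}

#: Maximum tolerated expected fraction of generated weights hitting the
#: clip bounds; beyond this the linear generative model is no longer faithful.
MAX_EXPECTED_CLIP_FRACTION = 1e-3


class ConfigError(ValueError):
    """Simulation configuration violates a generator invariant."""


def scaled_site_spec(total: int) -> dict[str, int]:
    """Table-1 site proportions scaled to roughly ``total`` subjects.

    Every site keeps at least 3 subjects (the minimum for per-site variance
    estimation).
    """
    frac = total / 484.0
    return {s: max(3, round(n * frac)) for s, n in TABLE1_SITE_SIZES.items()}


@dataclasses.dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Site-effect fields left at ``None`` are drawn once per cohort from the
    documented default distributions: ``gamma_i ~ N(0, site_shift_sd^2)``,
    ``delta_i ~ U(site_scale_range)``, and per-site flip probabilities
    ``flip_i = edge_flip_prob * exp(U(-log k, log k))`` with
    ``k = site_flip_factor``.
    """

    n_nodes: int = 90
    site_spec: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: dict(TABLE1_SITE_SIZES)
    )
    backbone_density: float = 0.35
    edge_flip_prob: float = 0.02
    weight_mean: float = 0.45
    weight_sd: float = 0.08
    age_range: tuple[float, float] = (8.00, 16.99)
    prop_male: float = 0.60
    prop_mtbi: float = 0.64
    beta_age: float = 0.006  # FA units per year
    beta_sex: float = 0.0
    beta_group: float = 0.0
    site_shift: Mapping[str, float] | None = None
    site_shift_sd: float = 0.03
    site_scale: Mapping[str, float] | None = None
    site_scale_range: tuple[float, float] = (0.8, 1.25)
    site_flip: Mapping[str, float] | None = None
    site_flip_factor: float = 4.0
    site_age_shift: Mapping[str, float] | None = None
    subject_sd: float = 0.03
    noise_sd: float = 0.04
    threshold: float = DEFAULT_EDGE_THRESHOLD
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.backbone_density < 1:
            raise ConfigError("backbone_density must be in (0,1)")
        if not 0 <= self.edge_flip_prob < 0.5:
            raise ConfigError("edge_flip_prob must be in [0, 0.5)")
        if any(n < 3 for n in self.site_spec.values()):
            small = {s: n for s, n in self.site_spec.items() if n < 3}
            raise ConfigError(f"every site needs n >= 3, got {small}")
        if len(self.site_spec) < 1:
            raise ConfigError("need at least one site")
        if not 0 < self.threshold < self.weight_mean < 1:
            raise ConfigError("require 0 < threshold < weight_mean < 1")


@dataclasses.dataclass
class GroundTruth:
    """Generating quantities persisted for parameter-recovery tests."""

    gamma: dict[str, float]
    delta: dict[str, float]
    flip_prob: dict[str, float]
    beta_age: float
    beta_sex: float
    beta_group: float
    age_mid: float
    backbone: np.ndarray  # boolean, upper-triangle order
    edge_mean: np.ndarray  # mu_e, upper-triangle order
    n_clipped: int = 0

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = dataclasses.asdict(self)
        payload["backbone"] = np.asarray(self.backbone).astype(int).tolist()
        payload["edge_mean"] = np.asarray(self.edge_mean).tolist()
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(payload, fh)
        return path


@dataclasses.dataclass
class Cohort:
    """A manifest plus the matching in-memory connectomes."""

    manifest: pd.DataFrame
    connectomes: dict[str, WeightedConnectome]
    ground_truth: GroundTruth | None = None

    @property
    def n_subjects(self) -> int:
        return len(self.manifest)

    def matrix(self, subject_id: str) -> np.ndarray:
        return self.connectomes[subject_id].weights


def null_config(**overrides) -> SimulationConfig:
    """A configuration with every site effect switched off.

    Used for type-I-error calibration: sites differ only by sampling noise.
    """
    cfg = SimulationConfig(**overrides)
    sites = list(cfg.site_spec)
    cfg.site_shift = {s: 0.0 for s in sites}
    cfg.site_scale = {s: 1.0 for s in sites}
    cfg.site_flip = {s: cfg.edge_flip_prob for s in sites}
    return cfg


def _expected_clip_fraction(cfg: SimulationConfig, gamma, delta) -> float:
    """Analytic estimate of the fraction of present-edge weights clipped.

    Weights are normal with per-edge mean ``mu_e + covariate terms + gamma_i``
    and sd ``sqrt(weight_sd^2 + delta_i^2 noise_sd^2)`` (marginally over the
    ``mu_e`` draw).  Averages the two-sided tail mass over sites (weighted by
    n) and a grid of ages.
    """
    lo, hi = cfg.age_range
    ages = np.linspace(lo, hi, 9)
    age_term = cfg.beta_age * (ages - (lo + hi) / 2.0)
    cov_extra = np.array([0.0, cfg.beta_sex, cfg.beta_group, cfg.beta_sex + cfg.beta_group])
    total_n = sum(cfg.site_spec.values())
    frac = 0.0
    for site, n in cfg.site_spec.items():
        sd = np.sqrt(
            cfg.weight_sd**2 + cfg.subject_sd**2 + (delta[site] * cfg.noise_sd) ** 2
        )
        mean = cfg.weight_mean + gamma[site] + age_term[:, None] + cov_extra[None, :]
        tail = stats.norm.cdf(cfg.threshold, mean, sd) + stats.norm.sf(1.0, mean, sd)
        frac += (n / total_n) * tail.mean()
    return float(frac)


def _draw_site_effects(cfg: SimulationConfig, rng: np.random.Generator):
    sites = list(cfg.site_spec)
    if cfg.site_shift is not None:
        gamma = {s: float(cfg.site_shift[s]) for s in sites}
    else:
        gamma = dict(zip(sites, rng.normal(0.0, cfg.site_shift_sd, len(sites))))
    if cfg.site_scale is not None:
        delta = {s: float(cfg.site_scale[s]) for s in sites}
    else:
        delta = dict(zip(sites, rng.uniform(*cfg.site_scale_range, len(sites))))
    if any(d <= 0 for d in delta.values()):
        raise ConfigError("site scale factors must be positive")
    if cfg.site_flip is not None:
        flip = {s: float(cfg.site_flip[s]) for s in sites}
    else:
        logk = np.log(cfg.site_flip_factor)
        flip = dict(
            zip(sites, cfg.edge_flip_prob * np.exp(rng.uniform(-logk, logk, len(sites))))
        )
    if any(not 0 <= f < 0.5 for f in flip.values()):
        raise ConfigError("per-site flip probabilities must lie in [0, 0.5)")
    return gamma, delta, flip


def generate_cohort(config: SimulationConfig | None = None, **overrides) -> Cohort:
    """Generate a multi-site cohort under the documented generative model.

    Returns a :class:`Cohort` whose manifest rows are sorted by subject id
    and whose :class:`GroundTruth` records every generating quantity.
    """
    cfg = config if config is not None else SimulationConfig(**overrides)
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    gamma, delta, flip = _draw_site_effects(cfg, rng)

    exp_clip = _expected_clip_fraction(cfg, gamma, delta)
    if exp_clip > MAX_EXPECTED_CLIP_FRACTION:
        raise ConfigError(
            f"expected clip fraction {exp_clip:.2e} exceeds "
            f"{MAX_EXPECTED_CLIP_FRACTION:.0e}; weights would leave "
            f"({cfg.threshold}, 1) too often for the linear model to hold"
        )

    n = cfg.n_nodes
    iu = np.triu_indices(n, 1)
    n_pairs = len(iu[0])
    mu = rng.normal(cfg.weight_mean, cfg.weight_sd, n_pairs)
    backbone = rng.random(n_pairs) < cfg.backbone_density
    lo, hi = cfg.age_range
    age_mid = (lo + hi) / 2.0

    rows = []
    connectomes: dict[str, WeightedConnectome] = {}
    n_clipped = 0
    sid = 0
    for site, n_sub in cfg.site_spec.items():
        age_shift = (cfg.site_age_shift or {}).get(site, 0.0)
        for _ in range(n_sub):
            sid += 1
            subject = f"S{sid:04d}"
            age = float(np.clip(rng.uniform(lo, hi) + age_shift, lo, hi))
            male = bool(rng.random() < cfg.prop_male)
            mtbi = bool(rng.random() < cfg.prop_mtbi)

            present = backbone ^ (rng.random(n_pairs) < flip[site])
            u = rng.normal(0.0, cfg.subject_sd) if cfg.subject_sd > 0 else 0.0
            eps = rng.normal(0.0, cfg.noise_sd, n_pairs)
            w = (
                mu
                + cfg.beta_age * (age - age_mid)
                + cfg.beta_sex * male
                + cfg.beta_group * mtbi
                + u
                + gamma[site]
                + delta[site] * eps
            )
            clipped = (w < cfg.threshold) | (w > 1.0)
            n_clipped += int((clipped & present).sum())
            w = np.clip(w, cfg.threshold, 1.0)
            w[~present] = 0.0

            mat = np.zeros((n, n))
            mat[iu] = w
            mat += mat.T
            connectomes[subject] = WeightedConnectome(subject, mat)
            rows.append(
                {
                    "subject_id": subject,
                    "site": site,
                    "age": round(age, 2),
                    "sex": "M" if male else "F",
                    "group": "mTBI" if mtbi else "OI",
                }
            )

    manifest = (
        pd.DataFrame(rows).sort_values("subject_id", kind="stable").reset_index(drop=True)
    )
    truth = GroundTruth(
        gamma=gamma,
        delta=delta,
        flip_prob=flip,
        beta_age=cfg.beta_age,
        beta_sex=cfg.beta_sex,
        beta_group=cfg.beta_group,
        age_mid=age_mid,
        backbone=backbone,
        edge_mean=mu,
        n_clipped=n_clipped,
    )
    return Cohort(manifest, connectomes, truth)


def inject_site_effects(
    cohort: Cohort,
    gamma: Mapping[str, float],
    delta: Mapping[str, float],
    seed: int | None = None,
) -> Cohort:
    """Add location/scale scanner effects to an existing cohort.

    Present-edge weights become ``m_e + delta_i * (w - m_e) + gamma_i`` where
    ``m_e`` is the cross-cohort mean of edge ``e`` over subjects in which the
    edge is present; topology is untouched.  The operation is deterministic
    (``seed`` is accepted for interface symmetry and ignored).

    Raises if any resulting weight would be non-positive (invalid FA).
    """
    del seed
    if any(delta[s] <= 0 for s in delta):
        raise ValueError("delta must be positive for every site")
    manifest = cohort.manifest
    subjects = manifest["subject_id"].tolist()
    n = cohort.connectomes[subjects[0]].n_nodes
    iu = np.triu_indices(n, 1)

    stack = np.stack([cohort.connectomes[s].weights[iu] for s in subjects])
    present = stack > 0
    with np.errstate(invalid="ignore"):
        edge_mean = np.where(
            present.any(axis=0), stack.sum(axis=0) / np.maximum(present.sum(axis=0), 1), 0.0
        )

    site_of = dict(zip(manifest["subject_id"], manifest["site"]))
    new_connectomes: dict[str, WeightedConnectome] = {}
    for k, subject in enumerate(subjects):
        site = site_of[subject]
        w = stack[k]
        out = np.where(
            present[k], edge_mean + delta[site] * (w - edge_mean) + gamma[site], 0.0
        )
        if np.any(out[present[k]] <= 0):
            raise ValueError(
                f"site effect for {site!r} drives weights non-positive (invalid FA)"
            )
        mat = np.zeros((n, n))
        mat[iu] = out
        mat += mat.T
        new_connectomes[subject] = WeightedConnectome(subject, mat)
    return Cohort(manifest.copy(), new_connectomes, cohort.ground_truth)


def save_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write manifest.csv, per-subject TSV matrices and ground_truth.json."""
    out_dir = Path(out_dir)
    mat_dir = out_dir / "matrices"
    mat_dir.mkdir(parents=True, exist_ok=True)
    manifest = cohort.manifest.copy()
    paths = []
    for subject in manifest["subject_id"]:
        p = mat_dir / f"{subject}.tsv"
        write_connectome(p, cohort.connectomes[subject])
        paths.append(str(p.relative_to(out_dir)))
    manifest["matrix_path"] = paths
    write_manifest(out_dir / "manifest.csv", manifest)
    if cohort.ground_truth is not None:
        cohort.ground_truth.to_json(out_dir / "ground_truth.json")
    return out_dir


def load_cohort(cohort_dir: str | Path, n_nodes: int = 90) -> Cohort:
    """Read a cohort previously written by :func:`save_cohort`."""
    from .io_core import read_connectome, read_manifest

    cohort_dir = Path(cohort_dir)
    manifest = read_manifest(cohort_dir / "manifest.csv", min_sites=1, min_per_site=1)
    connectomes = {}
    for _, row in manifest.iterrows():
        p = Path(row["matrix_path"])
        if not p.is_absolute():
            p = cohort_dir / p
        connectomes[row["subject_id"]] = read_connectome(
            p, n_nodes, subject_id=row["subject_id"]
        )
    return Cohort(manifest, connectomes)
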