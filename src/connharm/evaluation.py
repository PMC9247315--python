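"""Statistical battery comparing harmonization stages.

Per metric and stage: one-way site ANOVA with eta-squared, uncorrected
pairwise Welch t-tests and the proportion significant, within-site ICC
between stages (two-way mixed, single measures, consistency), ANCOVA for
covariate preservation, and Pearson age correlations compared across stages
with the Hittner-Silver-May z for dependent overlapping correlations.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import METRICS, STAGES

__all__ = [
    "SiteEffectResult",
    "EvaluationError",
    "site_anova",
    "pairwise_site_tests",
    "icc_consistency",
    "icc_pre_post_by_site",
    "icc_band",
    "compare_dependent_correlations",
    "weighted_within_site_reference",
    "covariate_effects",
    "age_correlations",
    "build_report",
    "load_report",
]

ALPHA = 0.05

#: Consistency bands for the intraclass correlation coefficient.
ICC_BANDS = (
    (0.50, "poor"),
    (0.75, "moderate"),
    (0.90, "good"),
    (np.inf, "excellent"),
)


class EvaluationError(ValueError):
    """Degenerate input to a statistical procedure."""


@dataclasses.dataclass
class SiteEffectResult:
    metric: str
    stage: str
    F: float
    df_between: int
    df_within: int
    p: float
    eta_squared: float
    pairwise: list[dict]
    prop_significant: float


def _groups(values, site) -> tuple[list[np.ndarray], list]:
    values = np.asarray(values, dtype=float)
    site = np.asarray(site)
    levels = sorted(set(site.tolist()))
    return [values[site == s] for s in levels], levels


def site_anova(values, site) -> dict:
    """One-way fixed-effects ANOVA of a metric on site, with eta-squared."""
    groups, levels = _groups(values, site)
    if len(levels) < 2:
        raise EvaluationError("site ANOVA needs >= 2 sites")
    if any(len(g) < 2 for g in groups):
        raise EvaluationError("every site needs n >= 2")
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_total = ((all_vals - grand) ** 2).sum()
    if ss_total == 0:
        raise EvaluationError("zero total variance")
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = ss_total - ss_between
    df_b = len(levels) - 1
    df_w = all_vals.size - len(levels)
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return {
        "F": float(F),
        "df_between": df_b,
        "df_within": df_w,
        "p": p,
        "eta_squared": float(ss_between / ss_total),
    }


def pairwise_site_tests(values, site, alpha: float = ALPHA) -> tuple[list[dict], float]:
    """All C(k,2) two-sample Welch t-tests, uncorrected.

    Returns the pairwise list and the proportion significant at ``alpha``.
    """
    groups, levels = _groups(values, site)
    by_level = dict(zip(levels, groups))
    out = []
    for a, b in itertools.combinations(levels, 2):
        if len(by_level[a]) < 2 or len(by_level[b]) < 2:
            raise EvaluationError(f"pair ({a}, {b}) has a site with n < 2")
        t, p = stats.ttest_ind(by_level[a], by_level[b], equal_var=False)
        out.append({"site_a": a, "site_b": b, "t": float(t), "p": float(p)})
    prop = float(np.mean([row["p"] < alpha for row in out]))
    return out, prop


def icc_consistency(pre, post) -> float:
    """ICC(3,1): two-way mixed effects, single measures, consistency.

    Treats the pre- and post-harmonization values of the same subjects as two
    raters.  The consistency form ignores additive shifts between raters
    (harmonization intentionally moves means).
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise EvaluationError("pre and post must be paired 1-D vectors")
    n = pre.size
    if n < 3:
        raise EvaluationError("ICC needs n >= 3 paired observations")
    data = np.stack([pre, post], axis=1)  # subjects x 2 raters
    k = 2
    grand = data.mean()
    subj_means = data.mean(axis=1)
    rater_means = data.mean(axis=0)
    ss_rows = k * ((subj_means - grand) ** 2).sum()
    ss_cols = n * ((rater_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if msr <= 0:
        raise EvaluationError("zero between-subject variance: ICC undefined")
    return float((msr - mse) / (msr + (k - 1) * mse))


def icc_band(icc: float) -> str:
    for upper, label in ICC_BANDS:
        if icc < upper:
            return label
    return "excellent"  # pragma: no cover


def icc_pre_post_by_site(pre_table: pd.DataFrame, post_table: pd.DataFrame) -> dict:
    """Per-site ICC between two stages of one metric.

    Both tables must be single-metric slices of a long metric table; subjects
    are aligned by id within site.
    """
    pre = pre_table.set_index("subject_id")
    post = post_table.set_index("subject_id")
    if set(pre.index) != set(post.index):
        raise EvaluationError("stage tables cover different subjects")
    out = {}
    for site_label, grp in pre.groupby("site"):
        ids = grp.index.tolist()
        icc = icc_consistency(
            grp["value"].to_numpy(), post.loc[ids, "value"].to_numpy()
        )
        out[site_label] = {"icc": icc, "band": icc_band(icc), "n": len(ids)}
    iccs = [v["icc"] for v in out.values()]
    return {
        "per_site": out,
        "mean": float(np.mean(iccs)),
        "min": float(np.min(iccs)),
        "max": float(np.max(iccs)),
    }


def compare_dependent_correlations(x, y1, y2) -> tuple[float, float]:
    """Hittner-Silver-May z for two dependent overlapping correlations.

    Compares r(x, y1) with r(x, y2) sharing the variable ``x`` and the same
    subjects, using Dunn & Clark's z with the back-transformed average of the
    two Fisher z's in the covariance term.  Returns (z, two-sided p);
    z = 0 when the correlations are equal, and the statistic is antisymmetric
    in (y1, y2).
    """
    x = np.asarray(x, dtype=float)
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    if not (x.shape == y1.shape == y2.shape) or x.ndim != 1:
        raise EvaluationError("x, y1, y2 must be 1-D vectors of equal length")
    n = x.size
    if n < 10:
        raise EvaluationError("need n >= 10 for the asymptotic z")
    r1 = float(np.corrcoef(x, y1)[0, 1])
    r2 = float(np.corrcoef(x, y2)[0, 1])
    r12 = float(np.corrcoef(y1, y2)[0, 1])
    for r in (r1, r2):
        if abs(r) >= 1:
            raise EvaluationError("|r| = 1: Fisher z undefined")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    if z1 == z2:
        return 0.0, 1.0
    rm = float(np.tanh((z1 + z2) / 2.0))  # back-transformed average
    c = (r12 * (1 - 2 * rm**2) - 0.5 * rm**2 * (1 - 2 * rm**2 - r12**2)) / (
        (1 - rm**2) ** 2
    )
    # c -> 1 only as y1 -> y2; keep the variance positive under roundoff
    c = min(c, 1.0 - 1e-12)
    z = (z1 - z2) * np.sqrt((n - 3) / (2.0 - 2.0 * c))
    p = float(2 * stats.norm.sf(abs(z)))
    return float(z), p


def weighted_within_site_reference(values, age, site) -> float:
    """Sample-size-weighted mean of within-site Pearson age correlations.

    The reference value a successfully harmonized pooled correlation should
    approximate: ``sum_i n_i r_i / sum_i n_i``.
    """
    values = np.asarray(values, dtype=float)
    age = np.asarray(age, dtype=float)
    site = np.asarray(site)
    num = den = 0.0
    for s in sorted(set(site.tolist())):
        mask = site == s
        n = int(mask.sum())
        if n < 4:
            raise EvaluationError(f"site {s!r} has n < 4; within-site r unstable")
        v = values[mask]
        if v.std() == 0 or age[mask].std() == 0:
            raise EvaluationError(f"site {s!r} has zero variance")
        r = float(np.corrcoef(age[mask], v)[0, 1])
        num += n * r
        den += n
    return num / den


def covariate_effects(values, manifest: pd.DataFrame) -> dict:
    """ANCOVA (Type II) of a metric on site + age + sex + group, plus the
    mTBI-vs-OI Welch t-test.

    With a single site the site term is dropped (with a warning) and the
    model still fits.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = manifest.copy()
    df["value"] = np.asarray(values, dtype=float)
    terms = ["C(site)", "age", "C(sex)", "C(group)"]
    if df["site"].nunique() < 2:
        warnings.warn("single site: dropping the site term from the ANCOVA")
        terms = terms[1:]
    model = smf.ols("value ~ " + " + ".join(terms), data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    table = {
        idx.replace("C(", "").replace(")", ""): {
            "F": float(row["F"]),
            "p": float(row["PR(>F)"]),
            "df": float(row["df"]),
        }
        for idx, row in anova.iterrows()
        if idx != "Residual"
    }
    a = df.loc[df["group"] == "mTBI", "value"]
    b = df.loc[df["group"] == "OI", "value"]
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return {"ancova": table, "group_ttest": {"t": float(t), "p": float(p)}}


def _stage_slice(table: pd.DataFrame, stage: str, metric: str) -> pd.DataFrame:
    out = table[(table["stage"] == stage) & (table["metric"] == metric)]
    return out.sort_values("subject_id", kind="stable").reset_index(drop=True)


def age_correlations(table: pd.DataFrame, metric: str, stages: Sequence[str]) -> dict:
    """Per-stage Pearson age correlations and all pairwise stage comparisons."""
    per_stage = {}
    vectors = {}
    for stage in stages:
        sl = _stage_slice(table, stage, metric)
        r, p = stats.pearsonr(sl["age"], sl["value"])
        per_stage[stage] = {"r": float(r), "p": float(p)}
        vectors[stage] = (sl["age"].to_numpy(), sl["value"].to_numpy())
    comparisons = {}
    for a, b in itertools.combinations(stages, 2):
        age_a, va = vectors[a]
        _, vb = vectors[b]
        z, p = compare_dependent_correlations(age_a, va, vb)
        comparisons[f"{a}_vs_{b}"] = {"z": z, "p": p}
    unharm = _stage_slice(table, "unharmonized", metric)
    reference = weighted_within_site_reference(
        unharm["value"], unharm["age"], unharm["site"]
    )
    return {
        "per_stage": per_stage,
        "comparisons": comparisons,
        "weighted_within_site_reference": reference,
    }


REPORT_SCHEMA_VERSION = 1


def build_report(
    table: pd.DataFrame,
    out_dir: str | Path | None = None,
    *,
    make_figures: bool = True,
) -> dict:
    """Assemble the full evaluation report from an all-stages metric table.

    Produces per metric x stage site-effect statistics (F, eta^2, pairwise
    proportion), per-site ICCs of each harmonized stage against the
    unharmonized baseline, age-correlation comparisons and covariate
    (ANCOVA) effects.  When ``out_dir`` is given, writes ``report.json``, a
    flat ``site_effects.csv`` and, optionally, violin/heatmap/scatter
    figures.
    """
    stages = [s for s in STAGES if s in set(table["stage"])]
    if not stages:
        raise EvaluationError("metric table contains no known stage")
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "stages": stages,
        "site_effects": {},
        "icc": {},
        "age": {},
        "covariates": {},
    }
    flat_rows = []
    for metric in METRICS:
        report["site_effects"][metric] = {}
        report["covariates"][metric] = {}
        for stage in stages:
            sl = _stage_slice(table, stage, metric)
            core = site_anova(sl["value"], sl["site"])
            pairwise, prop = pairwise_site_tests(sl["value"], sl["site"])
            report["site_effects"][metric][stage] = {
                **core,
                "pairwise": pairwise,
                "prop_significant": prop,
            }
            report["covariates"][metric][stage] = covariate_effects(sl["value"], sl)
            flat_rows.append(
                {
                    "metric": metric,
                    "stage": stage,
                    "F": core["F"],
                    "eta_squared": core["eta_squared"],
                    "p": core["p"],
                    "n_pairwise": len(pairwise),
                    "prop_significant_pairwise": prop,
                }
            )
        report["icc"][metric] = {}
        if "unharmonized" in stages:
            base = _stage_slice(table, "unharmonized", metric)
            for stage in stages:
                if stage == "unharmonized":
                    continue
                post = _stage_slice(table, stage, metric)
                report["icc"][metric][f"unharmonized_vs_{stage}"] = icc_pre_post_by_site(
                    base, post
                )
            report["age"][metric] = age_correlations(table, metric, stages)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        pd.DataFrame(flat_rows).to_csv(out_dir / "site_effects.csv", index=False)
        if make_figures:
            _make_figures(table, report, out_dir)
    return report


def load_report(path: str | Path) -> dict:
    with open(path) as fh:
        report = json.load(fh)
    if report.get("schema_version") != REPORT_SCHEMA_VERSION:
        raise EvaluationError("unknown report schema version")
    return report


def _make_figures(table: pd.DataFrame, report: dict, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    stages = report["stages"]
    sites = sorted(set(table["site"]))

    # Violin plots: metric distributions per site, one panel per stage.
    for metric in METRICS:
        fig, axes = plt.subplots(1, len(stages), figsize=(4 * len(stages), 3), sharey=True)
        axes = np.atleast_1d(axes)
        for ax, stage in zip(axes, stages):
            sl = _stage_slice(table, stage, metric)
            data = [sl.loc[sl["site"] == s, "value"].to_numpy() for s in sites]
            ax.violinplot(data, showmeans=True)
            ax.set_xticks(range(1, len(sites) + 1), sites, rotation=45, fontsize=7)
            ax.set_title(stage, fontsize=9)
        fig.suptitle(metric)
        fig.tight_layout()
        fig.savefig(out_dir / f"violin_{metric}.png", dpi=120)
        plt.close(fig)

    # Heatmap: pairwise |t| with per-site ICC on the diagonal, per metric/stage.
    for metric in METRICS:
        harm_stages = [s for s in stages if s != "unharmonized"]
        if not harm_stages:
            break
        fig, axes = plt.subplots(
            1, len(harm_stages), figsize=(4 * len(harm_stages), 3.5), squeeze=False
        )
        for ax, stage in zip(axes[0], harm_stages):
            k = len(sites)
            mat = np.full((k, k), np.nan)
            for row in report["site_effects"][metric][stage]["pairwise"]:
                i, j = sites.index(row["site_a"]), sites.index(row["site_b"])
                mat[max(i, j), min(i, j)] = abs(row["t"])
            icc_info = report["icc"][metric].get(f"unharmonized_vs_{stage}", {})
            for i, s in enumerate(sites):
                per = icc_info.get("per_site", {}).get(s)
                if per:
                    mat[i, i] = per["icc"]
            im = ax.imshow(mat, cmap="viridis")
            ax.set_xticks(range(k), sites, rotation=45, fontsize=7)
            ax.set_yticks(range(k), sites, fontsize=7)
            ax.set_title(f"{stage}", fontsize=9)
            fig.colorbar(im, ax=ax, shrink=0.8)
        fig.suptitle(f"{metric}: pairwise |t| (lower) and within-site ICC (diagonal)")
        fig.tight_layout()
        fig.savefig(out_dir / f"heatmap_{metric}.png", dpi=120)
        plt.close(fig)

    # Scatter: age vs metric per stage.
    for metric in METRICS:
        fig, axes = plt.subplots(1, len(stages), figsize=(4 * len(stages), 3), sharey=True)
        axes = np.atleast_1d(axes)
        for ax, stage in zip(axes, stages):
            sl = _stage_slice(table, stage, metric)
            ax.scatter(sl["age"], sl["value"], s=6, alpha=0.5)
            r = report["age"].get(metric, {}).get("per_stage", {}).get(stage)
            label = f"r = {r['r']:.2f}" if r else ""
            ax.set_title(f"{stage} {label}", fontsize=9)
            ax.set_xlabel("age (years)")
        axes[0].set_ylabel(metric)
        fig.tight_layout()
        fig.savefig(out_dir / f"age_scatter_{metric}.png", dpi=120)
        plt.close(fig)
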