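"""Shared fixtures: synthetic cohorts at the study's problem sizes.

The heavy fixtures are session-scoped so the site-effect, consistency and
covariate-preservation tests share one cohort and one metric computation.
"""

import numpy as np
import pandas as pd
import pytest

from connharm import pipelines, synthetic
from connharm.graph_metrics import MetricSettings

#: One fixed seed for every simulation-backed test in the suite.
SEED = 7

#: Null networks per subject in pipeline runs (the published analyses use
#: 1,000; 50 keeps the full-cohort runs tractable on one CPU).
N_NULL = 50


@pytest.fixture(scope="session")
def full_cohort() -> synthetic.Cohort:
    """Default study conditions: 6 sites at Table-1-like sizes, 484 subjects."""
    return synthetic.generate_cohort(synthetic.SimulationConfig(seed=SEED))


@pytest.fixture(scope="session")
def full_unharmonized(full_cohort) -> pd.DataFrame:
    return pipelines.compute_metric_table(
        full_cohort, MetricSettings(n_null=N_NULL), seed=SEED
    )


@pytest.fixture(scope="session")
def full_param_harmonized(full_cohort, full_unharmonized) -> pd.DataFrame:
    return pipelines.run_parameter_harmonization(
        full_unharmonized, full_cohort.manifest
    )


@pytest.fixture(scope="session")
def pipeline_cohort() -> synthetic.Cohort:
    """Reduced six-site cohort (~150 subjects) for the matrix pipeline."""
    cfg = synthetic.SimulationConfig(
        site_spec=synthetic.scaled_site_spec(150), seed=SEED
    )
    return synthetic.generate_cohort(cfg)


@pytest.fixture(scope="session")
def pipeline_unharmonized(pipeline_cohort) -> pd.DataFrame:
    return pipelines.compute_metric_table(
        pipeline_cohort, MetricSettings(n_null=N_NULL), seed=SEED
    )


@pytest.fixture(scope="session")
def pipeline_matrix_harmonized(pipeline_cohort):
    """(metric table, run log) of the matrix-harmonization pipeline."""
    return pipelines.run_matrix_harmonization(
        pipeline_cohort, MetricSettings(n_null=N_NULL), seed=SEED
    )


@pytest.fixture(scope="session")
def tiny_cohort() -> synthetic.Cohort:
    """Small, fast cohort (30 nodes, 3 sites x 10) with site effects."""
    cfg = synthetic.SimulationConfig(
        n_nodes=30,
        site_spec={"A": 10, "B": 10, "C": 10},
        seed=SEED,
    )
    return synthetic.generate_cohort(cfg)


def random_metric_table(seed: int = 0, n_per_site: int = 12) -> pd.DataFrame:
    """A cheap all-stages metric table (no graph computation) for report tests."""
    from connharm.io_core import METRICS, STAGES

    rng = np.random.default_rng(seed)
    sites = [f"site{i}" for i in range(3)]
    rows = []
    sid = 0
    subjects = []
    for site in sites:
        for _ in range(n_per_site):
            sid += 1
            subjects.append(
                {
                    "subject_id": f"S{sid:03d}",
                    "site": site,
                    "age": float(rng.uniform(8, 17)),
                    "sex": "M" if rng.random() < 0.6 else "F",
                    "group": "mTBI" if rng.random() < 0.64 else "OI",
                }
            )
    for stage in STAGES:
        for metric in METRICS:
            for subj in subjects:
                rows.append(
                    {
                        **subj,
                        "stage": stage,
                        "metric": metric,
                        "value": float(
                            0.02 * subj["age"] + rng.normal(0, 0.2)
                        ),
                    }
                )
    return pd.DataFrame(rows)
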