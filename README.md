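# connharm

Multisite ComBat harmonization of structural connectomes: harmonize the
**matrices** or harmonize the **metrics**?

Large multi-scanner diffusion-MRI studies map each subject's structural
connectome as a weighted adjacency matrix (here: 90 AAL nodes, edges
weighted by mean fractional anisotropy, absolute threshold 0.10) and then
summarize it with global graph metrics. Different scanners introduce
non-biological variability that must be removed before group inference.
In connectome analyses there are two places to apply ComBat — the standard
empirical-Bayes location/scale harmonization model

&nbsp;&nbsp;&nbsp;&nbsp;*y<sub>ijv</sub> = α<sub>v</sub> + x′<sub>ij</sub>β<sub>v</sub> + γ<sub>iv</sub> + δ<sub>iv</sub>ε<sub>ijv</sub>*

(feature *v*, subject *j*, scanner *i*, covariates *x* = group, age, sex) —
either:

* **Matrix harmonization** — vectorize each subject's lower triangle
  (4,005 edge features), run ComBat with empirical Bayes, reconstruct the
  matrices, restore each subject's original binary topology by masking, then
  compute graph metrics; or
* **Parameter harmonization** — compute the five global metrics (global
  efficiency, clustering coefficient, modularity, small-worldness σ,
  density) from unharmonized matrices, then harmonize each metric in its own
  single-feature ComBat model with `eb=FALSE`.

`connharm` implements both pipelines end to end, a from-scratch ComBat
(verified against `sva::ComBat` to ~1e-7), the graph-metric suite with
degree- and weight-preserving null-network normalization for σ, a synthetic
multi-site cohort generator (the reference cohort is not publicly
deposited), and the full statistical evaluation battery: per-metric site
ANOVA with η², uncorrected pairwise Welch t-tests (15 for six sites),
within-site ICC(3,1) consistency between stages, ANCOVA covariate checks,
and age-correlation comparisons via the Hittner–Silver–May z for dependent
overlapping correlations. It is intended for methodologists evaluating
harmonization strategies for network neuroimaging, and as a reproducible
reference implementation of the comparison.

## Worked example

```python
from connharm import synthetic, pipelines, evaluation
from connharm.graph_metrics import MetricSettings

cfg = synthetic.SimulationConfig(site_spec=synthetic.scaled_site_spec(150), seed=7)
cohort = synthetic.generate_cohort(cfg)          # 6 sites, 150 subjects
settings = MetricSettings(n_null=50)

unharm = pipelines.compute_metric_table(cohort, settings, seed=7)
par = pipelines.run_parameter_harmonization(unharm, cohort.manifest)

for metric in ("global_efficiency", "density"):
    pre, post = (t[t.metric == metric] for t in (unharm, par))
    a_pre = evaluation.site_anova(pre["value"], pre["site"])
    a_post = evaluation.site_anova(post["value"], post["site"])
    _, prop_pre = evaluation.pairwise_site_tests(pre["value"], pre["site"])
    _, prop_post = evaluation.pairwise_site_tests(post["value"], post["site"])
    print(f"{metric}: F={a_pre['F']:.1f} (eta2={a_pre['eta_squared']:.2f}, "
          f"{prop_pre:.0%} pairwise) -> F={a_post['F']:.2f} "
          f"(p={a_post['p']:.2f}, {prop_post:.0%} pairwise)")
```

prints

```
global_efficiency: F=9.9 (eta2=0.26, 40% pairwise) -> F=0.06 (p=1.00, 0% pairwise)
density: F=159.6 (eta2=0.85, 80% pairwise) -> F=0.01 (p=1.00, 0% pairwise)
```

Read: before harmonization both metrics differ strongly by scanner (large
site-ANOVA F, many significant pairwise site comparisons); after parameter
harmonization no scanner effect remains (F ≈ 0, p ≈ 1, 0 of 15 pairwise
comparisons significant). The injected biological age effect survives —
`evaluation.age_correlations` shows the pooled post-harmonization r matching
the sample-size-weighted mean of within-site correlations.

The same analysis is scriptable from the shell:

```bash
connharm simulate --total 150 --seed 7 --out-dir cohort/
connharm metrics --manifest cohort/manifest.csv --n-null 50 --seed 7 --out unharm.csv
connharm harmonize-matrix --manifest cohort/manifest.csv --n-null 50 --seed 7 --out-dir matrix/
connharm harmonize-params --metrics unharm.csv --manifest cohort/manifest.csv --out params.csv
connharm report --metrics unharm.csv --metrics matrix/metrics_matrix_harmonized.csv \
                --metrics params.csv --out-dir report/
```

`report/` then contains `report.json`, a flat `site_effects.csv`
(F, η², pairwise proportion per metric × stage) and violin / pairwise-t
heatmap / age-scatter figures.

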