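# connectopath

A tested, reusable pipeline for weighted structural-connectome analysis:

- **Graph topology** — proportional thresholding over a sparsity sweep
  (default 5–30% in 1% steps), weighted characteristic path length, Onnela
  clustering, global efficiency and per-region local efficiency, each
  aggregated into a trapezoidal AUC across the sweep.
- **Univariate inference** — pooled-variance t tests, ANCOVA, correlations,
  covariate-adjusted regressions, Benjamini–Hochberg FDR at fixed family
  sizes, and exact classifier-accuracy statistics (no-information rate,
  Clopper–Pearson CI, one-sided binomial test).
- **Multivariate models** — linear SVM classification (ADHD vs typically
  developing controls) and linear SVR treatment-response prediction over
  the 82 local-efficiency AUC features, leave-one-out cross-validation
  with fold-internal standardization, cost tuning, label-permutation
  significance, ROC-AUC and loess-r² variable importance.
- **Synthetic cohorts** — a generator producing 82×82 connectivity
  matrices and phenotype tables with planted, recoverable effects
  (attenuated subcortical connectivity in the patient group; treatment
  response linearly tied to baseline global efficiency), providing ground
  truth for every downstream stage.

The bundled parcellation has 68 cortical regions (34 per hemisphere,
Desikan–Killiany names) labelled with the seven canonical cortical
functional networks plus 14 subcortical structures.

## CLI

```bash
# generate a synthetic cohort (cohort.csv, matrices/<id>.csv, ground_truth.json)
connectopath simulate --out cohort_dir --seed 1

# per-subject graph-metric AUCs
connectopath metrics --matrices cohort_dir/matrices --out metrics.csv

# univariate group comparison (CSV with p and q columns)
connectopath compare-groups --matrices cohort_dir/matrices \
    --pheno cohort_dir/cohort.csv --out stats.csv

# SVM classification / treatment-response / severity analyses
connectopath classify --matrices cohort_dir/matrices \
    --pheno cohort_dir/cohort.csv --permutations 200 --seed 1 --out eval.json
connectopath predict-response --matrices cohort_dir/matrices \
    --pheno cohort_dir/cohort.csv --permutations 200 --seed 1 --out eval.json
connectopath severity --matrices cohort_dir/matrices \
    --pheno cohort_dir/cohort.csv --out severity.json

# all three research questions + JSON/Markdown report
connectopath report --matrices cohort_dir/matrices \
    --pheno cohort_dir/cohort.csv --permutations 200 --seed 1 --out report_dir
```

Matrices are plain delimited text (`<subject_id>.csv`/`.tsv`, n×n,
optional header of region names in atlas order). The atlas is a TSV with
columns `name, hemisphere, network`; a custom atlas can be passed with
`--atlas`. Phenotypes are a CSV with one row per subject (see
`connectopath.connectome_io.SubjectRecord` for the column set).

## Library use

```python
from connectopath import default_atlas, sweep_metrics, SimulationConfig, simulate_cohort
from connectopath.pipeline import RunConfig, run_full_analysis

cohort, truth = simulate_cohort(SimulationConfig(seed=1))
sections = run_full_analysis(cohort, default_atlas(), RunConfig(permutations=200, seed=1))
```
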