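# imodkit

Robust independent component analysis of bacterial expression compendia:
decomposition into **iModulons** (independently modulated gene sets),
regulator annotation against a transcriptional regulatory network (TRN), and
activity analytics for condition/time-course comparisons such as the
transition into stationary phase under nutrient starvation.

The package is aimed at microbial transcriptomics groups who assemble
RNA-seq compendia (TPM matrices over hundreds of samples) and want a fully
scripted, reproducible path from TPM to annotated iModulon activities —
plus a synthetic-compendium generator with planted ground truth, so every
stage of the pipeline can be validated without any external download.

## The model

A centered log-expression matrix **X** (genes × samples) is decomposed as

```
X = M A
```

where **M** (genes × components) holds condition-independent gene weights —
each column's heavy-tailed outliers are the member genes of one iModulon —
and **A** (components × samples) holds the condition-dependent activities.
The pipeline stages are:

1. **Preprocess** — concatenate new TPM profiles onto a base compendium
   (gene-intersection), take log2(TPM + 1), and center each gene on the mean
   of the reference samples; replicate Pearson-r QC and PCA
   cumulative-variance summaries.
2. **Robust ICA** — FastICA (log-cosh contrast, symmetric decorrelation,
   SVD whitening) repeated over bootstrap-resampled runs; components pooled
   and clustered under the 1 − |r| distance; only clusters recurring in
   enough runs are kept. Dimension selection scans a grid and picks the
   smallest dimension reaching the plateau of non-single-gene robust
   components (the OptICA idea).
3. **Structure** — member genes split from the Gaussian weight background by
   an iterative D'Agostino K² outlier scan; per-iModulon explained variance;
   optional matching against a prior structure (|Pearson r| > 0.7) to
   inherit names.
4. **Enrichment** — one-sided hypergeometric overlap tests against every
   regulon, Benjamini–Hochberg FDR (default 10⁻⁴) over the full test family,
   naming by the most significant regulator.
5. **Activities** — least-squares projection of (new) samples onto a fixed
   **M**, normalization relative to a reference sample, U/D/− differential
   calls at a fixed activity threshold (default 5), activity correlations
   with t-based p-values, and hierarchical clustering of activity profiles.

## Worked example

Run the whole pipeline on a synthetic starvation compendium with 10 planted
modules (3 conditions × 5 time points × 2 replicates + a 30-sample
reference block):

```python
from imodkit import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    out_dir="demo_out",
    seed=1,
    simulate=dict(n_genes=300, k_modules=10, genes_per_module=15,
                  timepoints=[3, 4, 6, 8, 12], background_samples=30),
    dim_grid=[5, 10, 15, 20],
    n_runs=10,
)
bundle = run_pipeline(cfg)
print(bundle.optica_diagnostics)
print("median membership F1:", round(bundle.recovery["median_f1"], 3))
print("modules named by their planted regulator:",
      bundle.recovery["n_named_by_planted_regulator"], "/ 10")
```

prints

```
     n_robust  n_single_gene  n_non_single_gene
dim
5           3              0                  3
10         10              2                  8
15         11              2                  9
20         10              2                  8
median membership F1: 0.929
modules named by their planted regulator: 10 / 10
```

The diagnostics table shows the dimension scan: at the true dimensionality
(10 planted modules) ten robust components appear and the non-single-gene
count plateaus, so the scan settles near 10–15. Membership F1 compares each
recovered iModulon's thresholded gene set with the planted module it best
matches; 0.93 means the member lists are recovered almost exactly at the
benchmark noise level (noise sd = 25% of the per-gene signal sd). All ten
iModulons are named by their planted regulator at FDR 10⁻⁴.

The same run from the shell:

```bash
imod run --config config.yaml --out demo_out
```

with stage-wise subcommands (`imod simulate|preprocess|decompose|structure|
enrich|activities|diff|correlate`) available for iterating on thresholds
without re-running the decomposition.

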