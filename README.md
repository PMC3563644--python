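# ergmeta

Cross-study meta-analysis of microarray gene expression for prostate cancer
subgroups, built for transcriptomics researchers who want to combine several
published, already-normalized expression studies into one robust
differential-expression signature and check it against an independent cohort.

## The problem and the method

Roughly half of prostate cancers carry an ERG gene rearrangement (most often
TMPRSS2-ERG), which places the ERG transcription factor under
androgen-responsive control and drives ERG overexpression. Public expression
studies rarely annotate rearrangement status, so tumors are assigned by a
surrogate: within each study, cancer samples are ranked by ERG expression and
split into tertiles — the top ⌈n/3⌉ samples are called ERG+, the bottom
⌊n/3⌋ ERG−, and the intermediate third is excluded.

Per study and per gene, a two-sided Welch t-test contrasts the groups
(ERG+ vs ERG−, or cancer vs benign) and yields a p-value and a log2 fold
change. Evidence is combined across the k studies that measure a gene with
Fisher's inverse chi-squared method:

    X = -2 · Σᵢ ln pᵢ,   X ~ χ²(2k) under the joint null,

giving a combined p from the chi-squared upper tail, alongside an optional,
more conservative permutational summary p (group labels shuffled within each
study, X recomputed B times). Fold changes are combined as a sample-size
weighted mean, Σ wᵢ·log2FCᵢ / Σ wᵢ with wᵢ = nᵢ. Combined p-values are
Benjamini-Hochberg adjusted, and a signature is the set of genes with linear
fold change above a cutoff (1.5 or 2) and adjusted p below 0.1. The signature
is then *verified* gene by gene in an independent validation cohort
(direction concordant and validation BH-adjusted p < 0.05), and the
verification percentage is compared with the array-wide background rate.

Probe-level matrices are first collapsed to gene level by keeping, for each
gene, the probe set with the highest variance across all samples of the
study. A synthetic multi-study generator with known ground truth (bimodal
marker gene, subgroup- and cancer-linked effects, study baselines, Gaussian
log2 noise) stands in for the original repository cohorts and makes every
stage testable.

## Worked example

```sh
ergmeta simulate --out bundle --seed 3          # 8 studies, 561 samples, 2000 genes
ergmeta run-all --studies bundle --out results
```

or, equivalently, in Python:

```python
from ergmeta import (SimConfig, RunConfig, PipelineInputs,
                     generate_study_set, generate_validation_study,
                     write_study_set, run_pipeline)

cfg = SimConfig(seed=42)                         # default eight-study design
studies, maps, truth = generate_study_set(cfg)
write_study_set(studies, maps, truth, "bundle/meta")
vstudy, vmap = generate_validation_study(cfg, truth)
write_study_set([vstudy], {"validation": vmap}, None, "bundle/val")

res = run_pipeline(RunConfig(seed=1),
                   PipelineInputs(meta_dir="bundle/meta",
                                  validation_dir="bundle/val"),
                   "results")
print(res.report.table.to_string(index=False))
```

which prints

```
 fc_threshold  n_signature  n_excluded  n_verified  percent_verified  array_wide_rate
          1.5          101           0         101               100           0.0505
          2.0           75           0          75               100           0.0325
```

At fold change > 1.5 the meta-analysis flags 101 genes (the 100 true
subgroup-linked genes plus ERG itself, which differs between tertile groups
by construction); every one is direction-concordant and significant in the
same-truth validation cohort (percent_verified = 100), against an array-wide
background rate of about 5% of all 2000 genes. `results/` holds the per-gene
tables (`results_subgroup.tsv`, `results_cancer_vs_benign.tsv`), volcano
exports, the per-study tertile assignments and a JSON run manifest.

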