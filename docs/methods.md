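# Methods

## Model and procedure

The pipeline treats each study as an independent experiment on its own
platform. Inputs are normalized log2 intensity matrices (probes × samples)
with per-sample phenotype annotation and a many-to-one probe → gene map.
Five stages run in order:

1. **Collapse.** For each gene with several probe sets, the probe with the
   largest sample variance across *all* samples of the study (ddof = 1,
   missing values skipped) is retained. Variance is computed pooled over
   phenotype groups: the selection rule is deliberately unsupervised so it
   cannot bias the downstream contrast, while still favoring probes that
   respond to biology. Ties break to the lexicographically smallest probe
   ID so repeated runs select identically.
2. **Assignment.** Two-group labels come either from annotation (cancer vs
   benign; externally assayed rearrangement status in a validation cohort)
   or from the marker-tertile surrogate: cancer samples sorted by marker
   expression descending (ties broken by sample ID ascending), top ⌈n/3⌉
   positive, bottom ⌊n/3⌋ negative, middle excluded and never imputed.
3. **Per-study statistics.** Two-sided Welch unequal-variance t-test with
   Welch–Satterthwaite degrees of freedom; log2FC = mean(positive) −
   mean(negative). The per-study test is a package choice — Welch is the
   conservative default for two-group array contrasts — and is kept behind
   a single function so a moderated-t variant could be swapped in.
4. **Combination.** Fisher's statistic X = −2·Σ ln pᵢ referred to χ²(2k);
   genes must be measured in ≥ 2 studies (configurable) to be combined, and
   k varies per gene because platforms cover different gene sets. Combined
   log2FC is the mean weighted by per-study sample count n_pos + n_neg
   (sample size as the precision proxy; equal weights available). BH
   adjustment is applied once per contrast, separately for the
   cancer-vs-benign and subgroup tables.
5. **Filtering and validation.** Signature membership uses strict
   inequalities (linear FC > threshold, adjusted p < threshold). A
   signature gene is *verified* in the validation cohort when its direction
   matches and its validation-side BH-adjusted p < 0.05 (declared, not
   inferred from any external source); genes unmeasured on the validation
   platform are excluded from the denominator and counted separately.
   Verification percentages are rounded to the nearest integer. The
   array-wide rate applies the same criterion to every measured gene and is
   the background for judging enrichment.

## Permutational summary p

The optional conservative null permutes group labels independently within
each study (preserving group sizes — the exchangeability-preserving scheme),
recomputes per-study Welch p-values and X, and reports
p = (1 + #{X_b ≥ X_obs}) / (B + 1). When the number of distinct within-study
splits is ≤ B the implementation enumerates them all instead and reports the
exact fraction #{X_b ≥ X_obs}/N (observed split included). One master seed
spawns per-study (and, in table mode, per-gene) substreams, so results are
reproducible and independent of evaluation order. Comparisons against X_obs
use a 1e-9 absolute slack so that the observed split always counts as at
least as extreme as itself under floating-point arithmetic.

## Numerical conventions

- p-values are clipped below at 1e-300 before logs so X stays finite.
- Degenerate variance (both groups constant): p = 1 when the means agree,
  the smallest positive double when they differ — extreme but finite, so it
  propagates through logarithms instead of producing NaN.
- Missing cells (`NA` on disk) are dropped per gene; a gene missing in more
  than half of either group, or with fewer than 2 usable values in a group,
  is dropped from that study with a logged warning.
- TSV output uses 17-significant-digit floats, giving exact binary round
  trips; results tables are sorted by adjusted p then gene ID so repeated
  runs are byte-identical.

## Synthetic data: what it emulates, what it does not

The generator mimics the statistical structure the meta-analysis assumes:
independent studies with disjoint probe namespaces, 1–3 probe sets per gene
(constant per-probe offsets, so probe selection is exercised without
shifting group differences), additive per-study-per-gene baselines,
i.i.d. Gaussian noise on the log2 scale (the variance-stabilized regime of
normalized arrays), a latent ~50%-prevalence tumor subgroup, a marker gene
elevated by `marker_gap_log2` in subgroup-positive cancer samples, and
disjoint sets of cancer- and subgroup-linked genes whose signed effects have
fair-coin directions so volcano plots are balanced in expectation.

Defaults encode the full study design the package targets: 8 studies with
(cancer, benign) sizes (21,8), (57,15), (41,13), (50,48), (23,49), (7,6),
(68,14), (138,3) — 561 samples — 2000 genes, `effect_log2 = 1.0` (true
linear FC 2), `noise_sd = 0.5` (typical post-normalization within-group SD),
`study_shift_sd = 0.5`, `marker_gap_log2 = 3.0` (six noise SDs: a strongly
bimodal marker), 10% cancer-linked and 5% subgroup-linked genes. The
validation generator draws an independent all-cancer cohort (default n = 57)
from the same truth table with externally annotated subgroup status.

Not emulated: raw probe-level intensity artifacts and normalization effects,
platform-specific coverage gaps (every synthetic platform measures every
gene, so the platform-exclusion path is exercised with constructed fixtures
instead), correlated genes, and heavy-tailed or sample-quality outliers.
Passing tests therefore demonstrate correctness of the machinery and its
calibration under the assumed model, not robustness to real-data artifacts.

One structural artifact is intentional and mirrors practice: the marker gene
itself always enters the subgroup signature, because sorting samples by its
expression makes it differ between tertile groups by construction. Null-run
tests except the marker for this reason.

## Problem sizes used in checks

Null calibration uses 4 studies × 2000 genes × (30+30) samples over 20
seeds, pooling 40,000 null p-values (binomial 3·SE bounds at α = 0.01 and
0.05); the BH false-discovery proportion is averaged over the 20 seeds.
Permutation-vs-chi-squared agreement uses B = 10,000 on one exchangeable
null gene, with exact enumeration cross-checked on a 3-vs-3 toy (20 splits).
Parameter recovery runs the default eight-study design end to end. The whole
suite completes in well under a minute on one CPU.

## Known limitations

- The tertile surrogate misclassifies when the marker gap is comparable to
  noise; detected subgroup effects are then attenuated toward zero (tested
  property). Exact-thirds rounding cannot reproduce every historical cohort
  split where quality exclusions preceded the tertile cut.
- Fisher's method assumes independent per-study p-values and weights all
  studies equally in the statistic; no between-study heterogeneity
  (random-effects) model is provided.
- No moderated/empirical-Bayes variance shrinkage; with very small studies
  (n per group near 2–3) Welch p-values are noisy and the combined p
  inherits that noise.
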