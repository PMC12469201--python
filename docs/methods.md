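# Methods

## Model and assumptions

`cytovam` scores a cells × genes matrix of log-normalized expression
(`ln(1 + 10⁴·count/total)` by default; pre-normalized input is accepted
as-is) against per-cytokine signed, weighted gene sets. The scoring
statistic is a variance-adjusted Mahalanobis distance from the origin:
for set *k* with genes *g* matched in the data,

```
M_c = Σ_j  w̃_j · x_cj² / σ²_tech,j ,          w̃_j = w_j · g / Σ w
```

Two deliberate departures from the classical Mahalanobis distance define
the method. First, the covariance matrix is replaced by the diagonal of
per-gene *technical* variances: the distance discounts deviations along
directions of high measurement noise while preserving coordinated
(biological) co-variation, which a full covariance inverse would remove.
Second, distances are measured from the origin rather than the
multivariate mean: for sparse non-negative expression, "far from zero on
the signature genes" is the biologically meaningful signal.

Because the raw distance scale depends on set size and variance
structure, each set's distances are calibrated to [0, 1] through the CDF
of a gamma distribution fitted by maximum likelihood to the strictly
positive distances of that same dataset (self-calibration). Scores are
therefore *relative within the scored dataset* — a score of 0.9 means
"in the top decile of this dataset for this signature", not an absolute
activity level, and scores are not transferable between datasets.

A cytokine's activity combines the up- and down-regulated sets by
matched-set-size weights:

```
s = n_pos/(n_pos+n_neg) · VAM_pos + n_neg/(n_pos+n_neg) · (1 − VAM_neg)
```

`n_pos`/`n_neg` are the sizes after intersecting with the target data's
genes — a set contributing zero genes contributes zero weight. The
combined score is a convex combination of `VAM_pos` and `1 − VAM_neg`,
hence always in [0, 1].

### Weight incorporation

The |log2FC| weights enter the distance multiplicatively per gene after
normalization to mean 1 over the matched genes. The normalization keeps
the expected distance scale equal to the unweighted case, so the gamma
calibration operates in the same regime regardless of the weight
distribution; with `use_weights=False` (or all-equal weights) the scheme
reduces exactly to the unweighted sum of standardized squares.

## Signature construction

For each condition label (except the control), cells of that condition
are compared against *all* remaining cells — other cytokines pooled with
the control — so the resulting markers are specific to the cytokine
relative to other, possibly similar cytokines, not merely
stimulation-vs-vehicle markers. Per gene:

- two-sided Wilcoxon rank-sum test, normal approximation with tie and
  continuity correction (`scipy.stats.mannwhitneyu`);
- `avg_log2fc = log2((mean(expm1(x)) + 1) / (mean(expm1(y)) + 1))` — the
  ratio of pseudocounted means on the de-logged (normalized count) scale;
- Bonferroni adjustment over the tested genes (a raw-p option exists, as
  does an off-by-default `min_pct` expressed-fraction prefilter, so users
  can match either convention of the common DE toolchains).

Genes with adjusted p < α (default 0.05) are ranked by |log2FC|
descending, ties broken by smaller p then gene id (so construction is
invariant to cell/gene order), the top `num_genes` (default 60) kept and
split by fold-change sign. Zero fold-changes are discarded. A cytokine
with no passing gene keeps empty sets and is skipped at scoring time
with a report entry — never silently zero-scored.

## Technical variance

The decomposition of log-normalized expression variance into technical
and biological parts is done by local regression: lowess (frac 0.3) of
log10 variance on log10 mean across genes, with the fitted trend value
at each gene's mean taken as its technical variance, floored at 1e−8.
Genes sitting above the trend are treated as biologically variable; only
the trend component enters the distance denominator. With fewer than 32
expressed genes the trend is unreliable and the estimator falls back to
per-gene total variance (with a warning); `total_variance` and `unit`
are also selectable directly. This lowess recipe is one reasonable
reading of "mean-variance-trend" decompositions in common use; it is a
documented choice, not asserted equivalent to any specific tool.

## Gamma fitting and degenerate inputs

The gamma MLE solves `ln k − ψ(k) = ln(mean) − mean(ln)` by Newton
iteration (halving steps guard the positive domain) from the standard
closed-form start, tolerance 1e−10, at most 200 iterations; rate =
shape/mean. The fit requires ≥ 3 strictly positive, non-identical
distances. When infeasible (tiny sets, near-constant columns) the score
falls back to empirical ranks (mean rank for ties, divided by n, zeros
pinned to 0) so degenerate sets still yield bounded, monotone scores;
the per-run report records the failed fit. Zero distances always map to
score 0 — the gamma CDF at the origin.

## Evaluation harness

- **Stratified k-fold**: per label, seeded shuffle then round-robin, so
  per-label fold counts differ by ≤ 1.
- **AUC-ROC**: Mann–Whitney rank formulation, ties ½, no automatic
  direction flipping (scores are defined as higher-is-more-active).
- **PR-AUC**: step integration over distinct score thresholds
  (Σ ΔRecall · Precision, no PR-space interpolation). The estimator is
  pinned and documented because PR-AUC values differ across common
  implementations.
- **Optimal threshold**: the cut minimizing (1−sens)² + (1−spec)² over
  all midpoints between distinct scores plus ±∞; ties resolved toward
  higher specificity, then lower threshold. Binarization is strict
  (positive iff score > threshold).
- **Confusion metrics**: sensitivity, specificity, precision, NPV, F1,
  prevalence, detection rate, detection prevalence, balanced accuracy;
  zero-denominator ratios are reported as missing, never zero.
- **Benchmark**: signatures are rebuilt per fold on training cells only;
  every method scores the held-out cells; metrics are averaged over
  folds; "proportion of cytokines where each method is best" summaries
  split ties fractionally so proportions sum to 1. A pairwise
  one-vs-one mode trains a's signature against b only and reports how
  separable each cytokine pair is.

## Synthetic data

The generator emulates a desk-scale stimulation corpus: one condition
per cytokine plus an optional PBS control, negative-binomial counts
(variance μ + φμ², default dispersion φ = 0.5) over gene baselines drawn
log-uniformly from [0.1, 2.0] mean counts. Each cytokine perturbs
`n_up` = 20 genes up and `n_down` = 10 down, multiplicatively on the
mean by 2^(±effect), with effects jittered ±20% around the configured
|log2FC| (default 1.5) — so planted effects are interpretable on the
avg_log2FC scale up to normalization attenuation and sampling noise.
Planted genes are placed on detectably expressed baselines (upper half
of the baseline range, log scale), since a perturbation signature is by
construction made of genes whose regulation is observable; down-
regulation of an essentially silent gene leaves no footprint.
`overlap_fraction` makes consecutive cytokines share that fraction of
their signature genes, mimicking the functional redundancy of real
cytokine responses (shared receptors, overlapping programs); recovery
degrades as overlap grows, as it should.

Defaults (5 cytokines × 200 cells + control, 400 genes) were chosen as
the smallest configuration at which the full pipeline is comfortably
identifiable: signature construction recovers essentially all planted
genes in the correct sign set, and held-out per-cytokine AUC is ≈ 0.99.
At 50 cells/condition the same generator yields ~75% planted-gene
recovery — the Wilcoxon-plus-Bonferroni power limit at this dispersion —
which the test suite documents rather than hides.

What the generator does **not** emulate: zero-inflation beyond the NB,
cell-type structure, batch/replicate effects, library-size confounding,
ambient RNA, or spatial correlation (spatial spots are scored identically
to cells, so no spatial model is needed). Passing tests on this
generator demonstrate correctness and identifiability of the method
under its own assumptions, not performance on real tissue data.

## Numerical choices

- Technical-variance floor 1e−8 (prevents division blow-ups).
- Weight normalization to mean 1 over matched genes (see above).
- Gamma-MLE tolerance 1e−10, 200 iterations, convergence flagged.
- wGMT weights serialized with `%.17g` (lossless round trip).
- The scoring path uses no randomness: identical inputs give identical
  outputs up to floating-point associativity.
- Problem sizes in tests and the acceptance script (e.g. 10 simulation
  seeds, 200 random oracle instances, n = 10,000 gamma draws) are chosen
  as the package's own reproducibility budget: large enough for stable
  medians, small enough to run in seconds.

## Known limitations

- Self-calibration makes scores dataset-relative; comparing absolute
  scores across datasets is not meaningful.
- Covariance between signature genes is ignored by design; strongly
  co-regulated noise (e.g. ambient contamination) is not discounted.
- Bonferroni is conservative; at low cell counts true signature genes
  with modest effects are missed (documented above).
- The ligand/receptor comparators require user-supplied mapping tables;
  no database is bundled.
- Cytokine signatures are cell-type-agnostic: one signature per cytokine
  is applied to every cell.
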