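# cytovam

Cell-level cytokine activity estimation for single-cell and spatial
transcriptomics, via signed, weighted variance-adjusted Mahalanobis
(VAM) gene-set scoring.

## The problem

Cytokines are secreted immune signaling proteins; knowing which cytokine
pathways are active in which cells is central to understanding infection
response, autoimmunity and tumor immunology. scRNA-seq measures each
cell's transcriptome, but single-gene readouts (the ligand or receptor
transcript) are sparse, noisy proxies for pathway *activity*. A better
readout is a gene-set score over the transcriptional footprint a cytokine
leaves on responding cells — including the genes it *represses*, not only
the ones it induces.

`cytovam` implements that idea end to end:

1. **Signature construction** (`cytovam.signatures`). From a labeled
   stimulation experiment (one condition per cytokine, optionally a
   vehicle control), each gene is tested per cytokine with a one-vs-rest
   two-sided Wilcoxon rank-sum test. Significant genes (Bonferroni-adjusted
   p < α, default 0.05) are ranked by |avg_log2FC| — the log2 ratio of
   pseudocounted mean de-logged expression, target vs rest — and the top
   *N* (default 60) are split by fold-change sign into an up-regulated
   (positive) set of size n_pos and a down-regulated (negative) set of
   size n_neg, each gene weighted by its |log2FC|.

2. **Scoring** (`cytovam.scoring`). For a target dataset X′ (cells ×
   genes, log-normalized) and each signed set k with matched genes g:

   - per-gene technical variance σ²_tech is estimated from a lowess
     mean-variance trend over all genes;
   - each cell's squared distance from the origin is
     `M[,k] = diag(X_k (I_g σ²_g,tech)⁻¹ X_kᵀ)`, with the |log2FC|
     weights (normalized to mean 1) multiplying each standardized squared
     term — covariances are deliberately ignored so only technical noise
     is discounted, and distances are taken from the origin, which suits
     sparse non-negative expression;
   - a gamma distribution is fitted by maximum likelihood to the
     strictly positive entries of each column of M, and the gamma CDF
     maps distances to scores in [0, 1];
   - the cytokine's activity combines both signed sets:

     ```
     s = n_pos/(n_pos+n_neg) · VAM_pos + n_neg/(n_pos+n_neg) · (1 − VAM_neg)
     ```

3. **Benchmarking** (`cytovam.evaluation`): stratified k-fold
   cross-validation, one-vs-rest AUC-ROC and PR-AUC, the
   closest-to-top-left ROC threshold (min (1−sens)² + (1−spec)²), nine
   confusion metrics, and best-method-proportion summaries, plus simple
   baselines (`cytovam.comparators`): ligand expression, mean receptor
   expression, ligand × receptor product, and unweighted mean-of-set.

4. **Synthetic experiments** (`cytovam.simulate`): a negative-binomial
   stimulation-experiment generator with planted up/down signatures, so
   every stage is testable end to end without external data.

## Worked example

```python
import numpy as np
from cytovam import SimulationConfig, build_signatures, score_signatures
from cytovam.simulate import simulated_labeled_dataset
from cytovam.evaluation import roc_auc_ovr

data, truth = simulated_labeled_dataset(SimulationConfig(seed=42))
sigs = build_signatures(data, num_genes=60, control_label="PBS")
result = score_signatures(data.expr, sigs)   # SignedVAM model -> results
print(result.summary().round(3))

labels = np.asarray(data.labels)
for name in sigs.names:
    auc = roc_auc_ovr(result.scores[name], labels == name)
    print(f"{name}: in-sample one-vs-rest AUC-ROC = {auc:.3f}")
```

prints

```
          n_pos  n_neg  gamma_shape_pos  gamma_rate_pos  gamma_shape_neg  gamma_rate_neg  score_mean  score_max
cytokine
CYT1         20     25           10.692           0.189           13.503           0.231       0.476      0.995
CYT2         20     23            9.975           0.176           11.793           0.217       0.477      0.996
CYT3         22     14            7.841           0.157            5.839           0.195       0.477      0.997
CYT4         20     15            8.538           0.173            6.122           0.198       0.477      0.997
CYT5         20     14            8.749           0.175            6.576           0.223       0.478      0.997
CYT1: in-sample one-vs-rest AUC-ROC = 0.998
...
```

Each row is one cytokine's fitted scoring model on this dataset: the
matched set sizes entering the signed combination, the gamma calibration
parameters for the positive and negative distance columns, and the score
distribution. The AUC lines say that cells actually stimulated with CYT*k*
essentially always outrank unstimulated cells on the CYT*k* score.

The same pipeline is available from the shell:

```
cytovam simulate --out-dir sim/ --seed 4
cytovam build-sets --expr norm.csv --labels sim/labels.tsv --control PBS --out sets.wgmt
cytovam score --expr norm.csv --sets sets.wgmt --out scores.csv --report report.json
cytovam evaluate --expr norm.csv --labels sim/labels.tsv --methods svam,meanset --out metrics.csv
```

Signatures are serialized in a signed, weighted GMT dialect (wGMT): a
`#wgmt1` header, then one TAB-separated set per line —
`IL6  positive  Socs3=1.5  Bcl3=0.9`.

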