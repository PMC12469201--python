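"""Benchmark harness: stratified cross-validation, one-vs-rest ranking
metrics, optimal-threshold binarization and confusion metrics.

Scores are always oriented so that higher means more active; no metric in
this module flips direction automatically.  The PR-AUC estimator is a
step integration over distinct score thresholds (no interpolation in PR
space), pinned so results are reproducible across tool versions.
"""

from __future__ import annotations

import math
import warnings
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, LabeledDataset, SignatureCollection

__all__ = [
    "METRIC_COLUMNS",
    "stratified_kfold",
    "roc_auc_ovr",
    "pr_auc",
    "optimal_threshold",
    "binarize_and_confusion",
    "evaluate_scores",
    "benchmark",
    "best_method_proportions",
    "pairwise_benchmark",
]

#: Columns of the metric table, in reporting order.
METRIC_COLUMNS = [
    "auc_roc",
    "pr_auc",
    "sensitivity",
    "specificity",
    "npv",
    "precision",
    "f1",
    "prevalence",
    "detection_rate",
    "detection_prevalence",
    "balanced_accuracy",
]

#: A scorer maps (trained signatures, test expression) to a cells x
#: cytokines score DataFrame.  Comparators that ignore the signatures
#: still accept them so every method shares one calling convention.
Scorer = Callable[[SignatureCollection, ExpressionMatrix], pd.DataFrame]


def stratified_kfold(labels: Sequence[str], k: int = 5, seed: int = 0) -> np.ndarray:
    """Assign each cell a fold in 1..k, stratified by label.

    Within each label the cells are shuffled (seeded) and dealt round-robin,
    so per-label fold counts differ by at most one.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    folds = np.zeros(labels.size, dtype=int)
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if idx.size < k:
            raise ValueError(f"label {lab!r} has {idx.size} cells, fewer than k={k}")
        perm = rng.permutation(idx)
        folds[perm] = (np.arange(perm.size) % k) + 1
    return folds


def roc_auc_ovr(scores, is_positive) -> float:
    """One-vs-rest AUC-ROC via the Mann-Whitney rank formulation.

    The probability that a random positive outranks a random negative,
    with ties counted one half.  Returns NaN (missing) when either class
    is absent.
    """
    scores = np.asarray(scores, dtype=np.float64)
    pos = np.asarray(is_positive, dtype=bool)
    n_pos = int(pos.sum())
    n_neg = int(pos.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = stats.rankdata(scores, method="average")
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def pr_auc(scores, is_positive) -> float:
    """Area under the precision-recall curve by threshold-step summation.

    Cells are sorted by descending score; at each distinct score value the
    recall increment is multiplied by the precision at that cut and the
    products summed.  With all scores equal this evaluates to the positive
    prevalence.  NaN when there are no positives.
    """
    scores = np.asarray(scores, dtype=np.float64)
    pos = np.asarray(is_positive, dtype=bool)
    n_pos = int(pos.sum())
    if n_pos == 0:
        return float("nan")
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    y = pos[order].astype(np.float64)
    tp = np.cumsum(y)
    fp = np.cumsum(1.0 - y)
    # Keep only the last index of each distinct-score run (the full cut).
    last = np.r_[s[1:] != s[:-1], True]
    tp, fp = tp[last], fp[last]
    recall = tp / n_pos
    precision = tp / (tp + fp)
    d_recall = np.diff(np.r_[0.0, recall])
    return float(np.sum(d_recall * precision))


def optimal_threshold(scores, is_positive) -> tuple[float, float, float]:
    """ROC operating point closest to the top-left corner.

    Minimizes (1 - sensitivity)^2 + (1 - specificity)^2 over every cut:
    midpoints between consecutive distinct scores plus -inf and +inf.
    Ties are broken toward higher specificity, then lower threshold.
    Prediction is strict: positive iff score > threshold.
    """
    scores = np.asarray(scores, dtype=np.float64)
    pos = np.asarray(is_positive, dtype=bool)
    n_pos = int(pos.sum())
    n_neg = int(pos.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    distinct = np.unique(scores)
    cuts = np.concatenate(
        [[-np.inf], (distinct[:-1] + distinct[1:]) / 2.0, [np.inf]]
    )
    best = None
    for t in cuts:
        pred = scores > t
        tp = int(np.sum(pred & pos))
        tn = int(np.sum(~pred & ~pos))
        sens = tp / n_pos
        spec = tn / n_neg
        crit = (1.0 - sens) ** 2 + (1.0 - spec) ** 2
        key = (crit, -spec, t)
        if best is None or key < best[0]:
            best = (key, float(t), sens, spec)
    return best[1], best[2], best[3]


def binarize_and_confusion(scores, is_positive, threshold: float) -> dict[str, float]:
    """Confusion metrics after strict binarization at ``threshold``.

    Predicted positive iff score > threshold.  Ratios with a zero
    denominator are returned as NaN (missing), never as zero.
    """
    scores = np.asarray(scores, dtype=np.float64)
    pos = np.asarray(is_positive, dtype=bool)
    if pos.all() or not pos.any():
        raise ValueError("both classes must be present")
    pred = scores > threshold
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    tn = int(np.sum(~pred & ~pos))
    n = tp + fp + fn + tn

    def ratio(a: int, b: int) -> float:
        return a / b if b else float("nan")

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    prec = ratio(tp, tp + fp)
    npv = ratio(tn, tn + fn)
    if math.isnan(prec) or math.isnan(sens) or (prec + sens) == 0:
        f1 = float("nan")
    else:
        f1 = 2.0 * prec * sens / (prec + sens)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "npv": npv,
        "precision": prec,
        "f1": f1,
        "prevalence": (tp + fn) / n,
        "detection_rate": tp / n,
        "detection_prevalence": (tp + fp) / n,
        "balanced_accuracy": (sens + spec) / 2.0
        if not (math.isnan(sens) or math.isnan(spec))
        else float("nan"),
    }


def evaluate_scores(scores: pd.DataFrame, labels: Sequence[str]) -> pd.DataFrame:
    """All 11 metrics for every cytokine column of a score DataFrame.

    Positives for column c are the cells labeled c.  Columns whose label
    never occurs (or always occurs) in the data yield missing metrics.
    """
    labels = np.asarray(labels)
    rows = []
    for cyt in scores.columns:
        is_pos = labels == cyt
        s = scores[cyt].to_numpy(dtype=np.float64)
        row: dict[str, float] = {m: float("nan") for m in METRIC_COLUMNS}
        row["auc_roc"] = roc_auc_ovr(s, is_pos)
        row["pr_auc"] = pr_auc(s, is_pos)
        if is_pos.any() and not is_pos.all():
            thr, _, _ = optimal_threshold(s, is_pos)
            row.update(binarize_and_confusion(s, is_pos, thr))
        rows.append(pd.Series(row, name=cyt))
    out = pd.DataFrame(rows)
    out.index.name = "cytokine"
    return out[METRIC_COLUMNS]


def best_method_proportions(table: pd.DataFrame) -> pd.DataFrame:
    """Per metric, the fraction of cytokines on which each method is best.

    ``table`` is indexed by (cytokine, method).  Ties at the maximum are
    split fractionally among the tied methods, so each metric's
    proportions sum to 1 over the cytokines with at least one non-missing
    value.
    """
    methods = table.index.get_level_values("method").unique()
    out = pd.DataFrame(0.0, index=METRIC_COLUMNS, columns=methods)
    counts = {m: 0 for m in METRIC_COLUMNS}
    for metric in METRIC_COLUMNS:
        wide = table[metric].unstack("method")
        for _, row in wide.iterrows():
            valid = row.dropna()
            if valid.empty:
                continue
            counts[metric] += 1
            top = valid[valid == valid.max()]
            for m in top.index:
                out.loc[metric, m] += 1.0 / len(top)
    for metric in METRIC_COLUMNS:
        if counts[metric]:
            out.loc[metric] /= counts[metric]
        else:
            out.loc[metric] = float("nan")
    out.index.name = "metric"
    return out


def _subset(data: LabeledDataset, mask: np.ndarray) -> LabeledDataset:
    expr = ExpressionMatrix(
        data.expr.values[mask],
        data.expr.gene_ids,
        [c for c, m in zip(data.expr.cell_ids, mask) if m],
    )
    return LabeledDataset(expr, [l for l, m in zip(data.labels, mask) if m])


def benchmark(
    data: LabeledDataset,
    methods: Mapping[str, Scorer],
    k: int = 5,
    seed: int = 0,
    control_label: str | None = None,
    num_genes: int = 60,
    build_kwargs: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified k-fold benchmark of scoring methods on labeled data.

    Per fold, signatures are built on the training cells only and every
    method scores the held-out cells; all 11 metrics are computed per
    cytokine and method, then averaged over folds (ignoring folds where a
    metric was missing).  Returns the averaged metric table (indexed by
    cytokine, method) and the best-method proportion summary.
    """
    from .signatures import build_signatures

    if len(set(data.labels)) < 2:
        raise ValueError("need at least 2 distinct labels")
    folds = stratified_kfold(data.labels, k=k, seed=seed)
    per_fold: list[pd.DataFrame] = []
    build_kwargs = dict(build_kwargs or {})
    for fold in range(1, k + 1):
        test_mask = folds == fold
        train = _subset(data, ~test_mask)
        test = _subset(data, test_mask)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            sigs = build_signatures(
                train, num_genes=num_genes, control_label=control_label, **build_kwargs
            )
        for method_name, scorer in methods.items():
            scores = scorer(sigs, test.expr)
            metrics = evaluate_scores(scores, test.labels)
            metrics["method"] = method_name
            metrics["fold"] = fold
            per_fold.append(metrics.reset_index())
    long = pd.concat(per_fold, ignore_index=True)
    table = (
        long.groupby(["cytokine", "method"])[METRIC_COLUMNS].mean().sort_index()
    )
    summary = best_method_proportions(table)
    return table, summary


def pairwise_benchmark(
    data: LabeledDataset,
    scorer: Scorer,
    k: int = 5,
    seed: int = 0,
    num_genes: int = 60,
    metric: str = "pr_auc",
) -> pd.DataFrame:
    """One-vs-one discrimination table for a single scoring method.

    For every ordered cytokine pair (a, b), signatures for a are trained
    on the training cells of conditions {a, b} only, the held-out cells of
    those two conditions are scored, and the requested metric for
    detecting a against b is recorded.  Entry (a, b) answers: how well can
    a's signature, trained specifically against b, tell the two apart?
    """
    from .signatures import build_signatures

    names = sorted(set(data.labels))
    folds = stratified_kfold(data.labels, k=k, seed=seed)
    labels = np.asarray(data.labels)
    out = pd.DataFrame(np.nan, index=names, columns=names)
    for a in names:
        for b in names:
            if a == b:
                continue
            vals = []
            for fold in range(1, k + 1):
                pair_mask = (labels == a) | (labels == b)
                train = _subset(data, pair_mask & (folds != fold))
                test = _subset(data, pair_mask & (folds == fold))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", UserWarning)
                    sigs = build_signatures(train, num_genes=num_genes)
                scores = scorer(sigs, test.expr)
                if a not in scores.columns:
                    continue
                m = evaluate_scores(scores[[a]], test.labels).loc[a, metric]
                if not math.isnan(m):
                    vals.append(m)
            if vals:
                out.loc[a, b] = float(np.mean(vals))
    out.index.name = "cytokine"
    return out
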