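"""Construction of signed, weighted cytokine signatures from labeled
stimulation data.

For each stimulation condition the cells of that condition are compared
against all remaining cells (other cytokines plus any vehicle control) with
a two-sided Wilcoxon rank-sum test per gene.  Genes passing the
significance filter are ranked by absolute average log2 fold-change; the
top ``num_genes`` are split by fold-change sign into an up-regulated
(positive) and a down-regulated (negative) set, each gene weighted by its
absolute log2 fold-change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    LabeledDataset,
    Sign,
    SignatureCollection,
    SignedSignature,
    WeightedGeneSet,
)

__all__ = [
    "DEResult",
    "wilcoxon_rank_sum",
    "avg_log2fc",
    "build_signatures",
    "min_abs_log2fc_report",
]


@dataclass(frozen=True)
class DEResult:
    """Differential-expression summary for one gene in one comparison."""

    gene: str
    log2fc: float
    p_value: float
    p_adjusted: float


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the normal approximation with tie correction and continuity
    correction.  Returns ``(U, p)`` where U is the Mann-Whitney statistic
    for ``x``.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        # Degenerate all-tied case: no evidence of a shift.
        return float(x.size * y.size / 2.0), 1.0
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def avg_log2fc(x, y, pseudocount: float = 1.0) -> float:
    """Average log2 fold-change between two groups of log-normalized values.

    Expression is de-logged (``exp(v) - 1``) before averaging, so the ratio
    is taken on the normalized-count scale:

        log2( (mean(expm1(x)) + pc) / (mean(expm1(y)) + pc) )
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    mx = float(np.mean(np.expm1(x))) + pseudocount
    my = float(np.mean(np.expm1(y))) + pseudocount
    return float(np.log2(mx / my))


def _de_one_vs_rest(
    values: np.ndarray,
    target_mask: np.ndarray,
    gene_ids: list[str],
    min_pct: float,
    pseudocount: float,
) -> pd.DataFrame:
    """Gene-wise Wilcoxon + avg_log2fc of target cells vs the rest."""
    xt = values[target_mask]
    xr = values[~target_mask]
    pct_t = (xt > 0).mean(axis=0)
    pct_r = (xr > 0).mean(axis=0)
    tested = np.maximum(pct_t, pct_r) >= min_pct
    n_tested = int(tested.sum())
    pvals = np.full(values.shape[1], np.nan)
    if n_tested:
        sub_t, sub_r = xt[:, tested], xr[:, tested]
        const = np.ptp(np.vstack([sub_t, sub_r]), axis=0) == 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.mannwhitneyu(
                sub_t,
                sub_r,
                alternative="two-sided",
                method="asymptotic",
                use_continuity=True,
                axis=0,
            )
        p_sub = np.where(const, 1.0, res.pvalue)
        pvals[tested] = p_sub
    mean_t = np.expm1(xt).mean(axis=0) + pseudocount
    mean_r = np.expm1(xr).mean(axis=0) + pseudocount
    log2fc = np.log2(mean_t / mean_r)
    p_adj = np.minimum(1.0, pvals * n_tested)
    return pd.DataFrame(
        {
            "gene": gene_ids,
            "log2fc": log2fc,
            "p_value": pvals,
            "p_adjusted": p_adj,
            "tested": tested,
        }
    )


def build_signatures(
    data: LabeledDataset,
    num_genes: int = 60,
    alpha: float = 0.05,
    control_label: str | None = None,
    min_pct: float = 0.0,
    use_adjusted: bool = True,
    pseudocount: float = 1.0,
) -> SignatureCollection:
    """Build per-cytokine signed weighted gene sets by one-vs-rest DE.

    Parameters
    ----------
    data : LabeledDataset
        Log-normalized expression with per-cell condition labels.
    num_genes : int
        Size cap on each cytokine's combined (positive + negative) set.
    alpha : float
        Significance level applied to the (Bonferroni-adjusted, unless
        ``use_adjusted=False``) Wilcoxon p-values.
    control_label : str, optional
        Label of the vehicle condition.  Control cells contribute to every
        "rest" group but get no signature of their own.
    min_pct : float
        Optional pre-filter: a gene is tested only if expressed in at
        least this fraction of cells in either group.
    use_adjusted : bool
        Filter on Bonferroni-adjusted p-values (default) or raw ones.
    pseudocount : float
        Pseudocount in the fold-change on the de-logged scale.

    Notes
    -----
    Ranking is by |log2fc| descending with ties broken by smaller p-value
    and then lexicographic gene id, so the construction is invariant to
    cell and gene order.  Genes with log2fc exactly 0 are discarded.  A
    cytokine for which no gene passes the filter keeps empty sets (with a
    warning); scoring later skips it.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if num_genes < 1:
        raise ValueError("num_genes must be positive")
    labels = np.asarray(data.labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need at least 2 distinct labels")
    small = uniq[counts < 3]
    if small.size:
        raise ValueError(f"conditions with fewer than 3 cells: {list(small)}")
    targets = [u for u in uniq if u != control_label]

    values = data.expr.values
    cytokines: dict[str, SignedSignature] = {}
    prov_frames = []
    for name in targets:
        mask = labels == name
        de = _de_one_vs_rest(values, mask, data.expr.gene_ids, min_pct, pseudocount)
        crit = de["p_adjusted"] if use_adjusted else de["p_value"]
        keep = de[(crit < alpha) & de["tested"] & (de["log2fc"] != 0.0)].copy()
        keep["abs_fc"] = keep["log2fc"].abs()
        keep = keep.sort_values(
            ["abs_fc", "p_value", "gene"], ascending=[False, True, True]
        ).head(num_genes)
        if keep.empty:
            warnings.warn(
                f"no gene passed the alpha={alpha} filter for condition {name!r}; "
                "its signature is empty and will be skipped at scoring time",
                UserWarning,
                stacklevel=2,
            )
        pos = keep[keep["log2fc"] > 0]
        neg = keep[keep["log2fc"] < 0]
        cytokines[name] = SignedSignature(
            WeightedGeneSet(name, Sign.positive, list(pos["gene"]), pos["abs_fc"].to_numpy()),
            WeightedGeneSet(name, Sign.negative, list(neg["gene"]), neg["abs_fc"].to_numpy()),
        )
        prov = keep[["gene", "log2fc", "p_value", "p_adjusted"]].copy()
        prov.insert(0, "cytokine", name)
        prov_frames.append(prov)
    provenance = (
        pd.concat(prov_frames, ignore_index=True)
        if prov_frames
        else pd.DataFrame(columns=["cytokine", "gene", "log2fc", "p_value", "p_adjusted"])
    )
    return SignatureCollection(cytokines, provenance, num_genes_requested=num_genes)


def min_abs_log2fc_report(collection: SignatureCollection) -> pd.Series:
    """Per-cytokine minimum |log2fc| over retained genes.

    This is the effective fold-change selection threshold implied by the
    top-N truncation.  Cytokines with empty signatures are absent from the
    result (reported as missing, never as zero).
    """
    if len(collection) == 0:
        raise ValueError("collection is empty")
    out = {}
    for name, sig in collection.cytokines.items():
        weights = np.concatenate([sig.positive.weights, sig.negative.weights])
        if weights.size:
            out[name] = float(weights.min())
    return pd.Series(out, name="min_abs_log2fc", dtype=float)
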