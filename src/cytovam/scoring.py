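"""Signed, weighted variance-adjusted Mahalanobis (VAM) gene-set scoring.

The scoring scheme turns a cell's expression over a gene set into a score
in [0, 1] in four steps:

1. **Technical variance** sigma^2_tech is estimated per gene from a
   mean-variance trend over all genes (or taken as the total variance, or
   as 1).
2. **Squared adjusted distances**: for set k with matched genes g and
   normalized weights w~ (scaled to mean 1), each cell's squared distance
   from the origin is  M_c = sum_j w~_j x_cj^2 / sigma^2_j.  Unlike a full
   Mahalanobis distance this uses no covariance terms — only technical
   variance is discounted, so coordinated (biological) variation is
   preserved — and the distance is taken from the origin rather than the
   mean, which suits non-negative sparse expression.
3. **Gamma calibration**: a gamma distribution is fitted by maximum
   likelihood to the strictly positive distances of each set; the gamma
   CDF maps distances to [0, 1].
4. **Signed combination**: a cytokine's activity is the set-size-weighted
   average of the positive-set score and one minus the negative-set score,

       s = n_pos/(n_pos+n_neg) * VAM_pos + n_neg/(n_pos+n_neg) * (1 - VAM_neg)

   so cells that look up-regulated on the up genes *and* down-regulated on
   the down genes score highest.

The model/results pair (`SignedVAM` / `SignedVAMResults`) wraps these
steps; `score_signatures` is the one-call functional entry point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .datatypes import (
    ExpressionMatrix,
    ScoreComponent,
    ScoreMatrix,
    SignatureCollection,
    WeightedGeneSet,
)

__all__ = [
    "VARIANCE_FLOOR",
    "TechnicalVariance",
    "GammaFit",
    "estimate_technical_variance",
    "squared_adjusted_distances",
    "fit_gamma_mle",
    "score_gene_set",
    "combine_scores",
    "SignedVAM",
    "SignedVAMResults",
    "score_signatures",
]

#: Floor applied to technical variances so near-constant genes cannot
#: blow up the inverse-variance standardization.
VARIANCE_FLOOR = 1e-8


@dataclass
class TechnicalVariance:
    """Per-gene technical variance estimates."""

    gene_ids: list[str]
    sigma2_tech: np.ndarray
    method: str

    def __post_init__(self) -> None:
        self.sigma2_tech = np.asarray(self.sigma2_tech, dtype=np.float64)
        if self.sigma2_tech.size != len(self.gene_ids):
            raise ValueError("sigma2_tech length must match gene_ids")
        if np.any(self.sigma2_tech < VARIANCE_FLOOR):
            raise ValueError(f"technical variances must be >= {VARIANCE_FLOOR}")

    def for_genes(self, genes: list[str]) -> np.ndarray:
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        return self.sigma2_tech[[idx[g] for g in genes]]


@dataclass(frozen=True)
class GammaFit:
    """Maximum-likelihood gamma fit to the positive distances of one set."""

    shape: float
    rate: float
    n_nonzero: int
    converged: bool


def estimate_technical_variance(
    expr: ExpressionMatrix, method: str = "trend_fit"
) -> TechnicalVariance:
    """Estimate per-gene technical variance from log-normalized expression.

    Methods
    -------
    ``trend_fit``
        Local regression (lowess, frac 0.3) of log10 variance on log10
        mean over expressed genes; the fitted trend value at each gene's
        mean is its technical variance.  Genes far above the trend carry
        biological signal, which this estimate deliberately excludes.
        Requires >= 32 genes with nonzero mean; otherwise falls back to
        ``total_variance`` with a warning.
    ``total_variance``
        Each gene's empirical variance (no decomposition).
    ``unit``
        All ones — plain squared distances.
    """
    if expr.n_genes < 1:
        raise ValueError("need at least one gene")
    if method == "unit":
        return TechnicalVariance(expr.gene_ids, np.ones(expr.n_genes), "unit")
    mu = expr.values.mean(axis=0)
    v = expr.values.var(axis=0, ddof=1) if expr.n_cells > 1 else np.zeros(expr.n_genes)
    if method == "total_variance":
        return TechnicalVariance(
            expr.gene_ids, np.maximum(v, VARIANCE_FLOOR), "total_variance"
        )
    if method != "trend_fit":
        raise ValueError(f"unknown technical-variance method {method!r}")
    usable = (mu > 0) & (v > 0)
    if int((mu > 0).sum()) < 32:
        warnings.warn(
            "fewer than 32 genes with nonzero mean; falling back to total_variance",
            UserWarning,
            stacklevel=2,
        )
        return TechnicalVariance(
            expr.gene_ids, np.maximum(v, VARIANCE_FLOOR), "total_variance"
        )
    log_mu = np.log10(mu[usable])
    log_v = np.log10(v[usable])
    fitted = lowess(log_v, log_mu, frac=0.3, return_sorted=False)
    sigma2 = np.full(expr.n_genes, VARIANCE_FLOOR)
    sigma2[usable] = np.maximum(10.0 ** fitted, VARIANCE_FLOOR)
    return TechnicalVariance(expr.gene_ids, sigma2, "trend_fit")


def squared_adjusted_distances(
    expr: ExpressionMatrix,
    gene_set: WeightedGeneSet,
    tech: TechnicalVariance,
    use_weights: bool = True,
) -> np.ndarray:
    """Per-cell squared origin distances for one signed gene set.

    Only set genes present in the expression matrix contribute; weights of
    the matched genes are rescaled to mean 1 (so the distance scale — and
    hence the gamma-fit regime — matches the unweighted case), and each
    gene's squared expression is standardized by its technical variance:

        M_c = sum_j  w~_j * x_cj^2 / sigma2_j .
    """
    present = set(expr.gene_ids)
    matched = [(g, w) for g, w in zip(gene_set.genes, gene_set.weights) if g in present]
    if not matched:
        raise ValueError(
            f"no gene of set {gene_set.name}/{gene_set.sign.value} is present in the data"
        )
    genes = [g for g, _ in matched]
    w = np.array([wt for _, wt in matched], dtype=np.float64)
    if use_weights:
        w_tilde = w * (len(w) / w.sum())
    else:
        w_tilde = np.ones_like(w)
    gi = expr.gene_index()
    cols = [gi[g] for g in genes]
    x = expr.values[:, cols]
    sigma2 = tech.for_genes(genes)
    return (x * x) @ (w_tilde / sigma2)


def fit_gamma_mle(values, tol: float = 1e-10, max_iter: int = 200) -> GammaFit:
    """Fit a gamma distribution to the strictly positive entries by MLE.

    Solves ln(k) - psi(k) = ln(mean) - mean(ln) by Newton's method from
    the standard closed-form start, falling back to bisection steps when a
    Newton update leaves the feasible region.  Requires at least 3
    positive, non-identical values; otherwise ``converged`` is False and
    downstream scoring falls back to empirical ranks.
    """
    values = np.asarray(values, dtype=np.float64)
    pos = values[values > 0]
    n = int(pos.size)
    if n < 3 or np.all(pos == pos[0]):
        return GammaFit(np.nan, np.nan, n, False)
    mean = float(pos.mean())
    s = float(np.log(mean) - np.mean(np.log(pos)))
    if s <= 0:  # numerically degenerate (essentially equal values)
        return GammaFit(np.nan, np.nan, n, False)
    # Closed-form starting value (method-of-moments-type approximation).
    k = (3.0 - s + np.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    converged = False
    for _ in range(max_iter):
        f = np.log(k) - special.digamma(k) - s
        if abs(f) < tol:
            converged = True
            break
        fp = 1.0 / k - special.polygamma(1, k)
        step = f / fp
        k_new = k - step
        if k_new <= 0:
            k_new = k / 2.0
        k = k_new
    rate = k / mean
    return GammaFit(float(k), float(rate), n, converged)


def score_gene_set(distances, fit: GammaFit) -> np.ndarray:
    """Map per-cell squared distances to [0, 1] scores.

    With a converged gamma fit the score is the gamma CDF of the distance;
    a zero distance scores 0.  Without a usable fit the score is the
    fraction of cells at or below the cell's distance (mean rank for ties,
    divided by the number of cells), again with zeros pinned to 0.
    """
    d = np.asarray(distances, dtype=np.float64)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    if fit.converged:
        scores = stats.gamma.cdf(d, a=fit.shape, scale=1.0 / fit.rate)
    else:
        scores = stats.rankdata(d, method="average") / d.size
    scores = np.asarray(scores, dtype=np.float64)
    scores[d == 0] = 0.0
    return scores


def combine_scores(vam_pos, vam_neg, n_pos: int, n_neg: int):
    """Signed combination of positive- and negative-set scores.

    s = n_pos/(n_pos+n_neg) * vam_pos + n_neg/(n_pos+n_neg) * (1 - vam_neg)

    With an empty negative set this reduces to ``vam_pos`` exactly; with an
    empty positive set, to ``1 - vam_neg``.  Accepts scalars or arrays.
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("set sizes must be non-negative")
    total = n_pos + n_neg
    if total == 0:
        raise ValueError("at least one of n_pos, n_neg must be positive")
    if n_neg == 0:
        return np.asarray(vam_pos, dtype=np.float64) + 0.0
    if n_pos == 0:
        return 1.0 - np.asarray(vam_neg, dtype=np.float64)
    fp = n_pos / total
    fn = n_neg / total
    return fp * np.asarray(vam_pos, dtype=np.float64) + fn * (
        1.0 - np.asarray(vam_neg, dtype=np.float64)
    )


# ---------------------------------------------------------------------------
# Model / results interface


@dataclass
class SignedVAMResults:
    """Fitted scores and diagnostics for one scoring run.

    Attributes
    ----------
    score_matrix : ScoreMatrix
        Cells x cytokines scores for the requested component.
    gamma_fits : dict
        Per cytokine, the ``(positive, negative)`` GammaFit pair (entries
        are None where a side had no matched genes or was not needed).
    matched_sizes : dict
        Per cytokine, the intersected (n_pos, n_neg) used in the signed
        combination.
    skipped : dict
        Cytokines omitted from the score matrix, mapped to the reason.
    tech : TechnicalVariance
        The technical-variance estimates used.
    """

    score_matrix: ScoreMatrix
    gamma_fits: dict[str, tuple[GammaFit | None, GammaFit | None]]
    matched_sizes: dict[str, tuple[int, int]]
    skipped: dict[str, str]
    tech: TechnicalVariance
    component: ScoreComponent

    @property
    def scores(self) -> pd.DataFrame:
        return self.score_matrix.to_dataframe()

    def report(self) -> dict:
        """JSON-serializable run report (skips, matched sizes, gamma fits)."""
        return {
            "component": self.component.value,
            "tech_method": self.tech.method,
            "skipped": dict(self.skipped),
            "cytokines": {
                name: {
                    "n_pos": self.matched_sizes[name][0],
                    "n_neg": self.matched_sizes[name][1],
                    "gamma": [
                        None
                        if f is None
                        else {
                            "shape": None if np.isnan(f.shape) else f.shape,
                            "rate": None if np.isnan(f.rate) else f.rate,
                            "n_nonzero": f.n_nonzero,
                            "converged": f.converged,
                        }
                        for f in self.gamma_fits[name]
                    ],
                }
                for name in self.score_matrix.cytokine_ids
            },
        }

    def summary(self) -> pd.DataFrame:
        """Per-cytokine summary table: matched sizes, gamma parameters,
        score mean/max."""
        rows = []
        df = self.scores
        for name in self.score_matrix.cytokine_ids:
            n_pos, n_neg = self.matched_sizes[name]
            fp, fn = self.gamma_fits[name]
            rows.append(
                {
                    "cytokine": name,
                    "n_pos": n_pos,
                    "n_neg": n_neg,
                    "gamma_shape_pos": fp.shape if fp else np.nan,
                    "gamma_rate_pos": fp.rate if fp else np.nan,
                    "gamma_shape_neg": fn.shape if fn else np.nan,
                    "gamma_rate_neg": fn.rate if fn else np.nan,
                    "score_mean": df[name].mean(),
                    "score_max": df[name].max(),
                }
            )
        return pd.DataFrame(rows).set_index("cytokine")


class SignedVAM:
    """Signed weighted VAM scoring model for one target dataset.

    Parameters
    ----------
    expr : ExpressionMatrix
        Log-normalized target data (cells or spatial spots x genes).
    signatures : SignatureCollection
        Per-cytokine signed weighted gene sets.
    tech_method : {"trend_fit", "total_variance", "unit"}
        Technical-variance estimator.
    use_weights : bool
        Incorporate the |log2fc| gene weights (mean-1 normalized) into the
        distances; with False the scheme reduces to unweighted VAM.

    Calibration is self-contained: the gamma distributions are fitted on
    the same dataset being scored, so scores are relative within the
    dataset, not transferable absolute activities.
    """

    def __init__(
        self,
        expr: ExpressionMatrix,
        signatures: SignatureCollection,
        tech_method: str = "trend_fit",
        use_weights: bool = True,
    ) -> None:
        if len(signatures) == 0:
            raise ValueError("signature collection is empty")
        self.expr = expr
        self.signatures = signatures
        self.use_weights = use_weights
        self.tech = estimate_technical_variance(expr, tech_method)

    def _score_side(self, gene_set: WeightedGeneSet):
        """Distances -> gamma fit -> CDF scores for one signed set, or
        None if no gene matches."""
        present = set(self.expr.gene_ids)
        n_matched = sum(1 for g in gene_set.genes if g in present)
        if n_matched == 0:
            return None, None, 0
        d = squared_adjusted_distances(self.expr, gene_set, self.tech, self.use_weights)
        fit = fit_gamma_mle(d)
        return score_gene_set(d, fit), fit, n_matched

    def fit(self, component: str | ScoreComponent = ScoreComponent.combined) -> SignedVAMResults:
        component = ScoreComponent(component)
        columns: list[str] = []
        col_values: list[np.ndarray] = []
        gamma_fits: dict[str, tuple[GammaFit | None, GammaFit | None]] = {}
        matched: dict[str, tuple[int, int]] = {}
        skipped: dict[str, str] = {}
        for name, sig in self.signatures.cytokines.items():
            s_pos = s_neg = None
            fit_pos = fit_neg = None
            n_pos = n_neg = 0
            if component in (ScoreComponent.combined, ScoreComponent.positive_only):
                s_pos, fit_pos, n_pos = self._score_side(sig.positive)
            if component in (ScoreComponent.combined, ScoreComponent.negative_only):
                s_neg, fit_neg, n_neg = self._score_side(sig.negative)
            if component is ScoreComponent.positive_only:
                if s_pos is None:
                    skipped[name] = "no positive-set gene present in the data"
                    continue
                scores = s_pos
            elif component is ScoreComponent.negative_only:
                if s_neg is None:
                    skipped[name] = "no negative-set gene present in the data"
                    continue
                scores = 1.0 - s_neg
            else:
                if s_pos is None and s_neg is None:
                    skipped[name] = "no signature gene present in the data"
                    continue
                scores = combine_scores(
                    s_pos if s_pos is not None else 0.0,
                    s_neg if s_neg is not None else 0.0,
                    n_pos,
                    n_neg,
                )
            columns.append(name)
            col_values.append(np.asarray(scores, dtype=np.float64))
            gamma_fits[name] = (fit_pos, fit_neg)
            matched[name] = (n_pos, n_neg)
        if not columns:
            raise ValueError(
                "no cytokine could be scored: no signature gene overlaps the data"
            )
        values = np.column_stack(col_values)
        score_matrix = ScoreMatrix(values, list(self.expr.cell_ids), columns, component)
        return SignedVAMResults(score_matrix, gamma_fits, matched, skipped, self.tech, component)


def score_signatures(
    expr: ExpressionMatrix,
    signatures: SignatureCollection,
    component: str | ScoreComponent = ScoreComponent.combined,
    tech_method: str = "trend_fit",
    use_weights: bool = True,
) -> SignedVAMResults:
    """One-call signed VAM scoring (build the model and fit it)."""
    return SignedVAM(expr, signatures, tech_method, use_weights).fit(component)
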