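"""Scoring core: brute-force distance oracle, gamma MLE recovery,
quadrature CDF oracle, signed-combination arithmetic, and pipeline
invariants."""

import numpy as np
import pytest
from scipy import integrate, stats

from cytovam import (
    ExpressionMatrix,
    GammaFit,
    Sign,
    SignatureCollection,
    SignedSignature,
    TechnicalVariance,
    WeightedGeneSet,
    combine_scores,
    estimate_technical_variance,
    fit_gamma_mle,
    score_gene_set,
    score_signatures,
    squared_adjusted_distances,
)
from cytovam.scoring import VARIANCE_FLOOR, SignedVAM


def brute_force_distances(x, weights, sigma2, use_weights=True):
    """Loop implementation of diag(X (I sigma^2)^-1 X^T) with mean-1
    weight normalization."""
    m, g = x.shape
    if use_weights:
        w = np.array(weights) * g / np.sum(weights)
    else:
        w = np.ones(g)
    out = np.zeros(m)
    for c in range(m):
        for j in range(g):
            out[c] += w[j] * x[c, j] ** 2 / sigma2[j]
    return out


def make_expr(values, prefix="g"):
    m, n = values.shape
    return ExpressionMatrix(
        values, [f"{prefix}{j}" for j in range(n)], [f"c{i}" for i in range(m)]
    )


class TestTechnicalVariance:
    def test_unit_method(self, small_expr):
        tech = estimate_technical_variance(small_expr, "unit")
        np.testing.assert_array_equal(tech.sigma2_tech, 1.0)

    def test_total_variance_floors_constant_genes(self):
        values = np.ones((5, 2))
        values[:, 1] = [0, 1, 2, 3, 4]
        tech = estimate_technical_variance(make_expr(values), "total_variance")
        assert tech.sigma2_tech[0] == VARIANCE_FLOOR
        assert tech.sigma2_tech[1] == pytest.approx(np.var(values[:, 1], ddof=1))

    def test_too_few_genes_falls_back_with_warning(self, rng):
        values = rng.gamma(1, 1, size=(30, 10))
        with pytest.warns(UserWarning, match="total_variance"):
            tech = estimate_technical_variance(make_expr(values), "trend_fit")
        assert tech.method == "total_variance"

    def test_trend_fit_recovers_quadratic_mean_variance_curve(self):
        """Genes whose variance is exactly quadratic in the mean: the
        lowess trend should sit within 15% of the generative curve for
        central genes (median over seeded replicates)."""
        errors = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            n_genes, n_cells = 120, 400
            mu = np.linspace(0.2, 3.0, n_genes)
            sd = np.sqrt(0.5 * mu**2)
            values = np.abs(rng.normal(mu, sd, size=(n_cells, n_genes)))
            tech = estimate_technical_variance(make_expr(values), "trend_fit")
            # moment correction: folding |N(mu, sd)| perturbs the variance,
            # so compare against the empirical generative curve instead
            target = values.var(axis=0, ddof=1)
            central = slice(20, 100)
            rel = np.abs(tech.sigma2_tech[central] - target[central]) / target[central]
            errors.append(np.median(rel))
        assert np.median(errors) < 0.15


class TestDistances:
    def test_single_gene_closed_form(self):
        expr = make_expr(np.array([[3.0]]))
        tech = TechnicalVariance(["g0"], np.array([1.0]), "unit")
        gs = WeightedGeneSet("k", Sign.positive, ["g0"], [1.0])
        assert squared_adjusted_distances(expr, gs, tech)[0] == pytest.approx(9.0)

    def test_all_zero_cell_has_zero_distance(self, rng):
        values = rng.gamma(1, 1, size=(4, 3))
        values[2] = 0.0
        expr = make_expr(values)
        tech = estimate_technical_variance(expr, "total_variance")
        gs = WeightedGeneSet("k", Sign.positive, ["g0", "g2"], [1.0, 2.0])
        d = squared_adjusted_distances(expr, gs, tech)
        assert d[2] == 0.0

    @pytest.mark.parametrize("use_weights", [True, False])
    def test_matches_brute_force_oracle(self, rng, use_weights):
        for _ in range(50):
            m = int(rng.integers(1, 11))
            g = int(rng.integers(1, 7))
            x = rng.gamma(1, 1, size=(m, g)) * rng.integers(0, 2, size=(m, g))
            w = rng.uniform(0.1, 3.0, size=g)
            sigma2 = rng.uniform(0.05, 2.0, size=g)
            expr = make_expr(x)
            tech = TechnicalVariance(expr.gene_ids, sigma2, "unit")
            gs = WeightedGeneSet("k", Sign.positive, expr.gene_ids, w)
            d = squared_adjusted_distances(expr, gs, tech, use_weights=use_weights)
            np.testing.assert_allclose(
                d, brute_force_distances(x, w, sigma2, use_weights), atol=1e-10
            )

    def test_no_matching_gene_is_an_error(self, small_expr):
        tech = estimate_technical_variance(small_expr, "unit")
        gs = WeightedGeneSet("k", Sign.positive, ["absent"], [1.0])
        with pytest.raises(ValueError, match="no gene"):
            squared_adjusted_distances(small_expr, gs, tech)

    def test_gene_order_within_set_is_irrelevant(self, small_expr, rng):
        tech = estimate_technical_variance(small_expr, "total_variance")
        genes = list(small_expr.gene_ids[:5])
        w = rng.uniform(0.5, 2.0, size=5)
        d1 = squared_adjusted_distances(
            small_expr, WeightedGeneSet("k", Sign.positive, genes, w), tech
        )
        perm = rng.permutation(5)
        d2 = squared_adjusted_distances(
            small_expr,
            WeightedGeneSet("k", Sign.positive, [genes[i] for i in perm], w[perm]),
            tech,
        )
        np.testing.assert_allclose(d1, d2, atol=1e-12)


class TestGammaMLE:
    @pytest.mark.parametrize("shape", [1.0, 2.0, 5.0])
    def test_shape_recovery_at_large_n(self, shape):
        # median over seeded replicates: a single n=10,000 draw has shape-
        # estimate SD up to ~0.07 at shape 5, so one seed is a coin toss
        # near the band edge while the median is a stable consistency check
        errors = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            fit = fit_gamma_mle(rng.gamma(shape, 1.0, size=10_000))
            assert fit.converged
            errors.append(abs(fit.shape - shape))
        assert np.median(errors) < 0.1

    def test_agrees_with_scipy_mle(self, rng):
        draws = rng.gamma(3.0, 0.5, size=2000)
        fit = fit_gamma_mle(draws)
        a, _, scale = stats.gamma.fit(draws, floc=0)
        assert fit.shape == pytest.approx(a, rel=1e-5)
        assert 1.0 / fit.rate == pytest.approx(scale, rel=1e-5)

    def test_degenerate_inputs_do_not_converge(self):
        assert not fit_gamma_mle(np.array([2.0, 2.0])).converged
        assert not fit_gamma_mle(np.array([1.0, 1.0, 1.0, 1.0])).converged
        assert not fit_gamma_mle(np.array([0.0, 0.0, 1.0])).converged

    def test_zeros_are_excluded_from_the_fit(self, rng):
        draws = rng.gamma(2.0, 1.0, size=5000)
        with_zeros = np.concatenate([draws, np.zeros(1000)])
        f1, f2 = fit_gamma_mle(draws), fit_gamma_mle(with_zeros)
        assert f1.shape == pytest.approx(f2.shape)
        assert f2.n_nonzero == 5000


class TestScoreGeneSet:
    def test_zero_distance_scores_zero(self):
        fit = GammaFit(2.0, 1.0, 10, True)
        assert score_gene_set(np.array([0.0, 1.0]), fit)[0] == 0.0

    def test_median_distance_scores_half(self):
        fit = GammaFit(2.0, 1.5, 10, True)
        med = stats.gamma.ppf(0.5, a=2.0, scale=1 / 1.5)
        assert score_gene_set(np.array([med]), fit)[0] == pytest.approx(0.5, abs=1e-9)

    def test_matches_quadrature_cdf_oracle(self, rng):
        shape, rate = 2.7, 0.8
        fit = GammaFit(shape, rate, 100, True)
        d = rng.gamma(shape, 1 / rate, size=20)
        scores = score_gene_set(d, fit)
        pdf = lambda t: stats.gamma.pdf(t, a=shape, scale=1 / rate)
        for di, si in zip(d, scores):
            quad, _ = integrate.quad(pdf, 0, di, limit=200)
            assert si == pytest.approx(quad, abs=1e-8)

    def test_rank_fallback_when_fit_failed(self):
        fit = GammaFit(np.nan, np.nan, 2, False)
        d = np.array([0.0, 1.0, 2.0, 2.0, 5.0])
        scores = score_gene_set(d, fit)
        assert scores[0] == 0.0
        # mean rank for the tie at 2.0: ranks (1,2,3.5,3.5,5)/5
        np.testing.assert_allclose(scores[1:], [2 / 5, 3.5 / 5, 3.5 / 5, 1.0])


class TestCombineScores:
    @pytest.mark.parametrize(
        "vp,vn,npos,nneg,expected",
        [
            (0.8, 0.2, 30, 30, 0.8),
            (0.9, 0.123, 40, 0, 0.9),
            (0.9, 0.3, 40, 20, (2 / 3) * 0.9 + (1 / 3) * 0.7),
            (0.4, 0.4, 0, 10, 0.6),
        ],
    )
    def test_forced_arithmetic(self, vp, vn, npos, nneg, expected):
        assert combine_scores(vp, vn, npos, nneg) == pytest.approx(expected)

    def test_both_empty_is_an_error(self):
        with pytest.raises(ValueError, match="n_pos"):
            combine_scores(0.5, 0.5, 0, 0)

    def test_convex_combination_grid_stays_in_unit_interval(self):
        grid = np.linspace(0, 1, 5)
        for vp in grid:
            for vn in grid:
                for npos, nneg in [(1, 0), (0, 1), (30, 30), (40, 20)]:
                    s = combine_scores(vp, vn, npos, nneg)
                    assert 0.0 <= s <= 1.0
                    if nneg == 0:
                        assert s == vp


def collection_from_sets(sets):
    cytokines = {}
    for name, (pos_genes, pos_w, neg_genes, neg_w) in sets.items():
        cytokines[name] = SignedSignature(
            WeightedGeneSet(name, Sign.positive, pos_genes, pos_w),
            WeightedGeneSet(name, Sign.negative, neg_genes, neg_w),
        )
    return SignatureCollection(cytokines, num_genes_requested=60)


class TestPipeline:
    def test_absent_sets_are_reported_not_scored(self, small_expr):
        sets = collection_from_sets(
            {
                "hit": (["g0", "g1"], [1.0, 2.0], ["g2"], [0.5]),
                "miss": (["zz1"], [1.0], ["zz2"], [1.0]),
            }
        )
        res = score_signatures(small_expr, sets, tech_method="total_variance")
        assert res.score_matrix.cytokine_ids == ["hit"]
        assert "miss" in res.skipped

    def test_all_sets_absent_is_a_hard_error(self, small_expr):
        sets = collection_from_sets({"miss": (["zz"], [1.0], [], [])})
        with pytest.raises(ValueError, match="no cytokine"):
            score_signatures(small_expr, sets)

    def test_positive_only_equals_forced_empty_negative(self, default_sim):
        data, _ = default_sim
        from cytovam import build_signatures

        sigs = build_signatures(data, control_label="PBS")
        pos_only = score_signatures(data.expr, sigs, component="positive_only")
        stripped = collection_from_sets(
            {
                n: (sigs[n].positive.genes, sigs[n].positive.weights, [], [])
                for n in sigs.names
                if len(sigs[n].positive)
            }
        )
        combined = score_signatures(data.expr, stripped, component="combined")
        shared = [c for c in pos_only.scores.columns if c in combined.scores.columns]
        np.testing.assert_allclose(
            pos_only.scores[shared].to_numpy(),
            combined.scores[shared].to_numpy(),
            atol=1e-12,
        )

    def test_scores_lie_in_unit_interval_and_combined_is_convex(self, default_sim):
        data, _ = default_sim
        from cytovam import build_signatures

        sigs = build_signatures(data, control_label="PBS")
        model = SignedVAM(data.expr, sigs)
        combined = model.fit("combined").scores
        pos = model.fit("positive_only").scores
        neg = model.fit("negative_only").scores
        assert ((combined.to_numpy() >= 0) & (combined.to_numpy() <= 1)).all()
        for name in combined.columns:
            n_pos = len([g for g in sigs[name].positive.genes if g in data.expr.gene_ids])
            n_neg = len([g for g in sigs[name].negative.genes if g in data.expr.gene_ids])
            vp = pos[name].to_numpy() if name in pos.columns else np.zeros(len(combined))
            vn = neg[name].to_numpy() if name in neg.columns else np.zeros(len(combined))
            if n_pos and n_neg:
                expected = (n_pos * vp + n_neg * vn) / (n_pos + n_neg)
                np.testing.assert_allclose(combined[name].to_numpy(), expected, atol=1e-12)

    def test_monotone_in_expression(self, rng):
        """Raising one in-set gene in one cell strictly raises that cell's
        distance and weakly raises its positive-set score, with the gamma
        fit and variances held fixed."""
        values = rng.gamma(1.5, 1.0, size=(30, 6))
        expr = make_expr(values)
        tech = estimate_technical_variance(expr, "total_variance")
        gs = WeightedGeneSet("k", Sign.positive, ["g0", "g3"], [1.0, 2.0])
        d0 = squared_adjusted_distances(expr, gs, tech)
        fit = fit_gamma_mle(d0)
        bumped = values.copy()
        bumped[4, 3] += 1.0
        d1 = squared_adjusted_distances(make_expr(bumped), gs, tech)
        assert d1[4] > d0[4]
        assert np.all(np.delete(d1, 4) == np.delete(d0, 4))
        s0, s1 = score_gene_set(d0, fit), score_gene_set(d1, fit)
        assert s1[4] >= s0[4]

    def test_unweighted_unit_variance_reduces_to_sum_of_squares(self, rng):
        values = rng.gamma(1, 1, size=(5, 5))
        expr = make_expr(values)
        tech = TechnicalVariance(expr.gene_ids, np.ones(5), "unit")
        gs = WeightedGeneSet("k", Sign.positive, expr.gene_ids, rng.uniform(0.5, 2, 5))
        d = squared_adjusted_distances(expr, gs, tech, use_weights=False)
        np.testing.assert_allclose(d, (values**2).sum(axis=1), atol=1e-12)

    def test_deterministic_rerun(self, default_sim):
        data, _ = default_sim
        from cytovam import build_signatures

        sigs = build_signatures(data, control_label="PBS")
        r1 = score_signatures(data.expr, sigs)
        r2 = score_signatures(data.expr, sigs)
        np.testing.assert_array_equal(
            r1.score_matrix.values, r2.score_matrix.values
        )

    def test_results_report_and_summary_are_well_formed(self, default_sim):
        import json

        data, _ = default_sim
        from cytovam import build_signatures

        sigs = build_signatures(data, control_label="PBS")
        res = score_signatures(data.expr, sigs)
        report = res.report()
        json.dumps(report)  # serializable
        assert report["component"] == "combined"
        summary = res.summary()
        assert set(summary.index) == set(res.score_matrix.cytokine_ids)
        assert (summary["score_max"] <= 1.0).all()
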