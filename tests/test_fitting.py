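"""Least-squares fitting, ANOVA partitioning, order selection, backward elimination."""

import numpy as np
import pytest

import mixamount as mx
from mixamount.fitting import anova, backward_eliminate, fit, r2_stats, select_model_order

from conftest import make_small_design


class TestFit:
    def test_exact_interpolation(self, paper_design, paper_config):
        truth = paper_config.truths["larval_weight_mg"].model
        y = truth.predict(paper_design.proportions, paper_design.amounts)
        f = fit(paper_design, y, mx.enumerate_terms(5, 2, 1))
        est = dict(zip(f.terms, f.coef))
        for t, c in zip(truth.terms, truth.coef):
            assert est[t] == pytest.approx(c, abs=1e-8)
        stats = r2_stats(f)
        assert stats.r2 == pytest.approx(1.0, abs=1e-12)
        assert anova(f).row("Lack of Fit").ss == pytest.approx(0.0, abs=1e-16)

    def test_constant_response(self, small_design):
        terms = mx.enumerate_terms(3, 2, 1)
        y = np.full(small_design.n, 7.5)
        f = fit(small_design, y, terms)
        for t, c in zip(f.terms, f.coef):
            expected = 7.5 if t.is_linear_mixture else 0.0
            assert c == pytest.approx(expected, abs=1e-7)

    def test_residuals_orthogonal_to_model(self, small_design):
        rng = np.random.default_rng(3)
        y = rng.normal(size=small_design.n)
        f = fit(small_design, y, mx.enumerate_terms(3, 1, 1))
        np.testing.assert_allclose(f.W.T @ f.residuals, 0.0, atol=1e-8)
        np.testing.assert_allclose(f.hat.sum(), f.n_params, atol=1e-8)
        assert f.block_effects.sum() == pytest.approx(0.0, abs=1e-10)

    def test_matches_statsmodels(self, small_design):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(5)
        y = rng.normal(size=small_design.n) + 2 * small_design.proportions[:, 0]
        terms = mx.enumerate_terms(3, 1, 1)
        f = fit(small_design, y, terms)
        res = sm.OLS(y, f.W).fit()
        np.testing.assert_allclose(f.beta_full, res.params, atol=1e-10)
        np.testing.assert_allclose(f.se, res.bse[: len(terms)], atol=1e-10)
        np.testing.assert_allclose(f.sigma2, res.mse_resid, atol=1e-10)

    def test_rank_deficiency_names_columns(self, small_design):
        terms = mx.enumerate_terms(3, 1, 0)
        dup = terms + [terms[0]]  # aliased duplicate column
        with pytest.raises(mx.InestimableError, match="aliased"):
            fit(small_design, np.zeros(small_design.n), dup)

    def test_length_mismatch_rejected(self, small_design):
        with pytest.raises(ValueError):
            fit(small_design, np.zeros(3), mx.enumerate_terms(3, 1, 0))


class TestAnova:
    def test_partial_f_equals_t_squared(self, small_design):
        rng = np.random.default_rng(9)
        y = rng.normal(size=small_design.n)
        f = fit(small_design, y, mx.enumerate_terms(3, 2, 1))
        tab = anova(f)
        coefs = f.coef_table()
        for _, row in coefs.iterrows():
            try:
                arow = tab.row(row["term"])
            except KeyError:
                continue  # linear mixture terms have no per-term row
            assert arow.F == pytest.approx(row["t"] ** 2, rel=1e-8)

    def test_linear_mixture_ss_bounded_by_model_ss(self, small_design):
        rng = np.random.default_rng(13)
        for _ in range(10):
            y = rng.normal(size=small_design.n)
            tab = anova(fit(small_design, y, mx.enumerate_terms(3, 2, 1)))
            assert tab.row("Model").ss >= tab.row("Linear Mixture").ss >= 0

    def test_paper_df_skeleton(self, paper_design, paper_config):
        rng = np.random.default_rng(2)
        truth = paper_config.truths["larval_weight_mg"]
        y = mx.simulate_continuous(paper_design, truth.model, 2.0, 1.0, seed=4)
        tab = anova(fit(paper_design, y, mx.enumerate_terms(5, 2, 2)))
        assert tab.row("Model").df == 44
        assert tab.row("Lack of Fit").df == 6
        assert tab.row("Pure Error").df == 45

    def test_sequential_ss_non_decreasing(self, paper_design):
        rng = np.random.default_rng(21)
        y = rng.normal(size=paper_design.n)
        prev_ss = -1.0
        for m, d in [(1, 1), (2, 1), (2, 2)]:
            tab = anova(fit(paper_design, y, mx.enumerate_terms(5, m, d)))
            assert tab.row("Model").ss >= prev_ss - 1e-10
            prev_ss = tab.row("Model").ss

    def test_no_pure_error_flagged(self):
        d = make_small_design(seed=10, n_unique=10, n_dup=0, n_blocks=1, q=3)
        y = np.random.default_rng(0).normal(size=d.n)
        tab = anova(fit(d, y, mx.enumerate_terms(3, 1, 1)))
        assert not tab.lof_available


class TestR2:
    def test_press_matches_brute_force_loo(self, small_design):
        rng = np.random.default_rng(17)
        y = rng.normal(size=small_design.n)
        f = fit(small_design, y, mx.enumerate_terms(3, 1, 1))
        press = 0.0
        for i in range(f.n):
            keep = [j for j in range(f.n) if j != i]
            b = np.linalg.lstsq(f.W[keep], y[keep], rcond=None)[0]
            press += (y[i] - f.W[i] @ b) ** 2
        assert r2_stats(f).press == pytest.approx(press, abs=1e-8)

    def test_ordering_pred_adj_r2(self):
        rng = np.random.default_rng(23)
        for k in range(30):
            d = make_small_design(seed=int(rng.integers(10**6)), n_unique=14, n_dup=3)
            y = rng.normal(size=d.n)
            s = r2_stats(fit(d, y, mx.enumerate_terms(3, 1, 1)))
            assert s.pred_r2 <= s.adj_r2 + 1e-10 <= s.r2 + 1e-10


class TestOrderSelection:
    def test_strong_quadratic_by_linear_truth_chosen(self, paper_design, paper_config):
        truth = paper_config.truths["larval_weight_mg"].model
        hits = 0
        reps = 40
        for r in range(reps):
            y = mx.simulate_continuous(paper_design, truth, 0.5, 0.0, seed=100 + r)
            sel = select_model_order(paper_design, y)
            hits += (sel.chosen.mixture_order, sel.chosen.amount_order) == (2, 1)
        assert hits / reps >= 0.95

    def test_pure_linear_truth_stays_linear(self, paper_design):
        space, factor = paper_design.space, paper_design.factor
        truth = mx.SurfaceModel.from_labeled(
            space, factor, {((i,), 0): v for i, v in enumerate([10, 12, 14, 11, 13])}
        )
        higher = 0
        reps = 40
        for r in range(reps):
            y = mx.simulate_continuous(paper_design, truth, 1.0, 0.0, seed=300 + r)
            sel = select_model_order(paper_design, y)
            higher += sel.chosen.mixture_order > 1
        # added quadratic terms are pure noise: chosen above linear at ~alpha rate
        assert higher / reps <= 0.20


class TestBackwardElimination:
    def test_alpha_out_one_is_identity(self, paper_design):
        y = np.random.default_rng(31).normal(size=paper_design.n)
        f = fit(paper_design, y, mx.enumerate_terms(5, 2, 1))
        red, removed = backward_eliminate(f, alpha_out=1.0)
        assert removed == []
        assert red.terms == f.terms

    def test_null_interactions_reduce_to_linear_mixture(self, paper_design):
        space, factor = paper_design.space, paper_design.factor
        truth = mx.SurfaceModel.from_labeled(
            space, factor, {((i,), 0): v for i, v in enumerate([10, 12, 14, 11, 13])}
        )
        kept_noise = 0
        reps = 30
        n_noise = len(mx.enumerate_terms(5, 2, 1)) - 5
        for r in range(reps):
            y = mx.simulate_continuous(paper_design, truth, 0.5, 0.0, seed=500 + r)
            f = fit(paper_design, y, mx.enumerate_terms(5, 2, 1))
            red, _ = backward_eliminate(f, alpha_out=0.10)
            kept_noise += sum(1 for t in red.terms if not t.is_linear_mixture)
        # elimination keeps each true-zero term at roughly the alpha_out rate
        assert kept_noise / (reps * n_noise) <= 0.2

    def test_linear_mixture_never_removed(self, paper_design):
        y = np.random.default_rng(37).normal(size=paper_design.n)
        f = fit(paper_design, y, mx.enumerate_terms(5, 2, 1))
        red, _ = backward_eliminate(f, alpha_out=0.001)
        kept_linear = [t for t in red.terms if t.is_linear_mixture]
        assert len(kept_linear) == 5


class TestCoefficientRecovery:
    def test_true_model_ci_coverage(self, paper_design, paper_config):
        """Fitting the true term set at dish noise 2 mg covers each true
        coefficient with its 95% CI in >= 90% of seeded replicates."""
        truth = paper_config.truths["larval_weight_mg"]
        terms = truth.model.terms
        reps = 200
        covered = np.zeros(len(terms))
        for r in range(reps):
            # dish noise only: with random block effects the surface level is
            # identified only up to the mean sampled block effect
            y = mx.simulate_continuous(paper_design, truth.model, 2.0, 0.0, seed=700 + r)
            f = fit(paper_design, y, terms)
            ci = f.confint(0.95)
            covered += (ci[:, 0] <= truth.model.coef) & (truth.model.coef <= ci[:, 1])
        assert (covered / reps >= 0.90).all()
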