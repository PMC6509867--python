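"""Elastic-net path, selection counting and the cutoff rule.

Oracles are independent of the implementation path: a bound-constrained
L-BFGS-B solve of the split-positive reformulation for the penalized
objective, the closed-form ridge solution, a 1-D grid search for the
single-feature lasso, and naive double-loop recounts for selection counts.
"""

import numpy as np
import pytest
from scipy.optimize import minimize

from stagewise.stagesel import (
    CoefficientPath,
    ElasticNetConfig,
    count_selections,
    fit_path,
    lambda_max,
    objective,
    run_summary,
    select_stage_genes,
)

from conftest import random_regression


def reference_minimum(X, y, lam, alpha_mix, restarts=3, seed=0):
    """Long-run reference minimization of the penalized objective.

    Splits beta = u - v with u, v >= 0, making the L1 term linear and the
    problem smooth; solves with L-BFGS-B from several starts.
    """
    m, n = X.shape

    def fun(z):
        u, v = z[:n], z[n:]
        beta = u - v
        r = y - X @ beta
        return (r @ r) / m + lam * (alpha_mix * (u + v).sum() + (1 - alpha_mix) * (beta @ beta))

    def grad(z):
        u, v = z[:n], z[n:]
        beta = u - v
        g_ls = -2.0 / m * (X.T @ (y - X @ beta))
        g_ridge = 2.0 * lam * (1 - alpha_mix) * beta
        gu = g_ls + g_ridge + lam * alpha_mix
        gv = -g_ls - g_ridge + lam * alpha_mix
        return np.concatenate([gu, gv])

    rng = np.random.default_rng(seed)
    best = np.inf
    best_beta = np.zeros(n)
    starts = [np.zeros(2 * n)] + [np.abs(rng.normal(size=2 * n)) for _ in range(restarts)]
    for z0 in starts:
        res = minimize(fun, z0, jac=grad, method="L-BFGS-B",
                       bounds=[(0, None)] * 2 * n,
                       options={"maxiter": 20000, "ftol": 1e-14, "gtol": 1e-12})
        if res.fun < best:
            best = res.fun
            best_beta = res.x[:n] - res.x[n:]
    return best, best_beta


class TestFitPath:
    def test_all_zero_at_lambda_max(self):
        rng = np.random.default_rng(0)
        X, y = random_regression(rng, 30, 8)
        cfg = ElasticNetConfig(n_models=10, cutoff=5)
        path = fit_path(X, y, cfg)
        assert np.allclose(path.betas[0], 0.0, atol=1e-10)
        assert np.all(np.diff(path.lambdas) < 0)
        assert path.n_models == 10

    def test_objective_matches_reference_minimizer(self):
        """Returned beta achieves the penalized objective of a long-run
        independent minimization to within 1e-6, across random instances."""
        rng = np.random.default_rng(42)
        worst = 0.0
        for trial in range(6):
            m = int(rng.integers(20, 50))
            n = int(rng.integers(5, 20))
            X, y = random_regression(rng, m, n)
            cfg = ElasticNetConfig(n_models=5, cutoff=3, tol=1e-12)
            path = fit_path(X, y, cfg)
            for i in (1, 3, 4):
                ref, _ = reference_minimum(X, y, path.lambdas[i], cfg.alpha_mix, seed=trial)
                gap = path.objective[i] - ref
                worst = max(worst, gap)
                assert gap < 1e-6, f"trial {trial}, path point {i}: gap {gap}"
        assert worst < 1e-6

    def test_single_feature_pure_lasso_soft_threshold(self):
        """alpha_mix=1, one standardized column: solution equals the
        soft-thresholded projection, cross-checked by 1-D grid search."""
        rng = np.random.default_rng(7)
        m = 40
        x = rng.normal(size=m)
        x = (x - x.mean()) / x.std()
        y = 0.8 * x + rng.normal(scale=0.3, size=m)
        cfg = ElasticNetConfig(alpha_mix=1.0, n_models=8, cutoff=4, tol=1e-12)
        path = fit_path(x[:, None], y, cfg)
        for lam, beta in zip(path.lambdas[1:], path.betas[1:, 0]):
            rho = x @ y / m
            expected = np.sign(rho) * max(abs(rho) - lam / 2, 0.0)
            assert beta == pytest.approx(expected, abs=1e-6)
            # 1-D grid search over the objective confirms the minimizer
            grid = np.linspace(beta - 0.05, beta + 0.05, 2001)
            objs = [objective(x[:, None], y, np.array([b]), lam, 1.0) for b in grid]
            assert abs(grid[int(np.argmin(objs))] - beta) < 1e-4

    def test_ridge_limit_closed_form(self):
        """alpha_mix -> 0 on a full-rank problem approaches the closed-form
        ridge solution (X'X/m + lam*I) beta = X'y/m."""
        rng = np.random.default_rng(3)
        X, y = random_regression(rng, 50, 6)
        mix = 1e-6
        cfg = ElasticNetConfig(alpha_mix=mix, n_models=4, cutoff=2, tol=1e-14)
        path = fit_path(X, y, cfg)
        m, n = X.shape
        for lam, beta in zip(path.lambdas[2:], path.betas[2:]):
            lam_ridge = lam * (1 - mix)
            closed = np.linalg.solve(X.T @ X / m + lam_ridge * np.eye(n), X.T @ y / m)
            assert np.max(np.abs(beta - closed)) < 1e-4

    def test_orthogonal_label_gives_zero_path(self):
        """y orthogonal to every column: beta stays 0 along the path."""
        X = np.kron(np.eye(2), np.ones(2)).T  # columns constant within halves
        X = (X - X.mean(axis=0)) / X.std(axis=0)
        y = np.array([1.0, -1.0, 1.0, -1.0])  # orthogonal to both columns
        assert np.allclose(X.T @ y, 0)
        path = fit_path(X, y + 1, ElasticNetConfig(n_models=5, cutoff=3))  # +1 keeps y non-constant
        assert np.allclose(path.betas, 0.0, atol=1e-10)

    def test_constant_label_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(ValueError, match="degenerate label"):
            fit_path(X, np.ones(10), ElasticNetConfig())

    def test_lambda_max_kkt_bound(self):
        rng = np.random.default_rng(1)
        X, y = random_regression(rng, 30, 5)
        lam = lambda_max(X, y, 0.5)
        # at any lambda above the bound the zero vector beats tiny perturbations
        base = objective(X, y, np.zeros(5), lam * 1.01, 0.5)
        for j in range(5):
            for eps in (1e-4, -1e-4):
                b = np.zeros(5)
                b[j] = eps
                assert objective(X, y, b, lam * 1.01, 0.5) >= base - 1e-12


class TestCountSelections:
    @staticmethod
    def random_path(rng, n_models=10, n_cols=8):
        betas = rng.normal(size=(n_models, n_cols)) * (rng.random((n_models, n_cols)) < 0.4)
        lambdas = np.geomspace(1, 0.01, n_models)
        return CoefficientPath(lambdas=lambdas, betas=betas, objective=np.zeros(n_models))

    def test_matches_naive_double_loop(self):
        """Vectorized counts equal a brute-force loop over (model, column)."""
        rng = np.random.default_rng(5)
        genes = ["g1", "g1", "g2", "g3", "g3", "g3", "g4", "g5"]
        for _ in range(20):
            path = self.random_path(rng)
            cfg = ElasticNetConfig(n_models=10, cutoff=4, coef_threshold=0.3)
            prof = count_selections(path, genes, cfg)
            naive = {g: 0 for g in set(genes)}
            for i in range(path.n_models):
                hit = set()
                for j, g in enumerate(genes):
                    if abs(path.betas[i, j]) > cfg.coef_threshold:
                        hit.add(g)
                for g in hit:
                    naive[g] += 1
            assert prof.counts == naive
            assert prof.selected == {g for g, c in naive.items() if c >= cfg.cutoff}

    def test_union_not_sum_across_a_genes_columns(self):
        """Expression and methylation columns active in the same model count once."""
        betas = np.zeros((5, 2))
        betas[:3, 0] = 1.0  # expression column active in models 0-2
        betas[:3, 1] = -1.0  # methylation column active in the same models
        path = CoefficientPath(np.geomspace(1, 0.1, 5), betas, np.zeros(5))
        prof = count_selections(path, ["gA", "gA"], ElasticNetConfig(n_models=5, cutoff=3))
        assert prof.counts["gA"] == 3
        assert prof.selected == {"gA"}

    def test_zero_coefficients_never_selected(self):
        path = CoefficientPath(np.geomspace(1, 0.1, 4), np.zeros((4, 2)), np.zeros(4))
        prof = count_selections(path, ["a", "b"], ElasticNetConfig(n_models=4, cutoff=1))
        assert prof.counts == {"a": 0, "b": 0}
        assert prof.selected == set()

    def test_threshold_monotonicity(self):
        """Lowering the coefficient threshold never decreases any count."""
        rng = np.random.default_rng(9)
        path = self.random_path(rng)
        genes = list("aabbccdd")
        hi = count_selections(path, genes, ElasticNetConfig(n_models=10, coef_threshold=1e-2, cutoff=1))
        lo = count_selections(path, genes, ElasticNetConfig(n_models=10, coef_threshold=1e-8, cutoff=1))
        assert all(lo.counts[g] >= hi.counts[g] for g in hi.counts)

    def test_selected_sets_nested_in_cutoff(self):
        rng = np.random.default_rng(13)
        path = self.random_path(rng, n_models=12)
        genes = list("aabbccdd")
        prev = None
        for cutoff in range(1, 13):
            cfg = ElasticNetConfig(n_models=12, cutoff=cutoff, coef_threshold=0.2)
            sel = count_selections(path, genes, cfg).selected
            if prev is not None:
                assert sel <= prev
            prev = sel


class TestSelectStageGenes:
    def test_unsatisfiable_cutoff_empties_selection(self, small_features):
        X, labels = small_features
        cfg = ElasticNetConfig(n_models=5, cutoff=6)
        profiles = select_stage_genes(X, labels, cfg)
        assert all(p.selected == set() for p in profiles.values())

    def test_planted_gene_recovery(self, small_features, small_world):
        """Default config recovers planted genes with high recall/precision."""
        X, labels = small_features
        truth = small_world["truth"]
        profiles = select_stage_genes(X, labels, ElasticNetConfig())
        recalls, precisions = [], []
        for st, prof in profiles.items():
            planted = truth.planted_genes[st]
            tp = len(prof.selected & planted)
            recalls.append(tp / len(planted))
            precisions.append(tp / max(len(prof.selected), 1))
        assert np.mean(recalls) >= 0.8
        assert np.mean(precisions) >= 0.6

    def test_determinism(self, small_features):
        X, labels = small_features
        cfg = ElasticNetConfig(n_models=10, cutoff=5)
        p1 = select_stage_genes(X, labels, cfg)
        p2 = select_stage_genes(X, labels, cfg)
        assert {s: p.counts for s, p in p1.items()} == {s: p.counts for s, p in p2.items()}

    def test_run_summary_schema(self, small_features):
        X, labels = small_features
        profiles = select_stage_genes(X, labels, ElasticNetConfig(n_models=8, cutoff=4))
        table = run_summary(profiles)
        assert list(table.columns) == ["stage", "models", "max_genes_detected", "genes_at_cutoff", "cutoff"]
        assert table["models"].tolist() == [8] * 4
        assert (table["genes_at_cutoff"] <= table["max_genes_detected"] + 1e-9).all()
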