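"""Constrained solver and grid co-inference contracts.

The Lasso-equivalence oracle here is an independently coded L1-constrained
logistic fit: a per-sample log-likelihood written from scratch, optimized
with trust-constr under the same linear constraint — sharing no code with
the package's objective or solver path.
"""

import numpy as np
import pytest
from scipy.optimize import LinearConstraint, minimize

from colabel import (
    FlipMatrix,
    GridSpec,
    MislabelBounds,
    SolverConfig,
    SyntheticSpec,
    generate,
    grid_coinfer,
    log_likelihood,
    solve_alpha,
)
from colabel.optimize import ConfigurationError


def oracle_l1_logistic(X, y01, c):
    """Independent L1-constrained logistic MLE (split-variable trust-constr)."""
    T, n = X.shape
    Xd = np.hstack([X, np.ones((T, 1))])

    def nll(z):
        w = np.append(z[:n] - z[n : 2 * n], z[-1])
        eta = Xd @ w
        # per-sample log-lik of y in {0,1}; stable log1p form
        return float(np.sum(np.log1p(np.exp(-(2 * y01 - 1) * eta)))) / T

    A = np.concatenate([np.ones(2 * n), [0.0]])
    res = minimize(
        nll,
        np.zeros(2 * n + 1),
        method="trust-constr",
        constraints=[LinearConstraint(A, -np.inf, c)],
        bounds=[(0, None)] * (2 * n) + [(None, None)],
        options={"gtol": 1e-12, "xtol": 1e-14, "maxiter": 3000},
    )
    return np.append(res.x[:n] - res.x[n : 2 * n], res.x[-1])


@pytest.fixture
def lasso_instance():
    spec = SyntheticSpec(
        n_binary=3,
        n_continuous=2,
        complement_pairs=False,
        true_alpha=[2.0, -1.5, 0.0, 1.0, -0.5, 0.3],
        group_sizes=(200,),
        seed=42,
    )
    dataset, _ = generate(spec)
    return dataset


class TestSolveAlpha:
    def test_zero_budget_reduces_to_base_rate(self, small_dataset):
        """C = 0 with identity mixing: slopes vanish and the intercept is the
        closed-form intercept-only logistic MLE logit(p_hat)."""
        alpha, obj, diag = solve_alpha(
            small_dataset, FlipMatrix.identity(2), 0.0, "logit", SolverConfig(n_restarts=1)
        )
        assert np.allclose(alpha[:-1], 0.0, atol=1e-9)
        p_hat = float(np.mean(small_dataset.observed_labels == 1))
        assert alpha[-1] == pytest.approx(np.log(p_hat / (1 - p_hat)), abs=1e-6)

    @pytest.mark.parametrize("c", [0.5, 2.0, 8.0])
    def test_matches_independent_lasso_oracle(self, lasso_instance, c):
        """With identity mislabeling the co-inference problem IS the
        L1-constrained (Lasso-style) logistic fit."""
        alpha, _, _ = solve_alpha(
            lasso_instance, FlipMatrix.identity(2), c, "logit", SolverConfig(n_restarts=2)
        )
        y01 = (lasso_instance.observed_labels == 1).astype(float)
        expected = oracle_l1_logistic(lasso_instance.features, y01, c)
        assert np.abs(alpha - expected).max() < 1e-4
        assert np.abs(alpha[:-1]).sum() <= c + 1e-6

    def test_budget_respected(self, small_dataset):
        for c in (0.1, 1.0, 5.0):
            alpha, _, _ = solve_alpha(
                small_dataset, FlipMatrix.from_off_diagonal([0.1], [0.1]), c,
                "logit", SolverConfig(n_restarts=1),
            )
            assert np.abs(alpha[:-1]).sum() <= c + 1e-6

    def test_stationarity_of_reoptimization(self, small_dataset):
        """Re-solving from a previous optimum cannot lose objective value."""
        eps = FlipMatrix.identity(2)
        _, obj1, _ = solve_alpha(small_dataset, eps, 2.0, "logit", SolverConfig(n_restarts=1))
        _, obj2, _ = solve_alpha(small_dataset, eps, 2.0, "logit", SolverConfig(n_restarts=3))
        assert obj2 >= obj1 - 1e-8

    def test_restart_objectives_monotone_in_count(self, small_dataset):
        eps = FlipMatrix.from_off_diagonal([0.2], [0.1])
        objs = []
        for k in (1, 2, 4):
            _, obj, _ = solve_alpha(
                small_dataset, eps, 1.0, "logit", SolverConfig(n_restarts=k, seed=3)
            )
            objs.append(obj)
        assert objs[1] >= objs[0] - 1e-9 and objs[2] >= objs[1] - 1e-9

    def test_negative_budget_rejected(self, small_dataset):
        with pytest.raises(ConfigurationError):
            solve_alpha(small_dataset, FlipMatrix.identity(2), -1.0)


class TestGridCoinfer:
    def test_single_point_grid_equals_solve_alpha(self, small_dataset):
        grid = GridSpec(r_values=(0.1,), c_values=(2.0,))
        bounds = MislabelBounds.uniform(0.0, 0.3)
        res = grid_coinfer(small_dataset, bounds, grid, "logit", SolverConfig(n_restarts=1))
        alpha, obj, _ = solve_alpha(
            small_dataset,
            FlipMatrix.from_off_diagonal([0.1], [0.1]),
            2.0,
            "logit",
            SolverConfig(n_restarts=1),
            _stream_key=(0,),
        )
        assert res.objective == pytest.approx(obj, abs=1e-12)
        assert np.allclose(res.alpha_star, alpha)
        assert res.c_star == 2.0
        assert len(res.grid_surface) == 1

    def test_objective_matches_reevaluation(self, small_dataset):
        bounds = MislabelBounds.uniform(0.0, 0.2)
        grid = GridSpec.from_bounds(bounds, 0.1, c_values=(1.0, 4.0))
        res = grid_coinfer(small_dataset, bounds, grid, "logit", SolverConfig(n_restarts=1))
        L = log_likelihood(small_dataset, res.alpha_star, res.flip_star, res.family)
        assert res.objective == pytest.approx(L, abs=1e-8)
        assert len(res.grid_surface) == 3 * 3 * 2
        assert res.grid_surface["L"].max() == pytest.approx(res.objective, abs=1e-10)

    def test_parallel_workers_do_not_change_results(self, small_dataset):
        bounds = MislabelBounds.uniform(0.0, 0.1)
        grid = GridSpec.from_bounds(bounds, 0.05, c_values=(1.0,))
        surfaces = []
        for workers in (1, 4):
            cfg = SolverConfig(n_restarts=2, seed=17, n_workers=workers)
            res = grid_coinfer(small_dataset, bounds, grid, "logit", cfg)
            surfaces.append(res.grid_surface["L"].to_numpy())
        assert np.array_equal(surfaces[0], surfaces[1])

    def test_clean_data_selects_near_zero_mislabeling(self):
        """Simulated with zero corruption: the selected off-diagonals sit
        within one grid step of zero."""
        spec = SyntheticSpec(
            n_binary=3, n_continuous=1, complement_pairs=False,
            true_alpha=[2.0, -2.5, 1.5, 1.0, -0.8], group_sizes=(2000,), seed=3,
        )
        dataset, _ = generate(spec)
        bounds = MislabelBounds.uniform(0.0, 0.25)
        grid = GridSpec.from_bounds(bounds, 0.05, c_values=(8.0,))
        res = grid_coinfer(dataset, bounds, grid, "logit", SolverConfig(n_restarts=1))
        assert res.flip_star.off_diagonals().max() <= 0.05 + 1e-12

    def test_lasso_path_sparsity_monotone_in_c(self, lasso_instance):
        """At identity mislabeling, the non-zero coefficient count grows with
        the budget (Lasso path behavior)."""
        grid = GridSpec(r_values=(0.0,), c_values=(0.25, 1.0, 4.0, 16.0))
        bounds = MislabelBounds.uniform(0.0, 0.1)
        counts = []
        for c in grid.c_values:
            alpha, _, _ = solve_alpha(
                lasso_instance, FlipMatrix.identity(2), c, "logit", SolverConfig(n_restarts=1)
            )
            counts.append(int(np.sum(np.abs(alpha[:-1]) > 1e-6)))
        assert counts == sorted(counts)

    def test_empty_grid_rejected(self, small_dataset):
        with pytest.raises(ConfigurationError):
            GridSpec(r_values=(0.1,), c_values=())

    def test_grid_outside_bounds_rejected(self, small_dataset):
        grid = GridSpec(r_values=(0.4,), c_values=(1.0,))
        bounds = MislabelBounds.uniform(0.0, 0.2)
        with pytest.raises(ConfigurationError, match="bounds"):
            grid_coinfer(small_dataset, bounds, grid)

    def test_tie_break_prefers_least_mislabeling_then_smallest_c(self):
        """A dataset with no feature signal: many grid points tie in L; the
        winner must be the smallest off-diagonal sum with the smallest C."""
        ds = __import__("colabel").LabeledDataset(
            np.zeros((20, 1)), [1, 2] * 10, np.ones(20, dtype=int)
        )
        # with zero features, only the intercept matters; symmetric flips
        # leave the optimal mixed likelihood identical across several points
        grid = GridSpec(r_values=(0.0, 0.1), c_values=(1.0, 2.0))
        bounds = MislabelBounds.uniform(0.0, 0.2)
        res = grid_coinfer(ds, bounds, grid, "logit", SolverConfig(n_restarts=1))
        assert res.flip_star.off_diagonals().sum() == pytest.approx(0.0)
        assert res.c_star == 1.0
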