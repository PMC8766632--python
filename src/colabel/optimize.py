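"""Two-stage co-inference: grid scan over (mislabeling entries, C), inner
L1-constrained likelihood maximization over alpha.

The inner problem is solved by sequential quadratic programming with each
penalized coefficient split into nonnegative positive/negative parts, so the
L1 budget becomes a single linear inequality. Grid points are independent and
may be evaluated by parallel worker processes; per-point restart seeds are
derived from the point index, so results do not depend on the worker count.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy.optimize import minimize

from .model import (
    CoInferenceResult,
    FlipMatrix,
    LabeledDataset,
    MislabelBounds,
    MislabelMatrix,
    ValidationError,
    log_likelihood,
    grad_alpha,
    phi,
)

__all__ = ["GridSpec", "SolverConfig", "solve_alpha", "grid_coinfer"]

#: default C ladder; geometric, bracketing typical optima
DEFAULT_C_LADDER = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0)
#: grid-point objective ties closer than this share the tie-break rule
TIE_TOL = 1e-10


class ConfigurationError(ValueError):
    """Raised for infeasible grids, bounds or solver settings."""


@dataclass
class GridSpec:
    """Rectangular scan grid for the two free off-diagonal mislabeling
    entries per group (two classes: ``eps[2,1,g]`` and ``eps[1,2,g]`` in the
    generative convention; diagonals follow from column normalization)
    crossed with the C ladder.

    ``r_values`` is one ordered list shared by every free entry, or a list of
    per-entry lists ordered ``(eps21_g1, eps12_g1, eps21_g2, ...)``.
    """

    r_values: Sequence[float] | Sequence[Sequence[float]] = (0.0,)
    c_values: Sequence[float] = DEFAULT_C_LADDER

    def __post_init__(self) -> None:
        self.c_values = tuple(float(c) for c in self.c_values)
        if len(self.c_values) == 0 or any(c < 0 for c in self.c_values):
            raise ConfigurationError("c_values must be nonnegative and nonempty")
        if list(self.c_values) != sorted(self.c_values):
            raise ConfigurationError("c_values must be increasing")

    @classmethod
    def from_bounds(
        cls,
        bounds: MislabelBounds,
        step: float = 0.05,
        c_values: Sequence[float] = DEFAULT_C_LADDER,
    ) -> "GridSpec":
        """Uniform grid with spacing ``step`` inside each entry's box."""
        if bounds.r_lo.shape[0] != 2:
            raise ConfigurationError("grid construction supports two classes")
        per_entry = []
        for g in range(bounds.r_lo.shape[2]):
            for (i, j) in ((1, 0), (0, 1)):
                lo, hi = bounds.r_lo[i, j, g], bounds.r_hi[i, j, g]
                n_steps = int(np.floor((hi - lo) / step + 1e-9))
                per_entry.append(tuple(lo + step * k for k in range(n_steps + 1)))
        return cls(tuple(per_entry), c_values)

    def entry_grids(self, n_groups: int) -> list[tuple[float, ...]]:
        """Per-free-entry value lists, expanded to ``2 * n_groups`` entries."""
        vals = self.r_values
        if len(vals) > 0 and np.isscalar(vals[0]):
            return [tuple(float(v) for v in vals)] * (2 * n_groups)
        expanded = [tuple(float(v) for v in entry) for entry in vals]
        if len(expanded) != 2 * n_groups:
            raise ConfigurationError(
                f"expected {2 * n_groups} per-entry grids (2 per group), got {len(expanded)}"
            )
        return expanded

    def points(self, n_groups: int) -> list[tuple[tuple[float, ...], float]]:
        """All (off-diagonal tuple, C) grid points, row-major."""
        grids = self.entry_grids(n_groups)
        return [
            (offs, c)
            for offs in itertools.product(*grids)
            for c in self.c_values
        ]


@dataclass
class SolverConfig:
    tolerance: float = 1e-12
    max_iterations: int = 500
    n_restarts: int = 3
    restart_scale: float = 1.0
    seed: int = 0
    n_workers: int = 1

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ConfigurationError("tolerance must be positive")
        if self.n_restarts < 1:
            raise ConfigurationError("need at least one restart")


def _flip_from_off_diagonals(offs: Sequence[float], n_groups: int) -> FlipMatrix:
    offs = np.asarray(offs, dtype=float).reshape(n_groups, 2)
    return FlipMatrix.from_off_diagonal(offs[:, 0], offs[:, 1])


def _check_within_bounds(offs: Sequence[float], bounds: MislabelBounds) -> None:
    offs = np.asarray(offs, dtype=float).reshape(-1, 2)
    for g in range(offs.shape[0]):
        for k, (i, j) in enumerate(((1, 0), (0, 1))):
            lo, hi = bounds.r_lo[i, j, g], bounds.r_hi[i, j, g]
            if not (lo - 1e-12 <= offs[g, k] <= hi + 1e-12):
                raise ConfigurationError(
                    f"grid value {offs[g, k]} for entry r[{i + 1},{j + 1},{g + 1}] "
                    f"violates its bounds [{lo}, {hi}]"
                )


def _restart_inits(
    p: int, intercept: bool, c: float, config: SolverConfig, stream_key: tuple[int, ...]
) -> list[np.ndarray]:
    """alpha = 0 first, then seeded uniform draws scaled into the L1 ball."""
    n_coef = p + (1 if intercept else 0)
    inits = [np.zeros(n_coef)]
    for k in range(1, config.n_restarts):
        rng = np.random.default_rng([config.seed & 0x7FFFFFFF, *stream_key, k])
        a = rng.uniform(-config.restart_scale, config.restart_scale, n_coef)
        slope_l1 = float(np.abs(a[:p]).sum())
        if np.isfinite(c) and slope_l1 > c:
            a[:p] *= (0.5 * c / slope_l1) if c > 0 else 0.0
        inits.append(a)
    return inits


def solve_alpha(
    dataset: LabeledDataset,
    r: MislabelMatrix,
    c: float,
    family: str = "logit",
    config: SolverConfig | None = None,
    intercept: bool = True,
    _stream_key: tuple[int, ...] = (),
) -> tuple[np.ndarray, float, dict]:
    """Maximize ``L(alpha, r)`` over alpha subject to ``|alpha_slopes|_1 <= c``.

    Returns ``(alpha_star, objective, diagnostics)`` where diagnostics carry
    convergence flags and the number of restarts agreeing with the best
    objective. The intercept (when present) is unpenalized.
    """
    if c < 0:
        raise ConfigurationError("L1 budget c must be nonnegative")
    config = config or SolverConfig()
    n = dataset.n_features
    p = n  # penalized coefficients
    dim = 2 * p + (1 if intercept else 0)

    def neg_objective(z: np.ndarray) -> float:
        alpha = _merge(z)
        return -log_likelihood(dataset, alpha, r, family, intercept)

    def neg_gradient(z: np.ndarray) -> np.ndarray:
        alpha = _merge(z)
        g = grad_alpha(dataset, alpha, r, family, intercept)
        out = np.empty(dim)
        out[:p] = -g[:p]
        out[p : 2 * p] = g[:p]
        if intercept:
            out[-1] = -g[-1]
        return out

    def _merge(z: np.ndarray) -> np.ndarray:
        w = z[:p] - z[p : 2 * p]
        return np.append(w, z[-1]) if intercept else w

    if np.isfinite(c):
        constraints = [
            {
                "type": "ineq",
                "fun": lambda z: c - z[: 2 * p].sum(),
                "jac": lambda z: np.concatenate(
                    [-np.ones(2 * p), np.zeros(dim - 2 * p)]
                ),
            }
        ]
        bounds = [(0.0, c)] * (2 * p) + ([(None, None)] if intercept else [])
    else:
        constraints = []
        bounds = [(0.0, None)] * (2 * p) + ([(None, None)] if intercept else [])

    best = None
    objectives = []
    any_converged = False
    for a0 in _restart_inits(p, intercept, c, config, _stream_key):
        z0 = np.zeros(dim)
        w0 = a0[:p]
        z0[:p] = np.maximum(w0, 0.0)
        z0[p : 2 * p] = np.maximum(-w0, 0.0)
        if intercept:
            z0[-1] = a0[-1]
        res = minimize(
            neg_objective,
            z0,
            jac=neg_gradient,
            method="SLSQP",
            bounds=bounds,
            constraints=constraints,
            options={"maxiter": config.max_iterations, "ftol": config.tolerance},
        )
        obj = -res.fun
        objectives.append(obj)
        any_converged = any_converged or bool(res.success)
        if best is None or obj > best[1]:
            best = (_merge(res.x), obj, bool(res.success))

    alpha_star, objective, converged = best
    # tidy tiny split-variable residue on the slopes
    alpha_star = np.where(np.abs(alpha_star) < 1e-12, 0.0, alpha_star)
    agree = int(np.sum(np.asarray(objectives) >= objective - 1e-6))
    diagnostics = {
        "converged": converged or any_converged,
        "n_restarts_agreeing": agree,
        "restart_objectives": objectives,
    }
    return alpha_star, objective, diagnostics


def _evaluate_point(
    dataset: LabeledDataset,
    offs: tuple[float, ...],
    c: float,
    family: str,
    config: SolverConfig,
    intercept: bool,
    point_index: int,
) -> dict:
    r = _flip_from_off_diagonals(offs, dataset.n_groups)
    alpha, obj, diag = solve_alpha(
        dataset, r, c, family, config, intercept, _stream_key=(point_index,)
    )
    return {
        "offs": offs,
        "c": c,
        "objective": obj,
        "alpha": alpha,
        "converged": diag["converged"],
        "n_restarts_agreeing": diag["n_restarts_agreeing"],
    }


def _implied_priors(
    dataset: LabeledDataset, alpha: np.ndarray, family: str, intercept: bool
) -> np.ndarray:
    """Per-group true-class priors implied by the fitted model:
    ``pi[i, g] = mean over group-g rows of phi_i(x, alpha)``."""
    p1 = phi(family, dataset.features, alpha, intercept)[:, 0]
    pi = np.empty((2, dataset.n_groups))
    for g in range(1, dataset.n_groups + 1):
        mean_p1 = float(p1[dataset.groups == g].mean())
        pi[:, g - 1] = (mean_p1, 1.0 - mean_p1)
    return pi


def grid_coinfer(
    dataset: LabeledDataset,
    bounds: MislabelBounds | None = None,
    grid: GridSpec | None = None,
    family: str = "logit",
    config: SolverConfig | None = None,
    intercept: bool = True,
) -> CoInferenceResult:
    """Scan the (r, C) grid, maximizing L over alpha at every point, and
    return the joint maximizer.

    Ties within ``TIE_TOL`` prefer the smallest off-diagonal sum, then the
    smallest C (the least-mislabeling, sparsest explanation).
    """
    config = config or SolverConfig()
    bounds = bounds or MislabelBounds.uniform(0.0, 0.5, 2, dataset.n_groups)
    grid = grid or GridSpec.from_bounds(bounds)
    if dataset.n_labels != 2:
        raise ValidationError("co-inference fitting supports two classes (m = 2)")
    points = grid.points(dataset.n_groups)
    if not points:
        raise ConfigurationError("empty grid")
    for offs, _ in points:
        _check_within_bounds(offs, bounds)

    if config.n_workers > 1:
        records = Parallel(n_jobs=config.n_workers)(
            delayed(_evaluate_point)(dataset, offs, c, family, config, intercept, k)
            for k, (offs, c) in enumerate(points)
        )
    else:
        records = [
            _evaluate_point(dataset, offs, c, family, config, intercept, k)
            for k, (offs, c) in enumerate(points)
        ]

    best_obj = max(rec["objective"] for rec in records)
    tied = [rec for rec in records if rec["objective"] >= best_obj - TIE_TOL]
    tied.sort(key=lambda rec: (sum(rec["offs"]), rec["c"]))
    winner = tied[0]

    n_g = dataset.n_groups
    off_cols = [
        f"eps{i}{j}_g{g + 1}" for g in range(n_g) for (i, j) in ((2, 1), (1, 2))
    ]
    surface = pd.DataFrame(
        [
            {**dict(zip(off_cols, rec["offs"])), "C": rec["c"], "L": rec["objective"]}
            for rec in records
        ]
    )
    flip_star = _flip_from_off_diagonals(winner["offs"], n_g)
    r_star = flip_star.to_mislabel(_implied_priors(dataset, winner["alpha"], family, intercept))
    return CoInferenceResult(
        alpha_star=winner["alpha"],
        r_star=r_star,
        flip_star=flip_star,
        c_star=winner["c"],
        objective=winner["objective"],
        grid_surface=surface,
        converged=all(rec["converged"] for rec in records),
        n_restarts_agreeing=winner["n_restarts_agreeing"],
        family=family,
        intercept=intercept,
        bounds=bounds,
    )
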