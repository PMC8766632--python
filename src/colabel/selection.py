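"""Model selection: repeated random-split cross-validation of the validation
likelihood over the (r, C) grid and candidate model families, plus an AIC
alternative.

Splits are drawn within each group (the cohort is the sampling unit; label
stratification would presume the labels are correct, which is exactly what
the model doubts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (
    CoInferenceResult,
    LabeledDataset,
    MislabelBounds,
    ValidationError,
    ZERO_TOL,
    log_likelihood,
    total_log_likelihood,
)
from .optimize import GridSpec, SolverConfig, solve_alpha, _flip_from_off_diagonals

__all__ = ["CvPlan", "SelectionReport", "cross_validate", "aic"]

logger = logging.getLogger(__name__)

MAX_REDRAWS = 100


@dataclass
class CvPlan:
    train_fraction: float = 0.75
    n_repeats: int = 500
    seed: int = 0
    stratify_by_group: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValidationError("train_fraction must lie in (0, 1)")
        if self.n_repeats < 1:
            raise ValidationError("n_repeats must be >= 1")


@dataclass
class SelectionReport:
    """Mean validation likelihood per grid point and the selected model."""

    table: pd.DataFrame  # family, off-diagonals, C, mean_val_L, se_val_L
    chosen_family: str
    chosen_offs: tuple[float, ...]
    chosen_c: float
    n_repeats: int
    per_family: dict = field(default_factory=dict)


def _split_group(rng: np.random.Generator, idx: np.ndarray, frac: float) -> tuple[np.ndarray, np.ndarray]:
    n_train = int(round(frac * idx.size))
    perm = rng.permutation(idx)
    return perm[:n_train], perm[n_train:]


def _draw_split(
    dataset: LabeledDataset, plan: CvPlan, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-group split at train_fraction, redrawn when a group would be left
    with fewer than 2 training or 1 validation rows."""
    for attempt in range(MAX_REDRAWS):
        train_parts, val_parts = [], []
        ok = True
        for g in range(1, dataset.n_groups + 1):
            idx = np.flatnonzero(dataset.groups == g)
            tr, va = _split_group(rng, idx, plan.train_fraction)
            if tr.size < 2 or va.size < 1:
                ok = False
                break
            train_parts.append(tr)
            val_parts.append(va)
        if ok:
            train = np.concatenate(train_parts)
            val = np.concatenate(val_parts)
            # both observed classes must appear in training, else refit degenerates
            if np.unique(dataset.observed_labels[train]).size == dataset.n_labels:
                return np.sort(train), np.sort(val)
        logger.info("cross-validation split redrawn (attempt %d)", attempt + 1)
    raise ValidationError("could not draw a usable split after 100 attempts")


def cross_validate(
    dataset: LabeledDataset,
    bounds: MislabelBounds | None = None,
    grid: GridSpec | None = None,
    families: Sequence[str] = ("logit",),
    plan: CvPlan | None = None,
    config: SolverConfig | None = None,
    intercept: bool = True,
) -> SelectionReport:
    """For every repeat: split within groups, fit alpha on the training set at
    each grid point, record the validation likelihood under the training alpha
    and the grid r. Selection is the argmax of the mean validation L; among
    points within one standard error of the best, ties prefer the smallest
    off-diagonal sum, then the smallest C.
    """
    plan = plan or CvPlan()
    config = config or SolverConfig()
    bounds = bounds or MislabelBounds.uniform(0.0, 0.5, 2, dataset.n_groups)
    grid = grid or GridSpec.from_bounds(bounds)
    points = grid.points(dataset.n_groups)
    rng = np.random.default_rng(plan.seed)

    scores = {
        (fam, offs, c): [] for fam in families for offs, c in points
    }
    for _ in range(plan.n_repeats):
        train_idx, val_idx = _draw_split(dataset, plan, rng)
        train, val = dataset.subset(train_idx), dataset.subset(val_idx)
        for fam in families:
            for k, (offs, c) in enumerate(points):
                r = _flip_from_off_diagonals(offs, dataset.n_groups)
                alpha, _, _ = solve_alpha(
                    train, r, c, fam, config, intercept, _stream_key=(k,)
                )
                val_l = log_likelihood(val, alpha, r, fam, intercept)
                scores[(fam, offs, c)].append(val_l)

    rows = []
    for (fam, offs, c), vals in scores.items():
        vals = np.asarray(vals)
        rows.append(
            {
                "family": fam,
                "offs": offs,
                "C": c,
                "mean_val_L": vals.mean(),
                "se_val_L": vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0,
            }
        )
    table = pd.DataFrame(rows)

    best_key = max(scores, key=lambda k: np.mean(scores[k]))
    best_vals = np.asarray(scores[best_key])
    # one-SE rule on the PAIRED difference: all grid points see the same
    # splits, so the split-to-split variance cancels in the comparison
    near_keys = []
    for key, vals in scores.items():
        d = best_vals - np.asarray(vals)
        se = d.std(ddof=1) / np.sqrt(d.size) if d.size > 1 else 0.0
        if d.mean() <= se + 1e-15:
            near_keys.append(key)
    near_keys.sort(key=lambda k: (sum(k[1]), k[2]))
    chosen_fam, chosen_offs, chosen_c = near_keys[0]
    chosen = {"family": chosen_fam, "offs": chosen_offs, "C": chosen_c}

    per_family = {
        fam: float(sub["mean_val_L"].max())
        for fam, sub in table.groupby("family")
    }
    return SelectionReport(
        table=table.drop(columns=[], errors="ignore"),
        chosen_family=str(chosen["family"]),
        chosen_offs=tuple(chosen["offs"]),
        chosen_c=float(chosen["C"]),
        n_repeats=plan.n_repeats,
        per_family=per_family,
    )


def aic(dataset: LabeledDataset, result: CoInferenceResult) -> float:
    """Akaike information criterion for a completed co-inference fit.

    ``AIC = 2k - 2 LL_total`` with ``LL_total`` the unnormalized sum of
    per-instance log mixed probabilities and ``k`` counting coefficients with
    ``|alpha_d| > 1e-6`` (intercept included) plus free off-diagonal
    mislabeling entries not pinned at one of their bounds.
    """
    ll = total_log_likelihood(
        dataset, result.alpha_star, result.flip_star, result.family, result.intercept
    )
    k = int(np.sum(np.abs(result.alpha_star) > ZERO_TOL))
    offs = result.flip_star.off_diagonals().reshape(-1, 2)
    bounds = result.bounds or MislabelBounds.uniform(0.0, 0.5, 2, result.r_star.n_groups)
    for g in range(offs.shape[0]):
        for kk, (i, j) in enumerate(((1, 0), (0, 1))):
            lo, hi = bounds.r_lo[i, j, g], bounds.r_hi[i, j, g]
            if offs[g, kk] > lo + 1e-12 and offs[g, kk] < hi - 1e-12:
                k += 1
    return 2.0 * k - 2.0 * ll
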