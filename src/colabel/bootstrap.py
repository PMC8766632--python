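"""Non-parametric bootstrap uncertainty for co-inference estimates.

Rows are resampled with replacement *within each group* (group sizes are part
of the design and are preserved exactly); each replicate re-runs the full
grid co-inference. The resulting replicate distribution serves as the
posterior for the mislabeling rates and the model coefficients, summarized by
percentile 95% intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    LabeledDataset,
    MislabelBounds,
    ValidationError,
    phi,
)
from .optimize import GridSpec, SolverConfig, grid_coinfer

__all__ = [
    "BootstrapEnsemble",
    "bootstrap_fit",
    "posterior_mislabeling",
    "individual_probabilities",
]

logger = logging.getLogger(__name__)

MAX_REDRAWS = 100


@dataclass
class BootstrapEnsemble:
    """Replicate-wise draws of (alpha*, r* off-diagonals, C*, objective)."""

    alphas: np.ndarray  # B x len(alpha)
    off_diagonals: np.ndarray  # B x (2 * N_g) flip entries, (eps21_g, eps12_g) per group
    r_off_diagonals: np.ndarray  # B x (2 * N_g) converted risks, (r12_g, r21_g) per group
    c_values: np.ndarray  # B
    objectives: np.ndarray  # B
    family: str
    intercept: bool
    n_groups: int
    seed: int

    @property
    def n_replicates(self) -> int:
        return self.alphas.shape[0]

    def alpha_summary(self, level: float = 0.95) -> pd.DataFrame:
        lo, hi = _percentiles(level)
        return pd.DataFrame(
            {
                "mean": self.alphas.mean(axis=0),
                "ci_lo": np.percentile(self.alphas, lo, axis=0),
                "ci_hi": np.percentile(self.alphas, hi, axis=0),
            }
        )


def _percentiles(level: float) -> tuple[float, float]:
    tail = 100.0 * (1.0 - level) / 2.0
    return tail, 100.0 - tail


def _resample_within_groups(
    dataset: LabeledDataset, rng: np.random.Generator
) -> np.ndarray:
    rows = []
    for g in range(1, dataset.n_groups + 1):
        idx = np.flatnonzero(dataset.groups == g)
        rows.append(rng.choice(idx, size=idx.size, replace=True))
    return np.concatenate(rows)


def bootstrap_fit(
    dataset: LabeledDataset,
    bounds: MislabelBounds | None = None,
    grid: GridSpec | None = None,
    family: str = "logit",
    config: SolverConfig | None = None,
    B: int = 100,
    seed: int = 0,
    intercept: bool = True,
) -> BootstrapEnsemble:
    """Fit the full (r, C) grid co-inference on ``B`` within-group resamples.

    A resample missing one of the observed classes entirely is redrawn (and
    logged); the ensemble is deterministic given ``seed``.
    """
    if B < 1:
        raise ValidationError("need at least one bootstrap replicate")
    config = config or SolverConfig()
    bounds = bounds or MislabelBounds.uniform(0.0, 0.5, 2, dataset.n_groups)
    grid = grid or GridSpec.from_bounds(bounds)

    alphas, offs, r_offs, cs, objs = [], [], [], [], []
    for b in range(B):
        for attempt in range(MAX_REDRAWS):
            rng = np.random.default_rng([seed & 0x7FFFFFFF, b, attempt])
            rows = _resample_within_groups(dataset, rng)
            resample = dataset.subset(rows)
            if np.unique(resample.observed_labels).size == dataset.n_labels:
                break
            logger.info("bootstrap replicate %d redrawn (missing class)", b)
        else:
            raise ValidationError(f"replicate {b}: no usable resample in 100 draws")
        rep_config = SolverConfig(
            tolerance=config.tolerance,
            max_iterations=config.max_iterations,
            n_restarts=config.n_restarts,
            restart_scale=config.restart_scale,
            seed=(config.seed * 100003 + b) & 0x7FFFFFFF,
            n_workers=config.n_workers,
        )
        res = grid_coinfer(resample, bounds, grid, family, rep_config, intercept)
        alphas.append(res.alpha_star)
        offs.append(res.flip_star.off_diagonals())
        r_offs.append(res.r_star.off_diagonals())
        cs.append(res.c_star)
        objs.append(res.objective)

    return BootstrapEnsemble(
        alphas=np.vstack(alphas),
        off_diagonals=np.vstack(offs),
        r_off_diagonals=np.vstack(r_offs),
        c_values=np.asarray(cs),
        objectives=np.asarray(objs),
        family=family,
        intercept=intercept,
        n_groups=dataset.n_groups,
        seed=seed,
    )


def posterior_mislabeling(ensemble: BootstrapEnsemble, level: float = 0.95) -> dict:
    """Posterior (bootstrap) summaries of the off-diagonal mislabeling rates.

    Returns per-entry mean / CI / histogram support plus the fraction of
    replicates whose off-diagonals all sit at zero — the posterior mass on
    perfect labeling.
    """
    if ensemble.n_replicates == 0:
        raise ValidationError("empty ensemble")
    lo_p, hi_p = _percentiles(level)

    def _summaries(draw_matrix: np.ndarray, labels: list[str]) -> dict:
        out = {}
        for k, name in enumerate(labels):
            draws = draw_matrix[:, k]
            values, counts = np.unique(draws, return_counts=True)
            out[name] = {
                "mean": float(draws.mean()),
                "ci_lo": float(np.percentile(draws, lo_p)),
                "ci_hi": float(np.percentile(draws, hi_p)),
                "support": {float(v): int(c) for v, c in zip(values, counts)},
            }
        return out

    flip_labels = [
        f"eps{i}{j}_g{g + 1}"
        for g in range(ensemble.n_groups)
        for (i, j) in ((2, 1), (1, 2))
    ]
    risk_labels = [
        f"r{i}{j}_g{g + 1}"
        for g in range(ensemble.n_groups)
        for (i, j) in ((1, 2), (2, 1))
    ]
    perfect = float(np.mean(np.all(ensemble.off_diagonals <= 1e-12, axis=1)))
    return {
        "entries": _summaries(ensemble.off_diagonals, flip_labels),
        "risk_entries": _summaries(ensemble.r_off_diagonals, risk_labels),
        "perfect_labeling_fraction": perfect,
    }


def individual_probabilities(
    ensemble: BootstrapEnsemble, dataset: LabeledDataset, level: float = 0.95
) -> pd.DataFrame:
    """Per-row mean and percentile CI of the class-1 probability across
    replicate coefficient draws."""
    expected = dataset.n_features + (1 if ensemble.intercept else 0)
    if ensemble.alphas.shape[1] != expected:
        raise ValidationError("ensemble coefficients do not match the dataset")
    draws = np.empty((ensemble.n_replicates, dataset.n_rows))
    for b in range(ensemble.n_replicates):
        draws[b] = phi(
            ensemble.family, dataset.features, ensemble.alphas[b], ensemble.intercept
        )[:, 0]
    lo_p, hi_p = _percentiles(level)
    return pd.DataFrame(
        {
            "mean": draws.mean(axis=0),
            "ci_lo": np.percentile(draws, lo_p, axis=0),
            "ci_hi": np.percentile(draws, hi_p, axis=0),
        }
    )
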