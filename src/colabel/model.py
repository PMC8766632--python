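"""Core model: labeled datasets, mislabeling matrices, model functions and the
marginal log-likelihood.

The central object is the marginal log-likelihood of observed labels under a
discriminative model phi (logit / probit / linear) for the *true* label,
mixed through a latent, group-specific mislabeling matrix. Two conventions
coexist:

* :class:`FlipMatrix` — class-conditional corruption ``eps[j, i, g] =
  P(obs j | true i, g)``; mixing with it gives the proper marginal
  ``P(obs j | x) = sum_i eps[j, i] phi_i`` that the co-inference maximizes.
* :class:`MislabelMatrix` — observed-conditioned risks ``r[i, j, g] =
  P(true i | obs j, g)``; the reporting convention of the results (mixing
  with it evaluates the observed-conditioned weighting literally).

Either way::

    L = sum_{g,t} 1/(N_g T_g) log sum_i c_i(j_obs(t), g) phi_i(x_t, alpha)

Columns of both matrices live on the probability simplex; the identity
matrix recovers the ordinary (average) GLM log-likelihood in both
conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr
from scipy.stats import norm

__all__ = [
    "LabeledDataset",
    "MislabelMatrix",
    "FlipMatrix",
    "MislabelBounds",
    "ModelSpec",
    "CoInferenceResult",
    "FAMILIES",
    "phi",
    "log_likelihood",
    "grad_alpha",
]

FAMILIES = ("logit", "probit", "linear")

#: clipping for the linear family so predicted probabilities stay in (0, 1)
LINEAR_EPS = 1e-6
#: floor applied to mixed per-instance probabilities before the log
LOG_FLOOR = 1e-300
#: threshold below which a fitted coefficient counts as zero
ZERO_TOL = 1e-6

SIMPLEX_TOL = 1e-12


class ValidationError(ValueError):
    """Raised when data or parameters violate a documented invariant."""


@dataclass
class LabeledDataset:
    """Feature matrix with observed (possibly mislabeled) classes and cohorts.

    Labels and groups are integer codes starting at 1; ``label_names`` and
    row-group bookkeeping translate back to the user's vocabulary.
    """

    features: np.ndarray
    observed_labels: np.ndarray
    groups: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    label_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.observed_labels = np.asarray(self.observed_labels, dtype=int)
        self.groups = np.asarray(self.groups, dtype=int)
        if self.features.ndim != 2:
            raise ValidationError("features must be a 2-D matrix")
        T, n = self.features.shape
        if T == 0 or n < 1:
            raise ValidationError("dataset must have at least one row and one feature")
        if not np.isfinite(self.features).all():
            raise ValidationError("features contain non-finite values")
        if self.observed_labels.shape != (T,) or self.groups.shape != (T,):
            raise ValidationError("labels/groups must align with feature rows")
        if not self.feature_names:
            self.feature_names = [f"x{d}" for d in range(1, n + 1)]
        if len(self.feature_names) != n:
            raise ValidationError("feature_names length mismatch")
        m = int(self.observed_labels.max(initial=0))
        if not self.label_names:
            self.label_names = [f"class_{i}" for i in range(1, max(m, 2) + 1)]
        m = len(self.label_names)
        if m < 2:
            raise ValidationError("need at least two label classes")
        if self.observed_labels.min(initial=1) < 1 or self.observed_labels.max(initial=1) > m:
            raise ValidationError(f"label codes must lie in 1..{m}")
        n_g = int(self.groups.max(initial=0))
        if self.groups.min(initial=1) < 1:
            raise ValidationError("group codes must start at 1")
        counts = np.bincount(self.groups, minlength=n_g + 1)[1:]
        if (counts < 1).any():
            raise ValidationError("every group code in 1..N_g must be populated")

    @property
    def n_rows(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def n_labels(self) -> int:
        return len(self.label_names)

    @property
    def n_groups(self) -> int:
        return int(self.groups.max())

    def group_sizes(self) -> np.ndarray:
        """Per-group instance counts ``T_g`` (index 0 = group 1)."""
        return np.bincount(self.groups, minlength=self.n_groups + 1)[1:]

    def subset(self, rows: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(
            self.features[rows],
            self.observed_labels[rows],
            self.groups[rows],
            list(self.feature_names),
            list(self.label_names),
        )


@dataclass
class _ColumnStochastic:
    """Shared machinery for the two mislabeling-matrix conventions: an
    m x m x N_g array of probabilities whose columns sum to one."""

    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.ndim == 2:  # single group convenience
            self.r = self.r[:, :, None]
        if self.r.ndim != 3 or self.r.shape[0] != self.r.shape[1]:
            raise ValidationError("r must be an m x m x N_g array")
        if (self.r < 0).any() or (self.r > 1).any():
            raise ValidationError("r entries must lie in [0, 1]")
        col_sums = self.r.sum(axis=0)
        if not np.allclose(col_sums, 1.0, atol=SIMPLEX_TOL, rtol=0):
            raise ValidationError("every r column must sum to 1 (simplex)")

    @property
    def m(self) -> int:
        return self.r.shape[0]

    @property
    def n_groups(self) -> int:
        return self.r.shape[2]

    @classmethod
    def identity(cls, m: int, n_groups: int = 1):
        return cls(np.repeat(np.eye(m)[:, :, None], n_groups, axis=2))

    @classmethod
    def uniform(cls, m: int, n_groups: int = 1):
        return cls(np.full((m, m, n_groups), 1.0 / m))

    @classmethod
    def _from_off(cls, upper: Sequence[float], lower: Sequence[float]):
        """Two-class builder from the two free off-diagonal entries per group:
        ``upper[g] -> [0, 1, g]`` and ``lower[g] -> [1, 0, g]``; diagonals by
        column normalization."""
        upper = np.atleast_1d(np.asarray(upper, dtype=float))
        lower = np.atleast_1d(np.asarray(lower, dtype=float))
        if upper.shape != lower.shape:
            raise ValidationError("off-diagonal vectors must have equal length")
        n_g = upper.shape[0]
        r = np.empty((2, 2, n_g))
        r[0, 0] = 1.0 - lower
        r[1, 0] = lower
        r[0, 1] = upper
        r[1, 1] = 1.0 - upper
        return cls(r)

    def is_identity(self, tol: float = 1e-12) -> bool:
        eye = np.eye(self.m)[:, :, None]
        return bool(np.abs(self.r - eye).max() <= tol)


class MislabelMatrix(_ColumnStochastic):
    """Observed-conditioned mislabeling risks:
    ``r[i, j, g] = P(true = class i | observed = class j, group g)``.

    This is the reporting convention of the co-inference results (the risk
    that a record labeled ``j`` truly belongs to class ``i``); columns (over
    the true class ``i``) sum to one.
    """

    @classmethod
    def from_off_diagonal(
        cls, r12: Sequence[float], r21: Sequence[float]
    ) -> "MislabelMatrix":
        """``r12[g] = P(true 1 | obs 2, g)``, ``r21[g] = P(true 2 | obs 1, g)``."""
        return cls._from_off(r12, r21)

    def off_diagonals(self) -> np.ndarray:
        """Flattened free entries ``(r[1,2,g], r[2,1,g])`` per group (m = 2)."""
        if self.m != 2:
            raise ValidationError("off_diagonals is defined for m = 2")
        return np.column_stack([self.r[0, 1, :], self.r[1, 0, :]]).ravel()


class FlipMatrix(_ColumnStochastic):
    """Class-conditional corruption (generative) convention:
    ``eps[j, i, g] = P(observed = class j | true = class i, group g)``.

    Columns (over the observed class ``j``) sum to one. This is the matrix
    the marginal likelihood mixes over — ``P(obs j | x) = sum_i eps[j, i]
    phi_i(x)`` — and the parameterization the co-inference grid scans; it is
    related to :class:`MislabelMatrix` by Bayes' rule through the class
    priors.
    """

    @classmethod
    def from_off_diagonal(
        cls, eps21: Sequence[float], eps12: Sequence[float]
    ) -> "FlipMatrix":
        """``eps21[g] = P(obs 2 | true 1, g)`` (class-1 records mislabeled as 2),
        ``eps12[g] = P(obs 1 | true 2, g)``."""
        return cls._from_off(eps12, eps21)

    def off_diagonals(self) -> np.ndarray:
        """Flattened free entries ``(eps[2,1,g], eps[1,2,g])`` per group."""
        if self.m != 2:
            raise ValidationError("off_diagonals is defined for m = 2")
        return np.column_stack([self.r[1, 0, :], self.r[0, 1, :]]).ravel()

    def to_mislabel(self, priors: np.ndarray) -> MislabelMatrix:
        """Bayes conversion to observed-conditioned risks using per-group
        class priors ``priors[i, g] = P(true = class i, g)``."""
        priors = np.atleast_2d(np.asarray(priors, dtype=float))
        if priors.shape[0] == self.m and priors.shape[1] == self.n_groups:
            pi = priors
        elif priors.shape == (1, self.m):  # single-group convenience
            pi = priors.T
        else:
            raise ValidationError("priors must be an m x N_g array")
        pi = np.clip(pi, 1e-12, None)
        pi = pi / pi.sum(axis=0, keepdims=True)
        joint = self.r * pi[None, :, :]  # [j, i, g] = P(obs j, true i)
        obs_marginal = joint.sum(axis=1)  # [j, g]
        r = joint.transpose(1, 0, 2) / obs_marginal[None, :, :]
        return MislabelMatrix(r)


@dataclass
class MislabelBounds:
    """Box bounds for the free (off-diagonal) mislabeling entries."""

    r_lo: np.ndarray
    r_hi: np.ndarray

    def __post_init__(self) -> None:
        self.r_lo = np.asarray(self.r_lo, dtype=float)
        self.r_hi = np.asarray(self.r_hi, dtype=float)
        if self.r_lo.ndim == 2:
            self.r_lo = self.r_lo[:, :, None]
        if self.r_hi.ndim == 2:
            self.r_hi = self.r_hi[:, :, None]
        if self.r_lo.shape != self.r_hi.shape or self.r_lo.ndim != 3:
            raise ValidationError("bounds must be matching m x m x N_g arrays")
        if (self.r_lo < 0).any() or (self.r_hi >= 1).any() or (self.r_lo > self.r_hi).any():
            raise ValidationError("need 0 <= r_lo <= r_hi < 1 elementwise")
        # off-diagonal feasibility: each column must admit a simplex point
        m = self.r_lo.shape[0]
        off = ~np.eye(m, dtype=bool)
        lo_sum = np.where(off[:, :, None], self.r_lo, 0).sum(axis=0)
        if (lo_sum > 1).any():
            raise ValidationError("lower bounds leave no simplex-feasible column")

    @classmethod
    def uniform(cls, lo: float, hi: float, m: int = 2, n_groups: int = 1) -> "MislabelBounds":
        """Same [lo, hi] box on every off-diagonal entry; diagonals unconstrained."""
        off = ~np.eye(m, dtype=bool)
        r_lo = np.where(off, lo, 0.0)[:, :, None].repeat(n_groups, axis=2)
        r_hi = np.where(off, hi, 1.0 - 1e-12)[:, :, None].repeat(n_groups, axis=2)
        return cls(r_lo, r_hi)


@dataclass
class ModelSpec:
    """A fitted (or to-be-fitted) discriminative model.

    ``l1_budget`` bounds the L1 norm of the slope coefficients; the intercept
    is unpenalized so the zero-budget limit is a base-rate model.
    """

    family: str = "logit"
    intercept: bool = True
    alpha: np.ndarray | None = None
    l1_budget: float = np.inf

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.l1_budget < 0:
            raise ValidationError("l1_budget must be nonnegative")
        if self.alpha is not None:
            self.alpha = np.asarray(self.alpha, dtype=float)


@dataclass
class CoInferenceResult:
    """Joint optimum over the scanned (mislabeling, C) grid.

    ``flip_star`` is the scanned optimum in the generative convention (the
    quantity the objective is maximized over); ``r_star`` is its Bayes
    conversion to observed-conditioned risks through the class priors implied
    by the fitted model.
    """

    alpha_star: np.ndarray
    r_star: MislabelMatrix
    flip_star: "FlipMatrix"
    c_star: float
    objective: float
    grid_surface: pd.DataFrame
    converged: bool
    n_restarts_agreeing: int
    family: str = "logit"
    intercept: bool = True
    bounds: MislabelBounds | None = None

    def nonzero_alpha(self, tol: float = ZERO_TOL) -> np.ndarray:
        return np.flatnonzero(np.abs(self.alpha_star) > tol)


# ---------------------------------------------------------------------------
# model functions


def _design(x: np.ndarray, intercept: bool) -> np.ndarray:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if intercept:
        return np.hstack([x, np.ones((x.shape[0], 1))])
    return x


def _check_alpha(alpha: np.ndarray, n: int, intercept: bool) -> np.ndarray:
    alpha = np.asarray(alpha, dtype=float).ravel()
    expected = n + (1 if intercept else 0)
    if alpha.shape[0] != expected:
        raise ValidationError(
            f"alpha has length {alpha.shape[0]}, expected {expected} "
            f"(n={n}, intercept={'on' if intercept else 'off'})"
        )
    return alpha


def _class1_probability(z: np.ndarray, family: str) -> np.ndarray:
    if family == "logit":
        return expit(z)
    if family == "probit":
        return ndtr(z)
    if family == "linear":
        return np.clip(z, LINEAR_EPS, 1.0 - LINEAR_EPS)
    raise ValidationError(f"unknown family {family!r}")


def _class1_derivative(z: np.ndarray, family: str) -> np.ndarray:
    """d phi_1 / dz for each family (zero where the linear family clips)."""
    if family == "logit":
        p = expit(z)
        return p * (1.0 - p)
    if family == "probit":
        return norm.pdf(z)
    if family == "linear":
        return ((z > LINEAR_EPS) & (z < 1.0 - LINEAR_EPS)).astype(float)
    raise ValidationError(f"unknown family {family!r}")


def phi(family: str, x: np.ndarray, alpha: np.ndarray, intercept: bool = True) -> np.ndarray:
    """Class-probability vector(s) ``(phi_1, phi_2)`` of the two-class model.

    ``x`` may be a single feature row or a (T, n) matrix; the result has one
    probability pair per row, summing to one.
    """
    single = np.asarray(x).ndim == 1
    X = _design(x, intercept)
    if not np.isfinite(X).all():
        raise ValidationError("non-finite feature values")
    alpha = _check_alpha(alpha, X.shape[1] - (1 if intercept else 0), intercept)
    p1 = _class1_probability(X @ alpha, family)
    out = np.column_stack([p1, 1.0 - p1])
    return out[0] if single else out


def _mix_coefficients(
    dataset: LabeledDataset, noise: _ColumnStochastic
) -> tuple[np.ndarray, np.ndarray]:
    """Per-instance mixing weights (c1, c2) over the true classes.

    A :class:`FlipMatrix` gives the proper marginal ``P(obs j | x) = sum_i
    eps[j, i] phi_i`` (the estimator's objective); a :class:`MislabelMatrix`
    gives the literal observed-conditioned mixture ``sum_i r[i, j] phi_i``.
    """
    if dataset.n_labels != 2 or noise.m != 2:
        raise ValidationError("likelihood evaluation supports two classes (m = 2)")
    if noise.n_groups != dataset.n_groups:
        raise ValidationError("mislabeling matrix group axis does not match dataset")
    j = dataset.observed_labels - 1
    g = dataset.groups - 1
    if isinstance(noise, FlipMatrix):
        return noise.r[j, 0, g], noise.r[j, 1, g]
    return noise.r[0, j, g], noise.r[1, j, g]


def _mixed_probabilities(
    dataset: LabeledDataset,
    alpha: np.ndarray,
    noise: _ColumnStochastic,
    family: str,
    intercept: bool,
) -> np.ndarray:
    """Per-instance mixed probability of the observed label (m = 2 only)."""
    X = _design(dataset.features, intercept)
    alpha = _check_alpha(alpha, dataset.n_features, intercept)
    p1 = _class1_probability(X @ alpha, family)
    c1, c2 = _mix_coefficients(dataset, noise)
    return c1 * p1 + c2 * (1.0 - p1)


def _instance_weights(dataset: LabeledDataset) -> np.ndarray:
    sizes = dataset.group_sizes()
    return 1.0 / (dataset.n_groups * sizes[dataset.groups - 1])


def log_likelihood(
    dataset: LabeledDataset,
    alpha: np.ndarray,
    r: MislabelMatrix,
    family: str = "logit",
    intercept: bool = True,
    floor: float = LOG_FLOOR,
) -> float:
    """Group-size-weighted marginal log-likelihood ``L(alpha, r)``.

    Each instance contributes ``1/(N_g T_g) * log`` of its mixed observed-label
    probability; the mixed probability is floored at ``floor`` before the log
    so degenerate parameters yield a finite (very negative) value.
    """
    mixed = _mixed_probabilities(dataset, alpha, r, family, intercept)
    w = _instance_weights(dataset)
    return float(np.sum(w * np.log(np.maximum(mixed, floor))))


def total_log_likelihood(
    dataset: LabeledDataset,
    alpha: np.ndarray,
    r: MislabelMatrix,
    family: str = "logit",
    intercept: bool = True,
    floor: float = LOG_FLOOR,
) -> float:
    """Unnormalized sum of per-instance log mixed probabilities (for AIC)."""
    mixed = _mixed_probabilities(dataset, alpha, r, family, intercept)
    return float(np.sum(np.log(np.maximum(mixed, floor))))


def grad_alpha(
    dataset: LabeledDataset,
    alpha: np.ndarray,
    r: MislabelMatrix,
    family: str = "logit",
    intercept: bool = True,
    floor: float = LOG_FLOOR,
) -> np.ndarray:
    """Analytic gradient of ``log_likelihood`` with respect to alpha.

    d/dalpha log(c1 phi_1 + c2 phi_2) = (c1 - c2) phi_1'(z) x / mixed,
    since phi_2 = 1 - phi_1 for two classes; the mixing weights (c1, c2)
    follow the convention of the matrix passed (see ``_mix_coefficients``).
    """
    X = _design(dataset.features, intercept)
    alpha = _check_alpha(alpha, dataset.n_features, intercept)
    z = X @ alpha
    p1 = _class1_probability(z, family)
    dp1 = _class1_derivative(z, family)
    c1, c2 = _mix_coefficients(dataset, r)
    mixed = np.maximum(c1 * p1 + c2 * (1.0 - p1), floor)
    w = _instance_weights(dataset)
    coef = w * (c1 - c2) * dp1 / mixed
    return X.T @ coef
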