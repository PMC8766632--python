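"""Ground-truth data generation for the co-inference model.

Features are drawn from a stated distribution, the true two-class label from
a logit model with known coefficients, and the *observed* label from a
class-conditional flip matrix ``epsilon`` with
``epsilon[j, i] = P(observed = class j | true = class i)``.

Note the direction mismatch that this module exists to manage: the
mislabeling matrix ``r`` of the likelihood conditions on the OBSERVED label,
while a generator naturally flips conditioned on the TRUE label. The two are
related by Bayes' rule through the class priors (``flip_to_r``), or
empirically from realized truth tables (``empirical_r``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import LabeledDataset, MislabelMatrix, ValidationError, phi

__all__ = ["SyntheticSpec", "SyntheticTruth", "generate", "flip_to_r", "empirical_r"]


def _validate_flip(epsilon: np.ndarray) -> np.ndarray:
    epsilon = np.asarray(epsilon, dtype=float)
    if epsilon.shape != (2, 2):
        raise ValidationError("flip matrix must be 2 x 2")
    if not np.allclose(epsilon.sum(axis=0), 1.0, atol=1e-12):
        raise ValidationError("flip matrix columns must sum to 1")
    if (epsilon < 0).any() or (epsilon > 1).any():
        raise ValidationError("flip probabilities must lie in [0, 1]")
    off = np.array([epsilon[1, 0], epsilon[0, 1]])
    if (off > 0.5).any():
        raise ValidationError("off-diagonal flip probabilities must be <= 0.5")
    return epsilon


@dataclass
class SyntheticSpec:
    """Fully-known generating process for a two-class labeled dataset.

    Defaults mimic the geometry of a categorical breast-imaging dataset:
    13 Bernoulli indicators emitted as indicator/complement pairs (26 binary
    columns), one continuous age-like feature rescaled to [0, 1], roughly
    830 instances in one group with near-balanced classes.
    """

    n_binary: int = 13
    binary_probs: Sequence[float] | float = 0.35
    complement_pairs: bool = True
    n_continuous: int = 1
    continuous_mean: float = 55.0
    continuous_sd: float = 14.0
    true_alpha: Sequence[float] | None = None
    flip: np.ndarray = field(default_factory=lambda: np.eye(2))
    group_sizes: Sequence[int] = (830,)
    seed: int = 0

    def __post_init__(self) -> None:
        self.flip = _validate_flip(self.flip)
        if any(t < 1 for t in self.group_sizes):
            raise ValidationError("group sizes must be >= 1")
        if np.isscalar(self.binary_probs):
            self.binary_probs = [float(self.binary_probs)] * self.n_binary
        if len(self.binary_probs) != self.n_binary:
            raise ValidationError("binary_probs length mismatch")
        if self.true_alpha is None:
            # sparse default: a few informative columns; intercept centers the
            # linear predictor at the feature means so classes are near-balanced
            n = self.n_features
            alpha = np.zeros(n + 1)
            rng = np.random.default_rng(12345)
            informative = rng.choice(n, size=min(5, n), replace=False)
            alpha[informative] = rng.uniform(0.8, 2.0, informative.size) * rng.choice(
                [-1, 1], informative.size
            )
            alpha[-1] = -float(alpha[:n] @ self._expected_column_means())
            self.true_alpha = alpha
        self.true_alpha = np.asarray(self.true_alpha, dtype=float)
        if self.true_alpha.shape != (self.n_features + 1,):
            raise ValidationError(
                f"true_alpha must have length n_features + 1 = {self.n_features + 1} "
                "(intercept last)"
            )

    @property
    def n_features(self) -> int:
        per_binary = 2 if self.complement_pairs else 1
        return per_binary * self.n_binary + self.n_continuous

    def _expected_column_means(self) -> np.ndarray:
        means = []
        for p in self.binary_probs:
            means.append(p)
            if self.complement_pairs:
                means.append(1.0 - p)
        means.extend([0.5] * self.n_continuous)  # min-max rescaled continuous
        return np.asarray(means)


@dataclass
class SyntheticTruth:
    """Per-row ground truth accompanying a generated dataset."""

    true_labels: np.ndarray
    observed_labels: np.ndarray
    flipped: np.ndarray
    spec: SyntheticSpec

    def __post_init__(self) -> None:
        mismatch = self.true_labels != self.observed_labels
        if not np.array_equal(mismatch, self.flipped.astype(bool)):
            raise ValidationError("flip record inconsistent with labels")


def generate(spec: SyntheticSpec) -> tuple[LabeledDataset, SyntheticTruth]:
    """Draw a dataset and its ground truth, fully determined by ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    T = int(np.sum(spec.group_sizes))
    groups = np.repeat(np.arange(1, len(spec.group_sizes) + 1), spec.group_sizes)

    cols = []
    names = []
    for b, p in enumerate(spec.binary_probs):
        x = (rng.random(T) < p).astype(float)
        cols.append(x)
        names.append(f"b{b + 1}_is")
        if spec.complement_pairs:
            cols.append(1.0 - x)
            names.append(f"b{b + 1}_not")
    for k in range(spec.n_continuous):
        raw = rng.normal(spec.continuous_mean, spec.continuous_sd, T)
        lo, hi = raw.min(), raw.max()
        cols.append((raw - lo) / (hi - lo) if hi > lo else np.zeros(T))
        names.append(f"c{k + 1}")
    X = np.column_stack(cols)

    p1 = phi("logit", X, spec.true_alpha, intercept=True)[:, 0]
    true_labels = np.where(rng.random(T) < p1, 1, 2)

    # observed label from the flip matrix, conditioned on the true label
    flip_prob = np.where(
        true_labels == 1, spec.flip[1, 0], spec.flip[0, 1]
    )  # P(observe the other class | true)
    flipped = rng.random(T) < flip_prob
    observed = np.where(flipped, 3 - true_labels, true_labels)

    dataset = LabeledDataset(
        X, observed, groups, feature_names=names, label_names=["class_1", "class_2"]
    )
    truth = SyntheticTruth(true_labels, observed, flipped, spec)
    return dataset, truth


def flip_to_r(epsilon: np.ndarray, priors: Sequence[float]) -> MislabelMatrix:
    """Bayes conversion from generative flips to the likelihood's
    observed-conditioned mislabeling matrix:

    ``r[i, j] = eps[j, i] pi_i / sum_k eps[j, k] pi_k``.
    """
    epsilon = _validate_flip(epsilon)
    pi = np.asarray(priors, dtype=float)
    if pi.shape != (2,) or not np.isclose(pi.sum(), 1.0, atol=1e-12) or (pi < 0).any():
        raise ValidationError("priors must be a 2-vector on the simplex")
    joint = epsilon * pi[None, :]  # joint[j, i] = P(obs j, true i)
    obs_marginal = joint.sum(axis=1)
    if (obs_marginal <= 0).any():
        raise ValidationError("an observed class has zero probability")
    r = (joint / obs_marginal[:, None]).T  # r[i, j] = P(true i | obs j)
    return MislabelMatrix(r[:, :, None])


def r_to_flip(r: MislabelMatrix, obs_marginal: Sequence[float]) -> np.ndarray:
    """Inverse Bayes conversion: recover ``epsilon`` from ``r`` and the
    observed-class marginals (single group)."""
    q = np.asarray(obs_marginal, dtype=float)
    joint = r.r[:, :, 0] * q[None, :]  # joint[i, j] = P(true i, obs j)
    true_marginal = joint.sum(axis=1)
    if (true_marginal <= 0).any():
        raise ValidationError("a true class has zero probability")
    return (joint / true_marginal[:, None]).T  # eps[j, i]


def empirical_r(truth: SyntheticTruth) -> MislabelMatrix:
    """Realized conditional frequencies P(true = i | observed = j) — the
    finite-sample target co-inference should recover (single group)."""
    r = np.empty((2, 2))
    for j in (1, 2):
        mask = truth.observed_labels == j
        if not mask.any():
            raise ValidationError(f"observed class {j} absent from the truth table")
        for i in (1, 2):
            r[i - 1, j - 1] = np.mean(truth.true_labels[mask] == i)
    return MislabelMatrix(r[:, :, None])
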