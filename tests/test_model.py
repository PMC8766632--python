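"""Likelihood, gradient and domain-type contracts of the core model."""

import numpy as np
import pytest
from scipy.special import expit

from colabel import (
    FlipMatrix,
    LabeledDataset,
    MislabelBounds,
    MislabelMatrix,
    grad_alpha,
    log_likelihood,
    phi,
)
from colabel.model import ValidationError


class TestPhi:
    @pytest.mark.parametrize(
        "family,alpha,x,expected_p1",
        [
            ("logit", [0.0, 0.0, 0.0], [1.0, 2.0], 0.5),
            ("logit", [np.log(3.0), 0.0, 0.0], [1.0, 5.0], 0.75),
            ("probit", [0.0, 0.0], [0.3], 0.5),
            ("linear", [1.0, 0.0], [0.4], 0.4),
        ],
    )
    def test_known_values(self, family, alpha, x, expected_p1):
        p = phi(family, np.asarray(x), np.asarray(alpha))
        assert p[0] == pytest.approx(expected_p1, abs=1e-12)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_rows_sum_to_one(self, small_dataset):
        rng = np.random.default_rng(0)
        alpha = rng.normal(size=small_dataset.n_features + 1)
        probs = phi("logit", small_dataset.features, alpha)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-12)
        assert (probs >= 0).all()

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValidationError, match="alpha has length"):
            phi("logit", np.array([1.0, 2.0]), np.array([0.5]))

    def test_nonfinite_features_raise(self):
        with pytest.raises(ValidationError, match="non-finite"):
            phi("logit", np.array([np.nan, 1.0]), np.zeros(3))


class TestLogLikelihood:
    def test_uniform_columns_collapse_to_log_m(self, small_dataset):
        """With every mixing entry 1/m the mixture is 1/m for any alpha."""
        rng = np.random.default_rng(3)
        for noise in (MislabelMatrix.uniform(2), FlipMatrix.uniform(2)):
            for _ in range(3):
                alpha = rng.normal(scale=2.0, size=small_dataset.n_features + 1)
                L = log_likelihood(small_dataset, alpha, noise)
                assert L == pytest.approx(-np.log(2.0), abs=1e-12)

    def test_identity_zero_alpha_gives_log_half(self, small_dataset):
        alpha = np.zeros(small_dataset.n_features + 1)
        for noise in (MislabelMatrix.identity(2), FlipMatrix.identity(2)):
            L = log_likelihood(small_dataset, alpha, noise)
            assert L == pytest.approx(-np.log(2.0), abs=1e-12)

    def test_single_instance_hand_value_posterior_mixing(self):
        """Observed class 2, posterior-mix columns (0.9,0.1) and (0.2,0.8),
        phi_1 = 0.75: the observed-conditioned weighting gives
        0.2*0.75 + 0.8*0.25 = 0.35."""
        ds = LabeledDataset(np.array([[np.log(3.0)]]), [2], [1])
        r = MislabelMatrix(np.array([[0.9, 0.2], [0.1, 0.8]]))
        alpha = np.array([1.0, 0.0])
        assert log_likelihood(ds, alpha, r) == pytest.approx(np.log(0.35), abs=1e-12)

    def test_single_instance_hand_value_flip_mixing(self):
        """Same matrix read as class-conditional flips: P(obs 2 | x) =
        eps[2,1]*phi_1 + eps[2,2]*phi_2 = 0.1*0.75 + 0.8*0.25 = 0.275."""
        ds = LabeledDataset(np.array([[np.log(3.0)]]), [2], [1])
        eps = FlipMatrix(np.array([[0.9, 0.2], [0.1, 0.8]]))
        alpha = np.array([1.0, 0.0])
        assert log_likelihood(ds, alpha, eps) == pytest.approx(np.log(0.275), abs=1e-12)

    def test_identity_matches_independent_glm_loglik(self, small_dataset):
        """r = identity reduces to the ordinary average GLM log-likelihood,
        recomputed here with an explicit per-sample loop."""
        rng = np.random.default_rng(8)
        alpha = rng.normal(size=small_dataset.n_features + 1)
        expected = 0.0
        for t in range(small_dataset.n_rows):
            z = small_dataset.features[t] @ alpha[:-1] + alpha[-1]
            p1 = 1.0 / (1.0 + np.exp(-z))
            p_obs = p1 if small_dataset.observed_labels[t] == 1 else 1.0 - p1
            expected += np.log(p_obs) / small_dataset.n_rows
        L = log_likelihood(small_dataset, alpha, FlipMatrix.identity(2))
        assert L == pytest.approx(expected, rel=1e-12)

    def test_never_positive(self, small_dataset):
        rng = np.random.default_rng(4)
        for _ in range(5):
            alpha = rng.normal(scale=3.0, size=small_dataset.n_features + 1)
            eps = FlipMatrix.from_off_diagonal([rng.uniform(0, 0.5)], [rng.uniform(0, 0.5)])
            assert log_likelihood(small_dataset, alpha, eps) <= 0.0

    def test_label_swap_symmetry(self, small_dataset):
        """Relabeling classes 1<->2 with the matching permutation of the
        mislabeling matrix leaves L unchanged."""
        rng = np.random.default_rng(9)
        alpha = rng.normal(size=small_dataset.n_features + 1)
        eps = FlipMatrix.from_off_diagonal([0.15], [0.05])
        L = log_likelihood(small_dataset, alpha, eps, "logit")
        swapped = LabeledDataset(
            small_dataset.features,
            3 - small_dataset.observed_labels,
            small_dataset.groups,
            small_dataset.feature_names,
            list(reversed(small_dataset.label_names)),
        )
        eps_sw = FlipMatrix(eps.r[::-1, ::-1, :])
        # phi_1 must describe the same (now second) class: negate the model
        L_sw = log_likelihood(swapped, -alpha, eps_sw, "logit")
        assert L_sw == pytest.approx(L, abs=1e-12)

    def test_non_simplex_matrix_rejected(self):
        with pytest.raises(ValidationError, match="simplex"):
            MislabelMatrix(np.array([[0.9, 0.3], [0.2, 0.7]]))

    def test_group_mismatch_rejected(self, two_group_dataset):
        alpha = np.zeros(two_group_dataset.n_features + 1)
        with pytest.raises(ValidationError, match="group"):
            log_likelihood(two_group_dataset, alpha, FlipMatrix.identity(2, 1))


class TestGradAlpha:
    @pytest.mark.parametrize("family", ["logit", "probit"])
    @pytest.mark.parametrize("convention", [MislabelMatrix, FlipMatrix])
    def test_matches_central_finite_differences(self, family, convention):
        from colabel import SyntheticSpec, generate

        spec_ds, _ = generate(
            SyntheticSpec(
                n_binary=2, n_continuous=1, complement_pairs=False,
                true_alpha=[1.0, -1.0, 0.5, 0.0], group_sizes=(20,), seed=2,
            )
        )
        rng = np.random.default_rng(21)
        noise = convention._from_off([0.1], [0.2])
        for _ in range(3):
            alpha = rng.normal(size=spec_ds.n_features + 1)
            g = grad_alpha(spec_ds, alpha, noise, family)
            h = 1e-6
            for d in range(alpha.size):
                e = np.zeros_like(alpha)
                e[d] = h
                fd = (
                    log_likelihood(spec_ds, alpha + e, noise, family)
                    - log_likelihood(spec_ds, alpha - e, noise, family)
                ) / (2 * h)
                assert g[d] == pytest.approx(fd, rel=1e-5, abs=1e-8)

    def test_uniform_mixing_gives_zero_gradient(self, small_dataset):
        alpha = np.random.default_rng(1).normal(size=small_dataset.n_features + 1)
        g = grad_alpha(small_dataset, alpha, FlipMatrix.uniform(2))
        assert np.allclose(g, 0.0, atol=1e-12)

    def test_zero_features_no_intercept_zero_gradient(self):
        ds = LabeledDataset(np.zeros((10, 2)), [1, 2] * 5, np.ones(10, dtype=int))
        g = grad_alpha(ds, np.array([1.0, -2.0]), FlipMatrix.identity(2), intercept=False)
        assert np.allclose(g, 0.0, atol=1e-12)

    def test_first_order_taylor_consistency(self, small_dataset):
        """L(a + t d) - L(a) ~ t g.d for small t at random points."""
        rng = np.random.default_rng(12)
        eps = FlipMatrix.from_off_diagonal([0.1], [0.1])
        for _ in range(10):
            alpha = rng.normal(size=small_dataset.n_features + 1)
            d = rng.normal(size=alpha.size)
            d /= np.linalg.norm(d)
            g = grad_alpha(small_dataset, alpha, eps)
            t = 1e-6
            delta = log_likelihood(small_dataset, alpha + t * d, eps) - log_likelihood(
                small_dataset, alpha, eps
            )
            assert delta == pytest.approx(t * float(g @ d), rel=1e-3, abs=1e-12)


class TestDomainTypes:
    def test_dataset_invariants_enforced(self):
        with pytest.raises(ValidationError):
            LabeledDataset(np.array([[1.0], [2.0]]), [1, 3], [1, 1], label_names=["a", "b"])
        with pytest.raises(ValidationError):
            LabeledDataset(np.array([[np.inf]]), [1], [1])
        with pytest.raises(ValidationError):
            LabeledDataset(np.array([[1.0], [1.0]]), [1, 2], [1, 3])  # group 2 empty

    def test_bounds_feasibility(self):
        # three classes: off-diagonal lower bounds 0.6 + 0.6 > 1 per column
        with pytest.raises(ValidationError, match="feasible"):
            MislabelBounds(np.full((3, 3, 1), 0.6), np.full((3, 3, 1), 0.7))
        with pytest.raises(ValidationError, match="r_lo"):
            MislabelBounds(np.full((2, 2, 1), 0.4), np.full((2, 2, 1), 0.2))
        b = MislabelBounds.uniform(0.0, 0.5)
        assert (b.r_lo <= b.r_hi).all()

    def test_flip_off_diagonal_roundtrip(self):
        eps = FlipMatrix.from_off_diagonal([0.1, 0.3], [0.2, 0.05])
        offs = eps.off_diagonals().reshape(2, 2)
        assert offs[0].tolist() == [0.1, 0.2]
        assert offs[1].tolist() == [0.3, 0.05]
        assert np.allclose(eps.r.sum(axis=0), 1.0)

    def test_flip_to_mislabel_bayes(self):
        """Symmetric flips with equal priors keep the off-diagonals."""
        eps = FlipMatrix.from_off_diagonal([0.1], [0.1])
        r = eps.to_mislabel(np.array([[0.5], [0.5]]))
        assert r.off_diagonals() == pytest.approx([0.1, 0.1], abs=1e-12)
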