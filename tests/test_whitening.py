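"""Oracle checks of the normalization operations.

Whitening matrices are checked against an explicit eigen-decomposition of
the batch covariance; the rotation ascent is checked against brute-force
search over all 2-D orthogonal matrices.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mdwhiten.autodiff import Tensor
from mdwhiten.whitening import (
    optimize_rotation,
    BatchNormState, IterNormState, RotationState,
    ValidationError, apply_rotation, batch_norm, center, iternorm_whiten,
    newton_whitening_matrix, roll_conv_batch, rotation_objective,
    unroll_conv_batch, update_rotation,
)


def eigen_whitening(X, eps=1e-5):
    """Independent oracle: W = Sigma^{-1/2} via eigen-decomposition."""
    XC = X - X.mean(axis=1, keepdims=True)
    Sigma = XC @ XC.T / X.shape[1] + eps * np.eye(X.shape[0])
    evals, evecs = np.linalg.eigh(Sigma)
    return evecs @ np.diag(evals**-0.5) @ evecs.T


def correlated_batch(rng, d, m):
    A = rng.standard_normal((d, d))
    return A @ rng.standard_normal((d, m)) + rng.standard_normal((d, 1))


# ---------------------------------------------------------------------------
# centering and batch normalization
# ---------------------------------------------------------------------------


class TestCenter:
    def test_zero_mean_input_unchanged(self, rng):
        X = rng.standard_normal((4, 10))
        X -= X.mean(axis=1, keepdims=True)
        XC, mu = center(X)
        assert np.allclose(XC, X)
        assert np.allclose(mu, 0)

    def test_constant_input_centers_to_zero(self):
        X = np.full((3, 7), 4.2)
        XC, mu = center(X)
        assert np.allclose(XC, 0)
        assert np.allclose(mu, 4.2)

    def test_row_sums_vanish(self, rng):
        X = 100.0 * rng.standard_normal((6, 50))
        XC, _ = center(X)
        tol = 1e-10 * X.shape[1] * np.abs(X).max()
        assert np.abs(XC.sum(axis=1)).max() < tol


class TestBatchNorm:
    def test_identity_on_standardized_input(self, rng):
        X = rng.standard_normal((4, 200))
        X -= X.mean(axis=1, keepdims=True)
        X /= np.sqrt((X**2).mean(axis=1, keepdims=True))
        state = BatchNormState.identity(4, eps=1e-12)
        out = batch_norm(X, state, training=True)
        assert np.allclose(out, X, atol=1e-6)

    def test_affine_contract(self, rng):
        X = correlated_batch(rng, 5, 300)
        state = BatchNormState(scale=np.full(5, 2.0), shift=np.full(5, 5.0))
        out = batch_norm(X, state, training=True)
        assert np.allclose(out.mean(axis=1), 5.0, atol=1e-8)
        assert np.allclose(np.sqrt((out - 5.0).var(axis=1)) / 2.0, 1.0, atol=1e-3)

    def test_matches_elementwise_loop(self, rng):
        d, m, eps = 4, 64, 1e-5
        X = correlated_batch(rng, d, m)
        scale = rng.standard_normal(d)
        shift = rng.standard_normal(d)
        state = BatchNormState(scale=scale.copy(), shift=shift.copy(), eps=eps)
        out = batch_norm(X, state, training=True)
        expected = np.empty_like(X)
        for i in range(d):
            mu = sum(X[i]) / m
            var = sum((X[i, j] - mu) ** 2 for j in range(m)) / m
            for j in range(m):
                xs = (X[i, j] - mu) / np.sqrt(var + eps)
                expected[i, j] = scale[i] * xs + shift[i]
        assert np.abs(out - expected).max() < 1e-10

    def test_inference_uses_running_statistics(self, rng):
        X = correlated_batch(rng, 3, 100)
        state = BatchNormState.identity(3, momentum=1.0)  # adopt batch stats
        batch_norm(X, state, training=True)
        out = batch_norm(X[:, :10], state, training=False)
        mu, var = X.mean(axis=1), X.var(axis=1)
        expected = (X[:, :10] - mu[:, None]) / np.sqrt(var + state.eps)[:, None]
        assert np.allclose(out, expected)

    def test_single_sample_training_rejected(self):
        with pytest.raises(ValidationError):
            batch_norm(np.ones((3, 1)), BatchNormState.identity(3), training=True)

    def test_column_permutation_equivariance(self, rng):
        X = correlated_batch(rng, 4, 40)
        perm = rng.permutation(40)
        out = batch_norm(X, BatchNormState.identity(4), training=True)
        out_p = batch_norm(X[:, perm], BatchNormState.identity(4), training=True)
        assert np.allclose(out[:, perm], out_p)


# ---------------------------------------------------------------------------
# IterNorm whitening
# ---------------------------------------------------------------------------


class TestIterNorm:
    def test_identity_covariance_fixed_point(self, rng):
        d, m = 4, 256
        X = correlated_batch(rng, d, m)
        # whiten exactly with the eigen oracle so cov is Id
        X = eigen_whitening(X, eps=0.0) @ (X - X.mean(axis=1, keepdims=True))
        state = IterNormState(d=d, num_iterations=20)
        XW, W = iternorm_whiten(X, state, training=True)
        assert np.abs(W - np.eye(d)).max() < 1e-3
        assert np.abs(XW - X).max() < 1e-3

    @pytest.mark.parametrize("d", [2, 4, 8, 16])
    def test_matches_eigen_oracle(self, d, rng):
        m = 64 * d
        X = correlated_batch(rng, d, m)
        state = IterNormState(d=d, num_iterations=20)
        _, W = iternorm_whiten(X, state, training=True)
        assert np.abs(W - eigen_whitening(X)).max() < 1e-4

    @pytest.mark.parametrize("K,tol", [(20, 0.05), (5, 0.3)])
    def test_output_covariance_near_identity(self, K, tol, rng):
        d, m = 8, 512
        # moderate spread so 5 Newton iterations reach the fixed point
        scales = np.exp(rng.uniform(-0.4, 0.4, d))
        X = scales[:, None] * rng.standard_normal((d, m))
        state = IterNormState(d=d, num_iterations=K)
        XW, _ = iternorm_whiten(X, state, training=True)
        cov = XW @ XW.T / m
        assert np.linalg.norm(cov - np.eye(d)) < tol

    def test_inference_applies_running_statistics(self, rng):
        d = 3
        X = correlated_batch(rng, d, 200)
        state = IterNormState(d=d, num_iterations=20, momentum=1.0)
        _, W = iternorm_whiten(X, state, training=True)
        XW_inf, _ = iternorm_whiten(X[:, :5], state, training=False)
        expected = W @ (X[:, :5] - X.mean(axis=1, keepdims=True))
        assert np.allclose(XW_inf, expected, atol=1e-10)

    def test_column_permutation_equivariance(self, rng):
        X = correlated_batch(rng, 4, 60)
        perm = np.random.default_rng(5).permutation(60)
        XW, _ = iternorm_whiten(X, IterNormState(d=4), training=True)
        XW_p, _ = iternorm_whiten(X[:, perm], IterNormState(d=4), training=True)
        assert np.allclose(XW[:, perm], XW_p)

    def test_input_validation(self):
        state = IterNormState(d=3)
        with pytest.raises(ValidationError):
            iternorm_whiten(np.ones((3, 1)), state, training=True)
        with pytest.raises(ValidationError):
            iternorm_whiten(np.ones((4, 8)), state, training=True)
        with pytest.raises(ValidationError):
            iternorm_whiten(np.full((3, 8), np.nan), state, training=True)

    def test_gradients_through_newton_iterations(self, rng):
        """Autodiff gradient of the whitened output vs finite differences."""
        d, m, K = 3, 8, 5
        X0 = rng.standard_normal((d, m))
        C = rng.standard_normal((d, m))  # fixed functional; plain sum is 0

        def f(x):
            XW, _ = iternorm_whiten(x, IterNormState(d=d, num_iterations=K),
                                    training=True)
            return float((C * XW).sum())

        Xt = Tensor(X0.copy(), requires_grad=True)
        XC = Xt - Xt.mean(axis=1, keepdims=True)
        W = newton_whitening_matrix(XC, m, 1e-5, K, Tensor(np.eye(d)))
        ((W @ XC) * C).sum().backward()
        fd = np.zeros_like(X0)
        h = 1e-6
        for i in range(d):
            for j in range(m):
                Xp, Xm = X0.copy(), X0.copy()
                Xp[i, j] += h
                Xm[i, j] -= h
                fd[i, j] = (f(Xp) - f(Xm)) / (2 * h)
        rel = np.abs(Xt.grad - fd).max() / np.abs(fd).max()
        assert rel < 1e-4


# ---------------------------------------------------------------------------
# rotation
# ---------------------------------------------------------------------------


def grid_search_best(XW, labels, resolution=1e-4):
    """Brute-force optimum over all 2-D orthogonal matrices."""
    thetas = np.arange(0.0, 2 * np.pi, resolution)
    nc = int(labels.max()) + 1
    M = np.stack([XW[:, labels == i].mean(axis=1) for i in range(nc)], axis=1)
    c, s = np.cos(thetas), np.sin(thetas)
    best = -np.inf
    for refl in (1.0, -1.0):
        # columns of Q: q0 = (c, s), q1 = refl * (-s, c)
        vals = (c * M[0, 0] + s * M[1, 0]) + refl * (-s * M[0, 1] + c * M[1, 1])
        best = max(best, vals.max())
    return float(best)


class TestRotation:
    def test_perfect_alignment_value(self):
        d, nc = 4, 3
        XW = np.eye(d)[:, :nc].repeat(2, axis=1)  # class means = basis vectors
        labels = np.repeat(np.arange(nc), 2)
        assert rotation_objective(XW, labels, np.eye(d)) == pytest.approx(nc)

    def test_axis_reflection_flips_one_term(self, rng):
        XW = rng.standard_normal((3, 30))
        labels = np.arange(30) % 3
        Q = np.eye(3)
        Qf = Q @ np.diag([-1.0, 1.0, 1.0])
        obj, obj_f = (rotation_objective(XW, labels, q) for q in (Q, Qf))
        means = [XW[:, labels == i].mean(axis=1) for i in range(3)]
        assert obj - obj_f == pytest.approx(2 * means[0][0], abs=1e-12)

    def test_missing_class_rejected(self):
        XW = np.ones((2, 4))
        with pytest.raises(ValidationError):
            rotation_objective(XW, np.array([0, 0, 0, 2]), np.eye(2))

    def test_zero_gradient_is_fixed_point(self, rng):
        d = 3
        half = rng.standard_normal((d, 10))
        XW = np.concatenate([half, -half], axis=1)  # all class means zero
        labels = np.tile(np.array([0, 1]).repeat(5), 2)
        state = RotationState.identity(d, 2)
        new = update_rotation(XW, labels, state)
        assert np.allclose(new.Q, state.Q)

    @pytest.mark.parametrize("seed", [0, 1, 12345])
    def test_ascent_reaches_grid_search_optimum(self, seed):
        """Two-branch Cayley ascent matches brute force over all of O(2)."""
        gen = np.random.default_rng(seed)
        XW = gen.standard_normal((2, 40))
        labels = np.arange(40) % 2
        best = grid_search_best(XW, labels)
        state = optimize_rotation(XW, labels, n_classes=2, steps=500)
        achieved = rotation_objective(XW, labels, state.Q)
        assert achieved == pytest.approx(best, abs=1e-3)

    def test_identity_branch_ascends_monotonically(self, rng):
        XW = rng.standard_normal((2, 40))
        labels = np.arange(40) % 2
        state = RotationState.identity(2, 2, step_size=0.05)
        prev = rotation_objective(XW, labels, state.Q)
        for _ in range(50):
            state = update_rotation(XW, labels, state)
            cur = rotation_objective(XW, labels, state.Q)
            assert cur >= prev - 1e-12
            prev = cur

    def test_orthogonality_preserved_over_many_updates(self, rng):
        d = 5
        XW = rng.standard_normal((d, 60))
        labels = np.arange(60) % 3
        state = RotationState.identity(d, 3, step_size=0.05)
        worst = 0.0
        for _ in range(1000):
            state = update_rotation(XW, labels, state)
            drift = np.abs(state.Q.T @ state.Q - np.eye(d)).max()
            worst = max(worst, drift)
        assert worst <= 1e-6
        assert state.num_updates == 1000

    def test_apply_rotation_contracts(self, rng):
        XW = rng.standard_normal((4, 100))
        assert np.allclose(apply_rotation(XW, np.eye(4)), XW)
        Q, _ = np.linalg.qr(rng.standard_normal((4, 4)))
        out = apply_rotation(XW, Q)
        assert np.linalg.norm(out) == pytest.approx(np.linalg.norm(XW))
        # whitened inputs stay whitened
        XWw = eigen_whitening(XW, eps=0.0) @ (XW - XW.mean(1, keepdims=True))
        cov = apply_rotation(XWw, Q) @ apply_rotation(XWw, Q).T / XWw.shape[1]
        assert np.abs(cov - np.eye(4)).max() < 1e-6


# ---------------------------------------------------------------------------
# unrolling
# ---------------------------------------------------------------------------


class TestUnroll:
    def test_shape_arithmetic(self, rng):
        A = rng.standard_normal((2, 2, 3, 4))
        assert unroll_conv_batch(A).shape == (3, 16)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        hd=st.integers(1, 5), wd=st.integers(1, 5),
        L=st.integers(1, 6), m=st.integers(1, 4),
    )
    def test_roll_inverts_unroll(self, hd, wd, L, m):
        A = np.random.default_rng(hd * 1000 + wd * 100 + L * 10 + m).normal(
            size=(hd, wd, L, m)
        )
        assert np.array_equal(roll_conv_batch(unroll_conv_batch(A), hd, wd), A)

    def test_rows_preserve_channel_multisets(self, rng):
        A = rng.standard_normal((3, 4, 5, 2))
        X = unroll_conv_batch(A)
        for ch in range(5):
            assert np.allclose(
                np.sort(X[ch]), np.sort(A[:, :, ch, :].ravel())
            )
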