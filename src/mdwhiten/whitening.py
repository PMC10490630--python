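"""Normalization layers: batch normalization, iterative batch whitening, rotation.

Three normalizations of a batch matrix ``X`` (shape ``d x m``: *d* features,
*m* samples) are implemented:

* **Batch normalization (BN)** — per-feature centering and variance scaling
  followed by a learnable affine transform.
* **IterNorm batch whitening** — full whitening ``XW = W @ XC`` with
  ``W ~ Sigma^{-1/2}`` computed by Newton's iterations on the
  trace-normalized covariance, avoiding an eigen-decomposition.  With ``K``
  iterations and trace normalization the iterates converge for any SPD
  covariance.
* **IterNorm + rotation** — exploits the rotational freedom of whitening
  (``Q.T @ W`` is a valid whitening matrix for any orthogonal ``Q``) to align
  the first ``Nc`` latent axes with the class labels, by Cayley-transform
  ascent of the summed per-class mean activations on the Stiefel manifold.

Two parallel APIs are provided.  The functional API (:func:`center`,
:func:`batch_norm`, :func:`iternorm_whiten`, :func:`rotation_objective`,
:func:`update_rotation`, :func:`apply_rotation`, :func:`unroll_conv_batch`)
operates on plain numpy arrays and carries explicit state objects; it is the
reference implementation validated against eigen-decomposition and
grid-search oracles.  The layer classes (:class:`BatchNormLayer`,
:class:`IterNormLayer`, :class:`IterNormRotationLayer`) run the same math on
:class:`~mdwhiten.autodiff.Tensor` inputs inside the CNN, so gradients
propagate through the centering, the covariance and all Newton iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, no_grad


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


class NumericalError(FloatingPointError):
    """Raised when an iterative computation produces non-finite values."""


# ---------------------------------------------------------------------------
# state containers
# ---------------------------------------------------------------------------


@dataclass
class BatchNormState:
    """Learnable and running state of a BN layer over ``d`` features."""

    scale: np.ndarray  # per-feature gain, length d
    shift: np.ndarray  # per-feature offset, length d
    eps: float = 1e-5
    momentum: float = 0.1
    running_mean: np.ndarray = None
    running_var: np.ndarray = None

    def __post_init__(self):
        d = len(self.scale)
        if self.eps <= 0:
            raise ValidationError("eps must be positive")
        if self.running_mean is None:
            self.running_mean = np.zeros(d)
        if self.running_var is None:
            self.running_var = np.ones(d)

    @classmethod
    def identity(cls, d: int, eps: float = 1e-5, momentum: float = 0.1):
        return cls(scale=np.ones(d), shift=np.zeros(d), eps=eps, momentum=momentum)


@dataclass
class IterNormState:
    """Hyperparameters and running inference statistics of a whitening layer."""

    d: int
    num_iterations: int = 5
    eps: float = 1e-5
    momentum: float = 0.1
    running_mean: np.ndarray = None
    running_whitening_matrix: np.ndarray = None

    def __post_init__(self):
        if self.num_iterations < 1:
            raise ValidationError("num_iterations must be >= 1")
        if self.eps <= 0:
            raise ValidationError("eps must be positive")
        if self.running_mean is None:
            self.running_mean = np.zeros(self.d)
        if self.running_whitening_matrix is None:
            self.running_whitening_matrix = np.eye(self.d)


@dataclass
class RotationState:
    """Orthogonal alignment matrix with class-to-axis bookkeeping.

    Class ``i`` (label-sort order) is aligned with column ``i`` of ``Q``;
    the remaining ``d - n_classes`` axes are unconstrained.
    """

    Q: np.ndarray
    n_classes: int
    step_size: float = 0.05
    num_updates: int = 0

    def __post_init__(self):
        d = self.Q.shape[0]
        if self.Q.shape != (d, d):
            raise ValidationError("Q must be square")
        if self.n_classes > d:
            raise ValidationError("n_classes may not exceed the feature dimension")

    @classmethod
    def identity(cls, d: int, n_classes: int, step_size: float = 0.05):
        return cls(Q=np.eye(d), n_classes=n_classes, step_size=step_size)


# ---------------------------------------------------------------------------
# functional API (numpy)
# ---------------------------------------------------------------------------


def _check_batch(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError("batch input must be a d x m matrix")
    if not np.all(np.isfinite(X)):
        raise ValidationError("batch input contains non-finite values")
    return X


def center(X: np.ndarray):
    """Remove the batch mean: returns ``(XC, mu)`` with ``XC = X - mu 1m^T``."""
    X = _check_batch(X)
    mu = X.mean(axis=1)
    return X - mu[:, None], mu


def batch_norm(X: np.ndarray, state: BatchNormState, training: bool = True):
    """Standardize each feature over the batch, then apply the affine transform.

    Training mode uses batch statistics (biased 1/m variance) and updates the
    exponential moving averages in ``state``; inference mode standardizes with
    the running statistics.
    """
    X = _check_batch(X)
    d, m = X.shape
    if training:
        if m < 2:
            raise ValidationError("training-mode batch_norm needs m >= 2")
        XC, mu = center(X)
        var = np.mean(XC**2, axis=1)
        XS = XC / np.sqrt(var + state.eps)[:, None]
        r = state.momentum
        state.running_mean = (1 - r) * state.running_mean + r * mu
        state.running_var = (1 - r) * state.running_var + r * var
    else:
        XS = (X - state.running_mean[:, None]) / np.sqrt(
            state.running_var + state.eps
        )[:, None]
    return state.scale[:, None] * XS + state.shift[:, None]


def newton_whitening_matrix(XC, m: int, eps: float, num_iterations: int, eye):
    """Shared Newton recursion for ``W ~ Sigma^{-1/2}``.

    Written against the minimal operator set (``@``, ``*``, ``+``, ``.T``,
    ``sum``, scalar ``**``) so the same code runs on numpy arrays and on
    autodiff tensors; ``eye`` must be an identity of the matching kind.

    Steps: ``Sigma = XC XC^T / m + eps I``; ``Sigma_N = Sigma / tr(Sigma)``;
    ``P_0 = I``, ``P_k = (3 P_{k-1} - P_{k-1}^3 Sigma_N) / 2``;
    ``W = P_K / sqrt(tr(Sigma))``.

    The recursion is evaluated in its coupled, self-correcting form
    (``T_k = (3 I - Z_{k-1}) / 2``, ``P_k = P_{k-1} T_k``,
    ``Z_k = T_k Z_{k-1} T_k`` with ``Z_0 = Sigma_N``), which produces the
    same iterates in exact arithmetic (all factors are polynomials in
    ``Sigma_N`` and commute) but remains numerically stable well past
    convergence, where the textbook one-matrix recursion amplifies roundoff
    once the condition number exceeds ~2.4.
    """
    Sigma = (XC @ XC.T) * (1.0 / m) + eps * eye
    tr = (Sigma * eye).sum()
    SigmaN = Sigma * tr**-1.0
    P = eye
    Z = SigmaN
    for _ in range(num_iterations):
        T = 0.5 * (3.0 * eye - Z)
        P = P @ T
        Z = T @ Z @ T
    return P * tr**-0.5


def iternorm_whiten(X: np.ndarray, state: IterNormState, training: bool = True):
    """Whiten a batch with the Newton-iteration whitening matrix.

    Returns ``(XW, W)``.  Training mode estimates ``W`` from the batch and
    updates the running mean and running whitening matrix; inference mode
    applies the stored running statistics.
    """
    X = _check_batch(X)
    d, m = X.shape
    if d != state.d:
        raise ValidationError(f"expected d={state.d} features, got {d}")
    if not training:
        XW = state.running_whitening_matrix @ (X - state.running_mean[:, None])
        return XW, state.running_whitening_matrix
    if m < 2:
        raise ValidationError("training-mode whitening needs m >= 2")

    XC, mu = center(X)
    eye = np.eye(d)
    Sigma = XC @ XC.T / m + state.eps * eye
    if not np.all(np.isfinite(Sigma)):
        raise NumericalError("covariance estimate (line 3) is non-finite")
    tr = np.trace(Sigma)
    if not tr > 0:
        raise NumericalError("trace normalization (line 4) undefined: tr(Sigma) <= 0")
    SigmaN = Sigma / tr
    P = eye
    Z = SigmaN
    for k in range(1, state.num_iterations + 1):
        T = 0.5 * (3.0 * eye - Z)
        P = P @ T
        Z = T @ Z @ T
        if not np.all(np.isfinite(P)):
            raise NumericalError(f"Newton iterate {k} (line 7) diverged to non-finite values")
    W = P / np.sqrt(tr)
    XW = W @ XC

    r = state.momentum
    state.running_mean = (1 - r) * state.running_mean + r * mu
    state.running_whitening_matrix = (
        (1 - r) * state.running_whitening_matrix + r * W
    )
    return XW, W


def _class_mean_matrix(XW: np.ndarray, labels: np.ndarray, n_classes: int):
    """d x n_classes matrix whose column i is the mean of class-i samples."""
    d, m = XW.shape
    labels = np.asarray(labels)
    if labels.shape != (m,):
        raise ValidationError("labels must have one entry per sample column")
    M = np.zeros((d, n_classes))
    for i in range(n_classes):
        mask = labels == i
        if not mask.any():
            raise ValidationError(f"class {i} has no samples in the batch")
        M[:, i] = XW[:, mask].mean(axis=1)
    return M


def rotation_objective(XW: np.ndarray, labels: np.ndarray, Q: np.ndarray) -> float:
    """Summed mean activation of each class along its assigned axis.

    ``sum_i q_i^T mean(XW restricted to class i)`` — the quantity the
    rotation module ascends, maximal when each class mean points along its
    own latent axis.
    """
    XW = _check_batch(XW)
    n_classes = int(np.max(labels)) + 1
    M = _class_mean_matrix(XW, labels, n_classes)
    return float(np.sum(Q[:, :n_classes] * M))


def _reorthogonalize(Q: np.ndarray) -> np.ndarray:
    # polar factor: nearest orthogonal matrix in Frobenius norm
    U, _, Vt = np.linalg.svd(Q)
    return U @ Vt


def cayley_ascent_step(Q: np.ndarray, G: np.ndarray, eta: float) -> np.ndarray:
    """One orthogonality-preserving ascent step along Euclidean gradient ``G``.

    The skew-symmetric relative gradient ``A = Q G^T - G Q^T`` is mapped
    through the Cayley retraction
    ``Q <- (I + eta/2 A)^{-1} (I - eta/2 A) Q`` (the sign of ``A`` is chosen
    so the objective increases for small ``eta``); orthogonality is
    preserved to roundoff, with a polar-factor re-orthogonalization if
    drift ever exceeds 1e-6.
    """
    d = Q.shape[0]
    A = Q @ G.T - G @ Q.T
    eye = np.eye(d)
    lhs = eye + 0.5 * eta * A
    if abs(np.linalg.det(lhs)) < 1e-12:
        raise NumericalError("Cayley factor is singular; reduce the step size")
    Q_new = np.linalg.solve(lhs, (eye - 0.5 * eta * A) @ Q)
    if np.max(np.abs(Q_new.T @ Q_new - eye)) > 1e-6:
        Q_new = _reorthogonalize(Q_new)
    return Q_new


def update_rotation(
    XW: np.ndarray, labels: np.ndarray, state: RotationState
) -> RotationState:
    """One Cayley-transform ascent step of the class-alignment objective.

    The Euclidean gradient ``G`` has the class means in its first ``Nc``
    columns and zeros elsewhere.  Classes absent from the batch contribute
    a zero gradient column.
    """
    XW = _check_batch(XW)
    d, m = XW.shape
    G = np.zeros((d, d))
    labels = np.asarray(labels)
    for i in range(state.n_classes):
        mask = labels == i
        if mask.any():
            G[:, i] = XW[:, mask].mean(axis=1)
    Q_new = cayley_ascent_step(state.Q, G, state.step_size)
    return RotationState(
        Q=Q_new,
        n_classes=state.n_classes,
        step_size=state.step_size,
        num_updates=state.num_updates + 1,
    )


def optimize_rotation(
    XW: np.ndarray,
    labels: np.ndarray,
    n_classes: int,
    step_size: float = 0.2,
    steps: int = 500,
) -> RotationState:
    """Run the Cayley ascent to convergence over both components of O(d).

    The Cayley retraction preserves the determinant, so a single ascent
    explores only one connected component of the orthogonal group.  The
    alignment objective admits reflections, whose optimum can exceed the
    best proper rotation; ascending from the identity and from one
    reflection seed covers both components, and the better endpoint is
    returned.
    """
    d = XW.shape[0]
    seeds = [np.eye(d), np.diag([1.0] * (d - 1) + [-1.0])]
    best_state, best_val = None, -np.inf
    for Q0 in seeds:
        state = RotationState(Q=Q0, n_classes=n_classes, step_size=step_size)
        for _ in range(steps):
            state = update_rotation(XW, labels, state)
        val = rotation_objective(XW, labels, state.Q)
        if val > best_val:
            best_state, best_val = state, val
    return best_state


def apply_rotation(XW: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Rotate whitened activations into the aligned frame: ``Q^T @ XW``."""
    return Q.T @ XW


def unroll_conv_batch(A: np.ndarray) -> np.ndarray:
    """Unroll conv activations ``(hd, wd, L, m)`` to a ``L x (m hd wd)`` batch.

    The channel index becomes the feature (row) dimension; every spatial
    position of every sample becomes one column.  Inverted exactly by
    :func:`roll_conv_batch`.
    """
    A = np.asarray(A)
    if A.ndim != 4:
        raise ValidationError("expected activations of shape (hd, wd, L, m)")
    hd, wd, L, m = A.shape
    return A.transpose(2, 3, 0, 1).reshape(L, m * hd * wd)


def roll_conv_batch(X: np.ndarray, hd: int, wd: int) -> np.ndarray:
    """Inverse of :func:`unroll_conv_batch`."""
    L, cols = X.shape
    m = cols // (hd * wd)
    if m * hd * wd != cols:
        raise ValidationError("column count incompatible with the spatial shape")
    return X.reshape(L, m, hd, wd).transpose(2, 3, 0, 1)


# ---------------------------------------------------------------------------
# autodiff layers (used inside the CNN)
# ---------------------------------------------------------------------------


class BatchNormLayer:
    """BN over an unrolled ``d x m_eff`` tensor batch, with learnable affine."""

    kind = "bn"

    def __init__(self, d: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float32):
        self.d = d
        self.eps = eps
        self.momentum = momentum
        self.weight = Tensor(np.ones((d, 1), dtype=dtype), requires_grad=True)
        self.bias = Tensor(np.zeros((d, 1), dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros((d, 1), dtype=dtype)
        self.running_var = np.ones((d, 1), dtype=dtype)

    def parameters(self):
        return [self.weight, self.bias]

    def forward(self, X: Tensor, labels_cols=None, training: bool = False) -> Tensor:
        if training:
            m = X.shape[1]
            mu = X.mean(axis=1, keepdims=True)
            XC = X - mu
            var = (XC * XC).mean(axis=1, keepdims=True)
            XS = XC * (var + self.eps) ** -0.5
            r = self.momentum
            self.running_mean = ((1 - r) * self.running_mean
                                 + r * mu.data.astype(self.running_mean.dtype))
            self.running_var = ((1 - r) * self.running_var
                                + r * var.data.astype(self.running_var.dtype))
        else:
            XS = (X - self.running_mean) * (self.running_var + self.eps) ** -0.5
        return self.weight * XS + self.bias

    def state_dict(self):
        return {
            "weight": self.weight.data,
            "bias": self.bias.data,
            "running_mean": self.running_mean,
            "running_var": self.running_var,
        }

    def load_state_dict(self, sd):
        self.weight.data = np.array(sd["weight"])
        self.bias.data = np.array(sd["bias"])
        self.running_mean = np.array(sd["running_mean"])
        self.running_var = np.array(sd["running_var"])


class IterNormLayer:
    """Newton-iteration whitening over an unrolled tensor batch.

    Gradients propagate through the batch mean, the covariance and all ``K``
    Newton iterates.  A learnable per-channel affine follows the whitening
    by default, restoring representation power the way BN's affine does.
    """

    kind = "iternorm"

    def __init__(self, d: int, num_iterations: int = 5, eps: float = 1e-5,
                 momentum: float = 0.1, affine: bool = True, dtype=np.float32):
        self.d = d
        self.K = num_iterations
        self.eps = eps
        self.momentum = momentum
        self.affine = affine
        self.running_mean = np.zeros((d, 1), dtype=dtype)
        self.running_W = np.eye(d, dtype=dtype)
        if affine:
            self.weight = Tensor(np.ones((d, 1), dtype=dtype), requires_grad=True)
            self.bias = Tensor(np.zeros((d, 1), dtype=dtype), requires_grad=True)

    def parameters(self):
        return [self.weight, self.bias] if self.affine else []

    def _whiten(self, X: Tensor, training: bool) -> Tensor:
        if training:
            m = X.shape[1]
            mu = X.mean(axis=1, keepdims=True)
            XC = X - mu
            eye = Tensor(np.eye(self.d, dtype=X.dtype))
            W = newton_whitening_matrix(XC, m, self.eps, self.K, eye)
            XW = W @ XC
            r = self.momentum
            self.running_mean = ((1 - r) * self.running_mean
                                 + r * mu.data.astype(self.running_mean.dtype))
            self.running_W = ((1 - r) * self.running_W
                              + r * W.data.astype(self.running_W.dtype))
            return XW
        return Tensor(self.running_W) @ (X - self.running_mean)

    def forward(self, X: Tensor, labels_cols=None, training: bool = False) -> Tensor:
        XW = self._whiten(X, training)
        if self.affine:
            XW = self.weight * XW + self.bias
        return XW

    def state_dict(self):
        sd = {"running_mean": self.running_mean, "running_W": self.running_W}
        if self.affine:
            sd["weight"] = self.weight.data
            sd["bias"] = self.bias.data
        return sd

    def load_state_dict(self, sd):
        self.running_mean = np.array(sd["running_mean"])
        self.running_W = np.array(sd["running_W"])
        if self.affine:
            self.weight.data = np.array(sd["weight"])
            self.bias.data = np.array(sd["bias"])


class IterNormRotationLayer(IterNormLayer):
    """IterNorm whitening followed by the class-aligning rotation ``Q^T``.

    ``Q`` is not a gradient-descent parameter of the loss: in training mode
    each batch takes one Cayley ascent step of the class-alignment
    objective, then applies the updated rotation.  Two refinements keep the
    per-batch updates stable on small batches:

    * the ascent gradient is built from an exponential moving average of
      the per-class mean activations rather than from the raw batch means
      (a handful of samples per class per batch is pure noise);
    * every update is a re-parameterization: rotating the latent axes by
      ``R = Q_new^T Q_old`` changes the layer output (post-affine) by the
      fixed linear map ``M = D_a R D_a^{-1}`` plus a shift in ``b``;
      counter-mixing the input channels of the next linear layer by
      ``M^{-1}`` preserves the network function (exactly in the linear
      interior; the constant-shift term is absorbed into the rotation
      bias itself, see below).  The model polls
      :meth:`consume_compensation` after the layer's forward pass.

    The layer order is whiten -> rotate -> affine, so the output covariance
    stays diagonal (whitened up to per-axis scale) and the diagonal affine
    rescales the aligned axes without re-mixing them.  To keep the
    compensation exact, the shift ``b`` is transported through the axis
    change (``b`` is re-expressed so that ``a (x) Q^T XW + b`` is
    continuous across the update): ``out_new = M (out_old - b_old) +
    b_old`` exactly when ``b`` is held fixed, so the full update is the
    linear map ``M`` around the point ``b_old``, and the next layer's
    weights absorb ``M`` while its bias absorbs ``(I - M) b_old`` through
    the layer's mean response.  In practice ``b`` starts at zero and stays
    small, and per-batch ``R`` is near identity; the induced interior
    compensation is exact and the padding-border residual is second-order.
    """

    kind = "iternorm_rot"

    def __init__(self, d: int, n_classes: int, num_iterations: int = 5,
                 eps: float = 1e-5, momentum: float = 0.1,
                 rotation_step: float = 0.05, mean_momentum: float = 0.1,
                 affine: bool = True, dtype=np.float32):
        super().__init__(d, num_iterations, eps, momentum, affine=affine,
                         dtype=dtype)
        self.rotation = RotationState.identity(d, n_classes, rotation_step)
        self.mean_momentum = mean_momentum
        self.class_means = np.zeros((d, n_classes))
        self._pending_compensation: np.ndarray | None = None

    def forward(self, X: Tensor, labels_cols=None, training: bool = False) -> Tensor:
        XW = self._whiten(X, training)
        if training and labels_cols is not None:
            with no_grad():
                self._update_rotation(XW.data.astype(float),
                                      np.asarray(labels_cols))
        out = Tensor(self.rotation.Q.T.astype(XW.dtype)) @ XW
        if self.affine:
            out = self.weight * out + self.bias
        return out

    def _update_rotation(self, XW: np.ndarray, labels: np.ndarray):
        r = self.mean_momentum
        # the alignment objective and its gradient live on the whitened
        # (pre-rotation) activations: G's column i is the class-i mean
        for i in range(self.rotation.n_classes):
            mask = labels == i
            if mask.any():
                self.class_means[:, i] = (
                    (1 - r) * self.class_means[:, i]
                    + r * XW[:, mask].mean(axis=1)
                )
        G = np.zeros((self.d, self.d))
        G[:, : self.rotation.n_classes] = self.class_means
        Q_old = self.rotation.Q
        Q_new = cayley_ascent_step(Q_old, G, self.rotation.step_size)
        R = Q_new.T @ Q_old
        if self.affine:
            # output transforms by M = D_a R D_a^{-1}; the shift is
            # transported along (b <- M b) so the map is purely linear,
            # and the next layer's input channels must be mixed by
            # C = M^{-T} = D_a^{-1} R D_a to cancel it exactly
            a = self.weight.data.astype(float).ravel()
            M = (a[:, None] * R) / a[None, :]
            self.bias.data = (M @ self.bias.data.astype(float)).astype(
                self.bias.data.dtype
            )
            C = (R * a[None, :]) / a[:, None]
        else:
            C = R
        self._pending_compensation = (
            C if self._pending_compensation is None
            else C @ self._pending_compensation
        )
        self.rotation = RotationState(
            Q=Q_new,
            n_classes=self.rotation.n_classes,
            step_size=self.rotation.step_size,
            num_updates=self.rotation.num_updates + 1,
        )

    def consume_compensation(self) -> np.ndarray | None:
        """The accumulated axis change since the last poll, or None.

        Mixing the next linear layer's input channels by the returned
        orthogonal matrix ``R`` preserves the network function exactly.
        """
        R = self._pending_compensation
        self._pending_compensation = None
        return R

    def state_dict(self):
        sd = super().state_dict()
        sd["Q"] = self.rotation.Q
        sd["rotation_step"] = np.array(self.rotation.step_size)
        sd["rotation_updates"] = np.array(self.rotation.num_updates)
        sd["class_means"] = self.class_means
        return sd

    def load_state_dict(self, sd):
        super().load_state_dict(sd)
        self.rotation = RotationState(
            Q=np.array(sd["Q"]),
            n_classes=self.rotation.n_classes,
            step_size=float(sd["rotation_step"]),
            num_updates=int(sd["rotation_updates"]),
        )
        self.class_means = np.array(sd["class_means"])


class IdentityNorm:
    """No-op stand-in used for variant-parity checks."""

    kind = "none"

    def __init__(self, d: int, **_):
        self.d = d

    def parameters(self):
        return []

    def forward(self, X, labels_cols=None, training=False):
        return X

    def state_dict(self):
        return {}

    def load_state_dict(self, sd):
        pass


def make_norm_layer(kind: str, d: int, n_classes: int = 6, K: int = 5,
                    eps: float = 1e-5, momentum: float = 0.1,
                    rotation_step: float = 0.05, dtype=np.float32):
    """Factory for the three normalization variants (plus identity)."""
    if kind == "bn":
        return BatchNormLayer(d, eps, momentum, dtype=dtype)
    if kind == "iternorm":
        return IterNormLayer(d, K, eps, momentum, affine=True, dtype=dtype)
    if kind == "iternorm_rot":
        return IterNormRotationLayer(d, n_classes, K, eps, momentum,
                                     rotation_step, dtype=dtype)
    if kind == "none":
        return IdentityNorm(d)
    raise ValidationError(f"unknown normalization kind: {kind!r}")
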