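"""The 3-layer CNN classifier with interchangeable normalization blocks.

Architecture: three building blocks, each `3x3 same-padded convolution ->
ReLU -> 3x3 max-pool (stride 3) -> normalization`, with 32, 64 and 128
filters; spatial sizes run 75 -> 25 -> 8 -> 2.  The flattened features pass
through dropout (15%) into a fully-connected 6-way softmax head.  The three
variants differ only in the normalization module of each block: batch
normalization (the base model), IterNorm whitening (model 1), or IterNorm
plus the class-aligning rotation (model 2).

Normalization operates on the unrolled activation batch: the channel axis
becomes the feature dimension ``d = L`` and every spatial position of every
sample becomes one column (``m_eff = m * hd * wd``).

Convolution and pooling are evaluated as im2col matrix products with
hand-derived backward rules registered in the autodiff graph; everything
else (including the whitening layers) differentiates through graph
primitives.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Tensor, from_op, no_grad
from .whitening import ValidationError, make_norm_layer

NORM_KINDS = ("bn", "iternorm", "iternorm_rot", "none")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class ConvBlockSpec:
    num_filters: int
    kernel: int = 3
    pool: int = 3
    norm_kind: str = "bn"

    def __post_init__(self):
        if self.num_filters <= 0:
            raise ValidationError("num_filters must be positive")
        if self.norm_kind not in NORM_KINDS:
            raise ValidationError(f"unknown norm kind {self.norm_kind!r}")


@dataclass
class ModelConfig:
    blocks: list = field(
        default_factory=lambda: [ConvBlockSpec(32), ConvBlockSpec(64),
                                 ConvBlockSpec(128)]
    )
    input_size: int = 75
    num_classes: int = 6
    dropout_rate: float = 0.15
    iternorm_iterations: int = 5
    norm_eps: float = 1e-5
    norm_momentum: float = 0.1
    rotation_step: float = 0.05

    def __post_init__(self):
        self.blocks = [
            b if isinstance(b, ConvBlockSpec) else ConvBlockSpec(**b)
            for b in self.blocks
        ]
        if not 0 <= self.dropout_rate < 1:
            raise ValidationError("dropout_rate must lie in [0, 1)")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "ModelConfig":
        return cls(**json.loads(s))


VARIANTS = ("base", "model1", "model2")
_VARIANT_NORM = {"base": "bn", "model1": "iternorm", "model2": "iternorm_rot"}


def model_config(variant: str = "base", ablation_layer: int | None = None,
                 **overrides) -> ModelConfig:
    """Config for a named variant, optionally replacing only one BN layer.

    ``ablation_layer`` (1-based) builds the base model with exactly that
    layer's BN swapped for the variant's whitening module, as in the
    single-layer replacement experiment.
    """
    if variant not in VARIANTS:
        raise ValidationError(f"unknown variant {variant!r}")
    kind = _VARIANT_NORM[variant]
    kinds = ["bn"] * 3
    if ablation_layer is None:
        kinds = [kind] * 3
    else:
        if not 1 <= ablation_layer <= 3:
            raise ValidationError("ablation_layer must be 1, 2 or 3")
        if variant == "base":
            raise ValidationError("single-layer replacement needs a whitening variant")
        kinds[ablation_layer - 1] = kind
    blocks = [ConvBlockSpec(f, norm_kind=k) for f, k in zip((32, 64, 128), kinds)]
    return ModelConfig(blocks=blocks, **overrides)


# ---------------------------------------------------------------------------
# layer primitives with custom backward rules
# ---------------------------------------------------------------------------


def conv2d_same(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Same-padded 2-D convolution, NHWC layout, via im2col.

    ``x``: (m, h, w, c_in); ``weight``: (kh, kw, c_in, c_out);
    ``bias``: (c_out,).  Output: (m, h, w, c_out).
    """
    kh, kw, cin, cout = weight.shape
    m, h, w, cx = x.shape
    if cx != cin:
        raise ValidationError(f"input has {cx} channels, filter expects {cin}")
    if h < kh or w < kw:
        raise ValidationError("spatial dimensions smaller than the kernel")
    ph, pw = kh // 2, kw // 2
    xpad = np.pad(x.data, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    windows = np.lib.stride_tricks.sliding_window_view(xpad, (kh, kw), axis=(1, 2))
    # (m, h, w, cin, kh, kw) -> columns ordered (kh, kw, cin)
    cols = np.ascontiguousarray(windows.transpose(0, 1, 2, 4, 5, 3)).reshape(
        m * h * w, kh * kw * cin
    )
    wf = weight.data.reshape(kh * kw * cin, cout)
    out_data = (cols @ wf + bias.data).reshape(m, h, w, cout)
    out = from_op(out_data, (x, weight, bias))
    if out.requires_grad:

        def bwd(g):
            g2 = np.ascontiguousarray(g).reshape(m * h * w, cout)
            if bias.requires_grad:
                bias._accumulate(g2.sum(axis=0))
            if weight.requires_grad:
                weight._accumulate((cols.T @ g2).reshape(weight.shape))
            if x.requires_grad:
                gcols = (g2 @ wf.T).reshape(m, h, w, kh, kw, cin)
                gpad = np.zeros_like(xpad)
                for i in range(kh):
                    for j in range(kw):
                        gpad[:, i : i + h, j : j + w, :] += gcols[:, :, :, i, j, :]
                x._accumulate(gpad[:, ph : ph + h, pw : pw + w, :])

        out._backward = bwd
    return out


def max_pool(x: Tensor, size: int = 3) -> Tensor:
    """Non-overlapping max-pooling with stride = window ``size`` (floor mode)."""
    m, h, w, c = x.shape
    ho, wo = h // size, w // size
    r = x.data[:, : ho * size, : wo * size, :].reshape(m, ho, size, wo, size, c)
    out_data = r.max(axis=(2, 4))
    out = from_op(out_data, (x,))
    if out.requires_grad:
        mask = r == out_data[:, :, None, :, None, :]
        counts = mask.sum(axis=(2, 4), keepdims=True).astype(x.dtype)

        def bwd(g):
            gr = mask * (g[:, :, None, :, None, :] / counts)
            gx = np.zeros_like(x.data)
            gx[:, : ho * size, : wo * size, :] = gr.reshape(m, ho * size, wo * size, c)
            x._accumulate(gx)

        out._backward = bwd
    return out


def dropout(x: Tensor, rate: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    if not training or rate == 0.0:
        return x
    mask = (rng.random(x.shape) >= rate).astype(x.dtype) / (1.0 - rate)
    return x * Tensor(mask)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray):
    """Mean cross-entropy of a softmax over logits; returns ``(loss, probs)``."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    m = len(labels)
    loss_val = -np.mean(np.log(probs[np.arange(m), labels] + 1e-12))
    loss = from_op(np.asarray(loss_val), (logits,))
    if loss.requires_grad:

        def bwd(g):
            onehot = np.zeros_like(probs)
            onehot[np.arange(m), labels] = 1.0
            logits._accumulate(g * (probs - onehot) / m)

        loss._backward = bwd
    return loss, probs


def unroll_nhwc(x: Tensor):
    """(m, h, w, c) tensor -> (c, m*h*w) batch plus the roll-back shape."""
    m, h, w, c = x.shape
    return x.transpose((3, 0, 1, 2)).reshape(c, m * h * w), (m, h, w, c)


def roll_nhwc(x2: Tensor, shape) -> Tensor:
    m, h, w, c = shape
    return x2.reshape(c, m, h, w).transpose((1, 2, 3, 0))


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------


class CNN:
    """3-block convolutional classifier over 75x75 grayscale signatures."""

    def __init__(self, config: ModelConfig, seed: int = 0, dtype=np.float32):
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        self.conv_weights: list[Tensor] = []
        self.conv_biases: list[Tensor] = []
        self.norms = []
        size = config.input_size
        cin = 1
        for spec in config.blocks:
            k, L = spec.kernel, spec.num_filters
            fan_in = k * k * cin
            wdata = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                               size=(k, k, cin, L)).astype(dtype)
            self.conv_weights.append(Tensor(wdata, requires_grad=True))
            self.conv_biases.append(Tensor(np.zeros(L, dtype=dtype),
                                           requires_grad=True))
            self.norms.append(
                make_norm_layer(
                    spec.norm_kind, L, n_classes=config.num_classes,
                    K=config.iternorm_iterations, eps=config.norm_eps,
                    momentum=config.norm_momentum,
                    rotation_step=config.rotation_step, dtype=dtype,
                )
            )
            size = size // spec.pool
            cin = L
        if size < 1:
            raise ValidationError("input too small for the block pyramid")
        self.feature_dim = size * size * cin
        # zero-initialized head: the untrained softmax is exactly uniform
        # (initial cross-entropy ln Nc); symmetry is broken by the inputs
        self.fc_weight = Tensor(
            np.zeros((self.feature_dim, config.num_classes), dtype=dtype),
            requires_grad=True,
        )
        self.fc_bias = Tensor(np.zeros(config.num_classes, dtype=dtype),
                              requires_grad=True)
        self.dropout_rng = np.random.default_rng(rng.integers(2**31))
        self.norm_outputs: list[np.ndarray] | None = None

    # -- parameters --------------------------------------------------------

    def parameters(self) -> list[Tensor]:
        params = []
        for w, b, n in zip(self.conv_weights, self.conv_biases, self.norms):
            params.extend([w, b])
            params.extend(n.parameters())
        params.extend([self.fc_weight, self.fc_bias])
        return params

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # -- forward ------------------------------------------------------------

    def forward(self, images: np.ndarray, labels: np.ndarray | None = None,
                training: bool = False, capture_norm: bool = False) -> Tensor:
        """Logits for a batch of images (m, 75, 75) with pixel values 0..255."""
        images = np.asarray(images)
        if images.ndim == 2:
            images = images[None]
        x = Tensor((images.astype(self.dtype) / 255.0)[..., None])
        self.norm_outputs = [] if capture_norm else None
        for w, b, norm, spec in zip(self.conv_weights, self.conv_biases,
                                    self.norms, self.config.blocks):
            x = conv2d_same(x, w, b).relu()
            x = max_pool(x, spec.pool)
            x2, shape = unroll_nhwc(x)
            labels_cols = None
            if labels is not None:
                _, h, wd, _ = shape
                labels_cols = np.repeat(np.asarray(labels), h * wd)
            x2 = norm.forward(x2, labels_cols=labels_cols, training=training)
            if training and hasattr(norm, "consume_compensation"):
                R = norm.consume_compensation()
                if R is not None:
                    self._compensate_downstream(norm, R)
            x = roll_nhwc(x2, shape)
            if capture_norm:
                self.norm_outputs.append(x.data.copy())
        x = x.reshape(x.shape[0], self.feature_dim)
        x = dropout(x, self.config.dropout_rate, self.dropout_rng, training)
        return x @ self.fc_weight + self.fc_bias

    def predict_proba(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Class probabilities, evaluated without graph construction."""
        outs = []
        with no_grad():
            for i in range(0, len(images), batch_size):
                logits = self.forward(images[i : i + batch_size], training=False)
                z = logits.data - logits.data.max(axis=1, keepdims=True)
                ez = np.exp(z)
                outs.append(ez / ez.sum(axis=1, keepdims=True))
        return np.concatenate(outs)

    def predict(self, images: np.ndarray) -> np.ndarray:
        return self.predict_proba(images).argmax(axis=1)

    def _compensate_downstream(self, norm, R: np.ndarray):
        """Counter-mix the next layer's input channels after an axis rotation.

        A rotation layer that remapped its output axes by the orthogonal
        ``R`` reports it here; mixing the input-channel dimension of the
        following convolution (or of the head, grouped per spatial
        position) by ``R`` leaves the network function exactly unchanged.
        """
        i = self.norms.index(norm)
        Rd = R.astype(self.dtype)
        if i + 1 < len(self.norms):
            w = self.conv_weights[i + 1]
            w.data = np.einsum("ik,hwko->hwio", Rd, w.data)
        else:
            c = self.config.blocks[-1].num_filters
            w3 = self.fc_weight.data.reshape(-1, c, self.config.num_classes)
            self.fc_weight.data = np.einsum("ik,pko->pio", Rd, w3).reshape(
                self.fc_weight.data.shape
            )

    # -- checkpointing -------------------------------------------------------

    def save(self, path: str):
        arrays = {"__config__": np.bytes_(self.config.to_json())}
        for i, (w, b, n) in enumerate(zip(self.conv_weights, self.conv_biases,
                                          self.norms)):
            arrays[f"conv{i}_w"] = w.data
            arrays[f"conv{i}_b"] = b.data
            for key, val in n.state_dict().items():
                arrays[f"norm{i}_{key}"] = val
        arrays["fc_w"] = self.fc_weight.data
        arrays["fc_b"] = self.fc_bias.data
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str) -> "CNN":
        with np.load(path, allow_pickle=False) as data:
            config = ModelConfig.from_json(bytes(data["__config__"]).decode())
            model = cls(config, seed=0)
            for i, n in enumerate(model.norms):
                model.conv_weights[i].data = data[f"conv{i}_w"]
                model.conv_biases[i].data = data[f"conv{i}_b"]
                sd = {
                    key[len(f"norm{i}_"):]: data[key]
                    for key in data.files
                    if key.startswith(f"norm{i}_")
                }
                if sd:
                    n.load_state_dict(sd)
            model.fc_weight.data = data["fc_w"]
            model.fc_bias.data = data["fc_b"]
        return model


def build_model(config: ModelConfig | str = "base", seed: int = 0,
                **overrides) -> CNN:
    """Construct a CNN from a ModelConfig or a variant name, deterministically."""
    if isinstance(config, str):
        config = model_config(config, **overrides)
    return CNN(config, seed=seed)
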