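"""Latent-space diagnostics of trained classifiers.

Three analyses of what the normalization layers do to the latent space:

* **Feature-pair correlations** — absolute Pearson correlation between
  every pair of channels at a normalization layer's output over a test
  set, using every spatial position as a sample (the unrolling convention).
  Whitening layers should show near-zero off-diagonal mass; BN layers,
  which only standardize, should not.
* **Top-activated signatures** — for the rotation-aligned variant, the test
  signature that maximally activates each class-aligned latent axis.  When
  alignment succeeds, deep-layer top activations carry the matching label.
* **Empirical receptive fields** — occlusion maps: a masking patch slides
  over the image and the reduction in an axis activation is recorded per
  position; the strongly reducing positions outline the image region the
  unit actually uses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import no_grad
from .model import CNN
from .whitening import ValidationError


def _norm_outputs(model: CNN, images: np.ndarray, layer_index: int,
                  batch_size: int = 64) -> np.ndarray:
    """Post-normalization activations at one layer, shape (n, h, w, c)."""
    if not 1 <= layer_index <= len(model.norms):
        raise ValidationError(f"layer_index must be in 1..{len(model.norms)}")
    outs = []
    with no_grad():
        for i in range(0, len(images), batch_size):
            model.forward(images[i : i + batch_size], training=False,
                          capture_norm=True)
            outs.append(model.norm_outputs[layer_index - 1])
    return np.concatenate(outs)


@dataclass
class CorrelationMap:
    values: np.ndarray  # d x d, |Pearson r|
    layer_index: int
    constant_features: np.ndarray  # boolean mask of zero-variance channels

    @property
    def mean_off_diagonal(self) -> float:
        d = self.values.shape[0]
        off = ~np.eye(d, dtype=bool)
        return float(self.values[off].mean())


def feature_correlations(model: CNN, images: np.ndarray,
                         layer_index: int) -> CorrelationMap:
    """Absolute correlation of every channel pair at a norm layer's output.

    Channels are unrolled over samples and spatial positions.  Channels
    with zero variance are flagged and assigned correlation 0 (their
    diagonal entry included).
    """
    acts = _norm_outputs(model, images, layer_index)
    n, h, w, c = acts.shape
    X = acts.transpose(3, 0, 1, 2).reshape(c, n * h * w).astype(np.float64)
    sd = X.std(axis=1)
    constant = sd == 0
    corr = np.zeros((c, c))
    ok = ~constant
    if ok.any():
        corr_ok = np.abs(np.corrcoef(X[ok]))
        corr[np.ix_(ok, ok)] = corr_ok
    return CorrelationMap(values=corr, layer_index=layer_index,
                          constant_features=constant)


def axis_activations(model: CNN, images: np.ndarray, layer_index: int,
                     statistic: str = "mean") -> np.ndarray:
    """Scalar activation of every sample on every latent axis, shape (n, d).

    A sample's activation on axis (channel) ``i`` is the spatial mean of
    that channel's normalized output (``statistic="max"`` uses the spatial
    maximum instead).
    """
    acts = _norm_outputs(model, images, layer_index)
    if statistic == "mean":
        return acts.mean(axis=(1, 2))
    if statistic == "max":
        return acts.max(axis=(1, 2))
    raise ValidationError(f"unknown statistic {statistic!r}")


def top_activated(model: CNN, images: np.ndarray, labels: np.ndarray,
                  layer_index: int, statistic: str = "mean") -> list[dict]:
    """The test signature maximally activating each class-aligned axis.

    Returns one record per class axis with the winning sample index and its
    true label; ties break toward the lowest sample index (argmax policy).
    """
    acts = axis_activations(model, images, layer_index, statistic)
    records = []
    for axis in range(model.config.num_classes):
        best = int(np.argmax(acts[:, axis]))
        records.append({
            "axis": axis,
            "sample_index": best,
            "true_label": int(labels[best]),
            "activation": float(acts[best, axis]),
        })
    return records


def label_match_fraction(records: list[dict]) -> float:
    """Fraction of axes whose top signature carries the matching label."""
    return float(np.mean([r["true_label"] == r["axis"] for r in records]))


@dataclass
class ReceptiveFieldMap:
    reduction: np.ndarray  # grid of activation reductions per mask position
    patch: int
    stride: int
    axis: int
    base_activation: float

    def highlight(self, quantile: float = 0.9) -> np.ndarray:
        """Boolean mask of patch positions in the top (1-q) reduction tail."""
        thr = np.quantile(self.reduction, quantile)
        return self.reduction >= thr


def empirical_receptive_field(
    model: CNN,
    image: np.ndarray,
    layer_index: int,
    axis: int,
    patch: int = 32,
    stride: int = 5,
    fill: str = "noise",
    seed: int = 0,
    statistic: str = "mean",
) -> ReceptiveFieldMap:
    """Occlusion map of one latent axis for one signature.

    A ``patch x patch`` mask slides with ``stride`` over the image (every
    fully contained position); each masked copy is re-evaluated and the
    drop in the axis activation recorded.  ``fill="noise"`` uses seeded
    uniform noise over the image's intensity range, ``fill="zero"`` blanks
    the patch.
    """
    image = np.asarray(image)
    if image.shape != (75, 75):
        raise ValidationError("expected a single 75x75 image")
    side = (image.shape[0] - patch) // stride + 1
    rng = np.random.default_rng(seed)
    base = float(
        axis_activations(model, image[None], layer_index, statistic)[0, axis]
    )
    masked = np.repeat(image[None].astype(float), side * side, axis=0)
    lo, hi = float(image.min()), float(image.max())
    pos = 0
    for i in range(side):
        for j in range(side):
            y, x = i * stride, j * stride
            if fill == "noise":
                patch_vals = rng.uniform(lo, hi, size=(patch, patch))
            elif fill == "zero":
                patch_vals = 0.0
            else:
                raise ValidationError(f"unknown fill {fill!r}")
            masked[pos, y : y + patch, x : x + patch] = patch_vals
            pos += 1
    acts = axis_activations(model, masked.astype(np.uint8), layer_index,
                            statistic)[:, axis]
    reduction = (base - acts).reshape(side, side)
    return ReceptiveFieldMap(reduction=reduction, patch=patch, stride=stride,
                             axis=axis, base_activation=base)
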