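"""Training, evaluation and the experiment matrix.

The training protocol: cross-entropy loss, plain SGD with momentum,
batch size 10, learning rate decayed by 10x every 7 epochs, at most 30
epochs.  The rotation-augmented variant (``model2``) is warm-started from a
trained IterNorm model (``model1``): rotation modules are inserted with
``Q = I`` and training continues for 5 more epochs at a lower rate.

Experiments: repeated class-stratified random train/test splits (20/80,
50/50, 80/20), a single-layer replacement study (one BN layer at a time
swapped for a whitening layer), and a subject-wise holdout in which no
person appears in both train and test sets.  Every experiment is
reproducible bit-exactly from its master seed: per-trial seeds are derived
through a fixed counter scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .model import CNN, build_model, model_config, softmax_cross_entropy
from .synthetic_radar import SignatureDataset
from .whitening import ValidationError

#: initial learning rate per variant, selected once per model on a held-out
#: calibration split (whitening smooths the loss surface and tolerates a
#: substantially larger rate); results are sensitive to these
DEFAULT_LR = {"base": 0.05, "model1": 0.1, "model2": 0.001}


@dataclass
class TrainConfig:
    batch_size: int = 10
    max_epochs: int = 30
    lr_init: float | None = None  # None: the per-variant default
    lr_decay_factor: float = 0.1
    lr_decay_every: int = 7
    momentum: float = 0.9
    iternorm_iterations: int = 5
    warm_start_epochs: int = 5  # model2 fine-tuning after the warm start
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 2:
            raise ValidationError("batch_size must be >= 2 (batch statistics)")
        if self.max_epochs < 1:
            raise ValidationError("max_epochs must be >= 1")

    def lr_at(self, epoch: int, lr0: float) -> float:
        return lr0 * self.lr_decay_factor ** (epoch // self.lr_decay_every)


# ---------------------------------------------------------------------------
# training and evaluation
# ---------------------------------------------------------------------------


def train(
    model: CNN,
    images: np.ndarray,
    labels: np.ndarray,
    cfg: TrainConfig,
    lr_init: float = 0.01,
    epochs: int | None = None,
    log: list | None = None,
) -> dict:
    """SGD-with-momentum training loop; returns the per-epoch history.

    Shuffling is driven by ``cfg.seed`` only, so two calls with identical
    inputs produce identical parameters.  Batches of size 1 (whitening
    statistics undefined) are dropped and noted in the history.
    """
    labels = np.asarray(labels)
    n = len(images)
    if n < cfg.batch_size:
        raise ValidationError("training set smaller than one batch")
    rng = np.random.default_rng(cfg.seed)
    params = model.parameters()
    velocity = [np.zeros_like(p.data) for p in params]
    history = {"loss": [], "accuracy": [], "lr": [], "dropped_batches": 0}
    epochs = cfg.max_epochs if epochs is None else epochs
    for epoch in range(epochs):
        lr = cfg.lr_at(epoch, lr_init)
        order = rng.permutation(n)
        losses, correct, seen = [], 0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            if len(idx) < 2:
                history["dropped_batches"] += 1
                continue
            batch_y = labels[idx]
            logits = model.forward(images[idx], labels=batch_y, training=True)
            loss, probs = softmax_cross_entropy(logits, batch_y)
            for p in params:
                p.zero_grad()
            loss.backward()
            for p, v in zip(params, velocity):
                v *= cfg.momentum
                v += p.grad
                p.data = p.data - lr * v
            losses.append(float(loss.data))
            correct += int((probs.argmax(axis=1) == batch_y).sum())
            seen += len(idx)
        history["loss"].append(float(np.mean(losses)))
        history["accuracy"].append(100.0 * correct / seen)
        history["lr"].append(lr)
        if log is not None:
            log.append(
                f"epoch {epoch + 1}: loss={history['loss'][-1]:.4f} "
                f"acc={history['accuracy'][-1]:.2f}% lr={lr:g}"
            )
    return history


def evaluate(model: CNN, images: np.ndarray, labels: np.ndarray):
    """Accuracy (%) and the raw confusion-count matrix (rows: true class)."""
    labels = np.asarray(labels)
    if len(images) == 0:
        raise ValidationError("empty test set")
    preds = model.predict(images)
    nc = model.config.num_classes
    confusion = np.zeros((nc, nc), dtype=int)
    np.add.at(confusion, (labels, preds), 1)
    accuracy = 100.0 * np.trace(confusion) / confusion.sum()
    return accuracy, confusion


def confusion_to_percent(confusion: np.ndarray) -> np.ndarray:
    """Row-normalize confusion counts to percentages (rows sum to 100)."""
    totals = confusion.sum(axis=1, keepdims=True).astype(float)
    totals[totals == 0] = 1.0
    return 100.0 * confusion / totals


def train_variant(
    variant: str,
    images: np.ndarray,
    labels: np.ndarray,
    cfg: TrainConfig,
    model_seed: int = 0,
    ablation_layer: int | None = None,
    pretrained_model1: CNN | None = None,
) -> CNN:
    """Build and train one model variant under the standard protocol.

    ``model2`` is warm-started: a model-1 network is trained first (or
    supplied), its convolutional, head and whitening running states are
    copied into the rotation-augmented architecture with ``Q = I``, and
    training continues for ``cfg.warm_start_epochs`` epochs.
    """
    lr = cfg.lr_init if cfg.lr_init is not None else DEFAULT_LR[variant]
    common = dict(iternorm_iterations=cfg.iternorm_iterations)
    if variant == "model2" and ablation_layer is None:
        m1 = pretrained_model1
        if m1 is None:
            m1 = train_variant("model1", images, labels, cfg, model_seed)
        model = build_model(model_config("model2", **common), seed=model_seed)
        _warm_start_from(model, m1)
        train(model, images, labels, cfg, lr_init=lr,
              epochs=cfg.warm_start_epochs)
        return model
    config = model_config(variant, ablation_layer=ablation_layer, **common)
    model = build_model(config, seed=model_seed)
    train(model, images, labels, cfg, lr_init=lr)
    return model


def _warm_start_from(model2: CNN, model1: CNN):
    """Copy conv/head parameters and whitening running statistics."""
    for i in range(len(model2.norms)):
        model2.conv_weights[i].data = model1.conv_weights[i].data.copy()
        model2.conv_biases[i].data = model1.conv_biases[i].data.copy()
        src, dst = model1.norms[i], model2.norms[i]
        if hasattr(src, "running_W") and hasattr(dst, "running_W"):
            dst.running_mean = src.running_mean.copy()
            dst.running_W = src.running_W.copy()
            if getattr(src, "affine", False) and getattr(dst, "affine", False):
                dst.weight.data = src.weight.data.copy()
                dst.bias.data = src.bias.data.copy()
    model2.fc_weight.data = model1.fc_weight.data.copy()
    model2.fc_bias.data = model1.fc_bias.data.copy()


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------


def stratified_split(labels: np.ndarray, train_fraction: float,
                     rng: np.random.Generator):
    """Class-stratified disjoint train/test index split."""
    labels = np.asarray(labels)
    train_idx, test_idx = [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        idx = rng.permutation(idx)
        n_train = int(round(train_fraction * len(idx)))
        if n_train == 0 or n_train == len(idx):
            raise ValidationError(
                f"split fraction {train_fraction} leaves class {c} empty"
            )
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
    return np.concatenate(train_idx), np.concatenate(test_idx)


def subject_wise_split(dataset: SignatureDataset, train_subjects: int = 27,
                       test_subjects: int = 6, seed: int = 0):
    """Split by person: no subject appears in both partitions."""
    subjects = np.unique(dataset.subjects)
    if len(subjects) < train_subjects + test_subjects:
        raise ValidationError(
            f"dataset has {len(subjects)} subjects, need "
            f"{train_subjects + test_subjects}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(subjects)
    train_set = set(order[:train_subjects].tolist())
    test_set = set(order[train_subjects : train_subjects + test_subjects].tolist())
    train_mask = np.isin(dataset.subjects, list(train_set))
    test_mask = np.isin(dataset.subjects, list(test_set))
    return dataset.subset(train_mask), dataset.subset(test_mask)


# ---------------------------------------------------------------------------
# experiment matrix
# ---------------------------------------------------------------------------


@dataclass
class ExperimentSpec:
    splits: list = field(default_factory=lambda: [(50, 50)])
    n_trials: int = 5
    variants: tuple = ("base", "model1", "model2")
    ablation_layers: tuple = ()
    subject_wise: bool = False

    def __post_init__(self):
        for tr, te in self.splits:
            if tr + te != 100:
                raise ValidationError(f"split {tr}/{te} does not sum to 100")
        if self.n_trials < 1:
            raise ValidationError("n_trials must be >= 1")


def _trial_seeds(master_seed: int, trial: int):
    """Fixed counter scheme: (split seed, model seed, shuffle seed)."""
    ss = np.random.SeedSequence([int(master_seed), int(trial)])
    return [int(s) for s in ss.generate_state(3) % (2**31)]


def run_split_experiment(
    dataset: SignatureDataset,
    spec: ExperimentSpec,
    cfg: TrainConfig,
    master_seed: int = 0,
    trained_hook=None,
) -> dict:
    """Repeated stratified-split training of every variant.

    Returns a report mapping ``"train/test"`` split keys to per-variant
    mean/std accuracy over trials and trial-averaged row-normalized
    confusion matrices.  ``trained_hook(variant, model, test_images,
    test_labels, trial)`` is called after each evaluation (used for latent
    diagnostics on the trained models).
    """
    report = {"master_seed": int(master_seed), "n_trials": spec.n_trials,
              "splits": {}}
    nc = len(dataset.class_names)
    for tr_pct, te_pct in spec.splits:
        per_variant = {v: {"accuracies": [], "confusions": []}
                       for v in spec.variants}
        for trial in range(spec.n_trials):
            split_seed, model_seed, shuffle_seed = _trial_seeds(master_seed, trial)
            rng = np.random.default_rng(split_seed)
            train_idx, test_idx = stratified_split(
                dataset.labels, tr_pct / 100.0, rng
            )
            trial_cfg = TrainConfig(**{**asdict(cfg), "seed": shuffle_seed})
            m1_cache = None
            for variant in spec.variants:
                model = train_variant(
                    variant, dataset.images[train_idx], dataset.labels[train_idx],
                    trial_cfg, model_seed=model_seed,
                    pretrained_model1=m1_cache if variant == "model2" else None,
                )
                if variant == "model1":
                    m1_cache = model
                acc, conf = evaluate(
                    model, dataset.images[test_idx], dataset.labels[test_idx]
                )
                per_variant[variant]["accuracies"].append(acc)
                per_variant[variant]["confusions"].append(confusion_to_percent(conf))
                if trained_hook is not None:
                    trained_hook(variant, model, dataset.images[test_idx],
                                 dataset.labels[test_idx], trial)
        key = f"{tr_pct}/{te_pct}"
        report["splits"][key] = {
            v: {
                "mean_accuracy": float(np.mean(d["accuracies"])),
                "std_accuracy": float(np.std(d["accuracies"])),
                "accuracies": [float(a) for a in d["accuracies"]],
                "confusion_mean_pct": np.mean(d["confusions"], axis=0).tolist(),
            }
            for v, d in per_variant.items()
        }
    return report


def run_layer_ablation(
    dataset: SignatureDataset,
    spec: ExperimentSpec,
    cfg: TrainConfig,
    master_seed: int = 0,
    split=(50, 50),
) -> dict:
    """Single-layer replacement study at one split.

    For each layer index and whitening method, the base model is rebuilt
    with exactly that BN layer replaced, then trained and evaluated under
    the standard protocol.
    """
    if not spec.ablation_layers:
        raise ValidationError("no ablation layers requested")
    arms = [("base", None)] + [
        (v, layer)
        for v in spec.variants if v != "base"
        for layer in spec.ablation_layers
    ]
    results = {f"{v}_layer{l}" if l else v: [] for v, l in arms}
    for trial in range(spec.n_trials):
        split_seed, model_seed, shuffle_seed = _trial_seeds(master_seed, trial)
        rng = np.random.default_rng(split_seed)
        train_idx, test_idx = stratified_split(dataset.labels, split[0] / 100.0, rng)
        trial_cfg = TrainConfig(**{**asdict(cfg), "seed": shuffle_seed})
        for v, layer in arms:
            model = train_variant(
                v, dataset.images[train_idx], dataset.labels[train_idx],
                trial_cfg, model_seed=model_seed, ablation_layer=layer,
            )
            acc, _ = evaluate(model, dataset.images[test_idx],
                              dataset.labels[test_idx])
            results[f"{v}_layer{layer}" if layer else v].append(acc)
    return {
        "master_seed": int(master_seed),
        "split": f"{split[0]}/{split[1]}",
        "arms": {
            k: {"mean_accuracy": float(np.mean(a)),
                "std_accuracy": float(np.std(a)),
                "accuracies": [float(x) for x in a]}
            for k, a in results.items()
        },
    }
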