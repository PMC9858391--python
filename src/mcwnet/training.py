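"""Stratified splitting and SGDM training of the ACL variants.

Training uses a fixed protocol: stochastic gradient descent with momentum
(0.9), initial learning rate 0.001, 5 epochs, minibatch 32, with the
held-out test split also serving as the validation curve sampled every 30
iterations.  That last convention re-uses the test set during training
monitoring — fine for benchmarking the architecture on synthetic data, but
a leakage caveat for real studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data_io import LabeledDataset
from .evaluation import MetricsReport, confusion_matrix, classification_metrics
from .model import NetworkModel, VARIANTS, build_acl
from .nn import F32

SPLIT_RATIOS = {"70-30": 0.70, "80-20": 0.80, "90-10": 0.90}


@dataclass
class TrainConfig:
    initial_lr: float = 0.001
    momentum: float = 0.9
    max_epochs: int = 5
    minibatch: int = 32
    validation_frequency: int = 30  # in iterations
    split_ratio: str = "90-10"
    seed: int = 0
    shuffle_each_epoch: bool = True

    def __post_init__(self) -> None:
        if self.initial_lr <= 0:
            raise ValueError("learning rate must be positive")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must lie in [0, 1)")
        if self.max_epochs < 1 or self.minibatch < 1:
            raise ValueError("epochs and minibatch must be >= 1")
        if self.split_ratio not in SPLIT_RATIOS:
            raise ValueError(f"split_ratio must be one of {set(SPLIT_RATIOS)}")


@dataclass
class TrainHistory:
    losses: list[float] = field(default_factory=list)       # per iteration
    val_points: list[tuple[int, float]] = field(default_factory=list)
    epoch_boundaries: list[int] = field(default_factory=list)
    final_train_accuracy: float | None = None


def _as_fraction(ratio: str | float) -> float:
    if isinstance(ratio, str):
        if ratio not in SPLIT_RATIOS:
            raise ValueError(f"unknown split ratio {ratio!r}")
        return SPLIT_RATIOS[ratio]
    ratio = float(ratio)
    if not 0.0 < ratio < 1.0:
        raise ValueError("train fraction must lie in (0, 1)")
    return ratio


def stratified_split(dataset: LabeledDataset, ratio: str | float,
                     seed: int = 0) -> tuple[LabeledDataset, LabeledDataset]:
    """Per-class split into (train, test) with a seeded permutation.

    The test count per class is the round-half-up of ``n_class * (1 - r)``
    and never below 1.  Sample order within each side follows the original
    dataset order, so counts are invariant to input ordering given the seed.
    """
    train_frac = _as_fraction(ratio)
    rng = np.random.default_rng(seed)
    test_ids: set[str] = set()
    for cname in dataset.class_names:
        ids = [s.id for s in dataset if s.label == cname]
        if len(ids) < 2:
            raise ValueError(f"class {cname!r} has fewer than 2 samples")
        n_test = max(1, math.floor(len(ids) * (1.0 - train_frac) + 0.5))
        if n_test >= len(ids):
            raise ValueError(f"class {cname!r} too small for ratio {ratio}")
        picked = rng.permutation(sorted(ids))[:n_test]
        test_ids.update(picked.tolist())
    train = dataset.subset([s.id for s in dataset if s.id not in test_ids])
    test = dataset.subset([s.id for s in dataset if s.id in test_ids])
    return train, test


def sgdm_update(params: dict[str, np.ndarray], grads: dict[str, np.ndarray],
                velocity: dict[str, np.ndarray], lr: float, momentum: float
                ) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """``v <- momentum*v - lr*grad; p <- p + v`` for every tensor (in place)."""
    for key, p in params.items():
        g = grads[key]
        if g.shape != p.shape:
            raise ValueError(f"gradient shape mismatch for {key}: "
                             f"{g.shape} vs {p.shape}")
        v = velocity.get(key)
        if v is None:
            v = np.zeros_like(p)
        v *= momentum
        v -= lr * g.astype(p.dtype)
        p += v
        velocity[key] = v
    return params, velocity


def _batch_tensor(dataset: LabeledDataset, indices: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    xs = np.stack([dataset.samples[i].pixels for i in indices]).astype(F32)
    ys = np.array([dataset.label_index(dataset.samples[i].label)
                   for i in indices])
    return xs, ys


def evaluate_accuracy(model: NetworkModel, dataset: LabeledDataset,
                      batch: int = 64) -> float:
    correct = 0
    for start in range(0, len(dataset), batch):
        idx = np.arange(start, min(start + batch, len(dataset)))
        xs, ys = _batch_tensor(dataset, idx)
        probs = model.forward(xs, train=False)
        correct += int((probs.argmax(axis=1) == ys).sum())
    return correct / len(dataset)


def predict(model: NetworkModel, dataset: LabeledDataset,
            batch: int = 64) -> tuple[np.ndarray, list[str]]:
    """(probability rows, predicted labels) for every sample in order."""
    rows = []
    for start in range(0, len(dataset), batch):
        idx = np.arange(start, min(start + batch, len(dataset)))
        xs, _ = _batch_tensor(dataset, idx)
        rows.append(model.forward(xs, train=False))
    probs = np.concatenate(rows, axis=0)
    preds = [dataset.class_names[i] for i in probs.argmax(axis=1)]
    return probs, preds


def train_model(model: NetworkModel, train_set: LabeledDataset,
                config: TrainConfig,
                validation_set: LabeledDataset | None = None
                ) -> tuple[NetworkModel, TrainHistory]:
    """Minimise cross-entropy with SGDM over shuffled minibatches."""
    if len(train_set) == 0:
        raise ValueError("empty train set")
    if len(train_set.class_names) != model.spec.n_classes:
        raise ValueError("train set classes do not match the model head")
    n = len(train_set)
    n_classes = model.spec.n_classes
    params = model.parameters()
    velocity: dict[str, np.ndarray] = {}
    history = TrainHistory()
    drop_rng = np.random.default_rng((config.seed, 0xD0))
    iteration = 0
    for epoch in range(config.max_epochs):
        order = np.arange(n)
        if config.shuffle_each_epoch:
            order = np.random.default_rng((config.seed, epoch)).permutation(n)
        for start in range(0, n, config.minibatch):
            idx = order[start:start + config.minibatch]
            xs, ys = _batch_tensor(train_set, idx)
            probs = model.forward(xs, train=True, rng=drop_rng)
            eps = 1e-12
            loss = float(-np.mean(np.log(probs[np.arange(len(ys)), ys] + eps)))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at iteration {iteration}: {loss}")
            onehot = np.zeros((len(ys), n_classes), dtype=F32)
            onehot[np.arange(len(ys)), ys] = 1.0
            model.backward_from_logits((probs - onehot) / len(ys))
            sgdm_update(params, model.gradients(), velocity,
                        config.initial_lr, config.momentum)
            history.losses.append(loss)
            iteration += 1
            if (validation_set is not None
                    and iteration % config.validation_frequency == 0):
                history.val_points.append(
                    (iteration, evaluate_accuracy(model, validation_set)))
        history.epoch_boundaries.append(iteration)
    _finalize_batchnorm(model, train_set, config.minibatch)
    history.final_train_accuracy = evaluate_accuracy(model, train_set)
    return model, history


def _finalize_batchnorm(model: NetworkModel, train_set: LabeledDataset,
                        batch: int) -> None:
    """Replace BN running statistics with population statistics.

    After the last update step, activation statistics are recomputed over
    the whole training set (the source framework finalises BN the same
    way); with few iterations the exponentially averaged running stats lag
    badly, which would distort inference-mode behaviour.
    """
    from . import nn as _nn

    bn_layers = [l for l in model.layers.values()
                 if isinstance(l, _nn.BatchNorm2D)]
    if not bn_layers:
        return
    sums = {id(l): [0.0, 0.0, 0] for l in bn_layers}
    originals = {id(l): l.forward for l in bn_layers}

    def make_collector(layer):
        def collect(x, *, train=False, rng=None):
            s = sums[id(layer)]
            s[0] = s[0] + x.sum(axis=(0, 1, 2), dtype=np.float64)
            s[1] = s[1] + (x.astype(np.float64) ** 2).sum(axis=(0, 1, 2))
            s[2] += x.shape[0] * x.shape[1] * x.shape[2]
            # normalise with batch stats so downstream layers see the same
            # distribution the final population stats will produce
            return originals[id(layer)](x, train=True, rng=rng)
        return collect

    try:
        for layer in bn_layers:
            layer.forward = make_collector(layer)
        for start in range(0, len(train_set), batch):
            idx = np.arange(start, min(start + batch, len(train_set)))
            xs, _ = _batch_tensor(train_set, idx)
            model.forward(xs, train=False)
    finally:
        for layer in bn_layers:
            del layer.forward  # restore the bound method
    for layer in bn_layers:
        s1, s2, count = sums[id(layer)]
        mean = s1 / count
        layer.running_mean = mean.astype(F32)
        layer.running_var = (s2 / count - mean ** 2).astype(F32)


def train_and_evaluate(dataset: LabeledDataset, variant: str,
                       config: TrainConfig,
                       attention_mode: str = "sequential",
                       input_dims: tuple[int, int, int] | None = None
                       ) -> tuple[NetworkModel, TrainHistory, MetricsReport]:
    """Split, train one variant, and report test-set metrics."""
    train_set, test_set = stratified_split(dataset, config.split_ratio,
                                           config.seed)
    if input_dims is None:
        s = dataset.samples[0]
        input_dims = (s.height, s.width, s.channels)
    model = build_acl(variant, input_dims, len(dataset.class_names),
                      seed=config.seed, attention_mode=attention_mode)
    model, history = train_model(model, train_set, config,
                                 validation_set=test_set)
    probs, preds = predict(model, test_set)
    cm = confusion_matrix(test_set.labels(), preds, test_set.class_names)
    report = classification_metrics(cm, scores=probs,
                                    true_labels=test_set.labels())
    report.case = variant
    report.ratio = config.split_ratio
    return model, history, report


def run_ablation(dataset: LabeledDataset,
                 ratios: tuple[str, ...] = ("70-30", "80-20", "90-10"),
                 seeds: tuple[int, ...] = (0,),
                 config: TrainConfig | None = None,
                 variants: tuple[str, ...] = VARIANTS,
                 ) -> dict[tuple[str, str, int], MetricsReport]:
    """Train every variant on identical splits for each (ratio, seed).

    Returns reports keyed ``(variant, ratio, seed)``; all variants within a
    key share the same split and initialisation seed, so differences reflect
    the architecture alone.
    """
    base = config or TrainConfig()
    reports: dict[tuple[str, str, int], MetricsReport] = {}
    for ratio in ratios:
        for seed in seeds:
            cfg = TrainConfig(initial_lr=base.initial_lr,
                              momentum=base.momentum,
                              max_epochs=base.max_epochs,
                              minibatch=base.minibatch,
                              validation_frequency=base.validation_frequency,
                              split_ratio=ratio, seed=seed,
                              shuffle_each_epoch=base.shuffle_each_epoch)
            for variant in variants:
                _, _, report = train_and_evaluate(dataset, variant, cfg)
                reports[(variant, ratio, seed)] = report
    return reports
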