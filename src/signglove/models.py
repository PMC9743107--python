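"""Parallel-path neural classifiers for static and dynamic gestures.

Static signs: each normalized time-series channel (5 flex + 3 earth-frame
linear acceleration by default) is processed by its own 1-D ConvNet block
producing a 50-d embedding; the embeddings are concatenated into a fully
connected prediction head.

Dynamic signs: the three spatial projection images go through a
MobileNetV2-style 2-D backbone (shared weights across the three planes, each
followed by its own 50-d projection), and the five flex channels through 1-D
ConvNet blocks — 8 parallel paths in total, concatenated into the head.

Training uses sparse categorical cross-entropy, Adam (learning rate 1e-4 by
default), a maximum of 300 epochs and early stopping on validation loss with
a patience of 30 epochs, restoring the best weights.
"""

from __future__ import annotations

import copy
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from . import nn

__all__ = [
    "Conv1DBlockSpec",
    "Backbone2DSpec",
    "TrainConfig",
    "ParallelPathModel",
    "conv1d_block",
    "mobilenet_v2",
    "build_static_model",
    "build_dynamic_model",
    "train",
    "predict",
    "save_weights",
    "load_weights",
]


@dataclass
class Conv1DBlockSpec:
    """Hyperparameters of one 1-D ConvNet block.

    Four convolution layers (kernel 3, stride 1, padding 1); each pair is
    followed by batch normalization and max pooling (pool 2); a dense layer
    then produces the embedding.
    """

    n_conv_layers: int = 4
    kernel: int = 3
    stride: int = 1
    padding: int = 1
    pool: int = 2
    embedding_dim: int = 50
    filters: tuple[int, ...] = (32, 32, 64, 64)


@dataclass
class Backbone2DSpec:
    """Hyperparameters of the MobileNetV2-style 2-D backbone.

    ``width_mult`` scales every channel count (0.35 is the reduced desk-scale
    setting); ``downsample`` average-pools the 224x224 input by that integer
    factor before the stem, trading spatial resolution for speed.  Weights
    are randomly initialized (``weights="random"``); there is no bundled
    pretrained checkpoint.
    """

    width_mult: float = 1.0
    downsample: int = 1
    embedding_dim: int = 50
    weights: str = "random"
    # (expansion, channels, repeats, first-stride) per stage
    ir_config: tuple[tuple[int, int, int, int], ...] = (
        (1, 16, 1, 1),
        (6, 24, 2, 2),
        (6, 32, 3, 2),
        (6, 64, 4, 2),
        (6, 96, 3, 1),
        (6, 160, 3, 2),
        (6, 320, 1, 1),
    )


@dataclass
class TrainConfig:
    """Training-loop settings; defaults follow the published recipe."""

    loss: str = "sparse_categorical_crossentropy"
    learning_rate: float = 1e-4
    max_epochs: int = 300
    patience: int = 30
    batch_size: int = 32
    val_fraction: float = 0.1
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _divisible(value: float, divisor: int = 4) -> int:
    return max(divisor, int(round(value / divisor)) * divisor)


def conv1d_block(
    spec: Conv1DBlockSpec, rng: np.random.Generator, c_in: int = 1,
    input_length: int = 150,
) -> nn.Sequential:
    """conv,conv,BN,pool,conv,conv,BN,pool, flatten, dense(embedding)."""
    n_pools = spec.n_conv_layers // 2
    out_len = input_length
    for _ in range(n_pools):
        out_len //= spec.pool
    if out_len < 1:
        raise ValueError(
            f"input length {input_length} too short for {n_pools} pool-"
            f"{spec.pool} stages"
        )
    layers: list[nn.Layer] = []
    c = c_in
    for i, f in enumerate(spec.filters[: spec.n_conv_layers]):
        layers.append(nn.Conv1D(c, f, rng, kernel=spec.kernel, padding=spec.padding))
        layers.append(nn.ReLU())
        c = f
        if i % 2 == 1:  # after each pair of conv layers
            layers.append(nn.BatchNorm(c))
            layers.append(nn.MaxPool1D(spec.pool))
    layers.append(nn.Flatten())
    layers.append(nn.Dense(c * out_len, spec.embedding_dim, rng))
    layers.append(nn.ReLU())
    return nn.Sequential(layers)


def mobilenet_v2(
    spec: Backbone2DSpec, rng: np.random.Generator, c_in: int = 1
) -> tuple[nn.Sequential, int]:
    """MobileNetV2-style backbone: 32-filter stem convolution, inverted
    residual bottlenecks, 1x1 expansion, global average pooling.

    Returns the layer stack and its output embedding width.
    """
    w = spec.width_mult
    c_stem = _divisible(32 * w)
    layers: list[nn.Layer] = [
        nn.Conv2D(c_in, c_stem, rng, kernel=3, stride=2, padding=1, bias=False),
        nn.BatchNorm(c_stem),
        nn.ReLU6(),
    ]
    c = c_stem
    for t, ch, n, s in spec.ir_config:
        c_out = _divisible(ch * w)
        for i in range(n):
            stride = s if i == 0 else 1
            layers.append(nn.InvertedResidual(c, c_out, rng, stride=stride, expand=t))
            c = c_out
    # the final 1x1 expansion scales with width so reduced-width models stay small
    c_last = 1280 if w == 1.0 else _divisible(1280 * w)
    layers += [
        nn.Conv2D(c, c_last, rng, kernel=1, padding=0, bias=False),
        nn.BatchNorm(c_last),
        nn.ReLU6(),
        nn.GlobalAvgPool2D(),
    ]
    return nn.Sequential(layers), c_last


class ParallelPathModel:
    """Several input branches whose embeddings are concatenated into a head.

    ``branches[i]`` consumes ``inputs[i]``; branch objects may share sublayers
    (the dynamic model applies one backbone to all three projection images).
    """

    def __init__(self, branches, head, input_shapes, n_classes: int):
        self.branches = list(branches)
        self.head = head
        self.input_shapes = list(input_shapes)  # per-branch, without batch dim
        self.n_classes = n_classes

    # -- plumbing ----------------------------------------------------------
    def _all_layers(self):
        return list(self.branches) + [self.head]

    def parameters(self):
        return nn.collect_parameters(self._all_layers())

    def zero_grads(self):
        seen = set()

        def visit(layer):
            if id(layer) in seen:
                return
            seen.add(id(layer))
            layer.zero_grads()
            for sub in layer.sublayers():
                visit(sub)

        for layer in self._all_layers():
            visit(layer)

    def check_inputs(self, inputs):
        if len(inputs) != len(self.branches):
            raise ValueError(
                f"model has {len(self.branches)} input paths, got {len(inputs)}"
            )
        for i, (x, shape) in enumerate(zip(inputs, self.input_shapes)):
            if tuple(x.shape[1:]) != tuple(shape):
                raise ValueError(
                    f"input {i} has shape {tuple(x.shape[1:])}, expected {tuple(shape)}"
                )

    def forward(self, inputs, train: bool):
        self.check_inputs(inputs)
        embeds, caches, widths = [], [], []
        for branch, x in zip(self.branches, inputs):
            e, cache = branch.forward(x, train)
            embeds.append(e)
            caches.append(cache)
            widths.append(e.shape[1])
        concat = np.concatenate(embeds, axis=1)
        logits, head_cache = self.head.forward(concat, train)
        return logits, (caches, widths, head_cache)

    def backward(self, dlogits, cache):
        caches, widths, head_cache = cache
        dconcat = self.head.backward(dlogits, head_cache)
        dinputs = []
        start = 0
        for branch, c, wdt in zip(self.branches, caches, widths):
            dinputs.append(branch.backward(dconcat[:, start : start + wdt], c))
            start += wdt
        return dinputs

    # -- state (for early-stopping restore and checkpointing) --------------
    def get_state(self):
        state = {}
        seen = set()

        def visit(layer, prefix):
            if id(layer) in seen:
                return
            seen.add(id(layer))
            for name, value in layer.params.items():
                state[f"{prefix}/{name}"] = value.copy()
            if isinstance(layer, nn.BatchNorm):
                state[f"{prefix}/running_mean"] = layer.running_mean.copy()
                state[f"{prefix}/running_var"] = layer.running_var.copy()
            for k, sub in enumerate(layer.sublayers()):
                visit(sub, f"{prefix}.{k}")

        for i, layer in enumerate(self._all_layers()):
            visit(layer, f"L{i}")
        return state

    def set_state(self, state):
        seen = set()

        def visit(layer, prefix):
            if id(layer) in seen:
                return
            seen.add(id(layer))
            for name in layer.params:
                layer.params[name][...] = state[f"{prefix}/{name}"]
            if isinstance(layer, nn.BatchNorm):
                layer.running_mean[...] = state[f"{prefix}/running_mean"]
                layer.running_var[...] = state[f"{prefix}/running_var"]
            for k, sub in enumerate(layer.sublayers()):
                visit(sub, f"{prefix}.{k}")

        for i, layer in enumerate(self._all_layers()):
            visit(layer, f"L{i}")


def _head(rng, n_in: int, n_classes: int) -> nn.Sequential:
    dense = nn.Dense(n_in, n_classes, rng)
    # small-scale init keeps initial logits near zero, so the initial loss
    # sits at the uniform-softmax value log(K)
    dense.params["w"] = rng.normal(0.0, 0.01, size=dense.params["w"].shape)
    return nn.Sequential([dense])


def build_static_model(
    rng: np.random.Generator,
    n_channels: int = 8,
    n_classes: int = 24,
    spec: Conv1DBlockSpec | None = None,
    input_length: int = 150,
) -> ParallelPathModel:
    """One independent 1-D ConvNet block per channel, concatenated head."""
    spec = spec or Conv1DBlockSpec()
    branches = [
        conv1d_block(spec, rng, c_in=1, input_length=input_length)
        for _ in range(n_channels)
    ]
    head = _head(rng, n_channels * spec.embedding_dim, n_classes)
    shapes = [(1, input_length)] * n_channels
    return ParallelPathModel(branches, head, shapes, n_classes)


def build_dynamic_model(
    rng: np.random.Generator,
    n_classes: int = 16,
    spec1d: Conv1DBlockSpec | None = None,
    spec2d: Backbone2DSpec | None = None,
    input_length: int = 150,
    image_size: int = 224,
    shared_backbone: bool = True,
) -> ParallelPathModel:
    """8 parallel paths: 3 projection images + 5 flex time series.

    The three image paths share one backbone by default (a third of the
    parameters); each image still gets its own embedding projection for
    symmetry with the 1-D paths.
    """
    spec1d = spec1d or Conv1DBlockSpec()
    spec2d = spec2d or Backbone2DSpec()

    def image_branch(backbone, backbone_dim):
        return nn.Sequential(
            [
                nn.AvgPool2D(spec2d.downsample),
                backbone,
                nn.Dense(backbone_dim, spec2d.embedding_dim, rng),
                nn.ReLU(),
            ]
        )

    if shared_backbone:
        backbone, dim = mobilenet_v2(spec2d, rng)
        image_branches = [image_branch(backbone, dim) for _ in range(3)]
    else:
        image_branches = []
        for _ in range(3):
            backbone, dim = mobilenet_v2(spec2d, rng)
            image_branches.append(image_branch(backbone, dim))
    flex_branches = [
        conv1d_block(spec1d, rng, c_in=1, input_length=input_length)
        for _ in range(5)
    ]
    branches = image_branches + flex_branches
    n_embed = 3 * spec2d.embedding_dim + 5 * spec1d.embedding_dim
    head = _head(rng, n_embed, n_classes)
    shapes = [(1, image_size, image_size)] * 3 + [(1, input_length)] * 5
    return ParallelPathModel(branches, head, shapes, n_classes)


def _batched_loss(model, inputs, labels, batch_size: int) -> float:
    total, n = 0.0, labels.shape[0]
    for start in range(0, n, batch_size):
        sl = slice(start, min(start + batch_size, n))
        logits, _ = model.forward([x[sl] for x in inputs], train=False)
        loss, _ = nn.softmax_cross_entropy(logits, labels[sl])
        total += loss * (sl.stop - sl.start)
    return total / n


def train(
    model: ParallelPathModel,
    train_inputs,
    train_labels,
    val_inputs,
    val_labels,
    cfg: TrainConfig | None = None,
) -> dict:
    """Fit with Adam + early stopping on validation loss; restore best weights.

    Returns a history dict with per-epoch ``loss`` and ``val_loss``.
    Deterministic for a fixed config seed on a single CPU thread.
    """
    cfg = cfg or TrainConfig()
    train_labels = np.asarray(train_labels)
    val_labels = np.asarray(val_labels)
    if train_labels.size == 0 or val_labels.size == 0:
        raise ValueError("empty training or validation set")
    rng = np.random.default_rng(cfg.seed)
    optimizer = nn.Adam(model.parameters(), lr=cfg.learning_rate)
    history: dict = {"loss": [], "val_loss": []}
    best_loss = np.inf
    best_state = model.get_state()
    best_epoch = 0
    n = train_labels.shape[0]
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            batch = [x[idx] for x in train_inputs]
            model.zero_grads()
            logits, cache = model.forward(batch, train=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, train_labels[idx])
            model.backward(dlogits, cache)
            optimizer.step()
            epoch_loss += loss * idx.shape[0]
        history["loss"].append(epoch_loss / n)
        val_loss = _batched_loss(model, val_inputs, val_labels, cfg.batch_size)
        history["val_loss"].append(val_loss)
        if val_loss < best_loss:
            best_loss = val_loss
            best_state = model.get_state()
            best_epoch = epoch
        elif epoch - best_epoch > cfg.patience:
            break
    model.set_state(best_state)
    history["best_epoch"] = best_epoch
    return history


def predict(model: ParallelPathModel, inputs, batch_size: int = 32):
    """Class probabilities and argmax labels (ties -> lowest class index)."""
    inputs = [np.asarray(x) for x in inputs]
    model.check_inputs(inputs)
    n = inputs[0].shape[0]
    probs = np.empty((n, model.n_classes))
    for start in range(0, n, batch_size):
        sl = slice(start, min(start + batch_size, n))
        logits, _ = model.forward([x[sl] for x in inputs], train=False)
        probs[sl] = nn.softmax(logits)
    return probs.argmax(axis=1), probs


def save_weights(model: ParallelPathModel, path) -> None:
    """Checkpoint all weights (and batch-norm statistics) to an .npz file."""
    state = model.get_state()
    np.savez(path, **state)


def load_weights(model: ParallelPathModel, path) -> None:
    with np.load(path) as data:
        model.set_state({k: data[k] for k in data.files})
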