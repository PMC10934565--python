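"""Multi-label disease classification.

Two architectures built from the same densely connected trunk:

* single-input — stem (conv + pool), 4 dense blocks with 3 transition
  layers between them, a 1x1 reduction of the final block's output to 16
  channels, global average pooling into a 16-vector, and a fully
  connected layer with 12 sigmoid outputs;
* dual-input — the same network, except the stem's feature maps are
  rescaled channel-wise by ``(1 + w)`` where ``w`` comes from a second
  input (the difference image) through two convolutions, a pooling layer
  and global average pooling.

With the second path's final convolution at zero, the dual network
reproduces the single network bit for bit under shared weights (the
operation block multiplies by exactly 1.0).

Loss is unweighted per-class binary cross-entropy; training uses Adam with
a plateau scheduler.  ``full_config`` mirrors the source recipe (512
inputs, batch 2, lr 1e-4, decay 0.1 / patience 3, 40 epochs);
``desk_config`` is the reduced CPU profile used in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import nn
from .metrics_cv import evaluate_auc
from .preprocess import to_unit
from .types import N_CLASSES

INPUT_MODES = ("post", "diff-linear", "diff-nl1", "diff-nl2")


@dataclass(frozen=True)
class ClassifierConfig:
    architecture: str = "single"          # "single" | "dual"
    input_mode: str = "post"
    image_size: int = 512
    stem_channels: int = 64
    growth: int = 32
    block_layers: tuple = (6, 12, 24, 16)
    final_channels: int = 16
    lr: float = 1e-4
    lr_decay: float = 0.1
    patience: int = 3
    batch_size: int = 2
    epochs: int = 40
    adam_betas: tuple = (0.9, 0.999)
    seed: int = 0


def full_config(**overrides) -> ClassifierConfig:
    return replace(ClassifierConfig(), **overrides)


def desk_config(**overrides) -> ClassifierConfig:
    base = ClassifierConfig(
        image_size=64, stem_channels=8, growth=6,
        block_layers=(2, 2, 2, 2), lr=1e-3, batch_size=8, epochs=10)
    return replace(base, **overrides)


def operation_block(f1: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Channel-weighted fusion: out[c] = f1[c] * (1 + w[c]).

    ``f1`` is (C, H, W) or (N, C, H, W); ``w`` is (C,) or (N, C).
    """
    f1 = np.asarray(f1)
    w = np.asarray(w)
    if f1.ndim == 3:
        if w.shape != (f1.shape[0],):
            raise ValueError("channel counts do not match")
        return f1 * (1.0 + w)[:, None, None]
    if w.shape != f1.shape[:2]:
        raise ValueError("channel counts do not match")
    return f1 * (1.0 + w)[:, :, None, None]


class _DenseBlock(nn.Module):
    def __init__(self, in_ch, n_layers, growth, rng):
        self.convs = [nn.Conv2d(in_ch + i * growth, growth, 3, rng=rng)
                      for i in range(n_layers)]
        self.norms = [nn.BatchNorm2d(growth) for _ in range(n_layers)]
        self.out_channels = in_ch + n_layers * growth

    def forward(self, x):
        for conv, norm in zip(self.convs, self.norms):
            x = nn.concat([x, norm(conv(x)).relu()], axis=1)
        return x


class _Transition(nn.Module):
    def __init__(self, in_ch, rng):
        self.out_channels = max(1, in_ch // 2)
        self.conv = nn.Conv2d(in_ch, self.out_channels, 1, rng=rng)
        self.norm = nn.BatchNorm2d(self.out_channels)

    def forward(self, x):
        return nn.avg_pool2x2(self.norm(self.conv(x)).relu())


class SingleInputNet(nn.Module):
    def __init__(self, config: ClassifierConfig | None = None):
        config = config or ClassifierConfig()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.stem = nn.Conv2d(1, config.stem_channels, 3, stride=2, rng=rng)
        self.stem_norm = nn.BatchNorm2d(config.stem_channels)
        ch = config.stem_channels
        self.blocks, self.transitions = [], []
        for i, n_layers in enumerate(config.block_layers):
            block = _DenseBlock(ch, n_layers, config.growth, rng)
            self.blocks.append(block)
            ch = block.out_channels
            if i < len(config.block_layers) - 1:
                tr = _Transition(ch, rng)
                self.transitions.append(tr)
                ch = tr.out_channels
        self.reduce = nn.Conv2d(ch, config.final_channels, 1, rng=rng)
        self.reduce_norm = nn.BatchNorm2d(config.final_channels)
        self.fc = nn.Linear(config.final_channels, N_CLASSES, rng=rng)

    def _stem_features(self, x: nn.Tensor) -> nn.Tensor:
        return nn.max_pool2x2(self.stem_norm(self.stem(x)).relu())

    def _trunk(self, h: nn.Tensor) -> nn.Tensor:
        for i, block in enumerate(self.blocks):
            h = block(h)
            if i < len(self.transitions):
                h = self.transitions[i](h)
        h = self.reduce_norm(self.reduce(h)).relu()
        feat = nn.global_avg_pool(h)          # (N, 16)
        return self.fc(feat)                  # logits (N, 12)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        return self._trunk(self._stem_features(x))


class DualInputNet(nn.Module):
    """Input 1 shares the single-input stem/trunk; input 2 goes through
    two convolutions, a pooling layer and GAP to produce the per-channel
    weights consumed by the operation block."""

    def __init__(self, config: ClassifierConfig | None = None):
        config = config or ClassifierConfig(architecture="dual")
        self.single = SingleInputNet(replace(config, architecture="single"))
        self.config = self.single.config
        rng = np.random.default_rng(self.config.seed + 1)
        c = self.config.stem_channels
        self.w_conv1 = nn.Conv2d(1, c, 3, stride=2, rng=rng)
        self.w_conv2 = nn.Conv2d(c, c, 3, rng=rng)

    def weighting(self, x2: nn.Tensor) -> nn.Tensor:
        h = self.w_conv1(x2).relu()
        h = nn.max_pool2x2(self.w_conv2(h).relu())
        return nn.global_avg_pool(h)          # (N, C)

    def forward(self, x1: nn.Tensor, x2: nn.Tensor) -> nn.Tensor:
        f1 = self.single._stem_features(x1)   # (N, C, h, w)
        w = self.weighting(x2)
        n, c = w.shape
        fused = f1 * (1.0 + w.reshape(n, c, 1, 1))
        return self.single._trunk(fused)

    def zero_second_path(self) -> None:
        """Zero the final convolution of the input-2 path so w == 0 and the
        network collapses onto its single-input core."""
        self.w_conv2.weight.data[:] = 0.0
        self.w_conv2.bias.data[:] = 0.0

    @classmethod
    def from_single(cls, single: SingleInputNet) -> "DualInputNet":
        dual = cls(single.config)
        dual.single.load_state_dict(single.state_dict())
        return dual


# ---------------------------------------------------------------------------
# training / inference
# ---------------------------------------------------------------------------


def _as_batches(inputs, config):
    if config.architecture == "dual":
        x1 = np.stack([to_unit(a) for a, _ in inputs]).astype(np.float32)
        x2 = np.stack([to_unit(b) for _, b in inputs]).astype(np.float32)
        return x1[:, None], x2[:, None]
    x = np.stack([to_unit(a) for a in inputs]).astype(np.float32)
    return x[:, None], None


def build_classifier(config: ClassifierConfig):
    if config.architecture == "single":
        return SingleInputNet(config)
    if config.architecture == "dual":
        return DualInputNet(config)
    raise ValueError(f"unknown architecture {config.architecture!r}")


def _forward(model, x1, x2, idx):
    b1 = nn.Tensor(x1[idx])
    if isinstance(model, DualInputNet):
        return model(b1, nn.Tensor(x2[idx]))
    return model(b1)


def train_classifier(inputs, labels, config: ClassifierConfig | None = None,
                     log: dict | None = None):
    """Train on (inputs, multi-hot labels).

    ``inputs`` is a list of images (single) or (post, diff) pairs (dual);
    ``labels`` is an (n, 12) 0/1 array.
    """
    if len(inputs) == 0:
        raise ValueError("empty dataset")
    config = config or ClassifierConfig()
    labels = np.asarray(labels, dtype=np.float32)
    model = build_classifier(config)
    x1, x2 = _as_batches(inputs, config)
    opt = nn.Adam(model.parameters(), lr=config.lr, betas=config.adam_betas)
    sched = nn.ReduceLROnPlateau(opt, factor=config.lr_decay,
                                 patience=config.patience)
    rng = np.random.default_rng(config.seed)
    n = len(inputs)
    history = {"train_loss": [], "lr": []}
    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            opt.zero_grad()
            logits = _forward(model, x1, x2, idx)
            loss = nn.bce_with_logits(logits, labels[idx])
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        epoch_loss = float(np.mean(losses))
        sched.step(epoch_loss)
        history["train_loss"].append(epoch_loss)
        history["lr"].append(opt.lr)
    if log is not None:
        log.update(history)
    return model


def predict_proba(model, inputs) -> np.ndarray:
    """Sigmoid class probabilities, shape (n, 12)."""
    config = model.config
    x1, x2 = _as_batches(inputs, replace(
        config, architecture="dual" if isinstance(model, DualInputNet)
        else "single"))
    was_training = getattr(model, "training", True)
    model.eval()
    out = []
    bs = 16
    for start in range(0, len(inputs), bs):
        idx = np.arange(start, min(start + bs, len(inputs)))
        logits = _forward(model, x1, x2, idx)
        out.append(1.0 / (1.0 + np.exp(-logits.data.astype(np.float64))))
    model.set_training(was_training)
    return np.concatenate(out, axis=0)


def evaluate_model(model, inputs, labels) -> tuple[np.ndarray, float]:
    """Per-class AUC and macro mean on a labeled dataset."""
    return evaluate_auc(predict_proba(model, inputs), np.asarray(labels))


def stratified_split(labels: np.ndarray, test_fraction: float = 0.2,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """80/20-style split stratified by no-findings vs any-disease."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    any_disease = labels.sum(axis=1) > 0
    train_idx, test_idx = [], []
    for group in (np.nonzero(any_disease)[0], np.nonzero(~any_disease)[0]):
        perm = rng.permutation(group)
        n_test = int(round(test_fraction * len(perm)))
        test_idx.extend(perm[:n_test])
        train_idx.extend(perm[n_test:])
    return np.sort(train_idx).astype(int), np.sort(test_idx).astype(int)
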