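"""One-stage lung-box detector.

Residual backbone + feature pyramid + class/box subnets trained with focal
loss and smooth-L1 box regression, in the spirit of a RetinaNet reduced to
a single-object task.  Two profiles are provided: ``full_config`` mirrors
the source training recipe (512 inputs, ResNet18-depth backbone, P3-P7,
batch 1, lr 1e-4, plateau decay 0.1 / patience 3, 200 epochs, Adam
betas (0.9, 0.999)); ``desk_config`` is a reduced CPU profile used by the
tests (128 inputs, shallow backbone, one pyramid level).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import nn
from .preprocess import to_unit
from .types import LungBox

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DetectorConfig:
    image_size: int = 512
    stem_channels: int = 16
    stage_channels: tuple = (32, 64, 128, 256)
    blocks_per_stage: tuple = (2, 2, 2, 2)      # 18-layer-style depth
    fpn_channels: int = 64
    level_strides: tuple = (8, 16, 32)
    anchor_scales: tuple = (0.45, 0.6, 0.75)    # fractions of image size
    anchor_ratios: tuple = (0.7, 1.0, 1.4)
    focal_alpha: float = 0.25
    focal_gamma: float = 2.0
    pos_iou: float = 0.5
    neg_iou: float = 0.4
    reg_loss_weight: float = 1.0
    score_threshold: float = 0.05
    nms_iou: float = 0.5
    #: refine each NMS survivor by score-weighted averaging of the
    #: candidate boxes overlapping it at IoU >= box_voting_iou (box
    #: voting); scores are untouched
    box_voting: bool = False
    box_voting_iou: float = 0.8
    lr: float = 1e-4
    lr_decay: float = 0.1
    patience: int = 3
    batch_size: int = 1
    epochs: int = 200
    adam_betas: tuple = (0.9, 0.999)
    seed: int = 0


def full_config(**overrides) -> DetectorConfig:
    return replace(DetectorConfig(), **overrides)


def desk_config(**overrides) -> DetectorConfig:
    """Reduced profile for CPU-scale training on 128x128 phantoms."""
    base = DetectorConfig(
        image_size=128,
        stem_channels=8,
        stage_channels=(16, 24, 32, 40),
        blocks_per_stage=(1, 1, 1, 1),
        fpn_channels=24,
        level_strides=(32,),
        anchor_scales=(0.55, 0.7, 0.85),
        anchor_ratios=(0.8, 1.0, 1.25),
        lr=2e-3,
        batch_size=4,
        epochs=10,
        reg_loss_weight=4.0,
        box_voting=True,
    )
    return replace(base, **overrides)


# ---------------------------------------------------------------------------
# losses and box arithmetic (plain-array contracts)
# ---------------------------------------------------------------------------


def focal_loss(pred_prob, target, alpha: float = 0.25, gamma: float = 2.0,
               eps: float = 1e-7) -> float:
    """FL = -alpha_t (1 - p_t)^gamma log(p_t), summed over elements.

    Probabilities are clamped to [eps, 1-eps] so exact 0/1 predictions do
    not produce infinities.
    """
    p = np.clip(np.asarray(pred_prob, dtype=np.float64), eps, 1.0 - eps)
    t = np.asarray(target, dtype=np.float64)
    p_t = np.where(t == 1, p, 1.0 - p)
    a_t = np.where(t == 1, alpha, 1.0 - alpha)
    return float(np.sum(-a_t * (1.0 - p_t) ** gamma * np.log(p_t)))


def _anchor_grid(config: DetectorConfig) -> np.ndarray:
    """All anchors as (N, 4) rows of (top, bottom, left, right), float."""
    s = config.image_size
    out = []
    for stride in config.level_strides:
        n = s // stride
        centers = (np.arange(n) + 0.5) * stride
        cy, cx = np.meshgrid(centers, centers, indexing="ij")
        for scale in config.anchor_scales:
            for ratio in config.anchor_ratios:
                h = s * scale * np.sqrt(ratio)
                w = s * scale / np.sqrt(ratio)
                out.append(np.stack([
                    cy - h / 2, cy + h / 2, cx - w / 2, cx + w / 2,
                ], axis=-1).reshape(-1, 4))
    # per level the layout is (anchor_type, row, col) flattened, matching
    # the head output reshape below
    per_level = []
    i = 0
    na = len(config.anchor_scales) * len(config.anchor_ratios)
    for stride in config.level_strides:
        n = (s // stride) ** 2
        level = np.stack(out[i:i + na])      # (A, n, 4)
        per_level.append(level.reshape(-1, 4))
        i += na
    return np.concatenate(per_level, axis=0)


def _pairwise_iou(anchors: np.ndarray, box: LungBox) -> np.ndarray:
    t, b, l, r = box.as_tuple()
    it = np.maximum(anchors[:, 0], t)
    ib = np.minimum(anchors[:, 1], b)
    il = np.maximum(anchors[:, 2], l)
    ir = np.minimum(anchors[:, 3], r)
    inter = np.clip(ib - it, 0, None) * np.clip(ir - il, 0, None)
    area_a = (anchors[:, 1] - anchors[:, 0]) * (anchors[:, 3] - anchors[:, 2])
    union = area_a + box.area - inter
    return inter / union


def _encode(anchors: np.ndarray, box: LungBox) -> np.ndarray:
    ah = anchors[:, 1] - anchors[:, 0]
    aw = anchors[:, 3] - anchors[:, 2]
    acy = (anchors[:, 0] + anchors[:, 1]) / 2
    acx = (anchors[:, 2] + anchors[:, 3]) / 2
    gh, gw = box.height, box.width
    gcy = (box.top + box.bottom) / 2
    gcx = (box.left + box.right) / 2
    return np.stack([(gcy - acy) / ah, (gcx - acx) / aw,
                     np.log(gh / ah), np.log(gw / aw)], axis=-1)


def _decode(anchors: np.ndarray, deltas: np.ndarray) -> np.ndarray:
    ah = anchors[:, 1] - anchors[:, 0]
    aw = anchors[:, 3] - anchors[:, 2]
    acy = (anchors[:, 0] + anchors[:, 1]) / 2
    acx = (anchors[:, 2] + anchors[:, 3]) / 2
    cy = acy + deltas[:, 0] * ah
    cx = acx + deltas[:, 1] * aw
    h = ah * np.exp(np.clip(deltas[:, 2], -4, 4))
    w = aw * np.exp(np.clip(deltas[:, 3], -4, 4))
    return np.stack([cy - h / 2, cy + h / 2, cx - w / 2, cx + w / 2], axis=-1)


def assign_anchors(anchors: np.ndarray, truth: LungBox, pos_iou: float = 0.5,
                   neg_iou: float = 0.4) -> tuple[np.ndarray, np.ndarray]:
    """Per-anchor class targets (1 pos / 0 neg / -1 ignore) and encoded
    regression targets.  The best-IoU anchor is always positive."""
    if not 0.0 <= neg_iou <= pos_iou <= 1.0:
        raise ValueError("need 0 <= neg_iou <= pos_iou <= 1")
    ious = _pairwise_iou(anchors, truth)
    cls = np.full(len(anchors), -1.0)
    cls[ious <= neg_iou] = 0.0
    cls[ious >= pos_iou] = 1.0
    cls[np.argmax(ious)] = 1.0
    return cls, _encode(anchors, truth)


@dataclass(frozen=True)
class Detection:
    box: LungBox
    score: float


def decode_and_nms(scores: np.ndarray, deltas: np.ndarray,
                   anchors: np.ndarray, config: DetectorConfig
                   ) -> list[Detection]:
    """Decode offsets, threshold on score, greedy NMS, descending order."""
    boxes = _decode(anchors, deltas)
    size = config.image_size
    boxes[:, :2] = np.clip(boxes[:, :2], 0, size)
    boxes[:, 2:] = np.clip(boxes[:, 2:], 0, size)
    keep = scores >= config.score_threshold
    boxes, scs = boxes[keep], scores[keep]
    order = np.argsort(-scs, kind="stable")
    survivors: list[Detection] = []
    taken: list[np.ndarray] = []
    for i in order:
        cand = boxes[i]
        suppressed = False
        for prev in taken:
            it = max(cand[0], prev[0])
            ib = min(cand[1], prev[1])
            il = max(cand[2], prev[2])
            ir = min(cand[3], prev[3])
            inter = max(0.0, ib - it) * max(0.0, ir - il)
            union = ((cand[1] - cand[0]) * (cand[3] - cand[2])
                     + (prev[1] - prev[0]) * (prev[3] - prev[2]) - inter)
            if union > 0 and inter / union >= config.nms_iou:
                suppressed = True
                break
        if suppressed:
            continue
        taken.append(cand)
        out_box = cand
        if config.box_voting and len(boxes):
            it = np.maximum(boxes[:, 0], cand[0])
            ib = np.minimum(boxes[:, 1], cand[1])
            il = np.maximum(boxes[:, 2], cand[2])
            ir = np.minimum(boxes[:, 3], cand[3])
            inter = np.clip(ib - it, 0, None) * np.clip(ir - il, 0, None)
            areas = ((boxes[:, 1] - boxes[:, 0])
                     * (boxes[:, 3] - boxes[:, 2]))
            cand_area = (cand[1] - cand[0]) * (cand[3] - cand[2])
            overl = inter / np.maximum(areas + cand_area - inter, 1e-9)
            voters = overl >= config.box_voting_iou
            if voters.any():
                w = scs[voters]
                out_box = (boxes[voters] * w[:, None]).sum(0) / w.sum()
        t = int(np.clip(np.round(out_box[0]), 0, size - 2))
        b = int(np.clip(np.round(out_box[1]), t + 1, size))
        l = int(np.clip(np.round(out_box[2]), 0, size - 2))
        r = int(np.clip(np.round(out_box[3]), l + 1, size))
        survivors.append(Detection(box=LungBox(t, b, l, r),
                                   score=float(scs[i])))
    return survivors


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------


class _BasicBlock(nn.Module):
    def __init__(self, in_ch, out_ch, stride, rng):
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, stride=stride, rng=rng)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, rng=rng)
        self.proj = (nn.Conv2d(in_ch, out_ch, 1, stride=stride, rng=rng)
                     if (stride != 1 or in_ch != out_ch) else None)

    def forward(self, x):
        y = self.conv2(self.conv1(x).relu())
        skip = self.proj(x) if self.proj is not None else x
        return (y + skip).relu()


class DetectorModel(nn.Module):
    def __init__(self, config: DetectorConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.stem = nn.Conv2d(1, config.stem_channels, 3, stride=2, rng=rng)
        self.stages = []
        in_ch = config.stem_channels
        self._stage_strides = []
        stride = 2
        for ch, n_blocks in zip(config.stage_channels,
                                config.blocks_per_stage):
            blocks = [_BasicBlock(in_ch, ch, 2, rng)]
            blocks += [_BasicBlock(ch, ch, 1, rng) for _ in range(n_blocks - 1)]
            self.stages.append(nn.Sequential(*blocks))
            in_ch = ch
            stride *= 2
            self._stage_strides.append(stride)
        fpn = config.fpn_channels
        self.laterals = [nn.Conv2d(config.stage_channels[
            self._stage_strides.index(s)], fpn, 1, rng=rng)
            for s in config.level_strides]
        self.fpn_out = [nn.Conv2d(fpn, fpn, 3, rng=rng)
                        for _ in config.level_strides]
        na = len(config.anchor_scales) * len(config.anchor_ratios)
        self.head_conv = nn.Conv2d(fpn, fpn, 3, rng=rng)
        self.cls_head = nn.Conv2d(fpn, na, 3, rng=rng)
        self.reg_head = nn.Conv2d(fpn, 4 * na, 3, rng=rng)
        # focal-loss prior: rare-positive initialization
        self.cls_head.bias.data[:] = -np.log((1 - 0.01) / 0.01)

    def forward(self, x: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        """Returns (cls_logits (N, A_total), reg (N, A_total, 4)) with the
        anchor ordering of `_anchor_grid`."""
        cfg = self.config
        feats = {}
        h = self.stem(x).relu()
        for stage, stride in zip(self.stages, self._stage_strides):
            h = stage(h)
            feats[stride] = h
        pyramid = []
        top = None
        for lvl in reversed(range(len(cfg.level_strides))):
            lat = self.laterals[lvl](feats[cfg.level_strides[lvl]])
            if top is not None:
                lat = lat + nn.upsample_nearest2x(top)
            top = lat
            pyramid.append((lvl, self.fpn_out[lvl](lat)))
        pyramid.sort(key=lambda t: t[0])
        cls_parts, reg_parts = [], []
        na = len(cfg.anchor_scales) * len(cfg.anchor_ratios)
        for _, p in pyramid:
            hshared = self.head_conv(p).relu()
            n = hshared.shape[0]
            cls = self.cls_head(hshared)        # (N, A, h, w)
            reg = self.reg_head(hshared)        # (N, 4A, h, w)
            cls_parts.append(cls.reshape(n, -1))
            # reorder to (anchor_type, position, coord) to match the
            # anchor-grid layout
            reg_parts.append(
                reg.reshape(n, na, 4, reg.shape[2], reg.shape[3])
                .transpose(0, 1, 3, 4, 2)
                .reshape(n, -1))
        cls_all = nn.concat(cls_parts, axis=1)
        reg_all = nn.concat(reg_parts, axis=1)
        return cls_all, reg_all


def _focal_from_logits(logits: nn.Tensor, cls_targets: np.ndarray,
                       alpha: float, gamma: float) -> nn.Tensor:
    """Fused focal loss on logits, ignoring targets == -1; sums and
    normalizes by the positive count."""
    t = cls_targets
    valid = (t >= 0).astype(np.float32)
    tpos = (t == 1).astype(np.float32)
    p = logits.sigmoid().clamp(1e-6, 1.0 - 1e-6)
    p_t = p * tpos + (1.0 - p) * (1.0 - tpos)
    a_t = alpha * tpos + (1.0 - alpha) * (1.0 - tpos)
    fl = (-1.0) * (((1.0 - p_t).pow_const(gamma)) * p_t.log() * (a_t * valid))
    npos = max(1.0, float(tpos.sum()))
    return fl.sum() * (1.0 / npos)


def _smooth_l1(x: nn.Tensor) -> nn.Tensor:
    ax = x.abs()
    cl = ax.clamp(0.0, 1.0)
    return ax * cl - 0.5 * (cl * cl)


def _reg_loss(reg: nn.Tensor, reg_targets: np.ndarray,
              cls_targets: np.ndarray) -> nn.Tensor:
    n, a4 = reg.shape
    mask = np.repeat((cls_targets == 1).astype(np.float32), 4, axis=-1)
    diff = (reg - nn.Tensor(reg_targets.reshape(n, a4))) * mask
    npos = max(1.0, float((cls_targets == 1).sum()))
    return _smooth_l1(diff).sum() * (1.0 / npos)


def detector_loss(model: DetectorModel, images: np.ndarray,
                  boxes: list[LungBox], anchors: np.ndarray) -> nn.Tensor:
    cfg = model.config
    cls_t = np.stack([assign_anchors(anchors, b, cfg.pos_iou,
                                     cfg.neg_iou)[0] for b in boxes])
    reg_t = np.stack([_encode(anchors, b) for b in boxes])
    cls_logits, reg = model(nn.Tensor(images[:, None]))
    loss_cls = _focal_from_logits(cls_logits, cls_t.astype(np.float32),
                                  cfg.focal_alpha, cfg.focal_gamma)
    loss_reg = _reg_loss(reg, reg_t.astype(np.float32),
                         cls_t.astype(np.float32))
    return loss_cls + cfg.reg_loss_weight * loss_reg


def train_detector(dataset: list[tuple[np.ndarray, LungBox]],
                   config: DetectorConfig | None = None,
                   val_fraction: float = 0.1,
                   log: dict | None = None) -> DetectorModel:
    """Train with Adam + plateau scheduler (factor ``lr_decay``, patience
    ``patience``), evaluating validation loss once per epoch."""
    if not dataset:
        raise ValueError("empty dataset")
    config = config or DetectorConfig()
    model = DetectorModel(config)
    anchors = _anchor_grid(config)
    opt = nn.Adam(model.parameters(), lr=config.lr, betas=config.adam_betas)
    sched = nn.ReduceLROnPlateau(opt, factor=config.lr_decay,
                                 patience=config.patience)
    rng = np.random.default_rng(config.seed)
    images = np.stack([to_unit(img) for img, _ in dataset]).astype(np.float32)
    boxes = [b for _, b in dataset]
    n = len(dataset)
    n_val = max(1, int(round(val_fraction * n))) if n > 1 else 0
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if len(train_idx) == 0:
        train_idx = perm
    history = {"train_loss": [], "val_loss": [], "lr": []}
    for _ in range(config.epochs):
        order = rng.permutation(train_idx)
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            opt.zero_grad()
            loss = detector_loss(model, images[idx],
                                 [boxes[i] for i in idx], anchors)
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        if n_val:
            vloss = float(detector_loss(
                model, images[val_idx], [boxes[i] for i in val_idx],
                anchors).data)
        else:
            vloss = float(np.mean(epoch_losses))
        sched.step(vloss)
        history["train_loss"].append(float(np.mean(epoch_losses)))
        history["val_loss"].append(vloss)
        history["lr"].append(opt.lr)
    if log is not None:
        log.update(history)
    return model


def detect(img: np.ndarray, model: DetectorModel) -> list[Detection]:
    cfg = model.config
    anchors = _anchor_grid(cfg)
    u = to_unit(img).astype(np.float32)
    if u.shape != (cfg.image_size, cfg.image_size):
        from .preprocess import resize_to

        u = resize_to(u, (cfg.image_size, cfg.image_size))
    cls_logits, reg = model(nn.Tensor(u[None, None]))
    scores = 1.0 / (1.0 + np.exp(-cls_logits.data[0].astype(np.float64)))
    deltas = reg.data[0].reshape(-1, 4).astype(np.float64)
    return decode_and_nms(scores, deltas, anchors, cfg)


def detect_lung(img: np.ndarray, model: DetectorModel) -> LungBox:
    """Highest-score detection as the single lung ROI, remapped to the
    input resolution."""
    dets = detect(img, model)
    if not dets:
        raise ValueError("no detection above score_threshold; consider "
                         "lowering config.score_threshold")
    box = dets[0].box
    h, w = np.asarray(img).shape
    s = model.config.image_size
    if (h, w) != (s, s):
        box = box.scaled(h / s, w / s).clipped((h, w))
    return box


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def save_detector(model: DetectorModel, path) -> None:
    import pickle

    from pathlib import Path

    state = {"config": model.config, "state": model.state_dict()}
    Path(path).write_bytes(pickle.dumps(state))


def load_detector(path) -> DetectorModel:
    import pickle

    from pathlib import Path

    state = pickle.loads(Path(path).read_bytes())
    model = DetectorModel(state["config"])
    model.load_state_dict(state["state"])
    return model
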