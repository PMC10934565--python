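"""Deformable registration of the working (pre) crop onto the reference
(post) crop.

Two routes share one displacement-field convention (pull-back:
``out[p] = img[p + field[:, p]]``, replicate border):

* ``classical_register`` — dense field initialized to zero and updated by
  gradient ascent on a similarity metric (windowed neighborhood
  correlation by default, joint-histogram mutual information optionally),
  with Gaussian field smoothing after every step.
* ``VoxelMorphNet`` / ``train_voxelmorph`` — a U-Net (4 stride-2 encoder
  stages down to 1/16 resolution, skip-concatenating decoder, Leaky ReLU
  activations, zero-initialized final layer) trained unsupervised with
  ``-similarity + lambda * |grad field|^2``.

The default pipeline path histogram-matches the working image before
either route runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.ndimage import gaussian_filter, uniform_filter

from . import nn
from .metrics_cv import ncc as global_ncc
from .metrics_cv import psnr, ssim
from .preprocess import histogram_match, to_unit
from .types import DisplacementField

# ---------------------------------------------------------------------------
# warping
# ---------------------------------------------------------------------------


def warp(img: np.ndarray, field: DisplacementField | np.ndarray) -> np.ndarray:
    """Bilinear pull-back warp with replicate-edge sampling (float64)."""
    vec = field.vectors if isinstance(field, DisplacementField) else np.asarray(field)
    img = np.asarray(img, dtype=np.float64)
    if vec.shape != (2,) + img.shape:
        raise ValueError(f"field shape {vec.shape} does not match image "
                         f"{img.shape}")
    h, w = img.shape
    sr = np.clip(np.arange(h)[:, None] + vec[0], 0.0, h - 1.0)
    sc = np.clip(np.arange(w)[None, :] + vec[1], 0.0, w - 1.0)
    r0 = np.floor(sr).astype(np.int64)
    c0 = np.floor(sc).astype(np.int64)
    r1 = np.minimum(r0 + 1, h - 1)
    c1 = np.minimum(c0 + 1, w - 1)
    fr, fc = sr - r0, sc - c0
    return ((1 - fr) * (1 - fc) * img[r0, c0] + (1 - fr) * fc * img[r0, c1]
            + fr * (1 - fc) * img[r1, c0] + fr * fc * img[r1, c1])


# ---------------------------------------------------------------------------
# similarity metrics
# ---------------------------------------------------------------------------


def local_ncc(img_a: np.ndarray, img_b: np.ndarray, radius: int = 4) -> float:
    """Mean windowed Pearson correlation over (2r+1)^2 neighborhoods.

    Windows where either image has zero variance are skipped.
    """
    a = np.asarray(img_a, dtype=np.float64)
    b = np.asarray(img_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    size = 2 * radius + 1
    box = lambda x: uniform_filter(x, size=size, mode="reflect")
    mu_a, mu_b = box(a), box(b)
    va = box(a * a) - mu_a ** 2
    vb = box(b * b) - mu_b ** 2
    cov = box(a * b) - mu_a * mu_b
    tol = 1e-12
    valid = (va > tol) & (vb > tol)
    if not valid.any():
        raise ValueError("no window with nonzero variance in both images")
    r = cov[valid] / np.sqrt(va[valid] * vb[valid])
    return float(np.clip(r, -1.0, 1.0).mean())


def mutual_information(img_a: np.ndarray, img_b: np.ndarray,
                       bins: int = 32) -> float:
    """Joint-histogram mutual information H(A)+H(B)-H(A,B), in bits.

    Marginals are taken from the joint histogram so MI(A, A) equals H(A)
    exactly under the same binning.
    """
    a = np.asarray(img_a, dtype=np.float64).ravel()
    b = np.asarray(img_b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    joint, _, _ = np.histogram2d(a, b, bins=bins)
    p = joint / joint.sum()
    pa = p.sum(axis=1)
    pb = p.sum(axis=0)

    def entropy(q):
        q = q[q > 0]
        return -np.sum(q * np.log2(q))

    return float(entropy(pa) + entropy(pb) - entropy(p))


# gradient helpers -----------------------------------------------------------


def _local_ncc_grad(m: np.ndarray, f: np.ndarray, radius: int,
                    tol: float = 1e-10) -> tuple[float, np.ndarray]:
    """Mean windowed Pearson r and its gradient w.r.t. the moving image.

    Windows with (near-)zero variance in either image are masked out of
    both the value and the gradient, so the gradient vanishes identically
    on identical inputs instead of carrying an epsilon-induced bias.
    """
    size = 2 * radius + 1
    box = lambda x: uniform_filter(x, size=size, mode="reflect")
    mu_m, mu_f = box(m), box(f)
    vm = np.maximum(box(m * m) - mu_m ** 2, 0.0)
    vf = np.maximum(box(f * f) - mu_f ** 2, 0.0)
    cov = box(m * f) - mu_m * mu_f
    valid = (vm > tol) & (vf > tol)
    denom = np.where(valid, np.sqrt(vm * vf), 1.0)
    r = np.where(valid, cov / denom, 0.0)
    n_valid = int(valid.sum())
    if n_valid == 0:
        return 0.0, np.zeros_like(m)
    value = float(r.sum() / n_valid)
    A = np.where(valid, 1.0 / denom, 0.0)
    B = np.where(valid, cov / (np.where(valid, vm, 1.0) * denom), 0.0)
    grad = (box(A) * f - box(A * mu_f)) - (box(B) * m - box(B * mu_m))
    return value, grad / n_valid


def _mi_grad(m: np.ndarray, f: np.ndarray, bins: int,
             eps: float = 1e-10) -> tuple[float, np.ndarray]:
    """MI (nats here; bits only differ by a constant factor) and its
    gradient w.r.t. the moving image via linear Parzen windows on m."""
    n = m.size
    fb = np.clip((f * (bins - 1)).astype(np.int64), 0, bins - 1)
    ms = np.clip(m, 0.0, 1.0) * (bins - 1)
    b0 = np.clip(np.floor(ms).astype(np.int64), 0, bins - 2)
    w1 = ms - b0
    joint = np.zeros((bins, bins))
    np.add.at(joint, (fb.ravel(), b0.ravel()), (1.0 - w1).ravel())
    np.add.at(joint, (fb.ravel(), b0.ravel() + 1), w1.ravel())
    pj = joint / n
    pm = pj.sum(axis=0)
    pf = pj.sum(axis=1)
    nz = pj > 0
    mi = float(np.sum(pj[nz] * np.log(pj[nz]))
               - np.sum(pm[pm > 0] * np.log(pm[pm > 0]))
               - np.sum(pf[pf > 0] * np.log(pf[pf > 0])))
    L = np.log(pj + eps) - np.log(pm + eps)[None, :]
    scale = (bins - 1) / n
    grad = scale * (L[fb, b0 + 1] - L[fb, b0])
    return mi, grad


# ---------------------------------------------------------------------------
# classical route
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassicalRegConfig:
    metric: str = "local_ncc"        # "local_ncc" | "mutual_information"
    radius: int = 4                  # local NCC window radius
    bins: int = 32                   # MI histogram bins
    step: float = 0.4                # max field update per iteration, px
    iterations: int = 150
    smooth_sigma: float = 2.0        # Gaussian smoothing of the field
    pyramid_levels: int = 2          # 1 = single scale, 2 adds a half-res pass


@dataclass
class RegistrationResult:
    field: DisplacementField
    warped: np.ndarray
    metrics_before: dict
    metrics_after: dict
    iterations: int
    metric_trace: list = dc_field(default_factory=list)


def _metric_and_grad(m, f, config: ClassicalRegConfig):
    if config.metric == "local_ncc":
        return _local_ncc_grad(m, f, config.radius)
    if config.metric == "mutual_information":
        return _mi_grad(m, f, config.bins)
    raise ValueError(f"unknown metric {config.metric!r}")


def _register_single_scale(moving, fixed, config, init_field):
    fld = init_field.copy()
    best_fld = fld.copy()
    best_val = -np.inf
    trace = []
    for _ in range(config.iterations):
        warped = warp(moving, fld)
        value, g_img = _metric_and_grad(warped, fixed, config)
        trace.append(value)
        if value > best_val:
            best_val = value
            best_fld = fld.copy()
        gr, gc = np.gradient(warped)
        upd = np.stack([g_img * gr, g_img * gc])
        upd[0] = gaussian_filter(upd[0], config.smooth_sigma)
        upd[1] = gaussian_filter(upd[1], config.smooth_sigma)
        peak = np.abs(upd).max()
        # a vanishing metric gradient means the optimum was reached;
        # renormalizing numerical noise would walk the field away from it
        if peak <= 1e-9:
            break
        fld = fld + upd * (config.step / peak)
        fld[0] = gaussian_filter(fld[0], config.smooth_sigma * 0.5)
        fld[1] = gaussian_filter(fld[1], config.smooth_sigma * 0.5)
    # evaluate the final field as well
    warped = warp(moving, fld)
    value, _ = _metric_and_grad(warped, fixed, config)
    trace.append(value)
    if value > best_val:
        best_val = value
        best_fld = fld
    return best_fld, trace


def classical_register(working: np.ndarray, reference: np.ndarray,
                       config: ClassicalRegConfig | None = None
                       ) -> RegistrationResult:
    """Gradient-ascent displacement-field registration.

    Non-convergence is not an error; the best-metric field seen during the
    iteration-capped run is returned.
    """
    config = config or ClassicalRegConfig()
    moving = to_unit(working)
    fixed = to_unit(reference)
    if moving.shape != fixed.shape:
        raise ValueError("working and reference must share a grid")

    before = _similarity_report(moving, fixed)
    trace_all: list[float] = []
    fld = np.zeros((2,) + moving.shape)
    if config.pyramid_levels >= 2 and min(moving.shape) >= 32:
        from .preprocess import resize_to

        half = (moving.shape[0] // 2, moving.shape[1] // 2)
        m2 = resize_to(moving, half)
        f2 = resize_to(fixed, half)
        cfg2 = ClassicalRegConfig(
            metric=config.metric, radius=max(2, config.radius // 2),
            bins=config.bins, step=config.step,
            iterations=config.iterations, smooth_sigma=config.smooth_sigma,
            pyramid_levels=1)
        fld2, trace = _register_single_scale(m2, f2, cfg2,
                                             np.zeros((2,) + half))
        trace_all.extend(trace)
        fld = 2.0 * np.stack([
            resize_to(fld2[0], moving.shape),
            resize_to(fld2[1], moving.shape),
        ])
    fld, trace = _register_single_scale(moving, fixed, config, fld)
    trace_all.extend(trace)
    warped = warp(moving, fld)
    return RegistrationResult(
        field=DisplacementField(fld),
        warped=warped,
        metrics_before=before,
        metrics_after=_similarity_report(warped, fixed),
        iterations=len(trace_all),
        metric_trace=trace_all,
    )


def _similarity_report(a: np.ndarray, b: np.ndarray) -> dict:
    return {
        "psnr": psnr(a, b, peak=1.0),
        "ssim": ssim(a, b, peak=1.0),
        "ncc": global_ncc(a, b),
    }


# ---------------------------------------------------------------------------
# learned route
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VoxelMorphConfig:
    enc_channels: tuple = (16, 32, 32, 32)
    dec_channels: tuple = (32, 32, 32, 32)
    extra_channels: tuple = (16, 16)
    lr: float = 1e-4
    batch_size: int = 8
    epochs: int = 400
    smooth_lambda: float = 0.01
    ncc_radius: int = 3
    seed: int = 0


class VoxelMorphNet(nn.Module):
    """U-Net field regressor: 4 stride-2 encoder stages (1/16 resolution at
    the bottleneck), decoder with skip concatenations, Leaky ReLU
    activations, and a zero-initialized 2-channel output head so the
    untrained network is the identity warp."""

    def __init__(self, config: VoxelMorphConfig | None = None):
        config = config or VoxelMorphConfig()
        self.config = config
        rng = np.random.default_rng(config.seed)
        enc = config.enc_channels
        self.enc_convs = []
        in_ch = 2
        for ch in enc:
            self.enc_convs.append(nn.Conv2d(in_ch, ch, 3, stride=2, rng=rng))
            in_ch = ch
        self.dec_convs = []
        skips = [2] + list(enc[:-1])
        for ch, skip_ch in zip(config.dec_channels, reversed(skips)):
            self.dec_convs.append(nn.Conv2d(in_ch + skip_ch, ch, 3, rng=rng))
            in_ch = ch
        self.extra_convs = []
        for ch in config.extra_channels:
            self.extra_convs.append(nn.Conv2d(in_ch, ch, 3, rng=rng))
            in_ch = ch
        self.out_conv = nn.Conv2d(in_ch, 2, 3, zero_init=True)

    def forward(self, moving: nn.Tensor, fixed: nn.Tensor) -> nn.Tensor:
        x = nn.concat([moving, fixed], axis=1)
        h, w = x.shape[2], x.shape[3]
        if h % 16 or w % 16:
            raise ValueError("input spatial size must be divisible by 16")
        skips = [x]
        for conv in self.enc_convs:
            x = conv(x).leaky_relu(0.2)
            skips.append(x)
        skips.pop()  # bottleneck is not its own skip
        for conv in self.dec_convs:
            x = nn.upsample_nearest2x(x)
            x = nn.concat([x, skips.pop()], axis=1)
            x = conv(x).leaky_relu(0.2)
        for conv in self.extra_convs:
            x = conv(x).leaky_relu(0.2)
        return self.out_conv(x)

    def predict_field(self, moving: np.ndarray,
                      fixed: np.ndarray) -> DisplacementField:
        m = nn.Tensor(to_unit(moving)[None, None])
        f = nn.Tensor(to_unit(fixed)[None, None])
        out = self.forward(m, f)
        return DisplacementField(out.data[0].astype(np.float64))


def voxelmorph_loss(model: VoxelMorphNet, moving: np.ndarray,
                    fixed: np.ndarray) -> nn.Tensor:
    """Unsupervised loss: -local CC(warp(moving, field), fixed)
    + lambda * |grad field|^2 on one batch (N, H, W arrays)."""
    cfg = model.config
    m = nn.Tensor(moving[:, None])
    f_t = nn.Tensor(fixed[:, None])
    fld = model.forward(m, f_t)
    warped = nn.warp_bilinear(m, fld)
    sim = nn.local_ncc_loss(warped, fixed[:, None], radius=cfg.ncc_radius)
    return sim + cfg.smooth_lambda * nn.field_smoothness(fld)


def train_voxelmorph(pairs: list[tuple[np.ndarray, np.ndarray]],
                     config: VoxelMorphConfig | None = None,
                     log=None) -> VoxelMorphNet:
    """Train on (moving, fixed) unit-range pairs with Adam."""
    if not pairs:
        raise ValueError("empty dataset")
    config = config or VoxelMorphConfig()
    model = VoxelMorphNet(config)
    opt = nn.Adam(model.parameters(), lr=config.lr)
    rng = np.random.default_rng(config.seed)
    movings = np.stack([to_unit(p[0]) for p in pairs]).astype(np.float32)
    fixeds = np.stack([to_unit(p[1]) for p in pairs]).astype(np.float32)
    n = len(pairs)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            opt.zero_grad()
            loss = voxelmorph_loss(model, movings[idx], fixeds[idx])
            loss.backward()
            opt.step()
            if log is not None:
                log.append(float(loss.data))
    return model


# ---------------------------------------------------------------------------
# orchestrator
# ---------------------------------------------------------------------------


def register(pre: np.ndarray, post: np.ndarray, method: str = "classical",
             config: ClassicalRegConfig | None = None,
             model: VoxelMorphNet | None = None) -> RegistrationResult:
    """Histogram-match the working (pre) crop to the reference (post) crop,
    then run the chosen registration route and report before/after
    similarity metrics."""
    moving = to_unit(histogram_match(to_unit(pre), to_unit(post)))
    fixed = to_unit(post)
    if method == "classical":
        return classical_register(moving, fixed, config)
    if method == "learned":
        if model is None:
            raise ValueError("learned registration needs a trained model")
        before = _similarity_report(moving, fixed)
        fld = model.predict_field(moving, fixed)
        warped = warp(moving, fld)
        return RegistrationResult(
            field=fld, warped=warped, metrics_before=before,
            metrics_after=_similarity_report(warped, fixed), iterations=0)
    raise ValueError(f"unknown method {method!r}")
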