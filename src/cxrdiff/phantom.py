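"""Synthetic pre/post chest-radiograph pairs with full ground truth.

The phantom renders a dark background, a brighter thorax ellipse, two
darker elliptical lung fields, periodic rib bands and optional circular
lesions.  A pair is a rendered "pre" anatomy plus a "post" image obtained
by warping the same anatomy with a known smooth displacement field, adding
new lesions, a detector gain/offset and fresh noise.  Ground truth (lung
mask, lung box, dense field, lesion mask, labels) is returned alongside so
every downstream stage can be scored without external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import zoom as ndi_zoom

from .types import (DisplacementField, LESION_LABEL_INDEX, LungBox,
                    label_vector)


@dataclass(frozen=True)
class Ellipse:
    """(center_row, center_col, semi_axis_row, semi_axis_col), pixels."""
    cr: float
    cc: float
    ar: float
    ac: float

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        rr = np.arange(shape[0])[:, None]
        cc = np.arange(shape[1])[None, :]
        return (((rr - self.cr) / self.ar) ** 2
                + ((cc - self.cc) / self.ac) ** 2) <= 1.0

    def contains(self, r: float, c: float, margin: float = 0.0) -> bool:
        return (((r - self.cr) / (self.ar - margin)) ** 2
                + ((c - self.cc) / (self.ac - margin)) ** 2) <= 1.0


@dataclass(frozen=True)
class Lesion:
    """Circular intensity bump: (center_row, center_col, radius px, delta)."""
    r: float
    c: float
    radius: float
    delta: float


def default_lungs(size: int) -> tuple[Ellipse, Ellipse]:
    return (
        Ellipse(0.52 * size, 0.33 * size, 0.25 * size, 0.125 * size),
        Ellipse(0.52 * size, 0.67 * size, 0.25 * size, 0.125 * size),
    )


@dataclass(frozen=True)
class PhantomSpec:
    image_size: int = 512
    lungs: tuple[Ellipse, Ellipse] | None = None
    thorax: Ellipse | None = None
    background: float = 0.08
    thorax_intensity: float = 0.72
    lung_intensity: float = 0.30
    #: vertical brightening of the lung fields toward the diaphragm; makes
    #: the lower lung boundary ambiguous for thresholding, as in real
    #: radiographs
    lung_gradient: float = 0.0
    rib_count: int = 6
    rib_amplitude: float = 0.05
    #: small dark non-lung structures (bowel-gas-like); they exercise the
    #: mean-area component filter of the classical segmentation chain
    distractors: tuple = ()
    lesions: tuple[Lesion, ...] = ()          # present in pre AND post
    new_lesions: tuple[Lesion, ...] = ()      # appear only in post
    noise_sigma: float = 0.0
    edge_blur_sigma: float = 0.0              # soft tissue boundaries, px
    grid_spacing: int = 32                    # control-grid spacing, px
    max_deformation: float = 0.0              # px; must stay < grid_spacing
    global_shift: tuple[float, float] = (0.0, 0.0)
    gain: float = 1.0
    offset: float = 0.0
    box_allowance: int = 10
    label_mode: str = "any"                   # "any" | "new_only"
    seed: int = 0

    def resolved(self) -> "PhantomSpec":
        out = self
        if out.lungs is None:
            out = replace(out, lungs=default_lungs(out.image_size))
        if out.thorax is None:
            s = out.image_size
            out = replace(out, thorax=Ellipse(0.55 * s, 0.5 * s,
                                              0.44 * s, 0.41 * s))
        return out

    def validate(self) -> "PhantomSpec":
        spec = self.resolved()
        if spec.max_deformation >= spec.grid_spacing:
            raise ValueError("max deformation must be < control-grid spacing")
        for les in spec.lesions + spec.new_lesions:
            if les.radius <= 0:
                raise ValueError("lesion radius must be positive")
            if not any(l.contains(les.r, les.c, margin=les.radius)
                       for l in spec.lungs):
                raise ValueError(
                    f"lesion at ({les.r:.0f},{les.c:.0f}) r={les.radius} "
                    "lies outside the lung fields")
        if spec.label_mode not in ("any", "new_only"):
            raise ValueError(f"unknown label_mode {spec.label_mode!r}")
        return spec


@dataclass
class GroundTruth:
    lung_mask: np.ndarray
    lung_box: LungBox
    true_field: DisplacementField
    labels: np.ndarray
    lesion_mask: np.ndarray
    new_lesion_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _lesion_bump(shape, lesion: Lesion) -> np.ndarray:
    rr = np.arange(shape[0])[:, None]
    cc = np.arange(shape[1])[None, :]
    d = np.sqrt((rr - lesion.r) ** 2 + (cc - lesion.c) ** 2)
    # soft 1-px edge so the bump is band-limited enough to warp cleanly
    return lesion.delta * np.clip(lesion.radius - d + 0.5, 0.0, 1.0)


def _render_anatomy(spec: PhantomSpec, lesions) -> np.ndarray:
    s = spec.image_size
    img = np.full((s, s), spec.background, dtype=np.float64)
    thorax = spec.thorax.mask((s, s))
    img[thorax] = spec.thorax_intensity
    lung_mask = np.zeros((s, s), dtype=bool)
    for lung in spec.lungs:
        lung_mask |= lung.mask((s, s))
    img[lung_mask] = spec.lung_intensity
    if spec.lung_gradient > 0:
        rr = np.arange(s, dtype=np.float64)[:, None] / s
        ramp = np.broadcast_to(spec.lung_gradient * rr, (s, s))
        img[lung_mask] += ramp[lung_mask]
    for d in spec.distractors:
        img[d.mask((s, s))] = spec.lung_intensity + 0.02
    if spec.rib_count > 0 and spec.rib_amplitude > 0:
        rows = np.arange(s)[:, None]
        ribs = spec.rib_amplitude * 0.5 * (
            1.0 + np.sin(2.0 * np.pi * spec.rib_count * rows / s))
        img = img + ribs * thorax
    for les in lesions:
        img = img + _lesion_bump((s, s), les)
    if spec.edge_blur_sigma > 0:
        from scipy.ndimage import gaussian_filter

        img = gaussian_filter(img, spec.edge_blur_sigma)
    return img


def _lesion_mask_of(shape, lesions) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    rr = np.arange(shape[0])[:, None]
    cc = np.arange(shape[1])[None, :]
    for les in lesions:
        m |= ((rr - les.r) ** 2 + (cc - les.c) ** 2) <= les.radius ** 2
    return m


def _smooth_random_field(spec: PhantomSpec,
                         rng: np.random.Generator) -> np.ndarray:
    """Coarse control-grid Gaussian samples upsampled with cubic splines.

    Max magnitude bounded by spec.max_deformation (< grid spacing), which
    keeps the map free of folding at phantom scale.
    """
    s = spec.image_size
    fld = np.zeros((2, s, s), dtype=np.float64)
    if spec.max_deformation > 0:
        n_ctrl = max(2, s // spec.grid_spacing + 1)
        ctrl = rng.normal(0.0, 1.0, size=(2, n_ctrl, n_ctrl))
        up = np.stack([
            ndi_zoom(ctrl[k], s / n_ctrl, order=3, mode="nearest",
                     grid_mode=True)
            for k in range(2)
        ])
        peak = np.abs(up).max()
        if peak > 0:
            up *= spec.max_deformation / peak
        fld += up
    fld[0] += spec.global_shift[0]
    fld[1] += spec.global_shift[1]
    return fld


def _warp_pullback(img: np.ndarray, fld: np.ndarray) -> np.ndarray:
    """out[p] = img[p + fld[:, p]], bilinear, replicate border (float64)."""
    h, w = img.shape
    sr = np.clip(np.arange(h)[:, None] + fld[0], 0.0, h - 1.0)
    sc = np.clip(np.arange(w)[None, :] + fld[1], 0.0, w - 1.0)
    r0 = np.floor(sr).astype(np.int64)
    c0 = np.floor(sc).astype(np.int64)
    r1 = np.minimum(r0 + 1, h - 1)
    c1 = np.minimum(c0 + 1, w - 1)
    fr, fc = sr - r0, sc - c0
    return ((1 - fr) * (1 - fc) * img[r0, c0] + (1 - fr) * fc * img[r0, c1]
            + fr * (1 - fc) * img[r1, c0] + fr * fc * img[r1, c1])


def _truth_for(spec: PhantomSpec, fld: np.ndarray,
               post_lesions, new_lesions, clip_fraction: float) -> GroundTruth:
    s = spec.image_size
    lung_mask = np.zeros((s, s), dtype=bool)
    for lung in spec.lungs:
        lung_mask |= lung.mask((s, s))
    rows = np.any(lung_mask, axis=1).nonzero()[0]
    cols = np.any(lung_mask, axis=0).nonzero()[0]
    box = LungBox(
        top=int(rows[0]) - spec.box_allowance,
        bottom=int(rows[-1]) + 1 + spec.box_allowance,
        left=int(cols[0]) - spec.box_allowance,
        right=int(cols[-1]) + 1 + spec.box_allowance,
        allowance=spec.box_allowance,
    ).clipped((s, s))
    lesion_mask = _lesion_mask_of((s, s), post_lesions) & lung_mask
    new_mask = _lesion_mask_of((s, s), new_lesions) & lung_mask
    labeled = new_lesions if spec.label_mode == "new_only" else post_lesions
    labels = (label_vector([LESION_LABEL_INDEX]) if len(labeled)
              else label_vector())
    return GroundTruth(
        lung_mask=lung_mask,
        lung_box=box,
        true_field=DisplacementField(fld),
        labels=labels,
        lesion_mask=lesion_mask,
        new_lesion_mask=new_mask,
        meta={"clip_fraction": clip_fraction},
    )


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a single phantom radiograph plus its ground truth."""
    spec = spec.validate()
    rng = np.random.default_rng(spec.seed)
    img = _render_anatomy(spec, spec.lesions)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    clipped = float(np.mean((img < 0) | (img > 1)))
    img = np.clip(img, 0.0, 1.0)
    truth = _truth_for(spec, np.zeros((2, spec.image_size, spec.image_size)),
                       spec.lesions, (), clipped)
    return img, truth


def generate_pair(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Render a (pre, post) pair related by a known displacement field.

    ``post = gain * warp(pre_anatomy, field) + offset + new lesions + noise``
    with the pull-back convention, so ``warp(pre, truth.true_field)``
    reconstructs the lesion-free post anatomy up to noise and gain/offset.
    """
    spec = spec.validate()
    rng = np.random.default_rng(spec.seed)
    pre_clean = _render_anatomy(spec, spec.lesions)
    fld = _smooth_random_field(spec, rng)
    post_clean = _warp_pullback(pre_clean, fld)
    for les in spec.new_lesions:
        bump = _lesion_bump(post_clean.shape, les)
        if spec.edge_blur_sigma > 0:
            from scipy.ndimage import gaussian_filter

            # same band-limiting as the pre-rendered anatomy, so new
            # lesions are not distinguishable by sharpness alone
            bump = gaussian_filter(bump, spec.edge_blur_sigma)
        post_clean = post_clean + bump
    post_clean = spec.gain * post_clean + spec.offset
    pre = pre_clean.copy()
    post = post_clean.copy()
    if spec.noise_sigma > 0:
        pre = pre + rng.normal(0.0, spec.noise_sigma, size=pre.shape)
        post = post + rng.normal(0.0, spec.noise_sigma, size=post.shape)
    clipped = float(np.mean((pre < 0) | (pre > 1) | (post < 0) | (post > 1)))
    pre = np.clip(pre, 0.0, 1.0)
    post = np.clip(post, 0.0, 1.0)
    post_lesions = spec.lesions + spec.new_lesions
    truth = _truth_for(spec, fld, post_lesions, spec.new_lesions, clipped)
    return pre, post, truth


# ---------------------------------------------------------------------------
# disk layout
# ---------------------------------------------------------------------------


def write_field(field: DisplacementField, path: Path) -> None:
    """Raw little-endian float32 container plus a JSON sidecar."""
    path = Path(path)
    v = field.vectors.astype("<f4")
    path.write_bytes(v.tobytes())
    sidecar = {
        "shape": list(v.shape),
        "dtype": "<f4",
        "ordering": "row-displacement then column-displacement",
        "convention": "pull-back: out[p] = img[p + field[:, p]]",
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2))


def read_field(path: Path) -> DisplacementField:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    v = np.frombuffer(path.read_bytes(), dtype=sidecar["dtype"])
    return DisplacementField(v.reshape(sidecar["shape"]).astype(np.float64))


def write_dataset(specs: list[PhantomSpec], out_dir: Path) -> None:
    """Write pairs as 8-bit PNGs with truth CSVs and field containers."""
    import imageio.v3 as iio

    from .types import DISEASE_NAMES

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    box_rows = ["image_id,top,bottom,left,right"]
    label_rows = ["image_id," + ",".join(DISEASE_NAMES)]
    for i, spec in enumerate(specs):
        pre, post, truth = generate_pair(spec)
        pid = f"pair{i:04d}"
        iio.imwrite(out_dir / f"{pid}_pre.png",
                    np.round(pre * 255).astype(np.uint8))
        iio.imwrite(out_dir / f"{pid}_post.png",
                    np.round(post * 255).astype(np.uint8))
        iio.imwrite(out_dir / f"{pid}_lungmask.png",
                    truth.lung_mask.astype(np.uint8) * 255)
        write_field(truth.true_field, out_dir / f"{pid}_field.bin")
        b = truth.lung_box
        box_rows.append(f"{pid},{b.top},{b.bottom},{b.left},{b.right}")
        label_rows.append(pid + "," + ",".join(str(int(x))
                                               for x in truth.labels))
    (out_dir / "boxes.csv").write_text("\n".join(box_rows) + "\n")
    (out_dir / "labels.csv").write_text("\n".join(label_rows) + "\n")


def random_pair_spec(rng: np.random.Generator, image_size: int = 128,
                     noise_sigma: float = 0.01, max_deformation: float = 3.0,
                     lesion_prob: float = 0.5,
                     new_lesion_prob: float = 0.5,
                     edge_blur_sigma: float | None = None,
                     lesion_radius: tuple[float, float] = (0.03, 0.05),
                     lesion_delta: tuple[float, float] = (0.25, 0.4),
                     label_mode: str = "any") -> PhantomSpec:
    """Draw a randomized but valid pair spec (jittered anatomy + lesions)."""
    s = image_size
    jit = lambda lo, hi: float(rng.uniform(lo, hi))
    # left/right lungs share a base size with a small asymmetry, as in
    # real thoraxes; wildly unequal lungs would defeat the mean-area
    # component filter of the classical chain.
    ar = jit(0.22, 0.26) * s
    ac = jit(0.11, 0.13) * s
    lungs = (
        Ellipse(jit(0.50, 0.53) * s, jit(0.31, 0.34) * s,
                ar * jit(0.96, 1.04), ac * jit(0.96, 1.04)),
        Ellipse(jit(0.50, 0.53) * s, jit(0.66, 0.69) * s,
                ar * jit(0.96, 1.04), ac * jit(0.96, 1.04)),
    )

    def draw_lesions(p):
        out = []
        if rng.uniform() < p:
            lung = lungs[int(rng.integers(2))]
            radius = jit(*lesion_radius) * s
            # place well inside the ellipse
            ang = jit(0, 2 * np.pi)
            rad = jit(0, 0.5)
            out.append(Lesion(
                r=lung.cr + rad * (lung.ar - radius - 1) * np.sin(ang),
                c=lung.cc + rad * (lung.ac - radius - 1) * np.cos(ang),
                radius=radius,
                delta=jit(*lesion_delta),
            ))
        return tuple(out)

    distractors = tuple(
        Ellipse(jit(0.87, 0.91) * s, jit(0.46, 0.54) * s,
                jit(0.03, 0.045) * s, jit(0.03, 0.045) * s)
        for _ in range(int(rng.integers(1, 3))))
    return _assemble_spec(s, rng, lungs, distractors,
                          draw_lesions(lesion_prob),
                          draw_lesions(new_lesion_prob),
                          noise_sigma, max_deformation, edge_blur_sigma,
                          label_mode, jit)


def random_change_task_spec(rng: np.random.Generator, image_size: int = 64,
                            noise_sigma: float = 0.01,
                            max_deformation: float = 2.0,
                            lesion_radius: tuple[float, float] = (0.06, 0.09),
                            lesion_delta: tuple[float, float] = (0.3, 0.45),
                            ) -> PhantomSpec:
    """Pair spec for a change-detection task where the post-image alone is
    uninformative.

    Every post-image contains exactly two lesions; with probability 1/2
    both were already present in the pre-image (label 0), otherwise one of
    them is new (label 1, ``label_mode='new_only'``).  Only the difference
    channel reveals which case holds.
    """
    s = image_size
    jit = lambda lo, hi: float(rng.uniform(lo, hi))
    ar = jit(0.22, 0.26) * s
    ac = jit(0.11, 0.13) * s
    lungs = (
        Ellipse(jit(0.50, 0.53) * s, jit(0.31, 0.34) * s,
                ar * jit(0.96, 1.04), ac * jit(0.96, 1.04)),
        Ellipse(jit(0.50, 0.53) * s, jit(0.66, 0.69) * s,
                ar * jit(0.96, 1.04), ac * jit(0.96, 1.04)),
    )

    def one_lesion(lung):
        radius = jit(*lesion_radius) * s
        ang = jit(0, 2 * np.pi)
        rad = jit(0, 0.5)
        return Lesion(
            r=lung.cr + rad * (lung.ar - radius - 1) * np.sin(ang),
            c=lung.cc + rad * (lung.ac - radius - 1) * np.cos(ang),
            radius=radius,
            delta=jit(*lesion_delta),
        )

    les_a = one_lesion(lungs[0])
    les_b = one_lesion(lungs[1])
    if rng.uniform() < 0.5:
        persistent, new = (les_a, les_b), ()
    else:
        persistent, new = (les_a,), (les_b,)
    return _assemble_spec(s, rng, lungs, (), persistent, new,
                          noise_sigma, max_deformation, None,
                          "new_only", jit)


def _assemble_spec(s, rng, lungs, distractors, lesions, new_lesions,
                   noise_sigma, max_deformation, edge_blur_sigma,
                   label_mode, jit) -> PhantomSpec:
    return PhantomSpec(
        image_size=s,
        lungs=lungs,
        distractors=distractors,
        lesions=lesions,
        new_lesions=new_lesions,
        noise_sigma=noise_sigma,
        lung_gradient=jit(0.2, 0.35),
        edge_blur_sigma=(1.5 * s / 128 if edge_blur_sigma is None
                         else edge_blur_sigma),
        max_deformation=max_deformation,
        grid_spacing=max(8, s // 4),
        gain=jit(0.95, 1.05),
        offset=jit(-0.02, 0.02),
        box_allowance=max(2, round(10 * s / 512)),
        label_mode=label_mode,
        seed=int(rng.integers(2 ** 31)),
    )
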