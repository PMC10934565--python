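"""Traditional lung segmentation.

Chain: CLAHE enhancement -> Otsu binarization -> connected-component
labeling with background (border-touching) removal -> morphological
open/close -> removal of components smaller than the mean area -> ROI box
with allowance.  The pipeline returns one box containing both lung fields.

Polarity: lung fields share the intensity class of the image border
(radiolucent lungs, dark background), so the Otsu class whose mean is
closer to the border mean is taken as the lung-bearing class, and the
border-touching components within it are discarded as background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .preprocess import clahe, otsu_binarize, resize_to, to_uint8
from .types import LungBox


@dataclass(frozen=True)
class ClassicalSegConfig:
    clahe_clip: float = 2.0
    clahe_grid: tuple[int, int] = (8, 8)
    connectivity: int = 8
    morph_radius: int = 3
    allowance: int = 10
    work_size: int = 512      # processing resolution; box is remapped back
    invert_auto: bool = True  # pick polarity from the border mean


@dataclass
class ComponentSet:
    labels: np.ndarray            # int label image, 0 = background
    areas: np.ndarray             # per-component pixel counts, index 0 unused

    @property
    def n_components(self) -> int:
        return len(self.areas) - 1


_STRUCTS = {4: ndi.generate_binary_structure(2, 1),
            8: ndi.generate_binary_structure(2, 2)}


def label_components(mask: np.ndarray, connectivity: int = 8) -> ComponentSet:
    """Connected components under 4- or 8-connectivity.

    scipy labels in raster order of first pixel, which makes the labeling
    deterministic.
    """
    if connectivity not in _STRUCTS:
        raise ValueError("connectivity must be 4 or 8")
    binary = np.asarray(mask) > 0
    labels, n = ndi.label(binary, structure=_STRUCTS[connectivity])
    areas = np.bincount(labels.ravel(), minlength=n + 1)
    areas[0] = 0
    return ComponentSet(labels=labels, areas=areas)


def remove_background_components(cs: ComponentSet) -> np.ndarray:
    """Delete components touching the image border (the background)."""
    border_labels = np.unique(np.concatenate([
        cs.labels[0, :], cs.labels[-1, :], cs.labels[:, 0], cs.labels[:, -1]]))
    keep = np.ones(len(cs.areas), dtype=bool)
    keep[border_labels] = False
    keep[0] = False
    return keep[cs.labels]


def disk_footprint(radius: int) -> np.ndarray:
    """Disk structuring element: pixels within radius + 0.5 of the
    center (a full 3x3 block at radius 1)."""
    span = np.arange(-radius, radius + 1)
    return np.hypot(span[:, None], span[None, :]) <= radius + 0.5


def morph_open_close(mask: np.ndarray, radius: int = 3) -> np.ndarray:
    """Opening then closing with a disk structuring element."""
    binary = np.asarray(mask) > 0
    if radius <= 0:
        return binary
    se = disk_footprint(radius)
    opened = ndi.binary_opening(binary, structure=se)
    return ndi.binary_closing(opened, structure=se)


def filter_small_components(cs: ComponentSet) -> np.ndarray:
    """Keep exactly the components with area >= mean component area."""
    if cs.n_components == 0:
        raise ValueError("no components to filter")
    mean_area = cs.areas[1:].mean()
    keep = np.zeros(len(cs.areas), dtype=bool)
    keep[1:] = cs.areas[1:] >= mean_area
    return keep[cs.labels]


def lung_box_from_mask(mask: np.ndarray, allowance: int = 0) -> LungBox:
    """Tight bounding box of the foreground plus allowance, clipped."""
    binary = np.asarray(mask) > 0
    rows = np.any(binary, axis=1).nonzero()[0]
    cols = np.any(binary, axis=0).nonzero()[0]
    if rows.size == 0:
        raise ValueError("empty mask has no bounding box")
    return LungBox(
        top=int(rows[0]) - allowance,
        bottom=int(rows[-1]) + 1 + allowance,
        left=int(cols[0]) - allowance,
        right=int(cols[-1]) + 1 + allowance,
        allowance=allowance,
    ).clipped(binary.shape)


def _lung_class_mask(enhanced: np.ndarray, config: ClassicalSegConfig) -> np.ndarray:
    """Binarize and pick the class sharing the border's intensity regime."""
    _, mask255 = otsu_binarize(enhanced)
    above = mask255 > 0
    if not config.invert_auto:
        return above
    u8 = enhanced.astype(np.float64)
    border = np.concatenate([u8[0, :], u8[-1, :], u8[:, 0], u8[:, -1]])
    border_mean = border.mean()
    mean_above = u8[above].mean() if above.any() else np.inf
    mean_below = u8[~above].mean() if (~above).any() else np.inf
    # lungs live in the class closer to the border (background) mean
    if abs(mean_below - border_mean) <= abs(mean_above - border_mean):
        return ~above
    return above


def segment_classical(img: np.ndarray, config: ClassicalSegConfig | None = None
                      ) -> tuple[LungBox, np.ndarray]:
    """Full traditional chain; returns (box, mask) at the input resolution.

    Processing happens at ``config.work_size``; the box is remapped back
    to the original resolution, the returned mask stays at working
    resolution mapped back via nearest resize.
    """
    config = config or ClassicalSegConfig()
    orig_shape = np.asarray(img).shape
    work = to_uint8(img)
    scale_r = orig_shape[0] / config.work_size
    scale_c = orig_shape[1] / config.work_size
    if orig_shape != (config.work_size, config.work_size):
        work = resize_to(work, (config.work_size, config.work_size))

    enhanced = clahe(work, config.clahe_clip, config.clahe_grid)
    candidate = _lung_class_mask(enhanced, config)

    cs = label_components(candidate, config.connectivity)
    no_bg = remove_background_components(cs)
    if not no_bg.any():
        raise ValueError("segmentation failed: only border-touching "
                         "components found after binarization")
    smoothed = morph_open_close(no_bg, config.morph_radius)
    if not smoothed.any():
        raise ValueError("segmentation failed: mask vanished during "
                         "morphological smoothing")
    cs2 = label_components(smoothed, config.connectivity)
    final_mask = filter_small_components(cs2)
    box = lung_box_from_mask(final_mask, config.allowance)
    box = box.scaled(scale_r, scale_c).clipped(orig_shape)
    from .preprocess import resize_mask

    mask_full = resize_mask(final_mask.astype(np.uint8), orig_shape) > 0
    return box, mask_full
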