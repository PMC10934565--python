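"""Shared intensity operations.

All operations are deterministic and depth-preserving.  Two depths are
supported throughout the package: 8-bit arrays (uint8, [0, 255]) and unit
arrays (float, [0, 1]).  Conversion between them is exact multiplication /
division by 255 with round-half-even on the way down.

Dialects (the source material names the techniques but not their
parameters):

* CLAHE — clip limit expressed as a multiple of the uniform bin height
  (the OpenCV convention), default 2.0, tile grid 8x8, 256 bins, clipped
  mass redistributed uniformly, tile mappings blended bilinearly.
* Histogram matching — 256-bin quantile mapping (a monotone lookup
  table); matching an image to itself is the identity on occurring grey
  levels.
* Resizing — bilinear for intensities, nearest for masks.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import resize as _sk_resize


# ---------------------------------------------------------------------------
# depth conversion
# ---------------------------------------------------------------------------


def to_unit(img: np.ndarray) -> np.ndarray:
    """8-bit -> unit range; unit input passes through unchanged."""
    img = np.asarray(img)
    if img.dtype == np.uint8:
        return img.astype(np.float64) / 255.0
    if img.dtype == np.uint16:
        return img.astype(np.float64) / 65535.0
    return img.astype(np.float64)


def to_uint8(img: np.ndarray) -> np.ndarray:
    """Unit range -> 8-bit; uint8 passes through; uint16 is rescaled by
    max-range division (65535 -> 255)."""
    img = np.asarray(img)
    if img.dtype == np.uint8:
        return img
    if img.dtype == np.uint16:
        return np.round(img.astype(np.float64) / 65535.0 * 255.0).astype(np.uint8)
    return np.round(np.clip(img, 0.0, 1.0) * 255.0).astype(np.uint8)


def _is_unit(img: np.ndarray) -> bool:
    return np.issubdtype(np.asarray(img).dtype, np.floating)


# ---------------------------------------------------------------------------
# CLAHE
# ---------------------------------------------------------------------------


def clahe(img: np.ndarray, clip_limit: float = 2.0,
          tile_grid: tuple[int, int] = (8, 8)) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    Per-tile 256-bin histograms are clipped at ``clip_limit`` times the
    uniform bin height, the clipped mass is redistributed uniformly, and
    per-tile equalization mappings are blended bilinearly between tile
    centers.  Depth preserved.
    """
    if clip_limit <= 0:
        raise ValueError("clip_limit must be positive")
    unit = _is_unit(img)
    u8 = to_uint8(img)
    h, w = u8.shape
    tr, tc = tile_grid
    if tr > h or tc > w:
        raise ValueError(f"tile grid {tile_grid} larger than image {u8.shape}")

    row_edges = np.linspace(0, h, tr + 1).astype(int)
    col_edges = np.linspace(0, w, tc + 1).astype(int)
    mappings = np.empty((tr, tc, 256), dtype=np.float64)
    centers_r = np.empty(tr)
    centers_c = np.empty(tc)
    for i in range(tr):
        centers_r[i] = (row_edges[i] + row_edges[i + 1] - 1) / 2.0
        for j in range(tc):
            centers_c[j] = (col_edges[j] + col_edges[j + 1] - 1) / 2.0
            tile = u8[row_edges[i]:row_edges[i + 1],
                      col_edges[j]:col_edges[j + 1]]
            hist = np.bincount(tile.ravel(), minlength=256).astype(np.float64)
            n = tile.size
            clip = max(1.0, clip_limit * n / 256.0)
            excess = np.maximum(hist - clip, 0.0).sum()
            hist = np.minimum(hist, clip) + excess / 256.0
            cdf = np.cumsum(hist)
            mappings[i, j] = cdf / cdf[-1] * 255.0

    # bilinear blending between the 4 surrounding tile mappings
    rows = np.arange(h, dtype=np.float64)
    cols = np.arange(w, dtype=np.float64)
    ri = np.clip(np.searchsorted(centers_r, rows) - 1, 0, tr - 2) if tr > 1 else np.zeros(h, int)
    ci = np.clip(np.searchsorted(centers_c, cols) - 1, 0, tc - 2) if tc > 1 else np.zeros(w, int)
    if tr > 1:
        fr = np.clip((rows - centers_r[ri]) / (centers_r[ri + 1] - centers_r[ri]), 0, 1)
    else:
        fr = np.zeros(h)
    if tc > 1:
        fc = np.clip((cols - centers_c[ci]) / (centers_c[ci + 1] - centers_c[ci]), 0, 1)
    else:
        fc = np.zeros(w)

    v = u8.astype(np.int64)
    RI = ri[:, None]
    CI = ci[None, :]
    FR = fr[:, None]
    FC = fc[None, :]
    ri1 = np.minimum(RI + 1, tr - 1)
    ci1 = np.minimum(CI + 1, tc - 1)
    out = ((1 - FR) * (1 - FC) * mappings[RI, CI, v]
           + (1 - FR) * FC * mappings[RI, ci1, v]
           + FR * (1 - FC) * mappings[ri1, CI, v]
           + FR * FC * mappings[ri1, ci1, v])
    out8 = np.clip(np.round(out), 0, 255).astype(np.uint8)
    return out8.astype(np.float64) / 255.0 if unit else out8


# ---------------------------------------------------------------------------
# Otsu
# ---------------------------------------------------------------------------


def otsu_binarize(img: np.ndarray) -> tuple[int, np.ndarray]:
    """Otsu threshold plus the binarized mask.

    The threshold maximizes between-class variance over all 256 candidate
    levels (smallest maximizer on ties).  Pixels strictly above the
    threshold become 255, the rest 0.  Returns the threshold on the 8-bit
    scale; the mask dtype is uint8 with values in {0, 255}.
    """
    u8 = to_uint8(img)
    hist = np.bincount(u8.ravel(), minlength=256).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        raise ValueError("Otsu threshold undefined for a constant image")
    n = hist.sum()
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)                     # class {0..t}
    mu0 = np.cumsum(hist * levels)
    mu_t = mu0[-1]
    w1 = n - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        m0 = mu0 / w0
        m1 = (mu_t - mu0) / w1
        sigma_b = w0 * w1 * (m0 - m1) ** 2
    sigma_b[~np.isfinite(sigma_b)] = -1.0
    t = int(np.argmax(sigma_b[:-1]))         # t=255 leaves class 1 empty
    mask = np.where(u8 > t, 255, 0).astype(np.uint8)
    return t, mask


# ---------------------------------------------------------------------------
# histogram matching
# ---------------------------------------------------------------------------


def histogram_match(working: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Monotone quantile mapping of ``working`` onto ``reference``.

    8-bit inputs use a 256-bin lookup table (for each grey level g the
    mapped value is the smallest reference level whose CDF reaches the
    working CDF at g).  Unit-range float inputs use the exact empirical
    quantile transform, so matching an image to itself is the identity to
    full float precision.  Depth preserved.
    """
    if _is_unit(working):
        w = np.asarray(working, dtype=np.float64)
        r = np.asarray(reference, dtype=np.float64)
        w_vals, w_idx, w_counts = np.unique(w.ravel(), return_inverse=True,
                                            return_counts=True)
        r_vals, r_counts = np.unique(r.ravel(), return_counts=True)
        w_quant = np.cumsum(w_counts) / w.size
        r_quant = np.cumsum(r_counts) / r.size
        mapped = np.interp(w_quant, r_quant, r_vals)
        return mapped[w_idx].reshape(w.shape)
    w8 = to_uint8(working)
    r8 = to_uint8(reference)
    cdf_w = np.cumsum(np.bincount(w8.ravel(), minlength=256)) / w8.size
    cdf_r = np.cumsum(np.bincount(r8.ravel(), minlength=256)) / r8.size
    lut = np.searchsorted(cdf_r, cdf_w, side="left").clip(0, 255).astype(np.uint8)
    return lut[w8]


# ---------------------------------------------------------------------------
# resizing
# ---------------------------------------------------------------------------


def resize_to(img: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Bilinear resample to (rows, cols); depth preserved, exact identity
    when the size is unchanged."""
    if size[0] <= 0 or size[1] <= 0:
        raise ValueError("target size must be positive")
    img = np.asarray(img)
    if tuple(img.shape) == tuple(size):
        return img.copy()
    out = _sk_resize(img.astype(np.float64), size, order=1,
                     anti_aliasing=False, preserve_range=True)
    if img.dtype == np.uint8:
        return np.round(out).clip(0, 255).astype(np.uint8)
    return out


def resize_mask(mask: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour resample so binary masks stay binary."""
    mask = np.asarray(mask)
    if tuple(mask.shape) == tuple(size):
        return mask.copy()
    out = _sk_resize(mask.astype(np.float64), size, order=0,
                     anti_aliasing=False, preserve_range=True)
    return out.astype(mask.dtype)


# ---------------------------------------------------------------------------
# PNG I/O
# ---------------------------------------------------------------------------


def load_image(path) -> np.ndarray:
    """Read an 8- or 16-bit grayscale PNG as uint8 (16-bit inputs are
    rescaled by max-range division)."""
    import imageio.v3 as iio

    img = np.asarray(iio.imread(path))
    if img.ndim == 3:
        img = img[..., 0]
    return to_uint8(img)


def save_image(path, img: np.ndarray) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, to_uint8(img))


def save_image16(path, unit_img: np.ndarray) -> None:
    """Write a unit-range array as 16-bit PNG (value * 65535)."""
    import imageio.v3 as iio

    iio.imwrite(path, np.round(np.clip(unit_img, 0, 1) * 65535).astype(np.uint16))
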