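"""Difference-image computation, nonlinear enhancement, highlighting and
heat-map rendering.

Conventions: both inputs are unit-range arrays, with the pre-image already
registered to the post-image.  The difference map is

    D = post * |post - pre|

and the enhanced map is D* = 2 / (1 + exp(-k D)) - 1 with k = 6
("nonlinear-1") or k = 12 ("nonlinear-2"); the "linear" display mode is
D* = D.  The highlighted image clips post + D* to [0, 1] and records the
clipped fraction, since it feeds the classifier and must stay a valid
image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MODE_COEFFS = {"linear": None, "nonlinear-1": 6.0, "nonlinear-2": 12.0}

#: accepted aliases for CLI convenience
MODE_ALIASES = {"linear": "linear", "nl1": "nonlinear-1", "nl2": "nonlinear-2",
                "nonlinear-1": "nonlinear-1", "nonlinear-2": "nonlinear-2"}


def _check_unit_pair(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    for name, x in (("img1", a), ("img2", b)):
        if x.min() < 0.0 or x.max() > 1.0:
            raise ValueError(f"{name} has values outside [0, 1]")


def difference_image(img1_aligned: np.ndarray, img2: np.ndarray) -> np.ndarray:
    """D = Img2 * |Img2 - Img1|, elementwise on unit-range inputs."""
    img1 = np.asarray(img1_aligned, dtype=np.float64)
    img2 = np.asarray(img2, dtype=np.float64)
    _check_unit_pair(img1, img2)
    return img2 * np.abs(img2 - img1)


def nonlinear_transform(d: np.ndarray, mode: str = "linear") -> np.ndarray:
    """Sigmoid-like squashing of the difference map (identity for linear)."""
    mode = MODE_ALIASES.get(mode, mode)
    if mode not in MODE_COEFFS:
        raise ValueError(f"unknown mode {mode!r}")
    d = np.asarray(d, dtype=np.float64)
    k = MODE_COEFFS[mode]
    if k is None:
        return d.copy()
    return 2.0 / (1.0 + np.exp(-k * d)) - 1.0


@dataclass
class DifferenceMap:
    D: np.ndarray
    D_star: np.ndarray
    mode: str


def compute_difference_map(img1_aligned: np.ndarray, img2: np.ndarray,
                           mode: str = "linear") -> DifferenceMap:
    mode = MODE_ALIASES.get(mode, mode)
    d = difference_image(img1_aligned, img2)
    return DifferenceMap(D=d, D_star=nonlinear_transform(d, mode), mode=mode)


@dataclass
class HighlightedImage:
    imgnew: np.ndarray
    clipped_fraction: float


def highlight(img2: np.ndarray, d_star: np.ndarray) -> HighlightedImage:
    """Imgnew = clip(Img2 + D*, 0, 1); clipping fraction recorded."""
    img2 = np.asarray(img2, dtype=np.float64)
    d_star = np.asarray(d_star, dtype=np.float64)
    if img2.shape != d_star.shape:
        raise ValueError("shape mismatch")
    raw = img2 + d_star
    clipped = float(np.mean((raw < 0.0) | (raw > 1.0)))
    return HighlightedImage(imgnew=np.clip(raw, 0.0, 1.0),
                            clipped_fraction=clipped)


def render_heatmap(d_star: np.ndarray, img2: np.ndarray,
                   colormap_name: str = "jet", blend: float = 0.5) -> np.ndarray:
    """Blue-to-red colormap of D* alpha-blended over the post-image.

    Returns a float RGB array in [0, 1].  Low difference maps to the blue
    end, high to the red end; blend=0 returns the grayscale image as RGB.
    """
    import matplotlib

    if not 0.0 <= blend <= 1.0:
        raise ValueError("blend must be in [0, 1]")
    d_star = np.asarray(d_star, dtype=np.float64)
    img2 = np.asarray(img2, dtype=np.float64)
    cmap = matplotlib.colormaps[colormap_name]
    colored = np.asarray(cmap(np.clip(d_star, 0.0, 1.0)))[..., :3]
    base = np.repeat(img2[..., None], 3, axis=-1)
    return (1.0 - blend) * base + blend * colored


def render_level_bar(height: int = 256, width: int = 24,
                     colormap_name: str = "jet") -> np.ndarray:
    """Vertical color level bar (high at the top) matching the heatmap."""
    import matplotlib

    cmap = matplotlib.colormaps[colormap_name]
    ramp = np.linspace(1.0, 0.0, height)
    return np.asarray(cmap(ramp))[:, None, :3].repeat(width, axis=1)
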