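"""Evaluation metrics (IoU, detection rate, PSNR, SSIM, NCC, AUC
aggregation) and the k-fold cross-validation harness."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

from .types import LungBox

PSNR_INF_SENTINEL = float("inf")


def iou(box_a: LungBox, box_b: LungBox) -> float:
    """Intersection over union under the half-open pixel-area convention."""
    if box_a.area <= 0 or box_b.area <= 0:
        raise ValueError("degenerate zero-area box")
    it = max(box_a.top, box_b.top)
    ib = min(box_a.bottom, box_b.bottom)
    il = max(box_a.left, box_b.left)
    ir = min(box_a.right, box_b.right)
    inter = max(0, ib - it) * max(0, ir - il)
    union = box_a.area + box_b.area - inter
    return inter / union


def detection_rate(ious, threshold: float = 0.7) -> float:
    """Percentage of IoU values at or above the threshold."""
    ious = np.asarray(list(ious), dtype=np.float64)
    if ious.size == 0:
        raise ValueError("empty IoU list")
    return 100.0 * float(np.mean(ious >= threshold))


def detection_rate_sweep(ious, thresholds) -> list[tuple[float, float]]:
    """(threshold, rate%) pairs for a detection-rate-vs-threshold curve."""
    return [(float(t), detection_rate(ious, t)) for t in thresholds]


def psnr(a: np.ndarray, b: np.ndarray, peak: float | None = None) -> float:
    """10*log10(peak^2 / MSE); identical images return an inf sentinel.

    ``peak`` defaults to the declared depth (255 for uint8, 1.0 for unit
    floats); mixing depths without an explicit peak is an error.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    if peak is None:
        if a.dtype != b.dtype:
            raise ValueError("depth mismatch: pass peak explicitly")
        peak = 255.0 if a.dtype == np.uint8 else 1.0
    mse = float(np.mean((a.astype(np.float64) - b.astype(np.float64)) ** 2))
    if mse == 0.0:
        return PSNR_INF_SENTINEL
    return 10.0 * np.log10(peak ** 2 / mse)


def ssim(a: np.ndarray, b: np.ndarray, peak: float | None = None) -> float:
    """Mean local SSIM, Gaussian window sigma=1.5 (11x11), K1=0.01,
    K2=0.03."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    if peak is None:
        if a.dtype != b.dtype:
            raise ValueError("depth mismatch: pass peak explicitly")
        peak = 255.0 if a.dtype == np.uint8 else 1.0
    return float(structural_similarity(
        a.astype(np.float64), b.astype(np.float64), data_range=peak,
        gaussian_weights=True, sigma=1.5, use_sample_covariance=False,
        K1=0.01, K2=0.03))


def ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Global Pearson correlation of pixel intensities."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("NCC undefined for a constant image")
    return float(np.corrcoef(a, b)[0, 1])


def evaluate_auc(scores: np.ndarray, labels: np.ndarray
                 ) -> tuple[np.ndarray, float]:
    """Per-class ROC AUC plus the macro mean over defined classes.

    Classes whose labels are single-valued get NaN and are excluded from
    the mean (with a warning), mirroring how multi-label AUC is usually
    aggregated.
    """
    from sklearn.metrics import roc_auc_score

    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    n_classes = scores.shape[1]
    per_class = np.full(n_classes, np.nan)
    for c in range(n_classes):
        col = labels[:, c]
        if col.min() == col.max():
            warnings.warn(f"class {c} has a single label value; AUC "
                          "undefined and excluded from the macro mean")
            continue
        per_class[c] = roc_auc_score(col, scores[:, c])
    defined = per_class[~np.isnan(per_class)]
    macro = float(defined.mean()) if defined.size else float("nan")
    return per_class, macro


@dataclass(frozen=True)
class FoldPlan:
    n_items: int
    k: int
    seed: int
    assignment: np.ndarray   # item index -> fold id

    def folds(self):
        """Yield (train_idx, test_idx) per fold."""
        for f in range(self.k):
            test = np.nonzero(self.assignment == f)[0]
            train = np.nonzero(self.assignment != f)[0]
            yield train, test


def kfold(n_items: int, k: int = 5, seed: int = 0) -> FoldPlan:
    """Shuffled partition into k folds whose sizes differ by at most 1."""
    if n_items < k:
        raise ValueError(f"cannot split {n_items} items into {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_items)
    assignment = np.empty(n_items, dtype=np.int64)
    sizes = np.full(k, n_items // k)
    sizes[: n_items % k] += 1
    start = 0
    for f, size in enumerate(sizes):
        assignment[order[start:start + size]] = f
        start += size
    return FoldPlan(n_items=n_items, k=k, seed=seed, assignment=assignment)
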