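"""Shared value types used across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The 12 disease columns of a label vector, in fixed order.  An all-zero
#: row encodes "no findings".
DISEASE_NAMES = (
    "Atelectasis",
    "Cardiomegaly",
    "Effusion",
    "Infiltration",
    "Mass",
    "Nodule",
    "Pneumonia",
    "Pneumothorax",
    "Consolidation",
    "Emphysema",
    "Fibrosis",
    "Pleural Thickening",
)

N_CLASSES = len(DISEASE_NAMES)

#: Index that phantom lesions map to (the phantom makes no clinical claim,
#: it only needs a fixed, separable label slot).
LESION_LABEL_INDEX = DISEASE_NAMES.index("Nodule")


@dataclass(frozen=True)
class LungBox:
    """Axis-aligned lung ROI with half-open pixel ranges.

    Rows covered are ``[top, bottom)`` and columns ``[left, right)``,
    0-based.  ``allowance`` records the margin that was added when the box
    was derived from a mask (informational; already included in the
    coordinates).
    """

    top: int
    bottom: int
    left: int
    right: int
    allowance: int = 0

    def __post_init__(self) -> None:
        if not (self.top < self.bottom and self.left < self.right):
            raise ValueError(
                f"degenerate box: rows [{self.top},{self.bottom}), "
                f"cols [{self.left},{self.right})"
            )

    @property
    def height(self) -> int:
        return self.bottom - self.top

    @property
    def width(self) -> int:
        return self.right - self.left

    @property
    def area(self) -> int:
        return self.height * self.width

    def clipped(self, shape: tuple[int, int]) -> "LungBox":
        """Clip the box to an image of the given (rows, cols) shape."""
        return LungBox(
            top=max(0, self.top),
            bottom=min(shape[0], self.bottom),
            left=max(0, self.left),
            right=min(shape[1], self.right),
            allowance=self.allowance,
        )

    def scaled(self, factor_r: float, factor_c: float) -> "LungBox":
        """Rescale box coordinates, e.g. to map a 512-scale box back to
        the original resolution.  Exact round-trip for integer factors."""
        return LungBox(
            top=int(round(self.top * factor_r)),
            bottom=int(round(self.bottom * factor_r)),
            left=int(round(self.left * factor_c)),
            right=int(round(self.right * factor_c)),
            allowance=self.allowance,
        )

    def crop(self, img: np.ndarray) -> np.ndarray:
        return img[self.top : self.bottom, self.left : self.right]

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.top, self.bottom, self.left, self.right)


@dataclass
class DisplacementField:
    """Dense per-pixel pull-back displacement.

    ``vectors`` has shape ``(2, H, W)``: channel 0 is the row displacement,
    channel 1 the column displacement, both in pixels.  The warp convention
    is pull-back: ``out[p] = img[p + vectors[:, p]]``, so a zero field is
    the identity.
    """

    vectors: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=np.float64)
        if v.ndim != 3 or v.shape[0] != 2:
            raise ValueError(f"field must have shape (2, H, W), got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("displacement field contains non-finite values")
        self.vectors = v

    @property
    def shape(self) -> tuple[int, int]:
        return self.vectors.shape[1:]

    @classmethod
    def zero(cls, shape: tuple[int, int]) -> "DisplacementField":
        return cls(np.zeros((2,) + tuple(shape)))


def label_vector(indices=()) -> np.ndarray:
    """Build a 12-way multi-hot label vector with the given indices set."""
    v = np.zeros(N_CLASSES, dtype=np.int64)
    for i in indices:
        v[int(i)] = 1
    return v
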