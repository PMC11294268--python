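"""Axis-aligned bounding boxes derived from segmentation masks.

A segmentation's bounding box takes the extremal row/column coordinates of
its foreground pixels (inclusive integer bounds in pixel coordinates). Boxes
are evaluated with the same three overlap/contour metrics as segmentations by
rasterising them back to filled rectangular masks, so box area counts lattice
pixels and the box contour used for the Hausdorff distance is the perimeter
pixel set of the rasterised rectangle. Degenerate single-row or single-column
boxes are legal.

The containment fraction scores how much of a reference segmentation falls
inside another annotator's box — the motivation for box annotation as a
lesion localiser: a box drawn around an uncertain margin should still capture
the whole mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .agreement_metrics import AgreementRecord, EmptyMaskError, agreement

__all__ = [
    "BoundingBox",
    "mask_to_bbox",
    "bbox_to_mask",
    "bbox_agreement",
    "containment_fraction",
]


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box with inclusive integer pixel bounds."""

    row_min: int
    row_max: int
    col_min: int
    col_max: int

    def __post_init__(self):
        if self.row_min > self.row_max or self.col_min > self.col_max:
            raise ValueError(f"inverted bounding box bounds: {self}")
        if min(self.row_min, self.col_min) < 0:
            raise ValueError(f"negative bounding box bounds: {self}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.row_max - self.row_min + 1, self.col_max - self.col_min + 1)

    @property
    def area(self) -> int:
        """Number of lattice pixels covered (inclusive bounds)."""
        r, c = self.shape
        return r * c


def mask_to_bbox(mask: np.ndarray) -> BoundingBox:
    """Tightest axis-aligned box around a mask's foreground pixels."""
    mask = np.asarray(mask, dtype=bool)
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise EmptyMaskError("cannot compute the bounding box of an empty mask")
    return BoundingBox(int(rows[0]), int(rows[-1]), int(cols[0]), int(cols[-1]))


def bbox_to_mask(box: BoundingBox, shape: tuple[int, int]) -> np.ndarray:
    """Rasterise a box to a filled rectangular mask of the given shape."""
    if box.row_max >= shape[0] or box.col_max >= shape[1]:
        raise ValueError(f"box {box} exceeds image shape {shape}")
    mask = np.zeros(shape, dtype=bool)
    mask[box.row_min : box.row_max + 1, box.col_min : box.col_max + 1] = True
    return mask


def bbox_agreement(a: np.ndarray, b: np.ndarray) -> AgreementRecord:
    """Agreement record of the rasterised bounding boxes of two masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        # delegate for a consistent error
        return agreement(a, b)
    return agreement(
        bbox_to_mask(mask_to_bbox(a), a.shape),
        bbox_to_mask(mask_to_bbox(b), b.shape),
    )


def containment_fraction(reference: np.ndarray, box: BoundingBox) -> float:
    """Fraction of the reference mask's pixels that lie inside the box."""
    reference = np.asarray(reference, dtype=bool)
    total = np.count_nonzero(reference)
    if total == 0:
        raise EmptyMaskError("containment of an empty reference is undefined")
    inside = np.count_nonzero(
        reference[
            box.row_min : box.row_max + 1, box.col_min : box.col_max + 1
        ]
    )
    return inside / total
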