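"""Pairwise similarity metrics for 2D binary segmentation masks.

Three metrics quantify inter-annotator agreement: the Jaccard index
(intersection over union, IoU), the Sørensen–Dice coefficient (DSC), and the
symmetric Hausdorff distance (HD) between the mask boundary-pixel sets.

IoU and DSC measure regional overlap by pixel counting and are algebraically
linked, DSC = 2·IoU/(1 + IoU). HD is the larger of the two directed max–min
Euclidean distances between the contours and is sensitive to the single worst
boundary disagreement, which makes it the natural metric for boundary
delineation uncertainty. All distances are Euclidean in pixel index space;
no physical spacing is applied.

Contours are the 8-connected boundary-pixel sets: mask pixels with at least
one background (or out-of-image) pixel among their 8 neighbours, with
coordinates at pixel centres. HD here is the full (100th percentile)
Hausdorff distance, not HD95.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree


__all__ = [
    "AgreementRecord",
    "EmptyMaskError",
    "ShapeMismatchError",
    "iou",
    "dsc",
    "extract_contour",
    "hausdorff",
    "agreement",
]


class EmptyMaskError(ValueError):
    """An operation received an empty mask/contour where content is required."""


class ShapeMismatchError(ValueError):
    """Two masks being compared do not share a shape."""


@dataclass(frozen=True)
class AgreementRecord:
    """The (IoU, DSC, HD) triple for one mask pair. HD is in pixels."""

    iou: float
    dsc: float
    hd: float

    def __iter__(self):
        yield from (self.iou, self.dsc, self.hd)


def _check_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ShapeMismatchError(f"mask shapes differ: {a.shape} vs {b.shape}")
    if not a.any() and not b.any():
        raise EmptyMaskError("both masks are empty; overlap metrics are undefined")
    return a, b


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard index |A∩B| / |A∪B| of two same-shape binary masks."""
    a, b = _check_pair(a, b)
    inter = np.count_nonzero(a & b)
    union = np.count_nonzero(a | b)
    return inter / union


def dsc(a: np.ndarray, b: np.ndarray) -> float:
    """Sørensen–Dice coefficient 2|A∩B| / (|A|+|B|)."""
    a, b = _check_pair(a, b)
    inter = np.count_nonzero(a & b)
    return 2 * inter / (np.count_nonzero(a) + np.count_nonzero(b))


_STRUCT8 = np.ones((3, 3), dtype=bool)


def extract_contour(mask: np.ndarray) -> np.ndarray:
    """Boundary pixels of a mask as an (N, 2) integer array of (row, col).

    A boundary pixel is a foreground pixel 8-adjacent to background; pixels on
    the image border count as boundary (the outside is treated as background).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("cannot extract the contour of an empty mask")
    interior = ndimage.binary_erosion(mask, structure=_STRUCT8, border_value=0)
    return np.argwhere(mask & ~interior)


def hausdorff(a_c: np.ndarray, b_c: np.ndarray) -> float:
    """Symmetric Hausdorff distance (pixels) between two contour point sets.

    max( max_a min_b ||a-b||, max_b min_a ||a-b|| ), computed with KD-trees.
    """
    a_c = np.atleast_2d(np.asarray(a_c, dtype=float))
    b_c = np.atleast_2d(np.asarray(b_c, dtype=float))
    if a_c.size == 0 or b_c.size == 0:
        raise EmptyMaskError("cannot compute Hausdorff distance of an empty contour")
    d_ab = cKDTree(b_c).query(a_c, k=1)[0].max()
    d_ba = cKDTree(a_c).query(b_c, k=1)[0].max()
    return float(max(d_ab, d_ba))


def agreement(a: np.ndarray, b: np.ndarray) -> AgreementRecord:
    """Bundle IoU, DSC and contour Hausdorff distance for one mask pair.

    Either mask may be empty only if the other is not — but the Hausdorff
    term requires both contours, so comparing against an empty mask raises.
    """
    a, b = _check_pair(a, b)
    return AgreementRecord(
        iou=iou(a, b),
        dsc=dsc(a, b),
        hd=hausdorff(extract_contour(a), extract_contour(b)),
    )
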