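"""Reading and writing segmentation masks, grayscale images, and the packaged
per-image agreement table.

Masks are plain 2D boolean :class:`numpy.ndarray`\\ s in (row, col) pixel
coordinates, 0-based, row axis increasing downward. Grayscale images are 2D
float arrays on the 8-bit intensity scale [0, 255]. Two on-disk formats are
supported for masks: NRRD as exported by 3D Slicer segmentations (any nonzero
label maps to foreground, singleton axes are squeezed) and 8-bit PNG. The
package operates purely in raw pixel space; NRRD orientation metadata is
ignored and all distances downstream are in pixel units.
"""

from __future__ import annotations

import os
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "FixtureIntegrityError",
    "MaskFormatError",
    "read_mask",
    "write_mask",
    "read_gray_image",
    "load_agreement_fixture",
    "validate_mask",
    "ANNOTATORS",
    "VARIANTS",
    "METRICS",
]

ANNOTATORS = ("An1", "An2", "An3")
VARIANTS = ("Seg", "BBox")
METRICS = ("iou", "dsc", "hd")

#: Worst-case |dsc - 2*iou/(1+iou)| when iou and dsc are independently rounded
#: to 3 decimals: 0.0005 * d(dsc)/d(iou) + 0.0005 with d(dsc)/d(iou) = 2/(1+iou)^2 <= 2.
_IDENTITY_ROUNDING_BOUND = 0.0016


class MaskFormatError(ValueError):
    """A mask file could not be parsed, or has unsupported dimensionality."""


class FixtureIntegrityError(ValueError):
    """The packaged agreement table is missing or internally inconsistent."""


def validate_mask(mask: np.ndarray) -> np.ndarray:
    """Coerce to a 2D boolean array, raising on invalid input."""
    arr = np.asarray(mask)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise MaskFormatError(f"mask must be 2D with positive shape, got {arr.shape}")
    return arr.astype(bool)


def _infer_format(path: str | os.PathLike, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    ext = os.path.splitext(str(path))[1].lower().lstrip(".")
    if ext in ("nrrd", "png"):
        return ext
    raise MaskFormatError(f"cannot infer mask format from {path!r}; pass format=")


def read_mask(path: str | os.PathLike, format: str | None = None) -> np.ndarray:
    """Read a binary segmentation mask from NRRD or PNG.

    Any nonzero on-disk label becomes foreground (True). A 3D NRRD whose
    third dimension is a singleton (the usual 3D Slicer single-slice export)
    is squeezed to 2D; a genuinely 3D volume is rejected — this package is
    2D-only.
    """
    fmt = _infer_format(path, format)
    if fmt == "nrrd":
        import SimpleITK as sitk

        try:
            img = sitk.ReadImage(str(path))
        except RuntimeError as exc:
            raise MaskFormatError(f"could not parse NRRD file {path!r}: {exc}") from exc
        arr = sitk.GetArrayFromImage(img)
        while arr.ndim > 2 and 1 in arr.shape:  # 3D Slicer single-slice export
            arr = np.squeeze(arr, axis=arr.shape.index(1))
        if arr.ndim != 2:
            raise MaskFormatError(
                f"NRRD at {path!r} has {arr.ndim} non-singleton dimensions; "
                "only 2D masks are supported"
            )
    elif fmt == "png":
        from PIL import Image, UnidentifiedImageError

        try:
            with Image.open(path) as im:
                arr = np.asarray(im)
        except (UnidentifiedImageError, OSError) as exc:
            raise MaskFormatError(f"could not parse PNG file {path!r}: {exc}") from exc
        if arr.ndim == 3:  # collapse RGB(A) labels
            arr = arr[..., :3].max(axis=2)
    else:
        raise MaskFormatError(f"unsupported mask format {fmt!r}")
    return validate_mask(arr != 0)


def write_mask(mask: np.ndarray, path: str | os.PathLike, format: str | None = None) -> None:
    """Write a binary mask to NRRD (labels 0/1) or PNG (0/255)."""
    mask = validate_mask(mask)
    fmt = _infer_format(path, format)
    if fmt == "nrrd":
        import SimpleITK as sitk

        sitk.WriteImage(sitk.GetImageFromArray(mask.astype(np.uint8)), str(path))
    elif fmt == "png":
        from PIL import Image

        Image.fromarray((mask.astype(np.uint8)) * 255, mode="L").save(path)
    else:
        raise MaskFormatError(f"unsupported mask format {fmt!r}")


def read_gray_image(path: str | os.PathLike, format: str | None = None) -> np.ndarray:
    """Read a grayscale image (PNG, or a single-frame DICOM) as float [0, 255].

    DICOM pixel data outside the 8-bit range is rescaled linearly onto
    [0, 255]; multi-frame DICOM is rejected.
    """
    ext = os.path.splitext(str(path))[1].lower().lstrip(".")
    fmt = (format or ext or "png").lower()
    if fmt in ("dcm", "dicom"):
        import pydicom

        ds = pydicom.dcmread(str(path))
        arr = ds.pixel_array
        if arr.ndim != 2:
            raise MaskFormatError("only single-frame 2D DICOM images are supported")
        arr = arr.astype(float)
        if arr.max() > 255 or arr.min() < 0:
            lo, hi = arr.min(), arr.max()
            arr = (arr - lo) / (hi - lo) * 255.0 if hi > lo else np.zeros_like(arr)
        return arr
    from PIL import Image

    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=float)


def load_agreement_fixture() -> pd.DataFrame:
    """Load the packaged 30-image agreement table.

    Returns a DataFrame with columns ``image_id`` (1..30), ``annotator``
    (An1..An3), ``variant`` (Seg or BBox), ``iou``, ``dsc`` (unitless, [0,1])
    and ``hd`` (pixels): the per-image similarity of each annotator's
    segmentation — and of its axis-aligned bounding box — against the
    MRI-informed reference standard. The table is validated on load: full
    30 x 3 x 2 cardinality, metric ranges, and row-wise consistency of dsc
    with 2*iou/(1+iou) up to the rounding of the stored 3-decimal values.
    """
    ref = resources.files("segvar").joinpath("data/agreement_table.csv")
    try:
        with resources.as_file(ref) as p:
            df = pd.read_csv(p)
    except FileNotFoundError as exc:
        raise FixtureIntegrityError("packaged agreement table is missing") from exc

    expected_cols = ["image_id", "annotator", "variant", "iou", "dsc", "hd"]
    if list(df.columns) != expected_cols:
        raise FixtureIntegrityError(f"unexpected fixture columns: {list(df.columns)}")

    problems = []
    if len(df) != 180:
        problems.append(f"expected 180 rows, found {len(df)}")
    counts = df.groupby(["annotator", "variant"])["image_id"].nunique()
    for (ann, var), n in counts.items():
        if n != 30:
            problems.append(f"{ann}/{var}: {n} image ids, expected 30")
    bad_range = df[
        (df.iou < 0) | (df.iou > 1) | (df.dsc < 0) | (df.dsc > 1) | (df.hd < 0)
    ]
    for _, r in bad_range.iterrows():
        problems.append(f"out-of-range metrics in row {tuple(r[:3])}")
    dev = (df.dsc - 2 * df.iou / (1 + df.iou)).abs()
    for _, r in df[dev > _IDENTITY_ROUNDING_BOUND].iterrows():
        problems.append(f"dsc/iou identity violated in row {tuple(r[:3])}")
    if (df.iou > df.dsc + 1e-12).any():
        problems.append("iou exceeds dsc in at least one row")
    if problems:
        raise FixtureIntegrityError("; ".join(problems))
    return df
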