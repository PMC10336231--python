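"""Gray level index (GLI) images.

A GLI image summarizes a cell-body stained section as the volume fraction of
stained tissue (0–100 %) per small square measuring field.  Cells are first
segmented from the grayscale image (dark objects on a bright background),
then the binary mask is reduced field-by-field to stain fractions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class GLIImage:
    """Stain volume fractions per measuring field.

    ``values`` are percentages in [0, 100].  ``field_size`` is the edge
    length of one GLI pixel in μm; ``origin_offset`` locates field (0, 0)
    in source-image pixel coordinates (x, y).
    """

    values: np.ndarray = field(repr=False)
    field_size: float = 16.0
    origin_offset: tuple[float, float] = (0.0, 0.0)
    source_pixel_size: float = 1.02

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("GLI values must be a 2D grid")
        if v.size and (v.min() < 0 or v.max() > 100):
            raise ValueError("GLI values must lie in [0, 100] percent")
        self.values = v

    @property
    def fields_per_side(self) -> int:
        return int(round(self.field_size / self.source_pixel_size))


def segment_cells(
    image: np.ndarray, method: str = "otsu", threshold: float | None = None
) -> np.ndarray:
    """Segment stained cell bodies (dark pixels) from a grayscale section.

    ``method="fixed"`` marks pixels strictly below ``threshold``;
    ``method="otsu"`` derives the threshold from the image histogram.  A
    constant image under Otsu yields an all-background mask with a warning.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("image is empty")
    if method == "fixed":
        if threshold is None:
            raise ValueError("fixed method requires a threshold")
        return image < threshold
    if method == "otsu":
        from skimage.filters import threshold_otsu

        if image.min() == image.max():
            warnings.warn(
                "constant image: Otsu threshold undefined, returning "
                "all-background mask",
                stacklevel=2,
            )
            return np.zeros(image.shape, dtype=bool)
        return image < threshold_otsu(image)
    raise ValueError(f"unknown segmentation method {method!r}")


def compute_gli_image(
    mask: np.ndarray,
    fields_per_side: int = 16,
    source_pixel_size: float = 1.02,
) -> GLIImage:
    """Reduce a binary cell mask to GLI values per measuring field.

    Each non-overlapping square field of ``fields_per_side``² source pixels
    becomes one GLI value, 100 × (stained pixels / field pixels).  Trailing
    partial fields are dropped so every value is an unbiased fraction.
    """
    mask = np.asarray(mask, dtype=bool)
    if fields_per_side < 1:
        raise ValueError("fields_per_side must be >= 1")
    h, w = mask.shape
    if fields_per_side > h or fields_per_side > w:
        raise ValueError(
            f"fields_per_side {fields_per_side} exceeds mask dimensions {mask.shape}"
        )
    nh, nw = h // fields_per_side, w // fields_per_side
    trimmed = mask[: nh * fields_per_side, : nw * fields_per_side]
    sums = trimmed.reshape(nh, fields_per_side, nw, fields_per_side).sum(axis=(1, 3))
    values = 100.0 * sums / fields_per_side**2
    return GLIImage(
        values=values,
        field_size=fields_per_side * source_pixel_size,
        origin_offset=(0.0, 0.0),
        source_pixel_size=source_pixel_size,
    )


def sample(gli: GLIImage, xy: np.ndarray) -> np.ndarray:
    """Bilinearly interpolate GLI values at source-image coordinates.

    ``xy`` is an (n, 2) array of (x, y) points in source-pixel coordinates;
    each GLI value is anchored at the center of its measuring field.
    """
    from scipy.ndimage import map_coordinates

    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    fps = gli.field_size / gli.source_pixel_size
    gx = (xy[:, 0] - gli.origin_offset[0]) / fps - 0.5
    gy = (xy[:, 1] - gli.origin_offset[1]) / fps - 0.5
    return map_coordinates(gli.values, [gy, gx], order=1, mode="nearest")


def save(gli: GLIImage, path) -> None:
    """Write the GLI grid as 32-bit float TIFF with a JSON sidecar."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, gli.values.astype(np.float32))
    sidecar = {
        "field_size": gli.field_size,
        "origin_offset": list(gli.origin_offset),
        "source_pixel_size": gli.source_pixel_size,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load(path) -> GLIImage:
    """Read a GLI TIFF + sidecar written by :func:`save`."""
    import tifffile

    path = Path(path)
    values = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return GLIImage(
        values=values,
        field_size=meta["field_size"],
        origin_offset=tuple(meta["origin_offset"]),
        source_pixel_size=meta["source_pixel_size"],
    )
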