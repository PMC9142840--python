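"""Label-mask ingestion, a simple built-in blob segmenter, and mask application.

Cell segmentation of real tissue images is delegated to external tools
(e.g. a learned instance segmenter run on the 2PF channel); this module
ingests the resulting label TIFFs.  The built-in segmenter is a classical
smooth / threshold / watershed chain adequate for synthetic fixtures and
simple well-separated cells — it is deliberately not a substitute for a
learned model on real tissue.

Whatever its origin, one mask is applied identically to all four channels
so per-region statistics are computed over the same pixel sets everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import tifffile
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.segmentation import watershed

from .errors import DegenerateInputError, MaskFormatError, ShapeError
from .image_io import MultimodalFrame

#: 4-connectivity for components: avoids diagonal bridging of adjacent cells.
_CONNECTIVITY = 1


@dataclass
class SegmentationMask:
    """Labeled-region integer raster; 0 is background, labels are 1..n."""

    labels: np.ndarray
    source: Literal["external", "builtin", "ground_truth"] = "external"

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 2:
            raise MaskFormatError("mask must be a single-channel 2-D raster")
        if not np.issubdtype(arr.dtype, np.integer):
            raise MaskFormatError("mask must be integer-valued")
        if arr.size and arr.min() < 0:
            raise MaskFormatError("mask labels must be non-negative")
        self.labels = canonicalize_labels(arr)

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def binary(self) -> np.ndarray:
        """Flatten to a foreground/background mask."""
        return self.labels > 0


def canonicalize_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel positive labels to contiguous 1..n, preserving region identity.

    Labels are renumbered in increasing order of their original value, so
    e.g. {0, 3, 7} becomes {0, 1, 2}.
    """
    arr = np.asarray(labels)
    uniq = np.unique(arr)
    uniq = uniq[uniq > 0]
    out = np.zeros_like(arr, dtype=np.int32)
    for new, old in enumerate(uniq, start=1):
        out[arr == old] = new
    return out


def load_mask(path: str | Path) -> SegmentationMask:
    """Read an externally produced label mask from a single-channel TIFF.

    Integer TIFFs are taken as-is; float TIFFs are accepted only when every
    value is integral.  A binary mask (values in {0, 1}) is first split
    into connected components (4-connectivity); labels are then
    canonicalized to contiguous 1..n.
    """
    arr = tifffile.imread(Path(path))
    if arr.ndim != 2:
        raise MaskFormatError(f"mask TIFF must be single-channel 2-D, got ndim {arr.ndim}")
    if np.issubdtype(arr.dtype, np.floating):
        rounded = np.round(arr)
        if not np.allclose(arr, rounded, atol=0, rtol=0):
            raise MaskFormatError("mask raster is not integer-valued")
        arr = rounded.astype(np.int64)
    elif not np.issubdtype(arr.dtype, np.integer):
        raise MaskFormatError(f"unsupported mask dtype {arr.dtype}")
    arr = arr.astype(np.int64)
    if arr.min() < 0:
        raise MaskFormatError("mask labels must be non-negative")
    if arr.max() <= 1:
        arr = cc_label(arr > 0, connectivity=_CONNECTIVITY)
    return SegmentationMask(labels=np.asarray(arr), source="external")


def write_mask(mask: SegmentationMask, path: str | Path) -> None:
    """Write a label mask as uint16 single-channel TIFF."""
    if mask.n_labels > np.iinfo(np.uint16).max:
        raise MaskFormatError("too many labels for uint16 output")
    tifffile.imwrite(Path(path), mask.labels.astype(np.uint16))


def segment_blobs(
    raster: np.ndarray,
    estimated_diameter_um: float,
    pixel_size_um: float,
) -> SegmentationMask:
    """Segment bright blobs of a known approximate diameter.

    Pipeline: Gaussian smoothing at diameter/4 FWHM, Otsu threshold with a
    contrast guard (a raster whose foreground is not well separated from
    background — e.g. pure noise — yields an empty mask), connected
    components (4-connectivity), removal of components smaller than 25% of
    the expected blob area, then a watershed split of merged blobs seeded
    by local intensity maxima separated by at least half the expected
    diameter.  Fully deterministic.
    """
    arr = np.asarray(raster, dtype=np.float64)
    if arr.ndim != 2:
        raise ShapeError("expected a 2-D raster")
    if np.ptp(arr) == 0:
        raise DegenerateInputError("constant raster cannot be thresholded")
    d_px = estimated_diameter_um / pixel_size_um
    if d_px < 2:
        raise ValueError("estimated diameter below 2 pixels")

    fwhm_to_sigma = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    smoothed = ndimage.gaussian_filter(arr, sigma=d_px / 4.0 * fwhm_to_sigma)
    fg = smoothed > threshold_otsu(smoothed)
    min_area = 0.25 * np.pi * (d_px / 2.0) ** 2

    # Otsu always splits something; demand real separation between classes
    if fg.any() and not fg.all():
        bg_vals = smoothed[~fg]
        contrast = smoothed[fg].mean() - bg_vals.mean()
        spread = bg_vals.std()
        if spread > 0 and contrast < 4.0 * spread:
            return SegmentationMask(labels=np.zeros_like(arr, dtype=np.int32),
                                    source="builtin")

    comp = cc_label(fg, connectivity=_CONNECTIVITY)
    for lab in range(1, comp.max() + 1):
        if (comp == lab).sum() < min_area:
            fg[comp == lab] = False

    if not fg.any():
        return SegmentationMask(labels=np.zeros_like(arr, dtype=np.int32),
                                source="builtin")

    peaks = peak_local_max(
        smoothed,
        min_distance=max(1, int(round(d_px / 2.0))),
        labels=fg,
        exclude_border=False,
    )
    markers = np.zeros_like(arr, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        labels = cc_label(fg, connectivity=_CONNECTIVITY)
    else:
        labels = watershed(-smoothed, markers=markers, mask=fg,
                           connectivity=_CONNECTIVITY)
    # watershed fragments below the size floor are dropped
    out = np.asarray(labels, dtype=np.int32)
    for lab in np.unique(out):
        if lab > 0 and (out == lab).sum() < min_area:
            out[out == lab] = 0
    return SegmentationMask(labels=out, source="builtin")


def segment_frame(
    frame: MultimodalFrame,
    estimated_diameter_um: float,
    channel: str = "2PF",
) -> SegmentationMask:
    """Run the built-in blob segmenter on one channel (2PF by default)."""
    return segment_blobs(frame.channel(channel), estimated_diameter_um,
                         frame.pixel_size_um)


def apply_mask(
    frame: MultimodalFrame,
    mask: SegmentationMask,
) -> dict[int, dict[str, np.ndarray]]:
    """Collect per-label, per-channel pixel values under one mask.

    The identical pixel membership is used for every channel; background
    (label 0) is excluded.  An empty mask yields an empty mapping.
    """
    if mask.shape != frame.shape:
        raise ShapeError(
            f"mask shape {mask.shape} does not match frame shape {frame.shape}"
        )
    out: dict[int, dict[str, np.ndarray]] = {}
    for lab in range(1, mask.n_labels + 1):
        sel = mask.labels == lab
        out[lab] = {name: raster[sel] for name, raster in frame.channels.items()}
    return out
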