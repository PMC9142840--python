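"""Multichannel frame I/O and display transforms.

A :class:`MultimodalFrame` holds one co-registered acquisition of up to four
nonlinear contrasts — two- and three-photon autofluorescence (``2PF``,
``3PF``), second- and third-harmonic generation (``SHG``, ``THG``) — as 2-D
non-negative intensity rasters sharing a pixel grid, together with the
physical pixel size and the acquisition time within a longitudinal series.

Frames are stored on disk as multi-page TIFF (one page per channel, in the
order given by the JSON sidecar) plus a ``<name>.tif.json`` sidecar carrying
``channels``, ``pixel_size_um`` (or ``fov_um`` from which it is derived) and
``time_min``.  Pixel content is never used to guess channel identity.

Display helpers mirror the common microscopy presentation: per-channel
contrast stretch that saturates a top fraction of pixels, and an additive
pseudo-color merge.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile
from matplotlib.colors import to_rgb

from .errors import ChannelError, DegenerateInputError, MetadataError, ShapeError

#: Canonical channel order used when writing frames to disk.
CHANNEL_ORDER: tuple[str, ...] = ("2PF", "3PF", "SHG", "THG")

#: Default pseudo-color assignment (matplotlib color names or RGB tuples).
DEFAULT_COLORS: dict[str, str] = {
    "2PF": "yellow",
    "3PF": "cyan",
    "SHG": "lime",
    "THG": "magenta",
}


@dataclass
class MultimodalFrame:
    """One co-registered multichannel intensity raster.

    Parameters
    ----------
    channels
        Mapping from channel name (subset of ``{"2PF", "3PF", "SHG", "THG"}``)
        to a 2-D non-negative raster in arbitrary detector units.  Integer
        input is promoted to ``float64``.
    pixel_size_um
        Lateral sampling in micrometres per pixel (isotropic).
    time_min
        Acquisition time in minutes since the start of the series.
    frame_id
        Free-text label, e.g. the source filename.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    time_min: float = 0.0
    frame_id: str = ""

    def __post_init__(self) -> None:
        if not self.channels:
            raise ChannelError("a frame needs at least one channel")
        clean: dict[str, np.ndarray] = {}
        shape = None
        for name, raster in self.channels.items():
            if name not in CHANNEL_ORDER:
                raise ChannelError(
                    f"unknown channel {name!r}; expected one of {CHANNEL_ORDER}"
                )
            arr = np.asarray(raster, dtype=np.float64)
            if arr.ndim != 2:
                raise ShapeError(f"channel {name!r} is not a 2-D raster")
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise ShapeError(
                    f"channel {name!r} has shape {arr.shape}, expected {shape}"
                )
            if arr.size and arr.min() < 0:
                raise ValueError(f"channel {name!r} has negative intensities")
            clean[name] = arr
        if not (self.pixel_size_um > 0):
            raise MetadataError("pixel_size_um must be positive")
        if self.time_min < 0:
            raise MetadataError("time_min must be non-negative")
        self.channels = clean

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(n for n in CHANNEL_ORDER if n in self.channels)

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise ChannelError(f"channel {name!r} absent from frame") from None

    def copy(self) -> "MultimodalFrame":
        return MultimodalFrame(
            channels={k: v.copy() for k, v in self.channels.items()},
            pixel_size_um=self.pixel_size_um,
            time_min=self.time_min,
            frame_id=self.frame_id,
        )


@dataclass
class DisplayImage:
    """Pseudo-colored RGB rendering of a frame; values in [0, 1]."""

    rgb: np.ndarray
    channel_color_map: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    saturation_fraction: float = 0.05

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb, dtype=np.float64)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ShapeError("rgb must be H x W x 3")
        if self.rgb.size and (self.rgb.min() < 0 or self.rgb.max() > 1):
            raise ValueError("rgb values must lie in [0, 1]")


def adjust_contrast(raster: np.ndarray, saturation_fraction: float = 0.05) -> np.ndarray:
    """Contrast-stretch a raster to [0, 1], saturating the brightest pixels.

    The upper display bound is the ``1 - saturation_fraction`` quantile
    (linear-interpolation convention); pixels at or above it map to 1, the
    minimum maps to 0, and the stretch is linear in between.  With
    ``saturation_fraction=0.05`` the top ~5% of intensities are saturated.

    A constant raster has no defined stretch; it returns all zeros and emits
    a :class:`UserWarning`.
    """
    arr = np.asarray(raster, dtype=np.float64)
    if arr.size == 0:
        raise DegenerateInputError("empty raster")
    if not 0 <= saturation_fraction < 1:
        raise ValueError("saturation_fraction must lie in [0, 1)")
    lo = float(arr.min())
    hi = float(np.quantile(arr, 1.0 - saturation_fraction))
    if hi <= lo:
        warnings.warn(
            "constant raster: contrast stretch undefined, returning zeros",
            UserWarning,
            stacklevel=2,
        )
        return np.zeros_like(arr)
    return np.clip((arr - lo) / (hi - lo), 0.0, 1.0)


def merge_pseudocolor(
    frame: MultimodalFrame,
    color_map: Mapping[str, object] | None = None,
    saturation_fraction: float = 0.05,
) -> DisplayImage:
    """Additively merge channels into a pseudo-colored RGB image.

    Each requested channel is contrast-adjusted independently
    (:func:`adjust_contrast`), tinted with its assigned color, summed, and
    clipped to [0, 1].
    """
    if color_map is None:
        color_map = {n: DEFAULT_COLORS[n] for n in frame.channel_names}
    resolved: dict[str, tuple[float, float, float]] = {}
    for name, color in color_map.items():
        if name not in frame.channels:
            raise ChannelError(f"color map references absent channel {name!r}")
        resolved[name] = to_rgb(color)

    h, w = frame.shape
    rgb = np.zeros((h, w, 3), dtype=np.float64)
    for name, color in resolved.items():
        chan = frame.channel(name)
        if np.ptp(chan) == 0 and chan.max() == 0:
            continue  # all-zero channel contributes nothing; avoid the warning
        scaled = adjust_contrast(chan, saturation_fraction)
        rgb += scaled[:, :, None] * np.asarray(color)[None, None, :]
    np.clip(rgb, 0.0, 1.0, out=rgb)
    return DisplayImage(rgb=rgb, channel_color_map=resolved,
                        saturation_fraction=saturation_fraction)


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_frame(frame: MultimodalFrame, path: str | Path) -> Path:
    """Write a frame as a multi-page TIFF plus a JSON metadata sidecar.

    Channels are stored one per page in canonical order
    (:data:`CHANNEL_ORDER` restricted to those present); the sidecar records
    the order explicitly so the reader never guesses.  Returns the sidecar
    path.
    """
    path = Path(path)
    names = frame.channel_names
    stack = np.stack([frame.channels[n] for n in names])
    tifffile.imwrite(path, stack, photometric="minisblack")
    sidecar = _sidecar_path(path)
    meta = {
        "channels": list(names),
        "pixel_size_um": frame.pixel_size_um,
        "time_min": frame.time_min,
        "frame_id": frame.frame_id,
    }
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return sidecar


def read_frame(
    path: str | Path,
    metadata: Mapping[str, object] | str | Path | None = None,
) -> MultimodalFrame:
    """Read a multi-page TIFF into a :class:`MultimodalFrame`.

    Metadata resolution order: an explicit ``metadata`` mapping (or path to
    a JSON file) wins; otherwise the ``<path>.json`` sidecar is used.  The
    metadata must declare ``channels`` (page order) and either
    ``pixel_size_um`` or ``fov_um`` (from which pixel size is derived as
    FOV / pixels along the image width); ``time_min`` defaults to 0.

    8-bit, 16-bit and floating TIFF are accepted; intensities are promoted
    to ``float64`` without assuming a dynamic-range maximum.
    """
    path = Path(path)
    if metadata is None:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise MetadataError(f"no metadata given and no sidecar at {sidecar}")
        meta = json.loads(sidecar.read_text())
    elif isinstance(metadata, (str, Path)):
        meta = json.loads(Path(metadata).read_text())
    else:
        meta = dict(metadata)

    channel_names = meta.get("channels")
    if not channel_names:
        raise MetadataError("metadata must declare the channel page order")

    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None, :, :]
    if data.ndim != 3:
        raise ShapeError(f"expected 2-D pages, got array of ndim {data.ndim}")
    if data.shape[0] != len(channel_names):
        raise ShapeError(
            f"TIFF has {data.shape[0]} pages but metadata declares "
            f"{len(channel_names)} channels"
        )

    pixel_size = meta.get("pixel_size_um")
    if pixel_size is None:
        fov = meta.get("fov_um")
        if fov is None:
            raise MetadataError(
                "metadata must supply pixel_size_um or fov_um"
            )
        pixel_size = float(fov) / data.shape[2]

    return MultimodalFrame(
        channels={name: data[i] for i, name in enumerate(channel_names)},
        pixel_size_um=float(pixel_size),
        time_min=float(meta.get("time_min", 0.0)),
        frame_id=str(meta.get("frame_id", path.stem)),
    )


def save_png(display: DisplayImage, path: str | Path) -> None:
    """Export a display image as 8-bit PNG."""
    import matplotlib.image

    matplotlib.image.imsave(str(path), display.rgb)


def read_series(directory: str | Path, pattern: str = "*.tif") -> list[MultimodalFrame]:
    """Read every ``pattern`` TIFF in a directory, sorted by acquisition time.

    Each file must have its JSON sidecar.  Frames are returned ordered by
    ``time_min`` (ties broken by filename).
    """
    directory = Path(directory)
    paths: Sequence[Path] = sorted(directory.glob(pattern))
    if not paths:
        raise FileNotFoundError(f"no {pattern} files in {directory}")
    frames = [read_frame(p) for p in paths]
    frames.sort(key=lambda f: f.time_min)
    return frames
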