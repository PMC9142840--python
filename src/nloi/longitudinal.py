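"""Longitudinal analysis of multichannel frame series.

Fresh tissue degrades on the hour timescale: channel intensities decay at
channel-specific rates, the field of view drifts laterally, and the
optical redox ratio drifts upward as 3PF (NAD(P)H) fades faster than 2PF
(FAD).  This module quantifies those trends for an ordered series of
frames:

* per-channel mean-intensity trajectories and percent change versus t=0,
* per-timepoint ORR distribution summaries — whole-frame or under a
  per-frame segmentation mask — with rank-based comparisons between
  selected timepoints (first/middle/last by default),
* lateral drift estimated by phase correlation with sub-pixel refinement.

By default trajectories are computed on the drifting field of view as-is
(no registration); :func:`register_series` can undo the estimated drift
first when a registered analysis is wanted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .errors import ChannelError, DegenerateInputError, ShapeError
from .image_io import MultimodalFrame
from .metabolic import (
    DistributionSummary,
    GroupComparison,
    compare_groups,
    orr_map,
    summarize,
)
from .segmentation import SegmentationMask

DEFAULT_DRIFT_CHANNEL = "SHG"  # structural contrast, decays least


@dataclass
class TimeSeriesResult:
    """Bundled longitudinal analysis of one frame series."""

    times_min: np.ndarray
    channel_means: pd.DataFrame
    percent_change: pd.DataFrame
    orr_summaries: list[DistributionSummary]
    orr_masked_summaries: list[DistributionSummary] | None = None
    drift_um: np.ndarray | None = None
    comparisons: dict[tuple[int, int], GroupComparison] = field(default_factory=dict)
    comparison_timepoints: tuple[int, ...] = ()
    whole_frame_pixels: str = "all"  # which pixels entered channel means


def _check_series(frames: list[MultimodalFrame]) -> None:
    if len(frames) < 2:
        raise ValueError("a series needs at least two frames")
    times = [f.time_min for f in frames]
    if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
        raise ValueError("frame times must be strictly increasing")
    names = set(frames[0].channel_names)
    for f in frames[1:]:
        if set(f.channel_names) != names:
            raise ChannelError("all frames must share the same channel set")


def channel_means(frames: list[MultimodalFrame]) -> pd.DataFrame:
    """Per-frame whole-frame mean intensity, rows indexed by time (min)."""
    _check_series(frames)
    rows = [
        {name: float(raster.mean()) for name, raster in f.channels.items()}
        for f in frames
    ]
    return pd.DataFrame(rows, index=pd.Index([f.time_min for f in frames],
                                             name="time_min"))


def intensity_trajectory(frames: list[MultimodalFrame]) -> pd.DataFrame:
    """Percent change of each channel's mean intensity versus t=0.

    Returns ``100 * (mean_t - mean_0) / mean_0`` per channel, indexed by
    time; a channel with zero initial mean gets NaN (with a warning) while
    the others are unaffected.
    """
    means = channel_means(frames)
    out = {}
    for name in means.columns:
        m0 = means[name].iloc[0]
        if m0 == 0:
            warnings.warn(
                f"channel {name!r} has zero mean at t=0; percent change undefined",
                UserWarning,
                stacklevel=2,
            )
            out[name] = np.full(len(means), np.nan)
        else:
            out[name] = 100.0 * (means[name].to_numpy() - m0) / m0
    return pd.DataFrame(out, index=means.index)


def _frame_orr_values(
    frame: MultimodalFrame,
    mask: SegmentationMask | None,
    denom_threshold: float,
) -> np.ndarray:
    omap = orr_map(frame, denom_threshold)
    if mask is None:
        return omap.valid_values()
    if mask.shape != frame.shape:
        raise ShapeError("mask shape does not match frame shape")
    return omap.masked_values(mask.labels)


def orr_trajectory(
    frames: list[MultimodalFrame],
    masks: list[SegmentationMask] | None = None,
    denom_threshold: float = 0.0,
) -> list[DistributionSummary]:
    """Per-frame ORR distribution summaries (whole-frame or masked).

    With ``masks`` given (one per frame, applied to its frame only), the
    pixel-level ORR is pooled over all labeled regions; otherwise all valid
    pixels of the frame enter.
    """
    _check_series(frames)
    if masks is not None and len(masks) != len(frames):
        raise ValueError("need exactly one mask per frame")
    out = []
    for i, frame in enumerate(frames):
        vals = _frame_orr_values(frame, None if masks is None else masks[i],
                                 denom_threshold)
        if vals.size == 0:
            raise DegenerateInputError(f"no valid ORR pixels in frame {i}")
        out.append(summarize(vals))
    return out


def default_comparison_timepoints(n_frames: int) -> tuple[int, int, int]:
    """First, middle, and last frame indices."""
    return (0, n_frames // 2, n_frames - 1)


def compare_timepoints(
    frames: list[MultimodalFrame],
    timepoints: tuple[int, ...] | None = None,
    masks: list[SegmentationMask] | None = None,
    denom_threshold: float = 0.0,
) -> dict[tuple[int, int], GroupComparison]:
    """Rank-based pairwise comparison of pixel-level ORR between timepoints."""
    _check_series(frames)
    if timepoints is None:
        timepoints = default_comparison_timepoints(len(frames))
    values = {
        t: _frame_orr_values(frames[t], None if masks is None else masks[t],
                             denom_threshold)
        for t in timepoints
    }
    out: dict[tuple[int, int], GroupComparison] = {}
    for a_idx, ti in enumerate(timepoints):
        for tj in timepoints[a_idx + 1:]:
            out[(ti, tj)] = compare_groups([values[ti], values[tj]])
    return out


def estimate_drift(
    reference: MultimodalFrame,
    moving: MultimodalFrame,
    channel: str = DEFAULT_DRIFT_CHANNEL,
    upsample_factor: int = 50,
) -> np.ndarray:
    """Lateral drift of ``moving`` relative to ``reference``, in micrometres.

    Phase correlation with sub-pixel refinement on one shared channel (the
    structural SHG contrast by default).  Returns ``(dx, dy)``: the
    translation that maps reference coordinates onto moving coordinates,
    i.e. the displacement the scene underwent.
    """
    ref = reference.channel(channel)
    mov = moving.channel(channel)
    if ref.shape != mov.shape:
        raise ShapeError("frames must share raster shape")
    if reference.pixel_size_um != moving.pixel_size_um:
        raise ShapeError("frames must share pixel size")
    if np.ptp(ref) == 0 or np.ptp(mov) == 0:
        raise DegenerateInputError(
            f"channel {channel!r} is featureless; drift undefined"
        )
    shift, _, _ = phase_cross_correlation(ref, mov,
                                          upsample_factor=upsample_factor)
    # phase correlation returns the (row, col) shift registering moving back
    # onto reference; the scene displacement is its negation
    dy_px, dx_px = -shift
    return np.array([dx_px, dy_px]) * reference.pixel_size_um


def drift_series(
    frames: list[MultimodalFrame],
    channel: str = DEFAULT_DRIFT_CHANNEL,
    upsample_factor: int = 50,
) -> np.ndarray:
    """Drift of every frame relative to the first, as an (n, 2) array of um."""
    _check_series(frames)
    out = np.zeros((len(frames), 2))
    for i, frame in enumerate(frames[1:], start=1):
        out[i] = estimate_drift(frames[0], frame, channel, upsample_factor)
    return out


def register_series(
    frames: list[MultimodalFrame],
    channel: str = DEFAULT_DRIFT_CHANNEL,
    upsample_factor: int = 50,
) -> tuple[list[MultimodalFrame], np.ndarray]:
    """Undo estimated lateral drift, returning shifted frames and the drift.

    Each frame is translated by the negated estimated drift (bilinear
    interpolation, zero fill) so its content aligns with frame 0.
    """
    drifts = drift_series(frames, channel, upsample_factor)
    registered = [frames[0].copy()]
    for frame, (dx_um, dy_um) in zip(frames[1:], drifts[1:]):
        shift_px = (-dy_um / frame.pixel_size_um, -dx_um / frame.pixel_size_um)
        channels = {
            name: np.clip(
                ndimage.shift(raster, shift_px, order=1, mode="constant",
                              cval=0.0, prefilter=False),
                0.0, None)
            for name, raster in frame.channels.items()
        }
        g = frame.copy()
        g.channels = channels
        registered.append(g)
    return registered, drifts


def analyze_series(
    frames: list[MultimodalFrame],
    masks: list[SegmentationMask] | None = None,
    denom_threshold: float = 0.0,
    drift_channel: str = DEFAULT_DRIFT_CHANNEL,
    comparison_timepoints: tuple[int, ...] | None = None,
    register: bool = False,
) -> TimeSeriesResult:
    """Full longitudinal report for a frame series.

    Combines channel-mean and percent-change trajectories, whole-frame (and
    optionally masked) ORR summaries, drift estimates relative to frame 0,
    and pairwise ORR comparisons between selected timepoints.  Whole-frame
    means include every pixel; set ``register=True`` to undo estimated
    drift before computing trajectories (drift estimates always refer to
    the original frames).
    """
    _check_series(frames)
    try:
        drifts = drift_series(frames, drift_channel)
    except DegenerateInputError:
        drifts = None
    working = frames
    if register:
        if drifts is None:
            raise DegenerateInputError("cannot register: drift not estimable")
        working, _ = register_series(frames, drift_channel)

    means = channel_means(working)
    pct = intensity_trajectory(working)
    orr_whole = orr_trajectory(working, None, denom_threshold)
    orr_masked = (orr_trajectory(working, masks, denom_threshold)
                  if masks is not None else None)
    if comparison_timepoints is None:
        comparison_timepoints = default_comparison_timepoints(len(frames))
    comparisons = compare_timepoints(working, comparison_timepoints, masks,
                                     denom_threshold)
    return TimeSeriesResult(
        times_min=np.array([f.time_min for f in frames]),
        channel_means=means,
        percent_change=pct,
        orr_summaries=orr_whole,
        orr_masked_summaries=orr_masked,
        drift_um=drifts,
        comparisons=comparisons,
        comparison_timepoints=tuple(comparison_timepoints),
        whole_frame_pixels="all (registered)" if register else "all",
    )
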