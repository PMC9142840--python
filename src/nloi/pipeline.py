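"""Config-driven orchestration of the analysis stages.

Each ``run_*`` function executes one analysis archetype end-to-end —
simulation, fiber orientation, metabolic profiling, segmentation, group
comparison, or longitudinal tracking — and writes a structured JSON report
(plus CSV/TIFF side outputs where natural).  Every report embeds the
configuration and seed that produced it, and report serialization is fully
deterministic (sorted keys, no timestamps), so any report can be
regenerated byte-identically from its own header.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import tifffile
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .errors import NloiError
from .fibers import AngularFilterParams, alignment_ratio, angular_spectrum
from .image_io import MultimodalFrame, read_frame, read_series, write_frame
from .longitudinal import analyze_series
from .metabolic import compare_groups, channel_profile, masked_summaries, orr_map, summarize
from .segmentation import SegmentationMask, load_mask, segment_frame, write_mask
from .synthetic import (
    CellSceneConfig,
    DecayModel,
    FiberSceneConfig,
    NoiseModel,
    generate_cell_scene,
    generate_fiber_image,
    generate_time_series,
)


# --------------------------------------------------------------------------
# config schema
# --------------------------------------------------------------------------

class SimulateConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    kind: Literal["fibers", "cells", "series"]
    fiber_scene: Optional[FiberSceneConfig] = None
    cell_scene: Optional[CellSceneConfig] = None
    decay: Optional[DecayModel] = None
    noise: Optional[NoiseModel] = None


class FiberAnalysisConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    input: str
    pixel_size_um: Optional[float] = Field(None, gt=0)
    angle_step_deg: float = 2.0
    wedge_half_width_deg: float = 1.0
    min_freq_cyc_per_um: float = 0.05
    max_freq_cyc_per_um: Optional[float] = None
    window: Literal["hann", "none"] = "hann"
    dc_block_radius_px: int = 3

    def filter_params(self) -> AngularFilterParams:
        return AngularFilterParams(
            angle_step_deg=self.angle_step_deg,
            wedge_half_width_deg=self.wedge_half_width_deg,
            min_freq_cyc_per_um=self.min_freq_cyc_per_um,
            max_freq_cyc_per_um=self.max_freq_cyc_per_um,
            window=self.window,
            dc_block_radius_px=self.dc_block_radius_px,
        )


class MetabolicConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    input: str
    mask: Optional[str] = None
    denom_threshold: float = Field(0.0, ge=0)


class TrackConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    series_dir: str
    masks_dir: Optional[str] = None
    denom_threshold: float = Field(0.0, ge=0)
    drift_channel: str = "SHG"
    register_frames: bool = False


class AnalysisConfig(BaseModel):
    """Top-level config: one mode plus its stage parameters."""

    model_config = ConfigDict(extra="forbid")

    mode: Literal["simulate", "fibers", "metabolic", "longitudinal"]
    simulate: Optional[SimulateConfig] = None
    fibers: Optional[FiberAnalysisConfig] = None
    metabolic: Optional[MetabolicConfig] = None
    longitudinal: Optional[TrackConfig] = None
    out_dir: str = "."
    seed: int = 0


# --------------------------------------------------------------------------
# deterministic serialization
# --------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(x) for x in obj.tolist()]
    if isinstance(obj, BaseModel):
        return _jsonable(obj.model_dump())
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        d = dataclasses.asdict(obj)
        for derived in ("significant", "iqr"):  # computed properties
            if hasattr(type(obj), derived):
                d[derived] = getattr(obj, derived)
        return _jsonable(d)
    if isinstance(obj, pd.DataFrame):
        return {
            "index": _jsonable(obj.index.to_numpy()),
            "columns": list(map(str, obj.columns)),
            "data": _jsonable(obj.to_numpy()),
        }
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(x) for x in obj]
    return obj


def write_report(payload: dict, path: str | Path) -> Path:
    """Serialize a report deterministically (sorted keys, stable floats)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    text = json.dumps(_jsonable(payload), indent=2, sort_keys=True)
    path.write_text(text + "\n")
    return path


def _header(mode: str, config, seed: int) -> dict:
    return {
        "tool": "nloi",
        "version": __version__,
        "mode": mode,
        "seed": seed,
        "config": _jsonable(config),
    }


# --------------------------------------------------------------------------
# stage runners
# --------------------------------------------------------------------------

def run_simulate(config: SimulateConfig, out_dir: str | Path, seed: int) -> Path:
    """Generate a synthetic scene or series; write TIFFs + ground truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth_payload: dict = _header("simulate", config, seed)

    if config.kind == "fibers":
        scene = (config.fiber_scene or FiberSceneConfig()).model_copy(
            update={"seed": seed})
        raster, truth = generate_fiber_image(scene)
        frame = MultimodalFrame(channels={"SHG": raster},
                                pixel_size_um=scene.pixel_size_um,
                                frame_id="synthetic-fibers")
        write_frame(frame, out / "shg.tif")
        truth_payload["ground_truth"] = {
            "fiber_angles_deg": truth.fiber_angles_deg,
        }
    elif config.kind == "cells":
        scene = (config.cell_scene or CellSceneConfig()).model_copy(
            update={"seed": seed})
        frame, truth = generate_cell_scene(scene)
        if config.noise is not None:
            from .synthetic import apply_noise

            rng = np.random.default_rng(seed)
            frame = frame.copy()
            frame.channels = {
                k: apply_noise(v, config.noise, rng)
                for k, v in frame.channels.items()
            }
        write_frame(frame, out / "frame.tif")
        write_mask(SegmentationMask(truth.label_mask, source="ground_truth"),
                   out / "mask.tif")
        truth_payload["ground_truth"] = {"cell_orr": truth.cell_orr}
    else:  # series
        scene = (config.cell_scene or CellSceneConfig(
            orr_targets=(0.72, 0.86, 0.94))).model_copy(update={"seed": seed})
        base, base_truth = generate_cell_scene(scene)
        if config.fiber_scene is not None or not base.channel("SHG").any():
            # give the structural channel real content (collagen texture) so
            # drift is estimable on SHG, as with real tissue
            fib = (config.fiber_scene or FiberSceneConfig(
                fiber_length_um=min(40.0, 0.4 * min(scene.image_size_px)
                                    * scene.pixel_size_um),
            )).model_copy(update={
                "seed": seed + 1,
                "image_size_px": scene.image_size_px,
                "pixel_size_um": scene.pixel_size_um,
            })
            shg, _ = generate_fiber_image(fib)
            base.channels["SHG"] = shg
        decay = config.decay or DecayModel()
        frames, truth = generate_time_series(base, decay, config.noise,
                                             seed=seed, ground_truth=base_truth)
        for k, frame in enumerate(frames):
            write_frame(frame, out / f"frame_{k:03d}.tif")
        write_mask(SegmentationMask(base_truth.label_mask, source="ground_truth"),
                   out / "mask.tif")
        truth_payload["ground_truth"] = {
            "cell_orr": truth.cell_orr,
            "times_min": truth.times_min,
            "expected_channel_means": truth.expected_channel_means,
            "drift_um": truth.drift_um,
            "decay_fractions": truth.extras["decay_fractions"],
            "sts_rise_end_min": truth.extras["sts_rise_end_min"],
        }
    return write_report(truth_payload, out / "ground_truth.json")


def _load_shg(path: str | Path, pixel_size_um: float | None) -> tuple[np.ndarray, float]:
    """Load an SHG raster from a plain 2-D TIFF or a sidecar'd frame."""
    path = Path(path)
    sidecar = path.with_name(path.name + ".json")
    if sidecar.exists():
        frame = read_frame(path)
        return frame.channel("SHG"), frame.pixel_size_um
    arr = tifffile.imread(path)
    if arr.ndim == 3 and arr.shape[0] == 1:
        arr = arr[0]
    if pixel_size_um is None:
        raise NloiError("pixel size required for a bare TIFF (no sidecar)")
    return np.asarray(arr, dtype=float), float(pixel_size_um)


def run_fibers(config: FiberAnalysisConfig, out_path: str | Path, seed: int = 0,
               csv_path: str | Path | None = None) -> Path:
    """Fiber orientation analysis of one SHG image -> JSON (+ CSV histogram)."""
    raster, pixel_size = _load_shg(config.input, config.pixel_size_um)
    dist = angular_spectrum(raster, pixel_size, config.filter_params())
    result = alignment_ratio(dist)
    if csv_path is not None:
        pd.DataFrame({"angle_deg": dist.angles_deg,
                      "energy": dist.energies}).to_csv(csv_path, index=False)
    payload = _header("fibers", config, seed)
    payload["results"] = {
        "alignment_ratio": result.ar,
        "dominant_angle_deg": result.dominant_angle_deg,
        "n_angles": dist.n_angles,
        "angles_deg": dist.angles_deg,
        "energies": dist.energies,
        "pixel_size_um": pixel_size,
    }
    return write_report(payload, out_path)


def run_metabolic(config: MetabolicConfig, out_path: str | Path, seed: int = 0,
                  pixels_csv: str | Path | None = None) -> Path:
    """ORR + channel-profile report for one frame, optionally masked."""
    frame = read_frame(config.input)
    omap = orr_map(frame, config.denom_threshold)
    payload = _header("metabolic", config, seed)
    results: dict = {
        "channel_profile": channel_profile(frame),
        "whole_frame_orr": summarize(omap.valid_values()),
        "n_valid_pixels": int(omap.valid.sum()),
    }
    if config.mask is not None:
        mask = load_mask(config.mask)
        results["per_label_orr"] = {
            str(lab): s for lab, s in masked_summaries(omap, mask.labels).items()
        }
        pooled = omap.masked_values(mask.labels)
        if pooled.size:
            results["masked_orr"] = summarize(pooled)
        if pixels_csv is not None:
            rows = [
                {"label": lab, "orr": v}
                for lab, vals in omap.per_label_values(mask.labels).items()
                for v in vals
            ]
            pd.DataFrame(rows).to_csv(pixels_csv, index=False)
    payload["results"] = results
    return write_report(payload, out_path)


def run_compare(csv_paths: list[str | Path], out_path: str | Path,
                seed: int = 0) -> Path:
    """Kruskal-Wallis comparison of single-column CSV value files."""
    groups = [pd.read_csv(p).iloc[:, 0].to_numpy(dtype=float) for p in csv_paths]
    comparison = compare_groups(groups)
    payload = _header("compare", {"groups": [str(p) for p in csv_paths]}, seed)
    payload["results"] = comparison
    return write_report(payload, out_path)


def run_segment(in_path: str | Path, out_path: str | Path,
                diameter_um: float, channel: str = "2PF") -> SegmentationMask:
    """Built-in blob segmentation of one frame channel -> label TIFF."""
    frame = read_frame(in_path)
    mask = segment_frame(frame, diameter_um, channel)
    write_mask(mask, out_path)
    return mask


def run_track(config: TrackConfig, out_path: str | Path, seed: int = 0,
              csv_path: str | Path | None = None) -> Path:
    """Longitudinal report for a directory of frames (+ optional masks)."""
    try:
        frames = read_series(config.series_dir, "frame_*.tif")
    except FileNotFoundError:
        frames = read_series(config.series_dir)
    masks = None
    if config.masks_dir is not None:
        mask_paths = sorted(Path(config.masks_dir).glob("*.tif"))
        if len(mask_paths) == 1:
            masks = [load_mask(mask_paths[0])] * len(frames)
        else:
            if len(mask_paths) != len(frames):
                raise NloiError(
                    f"{len(mask_paths)} masks for {len(frames)} frames"
                )
            masks = [load_mask(p) for p in mask_paths]
    result = analyze_series(
        frames,
        masks=masks,
        denom_threshold=config.denom_threshold,
        drift_channel=config.drift_channel,
        register=config.register_frames,
    )
    if csv_path is not None:
        table = result.percent_change.copy()
        table.columns = [f"pct_change_{c}" for c in table.columns]
        table["orr_mean"] = [s.mean for s in result.orr_summaries]
        table["orr_median"] = [s.median for s in result.orr_summaries]
        table["orr_iqr"] = [s.iqr for s in result.orr_summaries]
        if result.drift_um is not None:
            table["drift_x_um"] = result.drift_um[:, 0]
            table["drift_y_um"] = result.drift_um[:, 1]
        table.to_csv(csv_path)
    payload = _header("longitudinal", config, seed)
    payload["results"] = {
        "times_min": result.times_min,
        "channel_means": result.channel_means,
        "percent_change": result.percent_change,
        "orr_summaries": result.orr_summaries,
        "orr_masked_summaries": result.orr_masked_summaries,
        "drift_um": result.drift_um,
        "comparison_timepoints": list(result.comparison_timepoints),
        "comparisons": {
            f"{i}-{j}": comp for (i, j), comp in result.comparisons.items()
        },
        "whole_frame_pixels": result.whole_frame_pixels,
    }
    return write_report(payload, out_path)


def run(config: AnalysisConfig) -> Path:
    """Dispatch one validated :class:`AnalysisConfig` to its stage runner."""
    out = Path(config.out_dir)
    if config.mode == "simulate":
        if config.simulate is None:
            raise NloiError("mode=simulate requires a 'simulate' section")
        return run_simulate(config.simulate, out, config.seed)
    if config.mode == "fibers":
        if config.fibers is None:
            raise NloiError("mode=fibers requires a 'fibers' section")
        out.mkdir(parents=True, exist_ok=True)
        return run_fibers(config.fibers, out / "fibers.json", config.seed,
                          csv_path=out / "fibers.csv")
    if config.mode == "metabolic":
        if config.metabolic is None:
            raise NloiError("mode=metabolic requires a 'metabolic' section")
        out.mkdir(parents=True, exist_ok=True)
        return run_metabolic(config.metabolic, out / "metabolic.json",
                             config.seed)
    if config.longitudinal is None:
        raise NloiError("mode=longitudinal requires a 'longitudinal' section")
    out.mkdir(parents=True, exist_ok=True)
    return run_track(config.longitudinal, out / "track.json", config.seed,
                     csv_path=out / "track.csv")
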