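"""Synthetic multichannel scenes with known ground truth.

No public image data accompanies the analyses this package implements, so
validation rests on simulated scenes whose generating parameters are known
exactly.  The generator emulates the statistical structure of fresh-tissue
multiphoton images:

* fibrous SHG textures rendered as additive anti-aliased line segments
  ("capsules") with a controllable orientation distribution — fixed angle,
  axial von Mises (concentration ``kappa``), or uniform — standing in for
  collagen networks that range from co-aligned tumor nests to dense random
  margins;
* cell-like disks whose two- and three-photon autofluorescence intensities
  are scaled so every interior pixel carries an exact target optical redox
  ratio ORR = 2PF/(2PF+3PF); membranes and lipid-droplet boundaries appear
  in THG, droplet interiors in 3PF;
* photon noise (Poisson at a configurable photons-per-unit-intensity scale)
  plus Gaussian detector read noise and offset;
* longitudinal series with per-channel linear intensity decay to a stated
  total fractional loss, lateral field-of-view drift with sub-pixel
  interpolation, and an optional rise-then-fall modulation of the 3PF
  channel mimicking the transient NAD(P)H increase after an apoptotic
  drug (staurosporine) is added.

Every generator is deterministic under a fixed seed and returns a
:class:`GroundTruth` recording what was imposed, so recovery tests never
re-derive the truth from the rendered pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import ndimage

from .errors import PlacementError, SceneConfigError
from .image_io import MultimodalFrame


# --------------------------------------------------------------------------
# configuration models
# --------------------------------------------------------------------------

class FiberSceneConfig(BaseModel):
    """Configuration for a fibrous SHG texture.

    ``orientation`` selects the angular law for fiber angles (degrees,
    undirected, i.e. taken modulo 180): ``fixed`` uses ``theta0_deg`` for
    every fiber, ``von_mises`` draws from an axial von Mises law centred on
    ``mu_deg`` with concentration ``kappa`` (``kappa=0`` is uniform), and
    ``uniform`` is isotropic.
    """

    model_config = ConfigDict(extra="forbid")

    image_size_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = Field(0.7, gt=0)
    n_fibers: int = Field(60, gt=0)
    orientation: Literal["fixed", "von_mises", "uniform"] = "uniform"
    theta0_deg: float = Field(0.0, ge=0, lt=180)
    mu_deg: float = Field(0.0, ge=0, lt=180)
    kappa: float = Field(0.0, ge=0)
    fiber_width_um: float = Field(2.0, gt=0)
    fiber_length_um: float = Field(60.0, gt=0)
    amplitude: float = Field(1.0, gt=0)
    background_level: float = Field(0.0, ge=0)
    seed: int = 0

    @model_validator(mode="after")
    def _check_geometry(self) -> "FiberSceneConfig":
        h, w = self.image_size_px
        if h < 1 or w < 1:
            raise SceneConfigError("image_size_px must be positive")
        diag_um = math.hypot(h, w) * self.pixel_size_um
        if self.fiber_length_um > diag_um:
            raise SceneConfigError(
                f"fiber_length_um={self.fiber_length_um} exceeds the image "
                f"diagonal ({diag_um:.1f} um)"
            )
        if self.fiber_width_um < self.pixel_size_um:
            raise SceneConfigError("fibers must be at least one pixel wide")
        return self


class CellSceneConfig(BaseModel):
    """Configuration for a cell-like metabolic scene.

    ``orr_targets`` gives one target optical redox ratio in (0, 1] per cell;
    interior 2PF and 3PF are ``total_pf_brightness * orr`` and
    ``total_pf_brightness * (1 - orr)`` so the per-pixel ratio is exact.
    Cell radius defaults to 5 um (10 um diameter hepatocyte-scale cells).
    """

    model_config = ConfigDict(extra="forbid")

    image_size_px: tuple[int, int] = (256, 256)
    pixel_size_um: float = Field(0.35, gt=0)
    orr_targets: tuple[float, ...] = ()
    cell_radius_um: float = Field(5.0, gt=0)
    total_pf_brightness: float = Field(1.0, gt=0)
    n_lipid_droplets: int = Field(0, ge=0)
    droplet_radius_um: float = Field(1.5, gt=0)
    membrane_thg_level: float = Field(1.0, ge=0)
    background_level: float = Field(0.0, ge=0)
    seed: int = 0

    @property
    def n_cells(self) -> int:
        return len(self.orr_targets)

    @model_validator(mode="after")
    def _check(self) -> "CellSceneConfig":
        for orr in self.orr_targets:
            if not 0 < orr <= 1:
                raise SceneConfigError(f"ORR target {orr} outside (0, 1]")
        return self


class NoiseModel(BaseModel):
    """Photon (Poisson) + detector (Gaussian) noise model.

    ``photon_scale`` is the expected photon count produced by unit
    intensity; around 40 photons is the regime where ratio imaging starts
    to be reliable, and the default reflects that.  ``read_noise_sd`` and
    ``offset`` are in intensity units.  Output is clipped at zero.
    """

    model_config = ConfigDict(extra="forbid")

    photon_scale: float = Field(40.0, gt=0)
    read_noise_sd: float = Field(0.0, ge=0)
    offset: float = Field(0.0, ge=0)


class StsResponse(BaseModel):
    """Rise-then-fall multiplicative modulation of the 3PF channel.

    The factor climbs linearly from 1 at t=0 to ``1 + amplitude`` at
    ``rise_end_min``, then relaxes linearly back to 1 at the end of the
    series — a minimal unimodal stand-in for the transient NAD(P)H
    autofluorescence increase after an apoptotic inducer is perfused.
    """

    model_config = ConfigDict(extra="forbid")

    amplitude: float = Field(1.0, gt=0)
    rise_end_min: float = Field(30.0, gt=0)


class DecayModel(BaseModel):
    """Longitudinal degradation model for a frame series.

    ``decay_fractions`` maps channel name to the total fractional intensity
    loss over ``duration_min`` (0.25 means the channel ends at 75% of its
    initial level); the trajectory is linear in time.  ``drift_um_total``
    is the cumulative lateral field-of-view drift (dx, dy) in micrometres,
    applied linearly over the series with sub-pixel interpolation.
    """

    model_config = ConfigDict(extra="forbid")

    decay_fractions: dict[str, float] = Field(
        default_factory=lambda: {"2PF": 0.25, "3PF": 0.60, "SHG": 0.30, "THG": 0.65}
    )
    duration_min: float = Field(62.0, gt=0)
    n_frames: int = Field(8, ge=2)
    drift_um_total: tuple[float, float] = (0.0, 0.0)
    sts_response: Optional[StsResponse] = None

    @model_validator(mode="after")
    def _check(self) -> "DecayModel":
        for name, frac in self.decay_fractions.items():
            if not 0 <= frac < 1:
                raise SceneConfigError(
                    f"decay fraction for {name} must lie in [0, 1)"
                )
        return self


# --------------------------------------------------------------------------
# ground truth carrier
# --------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Imposed parameters of a synthetic scene or series."""

    fiber_angles_deg: np.ndarray | None = None
    cell_orr: np.ndarray | None = None
    label_mask: np.ndarray | None = None
    times_min: np.ndarray | None = None
    #: noise-free per-frame channel means (rows: time, columns: channel)
    expected_channel_means: pd.DataFrame | None = None
    #: imposed cumulative drift per frame, (dx, dy) micrometres
    drift_um: np.ndarray | None = None
    extras: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# fiber scenes
# --------------------------------------------------------------------------

def sample_fiber_angles(config: FiberSceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n_fibers`` undirected angles in [0, 180) per the config's law.

    Axial von Mises sampling uses the doubled-angle construction: draw from
    a von Mises on the circle and halve, so the doubled angles have circular
    mean ``2 * mu_deg``.
    """
    n = config.n_fibers
    if config.orientation == "fixed":
        return np.full(n, config.theta0_deg, dtype=float)
    if config.orientation == "uniform":
        return rng.uniform(0.0, 180.0, size=n)
    draws = rng.vonmises(0.0, config.kappa, size=n)  # radians in (-pi, pi]
    return (config.mu_deg + np.degrees(draws) / 2.0) % 180.0


def _render_capsule(
    image: np.ndarray,
    center: tuple[float, float],
    angle_deg: float,
    length_px: float,
    halfwidth_px: float,
    amplitude: float,
) -> None:
    """Additively draw one anti-aliased capsule (segment with round caps).

    The intensity profile ramps linearly from ``amplitude`` inside the
    half-width to zero one pixel outside it.  Angle convention: degrees from
    the +x (column) axis toward +y (row), matching the analysis module.
    """
    h, w = image.shape
    cy, cx = center
    theta = math.radians(angle_deg)
    ux, uy = math.cos(theta), math.sin(theta)
    half = length_px / 2.0
    pad = halfwidth_px + 2.0
    y0 = max(0, int(math.floor(cy - abs(uy) * half - pad)))
    y1 = min(h, int(math.ceil(cy + abs(uy) * half + pad)) + 1)
    x0 = max(0, int(math.floor(cx - abs(ux) * half - pad)))
    x1 = min(w, int(math.ceil(cx + abs(ux) * half + pad)) + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    ry = yy - cy
    rx = xx - cx
    t = np.clip(rx * ux + ry * uy, -half, half)  # projection onto the axis
    d = np.hypot(rx - t * ux, ry - t * uy)
    profile = np.clip(halfwidth_px + 1.0 - d, 0.0, 1.0) * amplitude
    image[y0:y1, x0:x1] += profile


def generate_fiber_image(config: FiberSceneConfig) -> tuple[np.ndarray, GroundTruth]:
    """Render a fibrous SHG raster; return it with the sampled angles.

    Fibers are placed with centers uniform over the image; overlaps add.
    The returned :class:`GroundTruth` records every sampled angle, so
    orientation-recovery tests compare against the imposed sample rather
    than a re-estimate.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.image_size_px
    angles = sample_fiber_angles(config, rng)
    centers = np.column_stack([rng.uniform(0, h, config.n_fibers),
                               rng.uniform(0, w, config.n_fibers)])
    image = np.full((h, w), float(config.background_level))
    length_px = config.fiber_length_um / config.pixel_size_um
    halfwidth_px = config.fiber_width_um / (2.0 * config.pixel_size_um)
    for (cy, cx), ang in zip(centers, angles):
        _render_capsule(image, (cy, cx), ang, length_px, halfwidth_px,
                        config.amplitude)
    truth = GroundTruth(fiber_angles_deg=angles,
                        extras={"centers_px": centers})
    return image, truth


# --------------------------------------------------------------------------
# cell scenes
# --------------------------------------------------------------------------

def _place_disks(
    rng: np.random.Generator,
    shape: tuple[int, int],
    n: int,
    radius_px: float,
    occupied: list[tuple[float, float, float]],
    max_attempts: int = 10_000,
) -> list[tuple[float, float]]:
    """Rejection-sample ``n`` disk centers avoiding ``occupied`` disks.

    ``occupied`` holds (cy, cx, radius) triples and is extended in place.
    Raises :class:`PlacementError` when a disk cannot be placed within the
    attempt budget.
    """
    h, w = shape
    margin = radius_px + 2.0
    if 2 * margin >= h or 2 * margin >= w:
        raise PlacementError(f"disks of radius {radius_px:.1f}px do not fit")
    centers: list[tuple[float, float]] = []
    for i in range(n):
        for _ in range(max_attempts):
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            ok = all(
                math.hypot(cy - oy, cx - ox) > radius_px + orad + 2.0
                for oy, ox, orad in occupied
            )
            if ok:
                centers.append((cy, cx))
                occupied.append((cy, cx, radius_px))
                break
        else:
            raise PlacementError(
                f"could not place disk {i + 1}/{n} in {max_attempts} attempts"
            )
    return centers


def generate_cell_scene(config: CellSceneConfig) -> tuple[MultimodalFrame, GroundTruth]:
    """Build a noise-free four-channel cell scene with exact per-cell ORR.

    For cell ``i`` every interior pixel satisfies
    ``2PF / (2PF + 3PF) == orr_targets[i]`` exactly.  THG is nonzero only on
    cell membranes and lipid-droplet boundary rings; droplet interiors add
    3PF (lipids fluoresce strongly in that channel).  The label mask labels
    cells 1..n in target order, background 0; droplets are unlabeled.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.image_size_px
    r_px = config.cell_radius_um / config.pixel_size_um
    dr_px = config.droplet_radius_um / config.pixel_size_um

    occupied: list[tuple[float, float, float]] = []
    cell_centers = _place_disks(rng, (h, w), config.n_cells, r_px, occupied)
    droplet_centers = (
        _place_disks(rng, (h, w), config.n_lipid_droplets, dr_px, occupied)
        if config.n_lipid_droplets
        else []
    )

    pf2 = np.full((h, w), float(config.background_level))
    pf3 = np.full((h, w), float(config.background_level))
    shg = np.full((h, w), float(config.background_level))
    thg = np.full((h, w), float(config.background_level))
    labels = np.zeros((h, w), dtype=np.int32)

    yy, xx = np.mgrid[0:h, 0:w]
    ring_px = 1.5  # membrane thickness in pixels
    for i, (cy, cx) in enumerate(cell_centers):
        d = np.hypot(yy - cy, xx - cx)
        interior = d <= r_px
        membrane = (d > r_px) & (d <= r_px + ring_px)
        orr = config.orr_targets[i]
        pf2[interior] = config.total_pf_brightness * orr
        pf3[interior] = config.total_pf_brightness * (1.0 - orr)
        thg[membrane] = config.membrane_thg_level
        labels[interior] = i + 1
    for cy, cx in droplet_centers:
        d = np.hypot(yy - cy, xx - cx)
        interior = d <= dr_px
        boundary = (d > dr_px) & (d <= dr_px + ring_px)
        pf3[interior] = config.total_pf_brightness
        thg[boundary] = config.membrane_thg_level

    frame = MultimodalFrame(
        channels={"2PF": pf2, "3PF": pf3, "SHG": shg, "THG": thg},
        pixel_size_um=config.pixel_size_um,
        frame_id="synthetic-cells",
    )
    truth = GroundTruth(
        cell_orr=np.asarray(config.orr_targets, dtype=float),
        label_mask=labels,
        extras={
            "cell_centers_px": np.asarray(cell_centers, dtype=float),
            "droplet_centers_px": np.asarray(droplet_centers, dtype=float),
            "cell_radius_px": r_px,
        },
    )
    return frame, truth


# --------------------------------------------------------------------------
# noise
# --------------------------------------------------------------------------

def apply_noise(
    raster: np.ndarray,
    model: NoiseModel,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Apply photon + detector noise to a non-negative raster.

    Output = Poisson(photon_scale * input) / photon_scale
    + Gaussian(0, read_noise_sd) + offset, clipped at zero.
    """
    arr = np.asarray(raster, dtype=np.float64)
    if arr.size and arr.min() < 0:
        raise ValueError("noise model requires non-negative input")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = rng.poisson(model.photon_scale * arr).astype(np.float64) / model.photon_scale
    if model.read_noise_sd > 0:
        out += rng.normal(0.0, model.read_noise_sd, size=arr.shape)
    out += model.offset
    return np.clip(out, 0.0, None)


# --------------------------------------------------------------------------
# longitudinal series
# --------------------------------------------------------------------------

def sts_factor(t_min: float, sts: StsResponse, duration_min: float) -> float:
    """Multiplicative 3PF modulation at time ``t_min`` (piecewise linear)."""
    if t_min <= sts.rise_end_min:
        return 1.0 + sts.amplitude * t_min / sts.rise_end_min
    tail = duration_min - sts.rise_end_min
    if tail <= 0:
        return 1.0 + sts.amplitude
    return 1.0 + sts.amplitude * max(0.0, (duration_min - t_min) / tail)


def generate_time_series(
    base: MultimodalFrame,
    decay: DecayModel,
    noise: NoiseModel | None = None,
    seed: int = 0,
    ground_truth: GroundTruth | None = None,
) -> tuple[list[MultimodalFrame], GroundTruth]:
    """Degrade a noise-free base frame into a longitudinal series.

    Frame ``k`` at time ``t_k`` (uniform grid over ``duration_min``) has
    each channel scaled by its linear decay trajectory ``1 - f_c * t/T``,
    translated by the cumulative drift (bilinear sub-pixel interpolation
    with periodic wraparound, emulating a field of view moving across
    statistically homogeneous tissue so new content enters as old content
    leaves and the frame mean is conserved), the 3PF channel additionally
    modulated by the staurosporine-response profile if configured, and
    finally noised.

    The returned ground truth records frame times, imposed per-frame drift,
    and the noise-free expected channel means (measured on the transformed
    rasters, so they remain exact under drift-induced edge loss).
    """
    times = np.linspace(0.0, decay.duration_min, decay.n_frames)
    h, w = base.shape
    dx_total, dy_total = decay.drift_um_total
    drift_px_total = (abs(dx_total) / base.pixel_size_um,
                      abs(dy_total) / base.pixel_size_um)
    if drift_px_total[0] >= w or drift_px_total[1] >= h:
        raise SceneConfigError("total drift pushes the scene fully out of frame")
    for name in decay.decay_fractions:
        if name not in base.channels:
            raise SceneConfigError(f"decay names absent channel {name!r}")

    rng = np.random.default_rng(seed)
    frames: list[MultimodalFrame] = []
    drift_rows = np.zeros((decay.n_frames, 2))
    mean_rows = []
    for k, t in enumerate(times):
        frac_t = t / decay.duration_min
        dx_um = dx_total * frac_t
        dy_um = dy_total * frac_t
        drift_rows[k] = (dx_um, dy_um)
        shift_px = (dy_um / base.pixel_size_um, dx_um / base.pixel_size_um)
        channels: dict[str, np.ndarray] = {}
        means: dict[str, float] = {}
        for name, raster in base.channels.items():
            scale = 1.0 - decay.decay_fractions.get(name, 0.0) * frac_t
            if name == "3PF" and decay.sts_response is not None:
                scale *= sts_factor(t, decay.sts_response, decay.duration_min)
            out = raster * scale
            if shift_px != (0.0, 0.0):
                out = ndimage.shift(out, shift_px, order=1, mode="grid-wrap",
                                    prefilter=False)
            means[name] = float(out.mean())
            if noise is not None:
                out = apply_noise(out, noise, rng)
            channels[name] = out
        mean_rows.append(means)
        frames.append(MultimodalFrame(
            channels=channels,
            pixel_size_um=base.pixel_size_um,
            time_min=float(t),
            frame_id=f"t{k:03d}",
        ))

    truth = GroundTruth(
        cell_orr=None if ground_truth is None else ground_truth.cell_orr,
        label_mask=None if ground_truth is None else ground_truth.label_mask,
        fiber_angles_deg=None if ground_truth is None else ground_truth.fiber_angles_deg,
        times_min=times,
        expected_channel_means=pd.DataFrame(mean_rows, index=times),
        drift_um=drift_rows,
        extras={
            "decay_fractions": dict(decay.decay_fractions),
            "sts_rise_end_min": (
                None if decay.sts_response is None
                else decay.sts_response.rise_end_min
            ),
        },
    )
    return frames, truth
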