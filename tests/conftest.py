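"""Shared fixtures: small synthetic scenes with exact ground truth."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from nloi import (
    CellSceneConfig,
    FiberSceneConfig,
    MultimodalFrame,
    generate_cell_scene,
    generate_fiber_image,
)


@pytest.fixture(scope="session")
def cell_scene():
    """Noise-free three-cell scene with ORR targets 0.72 / 0.86 / 0.94."""
    config = CellSceneConfig(
        image_size_px=(192, 192),
        orr_targets=(0.72, 0.86, 0.94),
        n_lipid_droplets=2,
        seed=11,
    )
    frame, truth = generate_cell_scene(config)
    return config, frame, truth


@pytest.fixture
def fiber_scene_factory():
    """Factory for fibrous SHG rasters at a requested orientation law."""

    def make(orientation="fixed", theta0=30.0, kappa=0.0, n_fibers=60,
             seed=7, size=(512, 512), **kw):
        config = FiberSceneConfig(
            image_size_px=size,
            orientation=orientation,
            theta0_deg=theta0 % 180.0,
            mu_deg=theta0 % 180.0,
            kappa=kappa,
            n_fibers=n_fibers,
            seed=seed,
            **kw,
        )
        return generate_fiber_image(config) + (config,)

    return make


@pytest.fixture
def simple_frame():
    """Tiny deterministic four-channel frame for plumbing tests."""
    rng = np.random.default_rng(0)
    base = rng.uniform(0.1, 1.0, size=(32, 32))
    return MultimodalFrame(
        channels={"2PF": base, "3PF": base * 0.5, "SHG": base * 2.0,
                  "THG": base * 0.25},
        pixel_size_um=0.35,
        time_min=0.0,
        frame_id="simple",
    )
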