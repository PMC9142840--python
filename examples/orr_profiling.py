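"""Metabolic profiling: pixel-wise optical redox ratio under a cell mask.

Builds a noise-free scene of cells with known ORR = 2PF/(2PF+3PF) targets,
adds photon noise at the ~40-photon regime, and recovers per-cell ORR
through the segmentation-masked statistics.
"""

import numpy as np

from nloi import (
    CellSceneConfig,
    NoiseModel,
    apply_noise,
    channel_profile,
    generate_cell_scene,
    masked_summaries,
    orr_map,
)

config = CellSceneConfig(image_size_px=(256, 256),
                         orr_targets=(0.72, 0.86, 0.94),
                         n_lipid_droplets=3, seed=2)
frame, truth = generate_cell_scene(config)

rng = np.random.default_rng(2)
noisy = frame.copy()
noisy.channels = {k: apply_noise(v, NoiseModel(photon_scale=40.0), rng)
                  for k, v in frame.channels.items()}

print("per-cell mean ORR (target -> noise-free -> 40-photon noise):")
clean = masked_summaries(orr_map(frame), truth.label_mask)
degraded = masked_summaries(orr_map(noisy), truth.label_mask)
for i, target in enumerate(config.orr_targets, start=1):
    print(f"  cell {i}: {target:.2f} -> {clean[i].mean:.4f} "
          f"-> {degraded[i].mean:.4f}  (IQR {degraded[i].iqr:.3f})")

profile = channel_profile(frame)
print("\nwhole-frame channel means (radar-plot input):")
for chan, mean in profile.items():
    print(f"  {chan}: {mean:.4f}")

print("\nNoise-free recovery is exact by construction; under Poisson photon")
print("noise at ~40 photons per unit intensity the per-cell means stay")
print("within about 0.02 of the imposed redox ratios.")
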