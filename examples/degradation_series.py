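"""Longitudinal tissue degradation: intensity decay, drift, and rising ORR.

Reproduces the degradation-monitoring analysis on a synthetic series: each
channel decays by its own fraction over ~1 h, the field of view drifts
15 um, and the ORR climbs because 3PF (NAD(P)H) fades faster than 2PF
(FAD).
"""

from nloi import (
    CellSceneConfig,
    DecayModel,
    FiberSceneConfig,
    analyze_series,
    generate_cell_scene,
    generate_fiber_image,
    generate_time_series,
)

scene = CellSceneConfig(image_size_px=(256, 256), orr_targets=(0.94,) * 6,
                        seed=3)
frame, truth = generate_cell_scene(scene)
shg, _ = generate_fiber_image(FiberSceneConfig(
    image_size_px=(256, 256), pixel_size_um=scene.pixel_size_um,
    orientation="uniform", n_fibers=40, fiber_length_um=40.0, seed=4))
frame.channels["SHG"] = shg

decay = DecayModel(
    decay_fractions={"2PF": 0.25, "3PF": 0.60, "SHG": 0.30, "THG": 0.65},
    duration_min=62.0, n_frames=6, drift_um_total=(15.0, 0.0))
frames, _ = generate_time_series(frame, decay, seed=5, ground_truth=truth)

result = analyze_series(frames)

print("percent intensity change vs t=0 (final frame):")
for chan, value in result.percent_change.iloc[-1].items():
    print(f"  {chan}: {value:+.1f}%")

print(f"\nestimated lateral drift at t=62 min: "
      f"({result.drift_um[-1][0]:.2f}, {result.drift_um[-1][1]:.2f}) um")

print("\nwhole-frame mean ORR trajectory:")
for t, s in zip(result.times_min, result.orr_summaries):
    print(f"  t={t:5.1f} min: mean ORR {s.mean:.3f} (IQR {s.iqr:.3f})")

print("\nThe recovered changes equal the imposed decay fractions; the drift")
print("matches the imposed 15 um; the ORR rises because the denominator")
print("channel (3PF) decays faster — the signature of metabolic decay.")
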