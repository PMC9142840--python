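"""Collagen fiber orientation from an SHG image via the Fourier wedge filter.

Builds two synthetic SHG scenes — one with co-aligned fibers (a tumor-nest
archetype) and one with isotropic fibers (a dense-network margin archetype)
— and compares their angular histograms.
"""

from nloi import FiberSceneConfig, analyze_fibers, generate_fiber_image

aligned_cfg = FiberSceneConfig(orientation="fixed", theta0_deg=30.0, seed=1)
random_cfg = FiberSceneConfig(orientation="uniform", seed=1)

for name, cfg in (("aligned (30 deg)", aligned_cfg), ("isotropic", random_cfg)):
    image, truth = generate_fiber_image(cfg)
    result = analyze_fibers(image, cfg.pixel_size_um)
    print(f"{name:18s} dominant angle = {result.dominant_angle_deg:6.1f} deg, "
          f"alignment ratio AR = {result.ar:5.2f}")

print()
print("AR is the peak/mean of the angular energy histogram: ~1 for an")
print("isotropic fiber network, larger the more co-aligned the fibers are.")
print("The dominant angle of the aligned scene recovers the imposed 30 deg.")
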