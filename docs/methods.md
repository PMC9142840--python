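# Methods

This note documents the models and procedures implemented in `nloi`, the
parameter choices that matter, what the synthetic scenes do and do not
emulate, and the numerical conventions used throughout.

## Image model and conventions

A frame is a set of co-registered 2-D non-negative intensity rasters, one
per channel in {2PF, 3PF, SHG, THG}, with an isotropic pixel size in µm
and an acquisition time in minutes.  Typical geometries are 500 × 500 px
at ~0.7 µm/px (≈350 µm field of view) for tumor imaging and 600 × 600 px
at 0.35 µm/px (≈210 µm) for liver imaging; the reader accepts 8/16-bit
and float TIFF and promotes to float64 without assuming a detector
maximum.  Coordinates are row-major with the origin at the top-left;
angles are measured in degrees from the +x (column) axis toward the +y
(row) axis and, being fiber orientations, are taken modulo 180°.  Drift
vectors are (dx, dy) in µm in the same frame.

Display transforms follow common practice: each channel is independently
contrast-stretched so that the top fraction (default 5%) of intensities
saturates — the upper bound is the (1 − f) quantile under the
linear-interpolation convention used everywhere in the package — then
tinted and summed with clipping for pseudo-color merges.  A constant
raster has no defined stretch and maps to zeros with a warning.

## Fourier-domain fiber orientation analysis

The SHG raster is center-cropped to square (isotropic frequency
sampling), mean-subtracted, multiplied by a periodic Hann window, and
Fourier transformed.  The power spectrum is accumulated within rotating
angular wedges: bin with spectral angle φ belongs to the wedge centred at
θ when |((φ + 90°) − θ) mod 180°| ≤ half-width — the +90° term converts
spectral angles to fiber angles, since a spatial fiber at θ concentrates
energy along θ + 90° (the classic FT-SHG pitfall, handled internally so
the API only ever reports fiber angles).  A DC disc (default 3 px) and
out-of-band radial frequencies (default band 0.05 cyc/µm to Nyquist) are
excluded; wedge energies are normalized to sum to 1.

**Angular resolution and the wedge grid.**  The default grid is 90 wedges
of 2° (abutting: half-width 1°).  The spectral ridge of a fiber of length
L px has transverse width ≈ N/L frequency bins, so at the energy-dominant
low radii its angular width is several degrees; a 1° grid over-resolves
it, and the histogram argmax then jitters by several degrees between
neighbouring bins and lattice-aligned directions (atan(1/2), atan(1/3),
the axes — where DFT bins line up exactly).  A dense scan over imposed
angles and seeds at the 512-px scene scale shows worst-case argmax error
of 1.5° at the 2° grid versus up to 5° at a 1° grid.  Finer grids remain
available through `AngularFilterParams` for large, strongly aligned
images.

Membership is hard (binary), which keeps the estimator identical to a
per-bin brute-force loop (tested to 1e-6 relative).  The alignment ratio
AR = max/mean of the histogram is 1 exactly for a flat distribution and
equals the bin count for a one-hot one; because of that bin-count
dependence, AR values are comparable only at equal binning.  Ties in the
peak break toward the smaller angle.  Constant rasters raise a
degenerate-spectrum error rather than returning a meaningless histogram.

## Optical redox ratio and distribution statistics

ORR = 2PF / (2PF + 3PF) per pixel, defined where 2PF + 3PF exceeds a
validity floor (default 0, i.e. only true-zero pixels are invalid; a
positive floor is recommended on detectors with offset, which otherwise
pushes background ORR toward 0.5).  Summaries report n, mean, median,
sample SD (ddof = 1), 25th/75th percentiles and IQR = p75 − p25, all with
linear-interpolation percentiles.  Whole-frame and mask-restricted
pooling are both first-class, because real analyses mix frame averages
with segmented per-cell statistics; reports label which pixel set was
used.

Group comparisons use the tie-corrected Kruskal–Wallis H with its
chi-squared p-value; "not significant" means p > 0.05 exactly.  For three
or more groups all pairwise two-group tests are reported with raw and
Holm-adjusted p-values — the adjustment is surfaced rather than silently
applied, since pairwise rank tests are often reported unadjusted.  A
comparison in which every pooled value is identical returns H = 0, p = 1
(nothing to rank), except the fully degenerate all-identical-singletons
case, which is an error.

## Segmentation

Real-tissue cell segmentation is an external concern: the package ingests
label masks produced by third-party instance segmenters (run on the 2PF
channel in the intended workflow) from integer TIFF, canonicalizing
labels to contiguous 1..n and splitting binary masks into 4-connected
components.  4-connectivity avoids diagonally bridging adjacent cells.
One mask is applied identically to every channel, so per-region
statistics always use the same pixel sets.

The built-in blob segmenter exists for synthetic fixtures and simple
well-separated cells: Gaussian smoothing at one quarter of the expected
diameter (FWHM), Otsu threshold, a contrast guard that returns an empty
mask when foreground and background are not separated by at least 4
background standard deviations (Otsu always "finds" a split, even in pure
noise), removal of components below 25% of the expected blob area, and a
watershed split of merged blobs seeded by local maxima at least half a
diameter apart.  It is deterministic and is not a substitute for a
learned segmenter on real tissue.

## Longitudinal analysis

Percent change per channel is 100 × (mean_t − mean_0)/mean_0 over whole
frames (a channel with zero initial mean yields NaN with a warning,
leaving the others intact).  By default no drift correction is applied
before computing trajectories — the drifting field of view is analyzed
as-is, with registration available as an option — and drift itself is
estimated by phase correlation with sub-pixel refinement (upsampled
cross-correlation, default 1/50 px) on the SHG channel, which is
structural and decays least.  The sign convention is the displacement the
scene underwent: drift(A→B) = −drift(B→A).

Timepoint comparisons default to first/middle/last, mirroring the
start/middle/end reporting common in hour-scale degradation experiments.

## Synthetic scenes: what they emulate, and what they do not

The generator provides the ground-truth-bearing inputs used for all
validation; its defaults are the study conditions the package is tested
under.

* **Fiber scenes** (512 × 512 px, 0.7 µm/px, 60 fibers of 60 × 2 µm,
  rendered as additive anti-aliased capsules): orientation laws are
  fixed-angle, axial von Mises (doubled-angle construction; κ = 0 is
  uniform), or uniform — spanning the co-aligned "tumor nest" and
  isotropic "dense network" archetypes.  Rendering is intensity-additive;
  coherent SHG speckle and phase effects are not modeled, so the spectra
  are smoother than real SHG.  No PSF convolution is applied.
* **Cell scenes** (0.35 µm/px, 5 µm cell radius ≈ 10 µm hepatocyte-scale
  diameter): non-overlapping disks placed by rejection sampling (10⁴
  attempts per object), interior 2PF/3PF scaled so every interior pixel
  carries its cell's target ORR exactly; THG only on membranes and
  droplet rings; droplet interiors are 3PF-bright.  Real cells have
  textured interiors and overlapping neighbours; exact interiors are what
  make machine-precision recovery tests meaningful, not realistic.
* **Noise**: Poisson photon statistics at a configurable photon scale
  (default 40 photons per unit intensity — the regime where ratio imaging
  becomes reliable) plus Gaussian read noise and offset, clipped at zero.
* **Series**: linear per-channel decay to a stated total fraction (only
  endpoint losses are constrained by observation; linear is the simplest
  consistent shape and is pluggable), lateral drift applied linearly over
  time with bilinear sub-pixel interpolation and periodic wraparound —
  emulating a field of view moving across statistically homogeneous
  tissue, so new content enters as old content leaves and frame means are
  conserved exactly.  The drug-response profile multiplies 3PF by a
  piecewise-linear factor rising to 1 + amplitude at a configurable
  turning time and relaxing to 1 at the series end; only the direction
  and approximate turning time of the real transient are constrained, so
  the amplitude is a free parameter.  Axial (z) drift and the
  discontinuous jumps seen in real series are not modeled.

Passing recovery tests on these scenes demonstrates the correctness of
the estimators under controlled conditions; it does not certify accuracy
on real tissue, where segmentation quality, spectral cross-talk (lipid
and vitamin A autofluorescence overlapping NAD(P)H), axial drift and
coherent image formation all add error sources outside this model.

## Determinism and reporting

All generators draw from `numpy.random.default_rng` seeded explicitly and
are bit-reproducible.  Pipeline reports embed the producing config and
seed and serialize with sorted keys and no timestamps, so any report is
byte-identically regenerable from its own header.  Problem sizes used in
the shipped validation runs (256–512 px scenes, 6–13 frame series, 10
seeds per alignment-ratio condition, 1000-replicate null calibration)
were chosen as the smallest at which the recovery claims are stable.
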