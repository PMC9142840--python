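# nloi — quantitative multimodal nonlinear optical image analysis

`nloi` analyzes four-channel label-free nonlinear optical microscopy images
of fresh tissue: two- and three-photon autofluorescence (**2PF**, **3PF**,
dominated by FAD and NAD(P)H respectively), second-harmonic generation
(**SHG**, collagen fibers) and third-harmonic generation (**THG**,
membranes and lipid-droplet boundaries).  It is aimed at groups doing
point-of-procedure assessment of fresh biopsy tissue, where quantitative
readouts must come from intensity images alone, without stains, fixation,
or slow morphology-based processing.

Three readouts are implemented, plus the synthetic scenes used to
validate them:

* **Collagen fiber orientation (FT-SHG).**  The 2-D power spectrum of the
  SHG channel is integrated over a rotating angular wedge, giving a
  normalized angular energy histogram E(θ) on [0°, 180°).  A fiber at
  angle θ concentrates spectral energy at θ ± 90°; the 90° mapping is
  applied internally so reported angles are fiber angles.  Two summaries
  are derived: the dominant angle argmaxθ E(θ) and the **alignment ratio**

      AR = max(E) / mean(E)

  which is 1 for an isotropic network and grows with fiber co-alignment
  (AR depends on the histogram binning; compare values only at equal
  binning).  The method is non-iterative and insensitive to overall
  signal strength.

* **Metabolic profiling (optical redox ratio).**  Pixel-wise

      ORR = 2PF / (2PF + 3PF)  ≈  FAD / (FAD + NAD(P)H)

  with a validity mask (denominator above a configurable floor), summarized
  whole-frame or under a cell segmentation mask applied identically to all
  channels: n, mean, median, SD, quartiles and IQR (linear-interpolation
  percentiles).  Lower ORR indicates relatively more NAD(P)H, i.e. more
  glycolytic metabolism.  Group differences use the tie-corrected
  Kruskal–Wallis rank test (p > 0.05 read as not significant), with
  raw + Holm-adjusted pairwise p-values for 3+ groups.

* **Longitudinal monitoring.**  For an ordered frame series: per-channel
  percent intensity change vs t = 0, ORR distribution trajectories
  (whole-frame and masked), lateral drift by sub-pixel phase correlation
  on the structural SHG channel, and rank-based comparisons between
  selected timepoints.  This quantifies tissue degradation (channel-specific
  decay, rising ORR as 3PF fades faster than 2PF) and transient drug
  responses (an apoptotic inducer transiently raises 3PF, dipping the ORR).

The synthetic generator (`nloi.synthetic`) renders fiber scenes with a
controllable orientation law (fixed / axial von Mises / uniform), cell
scenes carrying exact per-cell ORR, Poisson photon + Gaussian read noise,
and longitudinal series with programmed decay, drift, and drug-response
profiles — every generated scene returns its ground truth, so all analyses
are validated by parameter recovery.

## Worked example

`examples/degradation_series.py` builds a 62-minute synthetic series of
cells (ORR 0.94) over a collagen texture, with per-channel decay fractions
25 / 60 / 30 / 65 % and a 15 µm lateral drift, then analyzes it:

```
percent intensity change vs t=0 (final frame):
  2PF: -25.0%
  3PF: -60.0%
  SHG: -30.0%
  THG: -65.0%

estimated lateral drift at t=62 min: (15.03, -0.00) um

whole-frame mean ORR trajectory:
  t=  0.0 min: mean ORR 0.940 (IQR 0.000)
  t= 24.8 min: mean ORR 0.949 (IQR 0.000)
  t= 62.0 min: mean ORR 0.967 (IQR 0.000)
```

The recovered percent changes equal the imposed decay fractions exactly
(noise-free), the drift estimate matches the imposed 15 µm to a small
fraction of a pixel, and the mean ORR climbs from 0.94 to 0.97 purely
because the 3PF denominator decays faster — the metabolic-decay signature
the longitudinal analysis is designed to detect.  The other examples cover
fiber orientation (`fiber_orientation.py`: AR 30.5 for a co-aligned scene
vs 6.8 for an isotropic one, dominant angle recovered at 30°), masked ORR
recovery under photon noise (`orr_profiling.py`), and the drug-response
dip (`drug_response.py`: median ORR 0.86 → 0.74 at t = 40 min → 0.92).

## Command line

A thin CLI mirrors the library for shell pipelines; every report embeds
its config and seed and serializes deterministically:

```bash
nloi simulate series --config cfg.json --out data/ --seed 1
nloi fibers --in shg.tif --pixel-size 0.7 --out fibers.json --csv hist.csv
nloi orr --in frame.tif --mask mask.tif --out orr.json
nloi segment --in frame.tif --channel 2PF --diameter-um 10 --out mask.tif
nloi compare --groups a.csv --groups b.csv --out cmp.json
nloi track --series data/ --out report.json --csv report.csv
```

Frames are multi-page TIFF with a JSON sidecar (`channels`,
`pixel_size_um` or `fov_um`, `time_min`); masks are single-channel integer
TIFF (externally produced instance masks are ingested as-is; binary masks
are split into connected components).

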