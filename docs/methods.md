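# Methods

## The measurement model

Quadrant darkfield acquires four darkfield images, one per illuminated
quadrant of the LED annulus (TL, TR, BL, BR), and combines them pixel-wise:

    E   = |TL − BR| + |BL − TR|
    DF  = TL + TR + BL + BR
    QDF = c·DF − E

Large features refract light directionally: the arc of a convex body
*opposite* the illumination quadrant lights up. Sub-wavelength puncta scatter
a broad Mie cone and contribute (near-)equally to all four quadrants. In `E`
the isotropic component cancels and the directional component survives
(opposing-arc supports are disjoint, so `|TL − BR| = TL + BR` there, i.e.
`E = DF` on edges); subtracting `E` from the scaled darkfield leaves the
puncta. The scaling factor `c` absorbs the system-specific mismatch between
`DF` and `E` on edges — mainly PSF mixing across the seams where opposing
arc fields meet — and is estimated by least squares, `c = Σ(DF·E)/Σ(DF²)`
over a mask of bright edge pixels, on a designated calibration field of view.
The bead phantom is the natural calibration target and is what the default
workflow uses.

## The forward model (what the simulator emulates)

Scenes contain circularly symmetric **bodies** (cells, beads) and point
**puncta**. A body is described by footprint radius R, apex height H, and a
roundness parameter r interpolating the height profile between a flat disc
(r = 0, sharp rim) and a spherical cap (r = 1); a full sphere (bead) is r = 1
with H = 2R — its chord-length profile. Closed-form volume
V = 2πR²H·[(1−r)/2 + r/3] makes the morphs below exactly conservative.

* **Edge emission.** Under illumination direction û_q, each surface element
  emits `edge_gain · relu(∇h · û_q)` — a linear-slope refraction model. It
  reproduces the opposing-arc geometry and gives an analytic flat→hemisphere
  darkfield edge ratio of (π²RH/2)/(2πR₀h₀) ≈ 1.9 for the default cell, hence
  a ~46% total-darkfield increase when edges carry half the flat frame's
  signal. The model is linear in slope; it does not saturate at steep slopes
  (no total-internal-reflection or NA cutoff), so very steep surfaces emit
  proportionally more than a real system would.
* **Puncta.** Perfectly isotropic point scatterers: amplitude/4 into every
  quadrant, deposited with sub-pixel bilinear splatting. Scattering
  efficiency is a free ground-truth amplitude, not computed from Mie theory
  (the dichotomy being modelled is directionality, not absolute cross
  sections). Punctum radius only sets its phase bump.
* **Rendering.** Fields are rendered on a 4× supersampled grid and binned
  into camera pixels flux-conservingly, so steep rims and sub-pixel positions
  are resolved before pixel integration. Both components are blurred with a
  Gaussian PSF (σ = 0.21·λ/NA ≈ 0.4 μm for the default 10×/0.25 NA optics),
  composited with a smooth polynomial lamp background and optional stray
  light, then passed through the camera: Poisson shot noise at unit
  conversion gain, Gaussian read noise (2 counts), rounding, clipping to the
  bit depth (12), and ×16 storage in 16-bit containers. Seeds split
  deterministically per frame; identical scene + seed is bit-identical.
* **Phase channel.** φ = (2π/λ)·Δn·h plus small puncta bumps (integrated
  optical path of each punctum), a polynomial phase background, and Gaussian
  phase noise (0.02 rad). Phase reconstruction itself is upstream of this
  package; the simulator supplies the reconstructed phase directly.
* **Ground truth** is the pixel sum of the noiseless density map per body —
  exactly what an ideal phase pipeline should recover.

Default scene parameters (frozen once, from the system being emulated):
λ = 0.5 μm, pixel 0.5 μm, punctum amplitude 3000 counts (per-cell SNR lands
in the mid-20s to low-30s under default noise, the range reported for
pigmented cell lines on comparable systems), edge gain 250 counts per unit
slope (edges visibly dominate darkfield images of flat cells), population
dry mass uniform in 150–350 pg, organelle count Poisson with mean 2·mass
(proportional to mass in expectation, with natural counting noise),
mass-per-area set by height through α.

**What the simulator does not emulate:** partial punctum anisotropy,
out-of-focus scatter from thick samples, phase halos and reconstruction
artifacts, saturating edge refraction, spatially varying gain, cell-to-cell
variation in punctum brightness. Passing tests therefore establish that the
*pipeline math* behaves as designed under controlled optics, not that real
specimens will show the same numbers.

## Pipeline order and numerical choices

Per field of view: (1) divide each quadrant and reference frame by
2^(16−bit_depth) and round (container → native counts); (2) subtract the
empty-field reference per quadrant, **without** flooring at zero — flooring
rectifies noise in empty regions but not under signal, which after
background fitting biases cell interiors low by the rectified mean
(~17 counts/px at default noise; measured); (3) form DF and E; (4) segment
cells on the phase channel and derive the background region (complement of
labels dilated by 5 px); (5) fit and subtract a masked 2-D polynomial
background from DF and E (fitting DF directly is equivalent to fitting the
four quadrants, by linearity); (6) calibrate or reuse `c`; (7) QDF = c·DF − E,
kept unclipped for quantification (clipped copy for display); (8) phase
background correction, density ρ = φλ/(2πα)·10³ pg/μm², per-label dry mass;
(9) puncta threshold mask at 4× the 99th percentile of the background QDF,
per-cell totals and SNR.

Choices that matter:

* **Background polynomial degree.** Default 8 (all terms x^i y^j, i+j ≤ 8,
  OLS on coordinates normalised to [−1,1]), intended for full camera frames
  (~1900×1200 px). On small synthetic fields (~128 px) a degree-8 surface
  extrapolated into a cell-sized central hole has large variance (±10% of a
  cell's total signal across noise realisations; measured); flexibility
  should scale with field extent, so the packaged study configurations use
  degree 3. Rank-deficient designs degrade degree automatically.
* **Edge-image noise floor.** |differences| rectify noise: the floor grows
  with local shot variance, survives background fitting inside cells, and
  biases per-cell QDF low — more for spread-out cells than compact ones.
  The pipeline therefore re-estimates each pair magnitude as
  `sqrt(max(d² − v, 0))` with `v` the measured background variance of the
  difference plus a DF-proportional shot term (`conversion_gain` counts per
  photon-equivalent, default 1). Exact for strong edges; ~3× lower floor on
  signal-free pixels. Disable with `FrameParams(debias_edge=False)` to get
  the plain E of the defining equation.
* **Per-cell signal definitions.** `total_df`/`total_qdf` are plain label
  sums of the (unclipped) images — flux-complete, and the estimators used
  for per-mass statistics and the shape-invariance comparison.
  `puncta_df`/`puncta_qdf` sum over label ∩ threshold mask; they define the
  SNR but their capture fraction rises as puncta crowd together (87% → 97%
  across the flat→rounded morph; measured), so they are not used as totals.
* **Segmentation.** Foreground for the final pass is an absolute floor
  (0.1 rad ≈ 5× phase noise) on background-corrected phase; an Otsu split
  truncates the dim skirt of tall rounded cells and loses ~7% of their mass.
  Otsu remains the rough-pass threshold on uncorrected phase, where a fixed
  floor would be defeated by the background. Seeds are h-maxima (depth
  0.3 rad) of the smoothed phase; watershed on the inverted smoothed phase;
  components under 20 μm² dropped. Negative corrected-phase pixels are
  retained in mass sums (clipping biases mass upward).
* **Tracking.** Crocker–Grier linking realised as the exact per-frame-pair
  assignment optimum: cost d² for a link, gate at max_disp, cost max_disp²
  for a track start/end, solved by the Hungarian algorithm on an augmented
  matrix. Points are canonically sorted internally so results are independent
  of input order. Gap closing (`memory`) defaults to 0.
* **Calibration mask.** Boundary band (morphological gradient of the
  foreground, 3 px) ∩ brightest E pixels (99th percentile of the band,
  relaxed to keep at least 200 px on small fields).
* **Statistics.** Percentiles interpolate linearly between order statistics.
  The "no-fit" null for the F-test is the intercept-only (horizontal) model;
  F = (RSS₀−RSS₁)/(RSS₁/(n−2)), p from F(1, n−2). SNR's mean ± std is over
  cells. Binned scatter uses half-open bins [lo, lo+w), upper bin on ties.
* **Coordinates/conventions.** Pixel centres at integer indices, origin
  top-left, y increasing downward; quadrant azimuths default to
  135°/45°/225°/315° (TL/TR/BL/BR) in display orientation — the
  camera-to-LED orientation is a convention of this implementation, not a
  property of the method.

## Study configurations packaged with the tests and acceptance script

* **Flat→rounded cell:** 20 μm radius, 3 μm flat disc, 200 fixed-amplitude
  puncta; morph to a hemispherical cap of radius (3V/2π)^(1/3) ≈ 12.16 μm at
  conserved volume, puncta contracting affinely. Edge gain set so edges carry
  50% of the flat frame's darkfield; `c` calibrated on a separately rendered
  bead phantom. Totals compared per cell.
* **Population:** single-cell scenes, mass-per-area uniform in
  0.1–1.0 pg/μm², organelle count ∝ mass. The acceptance script uses 1000
  cells: the sampling noise of a Pearson estimate is ~1/√n, and at n = 300 a
  correlation that is truly zero still scatters by ±0.06 from sample to
  sample; 1000 cells resolve the question the configuration actually asks.
  The 300-cell configuration remains in the test suite.
* **Bead phantom:** 10 μm radius sphere (Δn = 0.03, the polystyrene/adhesive
  contrast) with an optional central imperfection punctum; used noise-free
  for edge-cancellation checks and noisy for calibration.

Problem sizes were chosen so the full test suite and the acceptance script
each complete in a few minutes on one CPU.

## Known limitations

The edge model is linear in slope and unbounded; absolute darkfield increases
for extreme shapes are upper bounds, not predictions. Puncta are perfectly
isotropic, so the edge image nulls them exactly — real Mie scatterers retain
mild directionality and leak slightly into E. Bodies are circularly
symmetric; irregular cell outlines, neighbours in contact, and confluent
fields are exercised only through the watershed/tracking tests, not the
optical model. The SNR definition follows the threshold-mask convention and
is not comparable across images with very different background statistics.
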