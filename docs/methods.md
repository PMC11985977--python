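# Methods

This note documents the models behind `skinqa`, the parameter choices that
matter, what the synthetic-data generator does and does not emulate, and
the numerical decisions a maintainer would want to know about.

## The measurement problem

An imaging skin is a stretchable scintillator (silicone elastomer +
GOS:Tb phosphor) placed in an X-ray beam and observed by a monochrome
scientific camera.  Unlike a flat-panel detector, the usable detector area
is a deformable bright region that moves and changes size within the
camera frame, so every image-quality quantity (mean pixel value, flat-field
normalisation, stretch geometry) is defined over a re-detected region of
interest rather than the full frame.

Default acquisition geometry (`DetectorConfig`): effective pixel pitch
0.051 mm at the skin plane, 10 buffered frames averaged per acquisition,
100 ms exposure per frame, and a 12-bit signal range (`full_scale = 4095`)
stored in 16-bit containers.  The digitiser depth of the physical camera
class is not fixed by the acquisition description; 12 bits is typical for
this class of scientific CMOS and makes the MPV uncertainty scale used in
the linearity study (≤ 1.72 DN) meaningful.

## Synthetic frames

`skinqa.synthetic` generates frame stacks with the statistical structure
the analysis assumes — no X-ray spectrum, attenuation, or
scintillation-yield physics:

- **Geometry.** The skin is a polygon in pixel coordinates (row-major,
  0-based, pixel-centre convention), rasterised by the pixel-centre rule.
  Rectangles with half-integer corners rasterise to exact pixel counts,
  which keeps area oracles sharp.
- **Response.** Expected in-skin value is `offset + slope · A_k`, clipped
  to the full scale; exceeding full scale raises a saturation error, since
  the measurement protocol explicitly avoids sensor saturation.
  Background pixels carry only the dark level.
- **Noise.** Per frame: Poisson shot noise on the light signal
  (`poisson_scale` photons per DN, i.e. variance = value/scale in DN²)
  plus additive Gaussian read noise everywhere.  Above a mean of 256
  photons the Poisson draw uses the standard Gaussian approximation
  N(λ, λ), rounded and clipped at zero (relative skewness < 1/16); below
  it the draw is exact.  Defaults (0.5 ph/DN, 2 DN read noise) put a
  10-frame-averaged 10⁵-pixel ROI mean far below the 1.72 DN
  repeat-uncertainty bound, mimicking a shot-noise-limited camera.
- **Edges.** For slanted-edge scenes the PSF (Gaussian, σ in mm) and the
  square pixel aperture are applied *analytically* along the edge normal:
  step ⊛ N(0, σ) ⊛ box(p·cos α) has a closed form via the antiderivative
  of the normal CDF.  This makes the analytic oracles exact: the measured
  SFR of a σ = 0 edge is the pixel-aperture sinc envelope, and of a
  blurred edge the Gaussian MTF `exp(−2π²σ²f²)` times that envelope.  The
  small second aperture component `p·sin α` is neglected (its MTF differs
  from 1 by < 1 % below Nyquist for α ≤ 7°).  For non-edge scenes the PSF
  is applied as a discrete Gaussian filter to the in-skin signal; the skin
  boundary itself is rendered sharp, since only its rasterised mask feeds
  the analysis.
- **Stretch series.** The skin polygon is scaled axially by `1 + e/100`
  and laterally by a pluggable `thinning_model` (default: incompressible
  isotropic lateral contraction, width factor `1/√(1 + e/100)`; a pure
  shear alternative is provided).  True thickness per step is
  `t₀·A₀/A` from continuous polygon areas.  The in-skin signal follows a
  pluggable `signal_model`; the default is a linear decline of 25 % at
  100 % elongation, the behaviour of the high-tube-voltage regime where
  thinning linearly reduces captured dose.  The geometric thinning ratio
  itself (`1/√(1+e/100)` laterally) is not linear in e, which is why the
  signal law is decoupled from the geometry.  Elongations above a
  configurable rupture limit (default 120 %) raise an error; behaviour
  beyond rupture is deliberately not modelled.
- **Determinism.** Every generator threads a `numpy` `SeedSequence`;
  identical seeds give bit-identical stacks.  Frames are stored as float64
  DN so noiseless stacks are exact (the noiseless STP pipeline recovers
  scene slope and offset to ≤ 1e−9 relative); quantisation to uint16
  happens only at TIFF write time.

What the generator does *not* emulate: beam-energy dependence,
self-absorption and warping effects (the non-monotone low-voltage MPV
behaviour seen on hardware), geometric distortion, focus loss, and
source-side blur from a large focal spot.  Passing tests therefore
validate the *analysis chain*, not detector physics; hardware numbers
(e.g. absolute SFR10 values) are expected to differ.

## ROI detection

Dark-subtracted flat → Otsu threshold refined by intermeans
(Ridler–Calvard) iterations → 3×3 morphological closing → largest
connected component → hole filling, with pixels where
`flat − dark ≤ full_scale·1e−4` excluded to protect the flat-field
division.  The intermeans refinement matters because Otsu's binned
threshold can land inside the background mode when a low-noise background
collapses into a single histogram bin.  An optional border erosion
(default 0) discards the zone near the skin edge where optical effects can
bias statistics.  Detection is expected to run on the highest-dose flat of
a session; re-detection cadence is the operator's call (each simulated
stretch step re-detects, since the skin changes shape).

## STP linearity

Unweighted OLS of MPV against `A_k`; R² is the squared Pearson
correlation.  Relative deviation per point is measured against the
*fitted* value (standard detector-linearisation practice), and the
linearity verdict is `max deviation ≤ 2 %`.  Slope tables across detector
variants aggregate replicate fits by mean ± population standard deviation
(zero for a single replicate).  Per-series R² and their minimum are
reported rather than a pooled R², which keeps the statistic well-defined
when tube settings differ.

## Slanted-edge chain

Canonical form is a near-vertical edge (horizontal-edge ROIs are
transposed, so orientation symmetry is exact).  Steps:

1. **Edge location.** Per scan line, the centroid of |d(line)/dx|, with
   the per-line median of the absolute derivative subtracted first — the
   median estimates the noise floor of the flat regions, whose absolute
   values would otherwise pull every centroid toward the ROI centre.  Two
   passes: the second recomputes centroids in a ±32 px window around the
   first-pass line fit.  A residual RMS above 2 px fails as "edge not
   straight".
2. **Validation.** Slant angle within 2–7° and each side of the edge
   occupying 40–60 % of the ROI; violations warn (or raise in strict
   mode) but do not stop the analysis.
3. **Projection and binning.** Signed perpendicular distance of every
   pixel from the fitted line, binned at pitch/4 (oversample 4,
   configurable — standard for this method family).  Bins take the mean
   of their members; empty bins are filled by linear interpolation, and
   more than 20 % empty bins aborts ("insufficient slant coverage", the
   fate of an exactly axis-aligned edge).
4. **Transform.** LSF = central difference of the ESF; Hamming window
   centred on the (leftmost) LSF peak spanning the full ESF; DFT
   magnitude divided by the derivative-filter response
   `sin(2πfΔ)/(2πfΔ)`; normalised to 1 at f = 0; truncated at the
   detector Nyquist `1/(2·pitch)`.  Both the window and the derivative
   correction are configurable, since method variants differ on these
   options.
5. **Summary.** SFR50/SFR10 are the *first* downward crossings of 0.5 and
   0.1 scanning up from f = 0 (robust to noisy re-crossings), linearly
   interpolated between grid frequencies; a missing crossing is reported
   as "beyond Nyquist" (`None`).

Verified accuracy at the study conditions (edge contrast ≥ 100× the
averaged-frame noise, ROI 200×192 px): the chain recovers the analytic
Gaussian MTF within 0.02 absolute up to 0.8× Nyquist for σ ∈ {0.1, 0.2,
0.4} mm and α ∈ {2°, 4.5°, 7°}, and slant angles within ±0.3°.  Known
limitation: with a full-width window the far-from-edge ESF noise sets a
low-frequency noise floor of order 1–2 % at SNR 100, so occasional noise
realisations can graze the 0.02 band for wide PSFs; averaging repeated
acquisitions is the physical remedy.

## Stretch analysis

Per step: average frames, subtract the dark mean, re-detect the ROI,
compute MPV, detected-area ratio against step 0, volume-conserved
thickness `t₀/area_ratio` (an area ratio below 1 is rejected — a skin
under tension cannot shrink), and the Bhattacharyya distance of the
mean-removed intensity histogram against step 0.  Histograms use 256 bins
over the joint min–max range of the compared pair (neither bin count nor
range is canonical; 256 matches the 8-bit-style convention and the joint
range guarantees comparable supports).  Mean removal makes the comparison
insensitive to the overall signal decline, isolating shape changes.
Identical-support distances are finite by construction since
`√(pᵢqᵢ) = 0` whenever either bin is empty; a fully disjoint support gives
+∞ and is flagged, with the one-sided ("disjoint") probability mass
reported separately.  Trend fits (MPV, SFR50, SFR10 vs elongation in
percent) share the OLS machinery of the STP fit; a constant metric is
reported as slope 0 with R² = 0 and a degenerate flag rather than NaN.
Border zones are percentile bands of the Euclidean distance-to-border
transform — pairwise disjoint, covering the ROI exactly — so per-zone MPV
tracks whether the border region evolves differently from the bulk.

## Problem sizes

The simulated studies are desk-scale by design: STP frames are 360×360 px
with a 336×336 skin (112,896-px ROI, above the 10⁵-px target), edge
scenes 320×320 px with a 200×192 analysis ROI, stretch scenes 256×464 px
with a 200×200 base skin that doubles axially at 120 % elongation.  The
acceptance script runs 100 STP repeats and 20 stretch series in ~1.5 min
on one CPU.

## Interface

`RunConfig` is a validated dataclass (YAML-loadable); every referenced
input path is checked before any computation, and each run writes a
manifest JSON listing outputs, the seed, a hash of the
computation-determining configuration, stage timings and all validation
warnings.  Identical config + seed reproduces identical manifest contents
and pixel data.  The CLI exits 0/1/2 for ok / validation failure / I/O
failure.
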