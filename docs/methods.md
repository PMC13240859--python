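# Methods

## The measurement this package models

A miniaturized SDS-PAGE lane containing the fluorescently labeled,
immunoprecipitated proteins of a single cell is scanned by a light-sheet
microscope whose illumination/detection plane is tilted 33.8° from the
gel plane.  The stage steps 10.73 µm along the electrophoresis axis
between frames, so adjacent optical sections are
`10.73 · sin(33.8°) ≈ 5.97 µm` apart — comparable to the detectable
thickness of the illuminated slice, so molecules are not lost between
sections.  Each frame is a 512 × 512 px, 16-bit image at 0.8 µm/px.

The analysis converts one such frame sequence per lane into a
*migration profile* — counts of detected single-molecule foci versus
migration distance — and decomposes profile heterogeneity across lanes
by PCA.

## Geometry and coordinates

Lab coordinates: `y` along the stage/electrophoresis axis, `z` depth
above the glass, `x` lateral.  Frame `i` images the tilted plane through
`(y = i·step, z = 0)`; the signed distance of a point to that plane is
`d = (y − i·step)·sin t − z·cos t`.  Throughout the package, migration
distance is measured on the projected-axis scale `m = y·cos t + z·sin t`
(µm along the tilted plane), which is the axis the shift-and-max
projection produces and the axis on which profiles are binned.

All modules use 0-based pixel indices, half-open intervals, and a
projected axis that grows with migration distance.

## Pipeline stages

1. **Background subtraction** — rolling-ball, radius 25 px: the
   background is the hull of a ball rolled under the intensity surface
   (grayscale erosion followed by dilation with a hemisphere
   structuring element).  It is computed with two passes of
   `skimage.restoration.rolling_ball`, which itself returns the ball
   *apex* (erosion + radius); negating and re-applying it gives the
   dilation.  The construction is verified in the tests against an
   independent scipy nonflat-morphology implementation.
2. **Cropping** — a fixed 150 px (height) × 312 or 412 px (width)
   window selecting the gel region.  The vertical offset is
   interpolated linearly between the gel/glass interface heights of the
   first and last frame (round-half-up to integer rows) to follow slow
   sample drift.  Interface heights are configuration inputs; a helper
   (`find_interface_row`, row of maximum mean intensity) can suggest
   them, but nothing is detected silently.
3. **Shift-and-max projection** — frame `i` is displaced `11·i` px
   along the projected axis and the canvas keeps the pixelwise maximum.
   The geometry implies `step·cos t / pixel = 11.146` px per frame; the
   integer 11 matches it within 0.5 px (asserted as a config
   self-check) and compresses the migration axis by a uniform 1.3 %.
   The exact fractional shift is available behind
   `use_geometric_shift`.  A brute-force deskew
   (`deskew_oracle`: frames resampled onto the common projected-axis
   grid at the exact geometric shift — linear interpolation, no integer
   approximation — then max along the sheet normal) serves as the
   test-scale reference; on sparse scans the two projections yield
   matching spot sets.
4. **Spot calling** — scale-normalized Laplacian-of-Gaussian blob
   detection (`skimage.feature.blob_log`) over a sigma ladder of 10
   steps from 0.4 to 1.5 px, overlap pruning at 0.5.  The reported
   intensity is the pixel value at the rounded blob center.  The
   detection threshold is a per-scan choice: one `DetectionConfig`
   applies to every lane of a scan.  For real data it should be set by
   inspecting `overlay` renderings (kept spots yellow, removed red);
   the shipped default (150 on the 16-bit scale) was calibrated on
   simulated scans, where the noise-only response ceiling is ≈100 and
   the dimmest in-band molecule responds ≳200.
5. **Impurity filtering** — particles with intensity > 15 000 or
   diameter > 2 px are removed (strict inequalities; intensity checked
   first and recorded as the removal reason).  Diameter is derived from
   the detected scale as `2√2·σ`, the standard LoG blob diameter; the
   2-px cutoff therefore keeps only σ ≤ 0.707 px.  Whether the original
   analysis used this, a radius, or a FWHM convention is not knowable
   from the outside; `2√2·σ` is this package's declared convention.
6. **Profiling** — kept foci are binned at 20 px (16 µm) from the lane
   origin in half-open intervals, out-of-range foci counted in a
   reported remainder, and the counts smoothed by a 5-bin centered
   moving average whose window shrinks symmetrically at the edges
   (output length = input length; constants are preserved exactly).
7. **Antibody cutoff** — the strong full-length-antibody peak
   (~3500 µm at full scale) swamps sample signal, so bins up to its
   trailing edge are excluded: the tallest local maximum inside a
   search window (default 2500–4500 µm) is found and the cutoff is the
   left edge of the first bin after it whose smoothed count falls below
   50 % of the peak.  A flat window falls back to the window end with a
   warning; the cutoff can also be supplied manually.  The rule is well
   defined because the antibody peak dominates the profile; if sample
   bands ever exceed half its height the walk overshoots, which is the
   main reason the manual override exists.
8. **Replicate variability** — per-bin sample SD (n−1 denominator)
   across replicate profiles, summarized by its median over
   beyond-cutoff bins.
9. **PCA** — columns mean-centered, *not* variance-scaled (profiles
   share one unit, counts; unit scaling would distort the
   overall-level component), then SVD.  Sign convention: the
   largest-magnitude loading entry of each component is positive, so
   results are bit-identical across platforms.  Three components are
   reported by default.  Treated and untreated lanes are analyzed
   jointly by default (conditions are labels, not separate fits).

## The simulator

`tiltgel.simulate` renders lanes with known ground truth:

* molecule counts per band ~ Poisson(expected), migration positions
  ~ Normal(center, width) truncated to the lane, lateral/depth uniform
  over the lane cross-section (default depth 5–45 µm);
* a molecule appears in frame `i` iff `|d| ≤ slab/2`
  (slab = 6.0 µm, a free parameter the instrument literature only
  bounds as "comparable to" the ~6 µm spacing) and renders as a 2D
  Gaussian (σ = 0.5 px, a diffraction-limited spot at 0.8 µm/px) whose
  peak is attenuated by `exp(−d²/(2(slab/4)²))`;
* impurities (aggregates, bubbles, dust) are *extended* objects: they
  render at full brightness in every frame that sees them, with sizes
  and intensities drawn so that they violate at least one filter rule;
* a bright interface scatter line (30 000 counts) drifts linearly
  across frames on the glass side of the crop boundary;
* camera noise is Poisson(signal + background 100) shot noise plus
  Gaussian read noise (SD 8), quantized and clipped to 16 bits —
  a standard EM-CCD approximation;
* identical (truth, optics, noise, seed) give bit-identical stacks.

What the simulator does **not** emulate: electrophoresis physics (band
positions are specified, not derived from molecular weight), realistic
PSF structure or depth aberrations, non-uniform labeling efficiency,
gel autofluorescence gradients, or stage jitter beyond the linear
interface drift.  Passing tests therefore demonstrate that the
*analysis* is correct and self-consistent under the stated imaging
model, not that the model captures every property of real gels.

## Desk-scale study conditions

Full-scale scans (~1490 frames of 512×512 px per lane) are much larger
than needed to exercise every stage, so the validation studies run on a
proportionally scaled lane: 114 frames of 168 × 96 px covering ~1000 µm
of migration, crop 150 × 80 px, an antibody-analogue band at 250 µm
(dominant, 1600 molecules) and six sample bands at 340–790 µm in 90 µm
steps (σ 30 µm, 120 molecules each — wider than the 80 µm smoothing
span, so bands stay resolvable in smoothed profiles), cutoff search
window 180–320 µm.  All physics parameters (tilt, step, pixel size,
slab, noise, rolling-ball radius, detection and filter settings, bin
width) keep their full-scale values.  The studies:

* **Projection equivalence** — 12 sparse 20-frame stacks; spots
  detected in the shift-and-max and deskew projections are matched
  one-to-one after a single global translation (the two canvases have
  different origins; over 20 frames the residual drift of the integer
  shift is ±1.4 px).
* **Detection recovery** — 3 sparse high-SNR lanes (molecules thinned
  to >3 px projected separation, brightness 8000 ± 800) with 5 injected
  impurities each; recall, spurious rate and impurity removal are
  measured against ground truth propagated through the exact pipeline
  geometry (greedy nearest-neighbor matching within 2 px).
* **Dilution linearity** — the band set scaled by 0.25/0.5/1.0, three
  replicates each; total kept counts vs loading ratios with Poisson
  standard errors.
* **Replicate variability** — 4 pseudo-single-cell lanes (one shared
  truth, different camera-noise seeds) vs 4 single-cell lanes (each
  band's expected count rescaled per lane by a log-normal factor,
  CV ≈ 0.35, then resampled); median per-bin SD beyond the cutoff.
* **PCA heterogeneity** — 8 untreated lanes (baseline, Poisson noise
  only) and 8 treated lanes (global 1.5× boost of every sample band)
  split into two sub-populations, one additionally doubling the three
  designated bands at 430/610/790 µm.  The designated bands are
  interleaved with unboosted bands so the band-specific contrast is
  distinct from the overall expression level (whose component carries
  nearly uniform loadings, on which a top-bin ranking would be
  meaningless).  The component best separating the sub-populations is
  checked for a clean score gap and for its top-9 |loading| bins
  covering all three designated band positions within half the
  smoothing span (2 bins = 32 µm, after the 1.3 % integer-shift axis
  compression).

## Numerical choices and degenerate inputs

* Offset rounding: round-half-up (`floor(x + 0.5)`) — deterministic,
  no banker's-rounding surprises.
* Binning: half-open `[lo, hi)` from the lane origin; counts are
  conserved (`sum(counts) + remainder = kept particles`).
* Smoothing: even windows are rejected; window 1 is the identity.
* Empty inputs: empty band lists, blank frames and zero-particle lanes
  flow through every stage (zero profiles, empty particle tables);
  lanes too short to cover the antibody search window fall back to
  no-cutoff with a logged warning rather than failing the run.
* Brightness values exceeding the bit depth are clipped, never errors.
* PCA on fewer than 2 samples, mismatched profile binning, crop
  windows leaving the frame, and non-16-bit inputs raise explicit
  errors naming the offending lane/frame.

## Known limitations

* Migration distances inherit the 1.3 % compression of the integer
  11-px shift; profiles are internally consistent but absolute
  positions are ~1.3 % short of the exact geometric axis.
* The diameter filter interacts with the discrete LoG ladder: spots
  near one pixel in size can be assigned the smallest ladder scale when
  they land pixel-centered, so the intensity rule — not the size
  rule — is the robust guard against bright impurities.
* No sub-pixel localization, no photometry beyond the peak pixel, no
  cross-gel profile alignment, and no molecular-weight calibration
  (profiles are reported in µm of migration, not kDa).
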