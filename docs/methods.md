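# Methods

## Measurement model

The system measures kernel color and size from staged photographs under the
assumption that staging is rigid: fixed camera, fixed lighting, a blue
100-cell tray in a known position, kernels warm-colored against a blue
background. Under those assumptions segmentation reduces to a single color
rule — a pixel belongs to the tray iff `r − b ≤ −40` on 8-bit channels —
and kernel identity reduces to fixed cell coordinates. The pipeline
normalizes each capture into a canonical frame before applying the rule:

- **Barrel model.** Radial remap `r_src = r (a r³ + b r² + c r + d)` with
  `d = 1 − (a+b+c)`, radii normalized by half the smaller image dimension
  about the image center. Defaults `(a, b, c) = (0, −0.22, 0)` describe the
  reference capture system's 8 mm wide-angle lens. `correct_barrel` inverts
  the polynomial numerically on its monotone prefix (8193-point grid,
  linear interpolation; radii beyond the invertible range map to black).
  Resampling is bilinear. The forward map (`synthetic_tray.apply_barrel`)
  exists only to create distorted fixtures; the pair round-trips kernel
  centroids to about 1.2 px RMS at full distortion, limited by two bilinear
  resamplings.

- **Rotation.** The tray's left edge is located in the top and bottom 20%
  bands: a band column qualifies when its mean `r − b` satisfies the tray
  rule, and the edge is the first qualifying column. The angle is
  `atan((x_top − x_bottom) / Δy)`. For `Δy` we use the distance between the
  centroids of tray-bearing *rows* within each band rather than the
  geometric band centers: the detected onset column corresponds to a
  coverage-weighted row inside the band, and the row-centroid separation
  cancels that offset between the two bands. With geometric band centers
  the estimate is biased low by several percent, which matters at the 0.1°
  accuracy the fixed-coordinate grid needs. Corrective rotation is bilinear
  about the image center with black fill (the fill never survives the
  crop). Recovery error on synthetic captures is ≤ 0.07° for |θ| ≤ 2°, and
  a second estimate after correction is ≤ 0.1°.

- **Crop.** Full-image row means then column means of `r − b` are
  thresholded with the tray rule; the crop spans the first through last
  qualifying row/column. First/last indexing (not contiguity) makes the
  scan robust to bright kernel rows in the tray interior. On the default
  geometry the crop is exactly 2780 × 2780; an extent deviating more than
  2% from the expected side logs a warning but is still returned, since a
  slightly off crop is diagnosable downstream while a refusal is not.

## Segmentation and statistics

Cells are a parametric 10 × 10 grid: pitch 278 px, box side 270 px, origin
(4, 4) on the cropped tray; explicit 100-box configs are also accepted and
validated (count, uniqueness, bounds, overlap). Within a cell, kernel
pixels are the complement of the tray rule. No connected-component analysis
is performed: the ≥ 500-pixel rule applies to the raw per-cell count, so
debris and kernel in one cell are not separated, and a kernel protruding
across a cell border contributes to the neighbor's record. Both behaviors
are intentional properties of the cell-wise rule, not defects; samples in
adjacent columns come from the same tree, which bounds the practical cost
of overlap.

Statistics are computed in floating point from the 8-bit channels: mean and
the 10/25/50/75/90th percentiles of R, G, B and of per-pixel CIELAB
L\*, a\*, b\*. Percentiles use linear interpolation between order
statistics (numpy's default, R type 7); the convention is exposed because
other ecosystems default to different types.

sRGB → CIELAB uses the IEC 61966-2-1 linearization and primaries with the
reference white taken as the matrix image of (1, 1, 1), so that pure white
maps to exactly (100, 0, 0). Tabulated D65 whites disagree with the sRGB
matrix at the third decimal, which would leave spurious chroma at the white
point; against skimage's implementation the difference is < 0.01 everywhere.

## Color-grade calibration

`derive_thresholds` fits `score = α + β L*` by unweighted OLS on per-nut
median L\* against ordinal human scores (1–4) and inverts the line at
1.5 / 2.5 / 3.5. Linearity forces equal spacing of the three cutoffs — a
useful internal consistency check on any published triple. A non-positive
slope is an error: lighter kernels must score higher, otherwise the
calibration data are unusable. The calibration set should span the ordinal
scale roughly symmetrically; scores clipped at one end of the scale bias
the fitted slope (the simulation tests construct their designs
accordingly). Classification is scale-agnostic and left-closed: a value
exactly at a cutoff takes the lighter grade. The shipped
`REFERENCE_THRESHOLDS` (3929.14 / 4610.63 / 5292.13) are on the original
instrument's raw lightness scale, whose quantum range is not documented;
they are recorded verbatim with a `scale_label` and are never mixed with
native 0–100 L\* values.

## Blank detection

Blanks are flagged by a logistic GLM on (`n_pixels`, `L_p10`, `R_mean`,
`B_mean`), standardized. The default fit is unpenalized maximum likelihood
(statsmodels IRLS) for determinism and interpretability; an elastic-net
penalty with fixed `(lam, alpha)` is available for parity with penalized
workflows — no cross-validation, since there is no principled default for
it here. Decision threshold 0.5. Undefined evaluation ratios (e.g.
precision with no positive predictions) are NaN, never 0: at 2.4%
prevalence the all-negative classifier is 97.6% accurate, and the report
must not let that masquerade as performance.

`simulate_blank_dataset` generates feature tables from a known logistic
model for parameter-recovery studies: independent Gaussian features on
realistic raw scales, standardized coefficients `(−2.5, −2.0, −1.5, 1.2)`
(blanks are dramatically smaller and darker, so the size and lightness
effects are strong), and an intercept calibrated numerically to a 2.4%
marginal prevalence. At n = 5000 that prevalence yields ~120 events, so
coefficient estimates carry ~5–10% relative sampling error; recovery checks
therefore run at a fixed seed, as is standard for stochastic acceptance
tests.

## Synthetic fixtures: what they do and do not show

The generator emulates the capture geometry (3300 × 3120 sensor, 2780 px
tray, 278 px pitch, sticker and swatch placement), the tray's published
face/wall blues, kernel color and size distributions, sub-threshold debris,
small rotations and barrel distortion. Kernel blobs are perturbed ellipses
selected to an *exact* pixel area via a radial field, which makes size
bookkeeping exact and lets percentile tests demand bit-level agreement.
Ground truth (masks, per-kernel statistics) lives in the canonical
unrotated tray frame, so rotated fixtures remain exactly checkable after
correction.

Deliberately not simulated: lighting non-uniformity, specular highlights,
embryo-side texture, kernel fragments, inter-cell kernel overlap, and JPEG
artifacts beyond what the JPEG writer produces. Consequently, passing tests
demonstrate the correctness of the geometry, the color rule, the statistics
and the aggregation logic under the staging assumptions — they do not
demonstrate robustness to staging violations, which on real systems is
handled by operator quality control.

Label stickers are rendered as white squares and sample labels travel in a
sidecar CSV; `decode_labels` attempts a QR decoder import first and falls
back to the sidecar, so machine-readable stickers plug in without code
changes wherever a decoder library is present.

## Problem sizes and defaults

Test fixtures default to a reduced geometry (1200 × 1160 sensor, 1000 px
tray) that scales every layout constant proportionally; geometry guarantees
(2780 px crop, 0.1° rotation recovery, end-to-end agreement over ten trays)
are verified at the full capture geometry. Simulation sizes follow the
calibration and recovery studies they mirror: n = 2000 score pairs at noise
sd 0.3 for threshold recovery, n = 5000 kernels at 2.4% prevalence for GLM
recovery.

## Known limitations

- One decision threshold (0.5) for blank flagging; cost-sensitive
  thresholds are the caller's responsibility.
- Per-nut averaging is unweighted (the two halves count equally regardless
  of size); a pixel-weighted mean is a defensible alternative that would
  matter only when halves differ greatly in size.
- The edge scan and the crop share the segmentation rule's −40 cutoff; both
  thresholds are configurable should a capture system need them decoupled.
- The paper-scale reference thresholds cannot be applied to native 0–100
  L\* data without an instrument-specific scale factor, which is left to
  the user precisely because the original scale is undocumented.
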