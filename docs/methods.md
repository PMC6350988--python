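# Methods

This note documents the models, parameter choices and numerical details
behind `qpmcell`, and what the synthetic experiments do and do not show.

## Imaging model

The pipeline's raster currency is a 2-D optical-path-length map in
nanometres. In reflection geometry the illumination passes through the
cell twice, so the unwrapped phase delay relates to OPL as
Δϕ = (4π/λ)·OPL; `phase_to_opl` inverts this with λ from the image
metadata (default 625 nm). Some instruments quote noise in single-pass
OPL, for which a `single_pass=True` flag applies the 2π convention
instead; the double-pass form is the default. Refractive index and
physical thickness are never reconstructed individually — only their
product, OPL, is data.

Background curvature (wavefront mismatch between sample and reference
arms) is modelled as a full bivariate quadratic
z(x, y) = a·x² + b·y² + c·x·y + d·x + e·y + f — six coefficients, fitted
by linear least squares. The general form subsumes tilted paraboloids.
Flattening is two-pass: fit the whole field, subtract, triangle-
threshold the residual to mask cells, then refit on background-only
pixels of the original field and subtract that refined surface. If the
first-pass residual is numerically flat (peak-to-peak < 10⁻⁸ of the
image range) the field is already a pure quadratic and the mask step is
skipped; if the cell mask covers more than 90 % of the field there is no
background to fit and the operation fails loudly.

Segmentation binarizes the flattened field at the triangle threshold
(256 histogram bins, ImageJ convention: threshold at the bin maximizing
the perpendicular distance to the chord from the histogram peak to the
farther non-empty tail), labels 8-connected components, and discards
components smaller than `min_area_px` (default 50) or touching the
field border — a cell cut by the field of view is not a valid sample.
Coordinates are row-major, 0-based, origin top-left, half-open boxes.

## Size-invariant normalization

Cell size is a confound: bigger cells are wider and optically thicker.
The predicted diameter D is the mean of the tight mask bounding box's
width and height (a floating cell is approximately a sphere). Two
longitudinal normalizations produce dimensionless maps:

* **OPL/D** — divide by D (in nm). Retains the hemispherical envelope.
* **OPL/PL** — divide pixelwise by the sphere chord
  PL(x, y) = 2·√((D/2)² − x² − y²), measured from the mask centroid
  (robust to ragged masks). For a homogeneous spherical cell OPL ∝ PL,
  so the quotient is flat and any residual texture is subcellular
  structure. PL vanishes at the rim, so pixels with
  PL < rim_floor·D (rim_floor = 0.05) are set to zero; this keeps all
  outputs finite and suppresses the rim divergence.

Laterally, the crop is resampled to 49×49 (bilinear for values, nearest
neighbour for the mask, re-binarized at 0.5) with m_x = 49/w,
m_y = 49/h. Resampling by a factor m rescales per-pixel gradients by
≈ 1/m, so the resized values are multiplied by the scalar
m = (m_x + m_y)/2, restoring gradient magnitudes for the HOG branch.

The preprocessing is two-branch: the m gain exists *only* to make
gradients comparable across cell sizes. The statistics descriptor
therefore divides the gain back out — otherwise the mask-area-dependent
factor m would leak cell size into every statistic and defeat the
purpose of the normalization. The size-invariance of the dimensionless
ratio (identical maps for geometrically similar cells at 0.5–2× scale,
away from the rim annulus) is asserted by a property test.

## HOG descriptor

Written from first principles so every numerical choice is explicit and
testable against a naive double-loop reference (kept in the test suite):

* gradients: centred differences [−1, 0, 1] per axis, replicated
  borders;
* orientations: unsigned, folded to [0°, 180°), 9 bins of 20°;
  magnitude-weighted bilinear voting into the two nearest bin centres
  with circular wrap;
* spatial layout: 7×7-px cells, 2×2-cell blocks, 7-px stride → 6×6
  block positions on a 49×49 window; pixels vote bilinearly into the
  block's cells (clamped at the block edge);
* block normalization: L2-Hys (L2-normalize, clip at 0.2,
  re-normalize), zero-guarded at 10⁻¹²;
* descriptor length: ((window − block)/stride + 1)² × (block/cell)² ×
  n_bins = 36 × 4 × 9 = **1296** at the default geometry (the window
  has 49² = 2401 pixels).

One departure from the textbook scheme: after L2-Hys each block vector
is multiplied by a soft magnitude gain r/(r + ε), where r is the
block's raw vote norm and ε = 0.02. Pure L2-Hys normalizes *any*
nonzero texture to full strength, so instrument noise inside a smooth
cell would be amplified to the same descriptor magnitude as genuine
organelle texture, and the descriptor would carry no texture-energy
information at all. Production descriptor implementations operate on
quantized fixed-point images and so have an intrinsic weak-response
floor; the soft gain models that floor explicitly. ε is calibrated to
the study conditions: it equals the central-block vote-norm scale
produced by σ = 5 nm OPL noise on a ~10 µm cell's ratio map (measured
≈ 0.022; organelle-scale texture measures ≈ 0.04 and up). Blocks well
above the noise floor are nearly unaffected; setting ε = 0 recovers the
exactly scale-invariant dialect, in which configuration the global
scale-invariance property (identical descriptors for I and 2·I) is
asserted by a test.

The 5-statistic descriptor is (mean, population std, max, skewness
m₃/m₂^1.5, excess kurtosis m₄/m₂² − 3) over in-mask pixels only;
including the zero background would let mask area dominate every
moment. Zero-variance inputs report skewness = kurtosis = 0 with a
degeneracy flag. Statistics are computed over the mask rather than the
full crop — an open choice; the alternative would re-introduce a strong
dependence on mask area.

## Classifier

A linear C-SVC (½‖w‖² + C·Σ hinge losses), solved by libsvm through
scikit-learn; the contract is the optimum, not the algorithm. A linear
kernel is the appropriate capacity class because the training set
(250 pairs by default) is smaller than the HOG dimension (1296).
Features enter unstandardized. Decision values divide by ‖w‖,
d = (w·x + b)/‖w‖, so they are Euclidean margins; d > 0 ⇒ WBC. Model
selection sweeps C over the ten integer powers 2⁻¹…2⁸ maximizing the
mean of per-fold AUCs under stratified, seeded 5-fold cross-validation
(stratification keeps the folds class-balanced; ties resolve to the
smallest C — the most regularized of the equally good models). The
final model is refit on all data at the winning C. Evaluation sweeps
the threshold over all distinct decision values; AUC is the trapezoidal
area, identical to the Mann–Whitney pairwise statistic with ties
counted ½ (asserted against a pairwise oracle). The DET curve is the
pointwise complement (1 − specificity, 1 − sensitivity) of the ROC.
Operating-point metrics are reported at d = 0, and both cross-validated
and resubstitution variants are emitted, labelled. The learning curve
fixes C = 16 and subsamples n positive + n negative cells per point.

## Synthetic data

The generators define the study conditions; all tests and experiments
run on them because no real images are available to the package.

* **Phantoms**: a radial base profile — hemispheroid cap, or a top-hat
  plateau with a raised-cosine shoulder (shoulder width 0.2·R) — plus a
  7×7 grid of radially symmetric raised-cosine bumps whose peak height
  is `bump_height_frac` × plateau. The lattice spans ±0.6·R, bump
  radius 0.45 × lattice spacing (bumps tile without overlap); bumps are
  continuous in value and slope, mimicking organelles. The crop size is
  odd so the central bump peaks exactly on a pixel, making
  max = plateau × (1 + frac) exact. Rotation of the lattice is
  analytic (no interpolation). The mask is the exact support of the
  base profile.
* **Interpretation phantoms**: the bump-height sweep (heights 0, 3.5,
  7.1, 11, 14 %) uses the *hemispheroid* base: its OPL/PL map is a
  flat "top hat" whose only texture is the bump grid, so the decision
  curve isolates the classifier's response to subcellular
  heterogeneity. An OPL-domain top-hat divided by the sphere chord
  would instead carry a strong radial ramp foreign to both training
  classes. The rotation sweep uses a smooth 10 µm hemispheroid (WBC
  reference) and an 11 %-bumpy 16 µm one (CL reference), rotated 0–350°
  in 10° steps.
* **Populations**: WBC-like cells are smooth hemispheroids with
  diameter ~ N(10, 1) µm; CL-like cells carry bumps with height
  fraction ~ U(0.07, 0.14) and diameter ~ N(18, 3) µm (truncated
  positive). Peak OPL scales with diameter at 30 nm/µm (a 10 µm WBC
  peaks near 300 nm) with 5 % lognormal-like jitter; every crop gets
  i.i.d. Gaussian OPL noise, σ = 5 nm. Pixel pitch is 0.27 µm
  (a 3.75 µm camera pixel behind ~14× magnification). Defaults are 250
  cells per class; each cell has a random orientation.
* **Fields**: paraboloid background (coefficients configurable) +
  disjointly placed noise-free cells + field-wide i.i.d. Gaussian
  noise, with ground-truth placements returned for segmentation tests.

What the generator does **not** model: diffraction and defocus blur,
speckle or spatially correlated noise, non-spherical (adherent) cell
shapes, multi-modal WBC subtypes, and intensity quantization. Passing
tests therefore demonstrate internal consistency of the pipeline and
reproduction of the method's qualitative behaviour under idealized
imaging, not clinical performance on real cells: the synthetic classes
are better separated than real WBC/CL populations, which inflates
absolute AUCs (near 1.0 here) relative to what heterogeneous real data
would give.

## Experiment sizes and numerical choices

The end-to-end checks use the default study size (250 cells per class)
with 5-fold cross-validation; the descriptor/normalization ranking is
asserted over 5 population seeds with a −0.02 AUC margin; example
scripts use 60 cells per class. Bilinear interpolation is used for all
value resampling, nearest-neighbour for masks; rotations by multiples
of 90° are exact index permutations. The paraboloid fit uses
`numpy.linalg.lstsq` on the raw pixel coordinates (well-conditioned at
the field sizes used; a rank check guards degenerate layouts).
Triangle thresholding maps the data range linearly onto 256 bins and
returns the winning bin's centre. All randomness flows from explicit
integer seeds through `numpy.random.default_rng`; every generator is a
pure function of (spec, seed).

## Known limitations

* The soft magnitude gain makes the HOG descriptor only approximately
  invariant to global input rescaling (exact invariance at ε = 0); the
  dimensionless OPL/PL input has a physically fixed scale, which is
  what the calibrated ε presumes.
* OPL/PL normalization assumes a spherical cell; for adherent or
  irregular cells the chord model and the bounding-box diameter
  predictor both degrade.
* The rim annulus of the ratio map mixes mask-edge gradients into the
  outer HOG blocks; classification then partly keys on rim signatures
  shared by both classes. The interior blocks dominate the learned
  weights, as the phantom sweeps confirm.
* With perfectly separable synthetic classes the C grid search is
  degenerate (all C values reach AUC 1.0 and the tie rule picks
  C = 2⁻¹); the grid machinery is exercised, not stressed.
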