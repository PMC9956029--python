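# Methods

## The descriptor

Echo-weighted median patterns encode local texture as 8-bit codes that are
robust to multiplicative speckle.  For a kernel window `R_{n×m}` centred on
pixel `I_C`:

1. **Echo-weighted median.**  A 2-D Gaussian
   `G(x,y) = exp(−(x²+y²)/(2σxσy)) / (2πσxσy)` is sampled at the integer
   offsets of the window (note the *product* `σxσy` appears in both the
   prefactor and the exponent denominator — the surface is isotropic in the
   offsets, with the product setting its width).  The echo weights are
   `ξ = ⌈G / min G⌉`: positive integers with minimum exactly 1 and, under
   the default widths, a strictly maximal centre.  Each window value is
   duplicated by its weight and `I_median` is the plain median of the
   expanded multiset (even cardinalities average the two central order
   statistics).
2. **Sub-region medians.**  Eight directional groups around the centre:
   E/W are the centre-row half-rows; NE/NW/SE/SW the corner quadrants; N/S
   the rows above/below restricted to the three columns straddling the
   centre column.  This rule reproduces the reference 5×5 cardinalities
   (2, 4, 6, 4, 2, 4, 6, 4) exactly; for 3-wide kernels the N/S bands
   overlap the corner groups, which is intentional — the eight groups must
   jointly cover every non-centre position but need not be disjoint.
   `m_i` is the plain median of group `i`.
3. **Encoding.**  Bit `i` is set iff `m_i − I_median ≥ T`, with `T = 0`;
   equality sets the bit, so a perfectly constant window encodes 255.  The
   default bit order runs counter-clockwise from East (`m_1` ↔ bit 0); any
   fixed bijection gives an equivalent descriptor up to a permutation of
   histogram bins, so the order is configurable but immaterial.

Borders are replicate-padded so the code image has the input's shape.  The
whole computation is vectorised: windows come from a strided sliding view,
the multiset expansion is a single `np.repeat` (repetition counts are
constant per kernel), and all medians reduce along the window axis.  A
256×512 image encodes under all six kernels in ≈1.5 s on one CPU core.

### Gaussian widths

The reference width for the 3×3 kernel is σ = 1.2, which makes the
centre-to-corner Gaussian ratio `exp(2/2.88) ≈ 2.002` — just above 2, so
the centre ceils to 3 while every neighbour ceils to 2 or 1.  For larger
and rectangular kernels we preserve that ratio: the product of the two
widths is fixed at `0.72·R`, where `R` is the squared centre-to-corner
distance, and the two widths stay proportional to the half-widths of their
axes.  For square kernels this reduces to σ = 1.2 × half-width (3→1.2,
5→2.4, 7→3.6).  A simpler per-axis rule (σ_axis = 1.2 × half-axis) breaks
the strictly-maximal-centre property for rectangular kernels under the
isotropic-exponent Gaussian (for 3×5 it produces a tie at offset (±1, 0)),
which is why the product rule is used.  The widths are configurable per
kernel; every generated weight matrix is checked for min = 1, strict centre
maximum, and reflection symmetry.

### Known inconsistency in the reference sub-region example

In the published 5×5 worked example, every directional median matches the
plain median of its printed values except the NE group, whose printed
result (106) is not the median of its printed values (123, 147, 0, 135 →
129).  The implementation uses plain sub-region medians throughout and the
NE value is not asserted in tests; no alternative rule is guessed.

## Features

Per kernel, four 256-bin code histograms: the whole 256×512 image plus
three overlapping 256×256 windows at column offsets 0/128/256 (the minimal
equal-spaced overlapping tiling of the width; offsets configurable).
Histograms are normalised to frequencies so region area does not leak into
feature scale.  Blocks concatenate kernel-major, region-minor: six kernels
give 6144 features, the five-kernel variant (3×3 omitted) 5120.

## Preprocessing

Raw B-scans pass through: (1) white-area removal — pixels ≥ 250 (default;
scanner-misalignment regions are near-saturated) set to 0; (2) bilinear
resize to 256×512; (3) Otsu binarisation; (4) 5×5 median filter to remove
isolated speckle blobs outside the retina, then dilation with a disk of
radius 15 to close fluid holes in the mask ("large" relative to typical
fluid pockets at this resolution; both configurable); (5) flattening —
the topmost white mask row per column is fitted by polynomials of order 2
and 3, the higher-R² order wins (ties to the lower order; order 3 can only
tie, never lose, since the fits are nested), and each column is shifted by
an integer so the fitted curve maps to its mean row.  Columns without mask
content get interpolated shifts; vacated pixels fill with 0.  R² is
`1 − SS_res/SS_tot` over the fitted boundary rows.  Which anatomical
boundary to fit is an open choice; the topmost surface is used because it
is the most reliably segmented by thresholding.

## Feature selection and search

- **PCA** is SVD-based (`sklearn` full SVD behind the module surface),
  column-mean centring only, retaining exactly η components (η = 100
  default).  A cumulative-variance mode is available but not default,
  since the protocol fixes η directly.
- **NCA feature weighting** maximises the expected leave-one-out
  soft-nearest-neighbour accuracy with per-feature weights.  Distances are
  weighted L1, `d_ij = Σ_r w_r |x_ir − x_jr|`, with `w_r = u_r²` so an
  unconstrained L-BFGS solve keeps weights nonnegative; an L2 penalty
  (λ = 1/N) regularises.  Features are standardised internally.  Raw NCA
  weights are scale-dependent, so the output is rescaled to max 1 — this is
  what makes the dropout grid τ ∈ [0.1, 1] meaningful.  scikit-learn's NCA
  learns a full linear transform rather than diagonal weights, so the
  diagonal objective is implemented here; the optimiser is deterministic
  (fixed initialisation at w = 1), which subsumes seeded reproducibility.
- **Dropout search**: for each τ in the grid, drop features with weight
  strictly below τ (equality retains), multiply survivors by their weights,
  and score each classifier by stratified k-fold CV.  A τ that drops all
  features scores 0 and trains nothing.  The argmax over the (τ,
  classifier) table breaks ties toward lower τ, then classifier order.
  Classifier exceptions are recorded in the result, not raised.
- **Selection scope.**  Default `scope="fold"` refits PCA and NCA inside
  each CV fold (no test-fold leakage into projection or weights);
  `scope="global"` fits once on all data, which matches how single-CV
  protocols are often run in practice but is optimistically biased.  Folds
  are stratified at image level; when images come from patient volumes,
  image-level splitting risks patient leakage — grouping by volume is the
  caller's responsibility via custom splits.

### Classifier bank

Polynomial-kernel SVM (degree 3, `coef0 = 1`, γ = scale — the
inhomogeneous cubic kernel; the homogeneous variant without the constant
term underfits badly on histogram features), RBF SVM, random forest (100
trees), AdaBoost (decision-stump weak learner by default; a KNN option
boosted by weighted resampling is provided, as ensembling KNN under
AdaBoost is nonstandard), Gaussian naive Bayes, and RUSBoost.  RUSBoost is
implemented in-package (SAMME-style boosting where each round's weak
learner — a depth-3 tree — trains on a class-balanced random subsample
drawn by boosting weight); no installed library provides it.  All
hyperparameters are configurable; all stochastic classifiers are seeded.

## Metrics

Accuracy, sensitivity (recall), specificity, precision and F1 from the
standard binary formulas; zero denominators report 0 and are flagged.
Multiclass tables reduce one-vs-rest per class; single-number summaries are
macro averages (micro is also emitted — the reference protocol's averaging
convention for 3-class sensitivity/specificity is unstated).  ROC curves
and AUC are one-vs-rest per class via threshold sweep with trapezoidal
integration; tests cross-check AUC against a Mann–Whitney pairwise
estimator to 1e−12.

## Synthetic phantoms

Phantoms emulate what the descriptor is supposed to exploit in real
B-scans: a stack of curved, alternating bright/dark layers (five bands,
default intensities 190/110/160/90/200, thicknesses 12/18/14/20/26 px on
the 256×512 grid) following a quadratic-plus-cubic baseline, degraded by
the signal-dependent speckle model `u = v + v·η`, `η ~ N(0, σ²)`, clipped
to [0, 255] (so zero background stays zero).  Three classes:

- **normal** — bands only;
- **fluid** (edema/neovascular-like) — 3–5 dark elliptic pockets (mean
  semi-axes 14×35 px) carved into the stack at well-separated columns;
- **deposits** (drusen-like) — 12 bumps (mean semi-axes 16×22 px) that
  scallop the lowest bright band upward, with dim material filling the
  vacated space beneath, mimicking drusen elevating the retinal pigment
  epithelium.  Isolated bright blobs on top of the band were tried first
  and produce a much weaker histogram signature than band deformation;
  deformation is also the anatomically faithful choice.

Per-image jitter draws base row (65–95), sag (15–35 px), skew (±8 px),
band thicknesses (±2 px) and intensities (±10) from a seeded generator, so
classes differ by pathology, not by a fixed template.  σ² defaults to 0.01
(10% speckle amplitude on bright bands), the moderate-noise study
condition; the end-to-end check uses 50 images per class.

What the phantoms do **not** model: Fisher–Tippett speckle marginals (the
implemented model is the multiplicative-Gaussian equation), axial PSF
blur, vessel shadows, motion artefacts, inter-device intensity response,
or patient-level correlation between B-scans.  Passing the synthetic
end-to-end check therefore demonstrates that the pipeline separates
structurally distinct classes under signal-dependent noise — not that it
attains any particular accuracy on clinical data.

## Problem sizes and numerical choices

The end-to-end check runs 50 phantoms per class with the full six-kernel
descriptor, η = 100, the full τ grid (0.1…1, step 0.01), and leak-free
10-fold CV with the polynomial SVM (≈3–4 min on one core).  The
noise-monotonicity property test runs at a reduced size (8 per class, two
kernels, 4-fold CV) — large enough for the effect's direction, small
enough to keep the suite fast.  Medians use `np.median`/`np.partition`
semantics (even counts averaged); histogram bins are exact integer counts
before normalisation; τ grid values are rounded to 10 decimals to avoid
floating-point drift in `arange`; the flattening shift is integer by
construction, so flattening an already-flat boundary is a no-op up to ±1
row of rounding.

## Limitations

The descriptor is invariant to positive affine intensity maps but not to
general monotone maps (even-count median averaging breaks them).  The
dropout search selects on the same CV it reports (as in the reference
protocol); nested CV for unbiased selection error is out of scope.  DICOM
and vendor-proprietary OCT container formats are not read; inputs are
PNG/TIFF/JPEG.
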