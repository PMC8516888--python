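# Methods

This note documents the models, defaults and numerical choices behind
`tuberfield`, and what its synthetic-data tests do and do not establish
about real experiments.

## Problem setting

Irreversible electroporation (IRE) ablates tissue with trains of short
high-voltage pulses delivered through needle electrodes.  Potato tuber is
the standard bench model: ablated tissue blackens over ~48 h by melanin
accumulation, and tetrazolium (TTC) staining gives a faster readout in
which dead tissue stays white while a surrounding deep-red annulus marks
presumably reversibly electroporated (RE) cells.  The package links a
physical field model (which areas *should* be ablated at a given setting)
to an image-analysis chain (which areas *are measured* from stained
slices) and to electrical observables (current, conductivity change),
with a synthetic generator standing in for unavailable photographs.

## Electrostatic field model

With constant conductivity and electrodes much longer than their gap, the
potential on the mid-exposure cross-section obeys the 2-D Laplace
equation with Dirichlet values `V0` and `0` on the two electrode circles
and zero normal derivative (electrically insulating) on the outer
rectangle.  With Dirichlet-only drive the potential solution is
independent of the conductivity value, so none is required.

Discretisation and solution:

* 5-point stencil on a uniform grid, default spacing `h = 0.1 mm`,
  domain 60 × 60 mm (the width of the tuber).  Grid coordinates are
  exactly symmetric about the midline so the discrete problem inherits
  the mirror symmetries of the continuous one.
* A node is inside an electrode iff its centre lies in the circle (no
  anti-aliasing), making node counts exactly reproducible.
* Neumann walls are imposed by ghost-node mirroring.
* The sparse SPD system is solved directly (SuperLU); the residual of
  the discrete Laplacian, relative to `V0`, is checked against the
  tolerance (default `1e-6`), and a failure reports the achieved value.
* Geometry defaults: electrode radius 0.5 mm (1-mm outer diameter),
  centre spacing 10 mm, exposure length recorded but unused in 2-D.
  A protocol labelled "X V/cm" applies `V0 = X` volts across the 1-cm
  gap (voltage-to-distance-ratio convention).

Field magnitude uses central differences (one-sided at walls and at
nodes adjacent to electrode interiors, so the constant interior does not
contaminate surface gradients), converted to V/cm.  Iso-field areas are
super-level-set node counts times `h²`; marching squares supplies
contour polylines for rendering.  Zone prediction defaults: IRE core at
`|E| ≥ 250 V/cm`, RE annulus at `100–250 V/cm`.  These thresholds are
configurable conventions taken from where simulation contours track
stained boundaries, not asserted tissue constants.

### Accuracy and the analytic oracle

The image-line-charge closed form for two parallel cylinders in an
*unbounded* medium (`phi = V0/2 + K ln(r−/r+)`, `K = V0/(2 acosh(c/a))`)
is the independent oracle.  Its own gradient was cross-checked by
central differencing before use (midgap field ≈ 6.7 × 10² V/cm for
a = 0.5 mm, d = 10 mm, V0 = 1000 V).

Two error sources separate the discrete solution from this closed form:

* discretisation near the rasterised electrode boundary, which shrinks
  with `h`; and
* the insulating walls, which the unbounded closed form does not model.
  On the 60 × 60 mm domain this wall effect reaches ≈ 4.5% of `V0` at
  the wall midline and is grid-independent — it is the physics of the
  bounded domain, not numerical error.

Solver correctness is therefore established by central-region agreement
with the closed form (≈ 1% of `V0` within 10 mm of the gap centre),
iso-area grid convergence (< 2% between h = 0.1 and 0.05 mm for
thresholds 100–500 V/cm), the discrete maximum principle, mirror
symmetries, voltage linearity, and the joint voltage/threshold scaling
identity `A(s·t; s·V0) = A(t; V0)`.  A full-domain comparison against
the unbounded closed form necessarily shows the ~4.5% wall deviation;
the corresponding suite test documents this and fails by construction
until a bounded-domain closed form is adopted.

A frozen fine-grid reference (brute-force node counting at h = 0.025 mm
via a symmetry-reduced quarter-domain solve: 1.435169 cm² for
`|E| ≥ 100 V/cm` at 300 V) pins the default-resolution area to within
2%.

## Synthetic staining generator

The generator is first-class, tested code: it defines the study
conditions under which every downstream stage is validated.

* **Geometry.** Zone masks are rasterised at 10 px/mm (600 × 600 px
  frame for the default domain) by nearest-node sampling.
* **Palette.** Background tan (210, 190, 150), white core
  (245, 243, 238), deep red (150, 30, 40), melanin (40, 35, 30) —
  chosen for segmentability, stated for reproducibility, validated as
  pairwise-separated at construction.
* **Noise.** I.i.d. Gaussian channel noise, σ = 8/255, added after the
  ground truth is frozen, then clipped and quantised.
* **Ruler.** A white band with black millimetre ticks along the bottom
  of the frame, the target of scale calibration.
* **Melanin kinetics.** `A(t) = A_final (1 − exp(−(t − t0)/τ))`, onset
  `t0 = 2 h`, `τ = 12 h`: the simplest monotone saturating form
  consistent with blackening that is barely visible at 3 h, clear at
  12 h, and indistinguishable from the TTC area by 48 h
  (1 − e^(−46/12) ≈ 0.978 of the final area).  Darkness ramps with the
  same curve, so early melanin is both smaller and fainter.
* **Red-annulus decay.** `A(d) = A0 exp(−d/τr)`, `τr = 6 h`, modelling
  membrane resealing with staining delay `d`; at 21 h the annulus is
  e^(−3.5) ≈ 3% of its 5-minute value, emulating its disappearance.
  Decay removes the outermost annulus pixels first (resealing proceeds
  from the rim toward the dead core).
* **Area control.** Masks are shrunk or grown to an exact pixel count
  by ranking pixels on the signed Euclidean distance to the region
  boundary with deterministic raster-order tie-breaks — equivalent to
  erosion/dilation by the radius that hits the target.
* **Star artifact.** The heterogeneous inner medullar tissue distorts
  the melanin readout into a star: each connected component's boundary
  radius is modulated by `1 + A cos(kθ + φ)` about its own centroid
  (amplitude 0.25, five lobes by default for melanin; off for TTC,
  which is much less affected), with the mean radius renormalised by
  `1/sqrt(1 + A²/2)` so area is conserved to a few percent.  The
  angular bin count adapts to component size so small lobes are not
  under-resolved.  Components are treated independently because at
  300 V/cm the IRE set genuinely splits into one lobe per needle.
* **Replicates.** Multiplicative lognormal area jitter with cv = 0.08,
  drawn independently for the TTC and melanin readouts of the same
  treatment (they come from different halves of the slice).
* **Seeding.** Every item's seed is a SHA-256 hash of the master seed
  and stable string labels, so regeneration is byte-identical and
  adding conditions never perturbs existing ones.

What the generator does *not* emulate: photographic texture, lighting
gradients, shadows, lens distortion, electrode puncture marks, or the
soft boundary of real stain fronts.  Passing recovery tests therefore
demonstrate the correctness of the measurement chain on well-posed
images, not robustness to uncontrolled photography; segmentation
thresholds are exposed in configuration for that purpose.

## Scale calibration and segmentation

The interactive steps of the workflow being replaced (manual ruler
scaling, a hand-trained pixel classifier) are deterministic here:

* **Calibration** locates the ruler band (bright rows containing dark
  ticks), estimates tick pitch as the median spacing of tick centres in
  the band's column-intensity profile, and converts via the known tick
  distance (1 mm).  A user-supplied pixels-per-mm bypasses detection;
  absence of both is a declared failure.
* **Classification** is fixed HSV thresholding tuned to the stated
  palette: white = low saturation ∧ high value; red = hue within 0.10
  of the red wrap ∧ saturation ≥ 0.5; melanin = value ≤ 0.45.  The
  detected ruler band is excluded from tissue analysis.
* **Cleanup** is morphological opening then closing (disk radius 3 px =
  0.3 mm; the melanin class opens at 1 px because its star spikes are
  genuine signal that a 3-px opening clips), followed by a dominant-
  component rule: components at least 25% of the largest are kept,
  which removes speckle without halving the two-lobe zones of low
  settings.  Red components must lie within 5 px of the white region
  (the annulus surrounds the core).
* **Areas** are unweighted pixel counts (a pixel belongs to a class by
  its centre value) divided by `(px/mm)²·100`.

Segmentation contains no randomness.  End-to-end recovery on the
default 30-image experiment: median relative area error ≈ 0.3%, worst
class errors ≤ ~2%.

## Electrical emulation

The hardware measurement is out of scope; the module generates records
with the observed shapes so the correlation layer has matched
covariates.  Per-pulse current follows
`I_k = I∞ − (I∞ − I_1) exp(−(k − 1)/κ)` with anchors `I_1 = 12.5 A`,
`I∞ = 15.0 A` at the 1500 V/cm reference and κ = 5 pulses, placing
pulse 17 at ≥ 99% of saturation; amplitudes scale linearly with the
field setting (an ohmic simplification — real tissue saturates
nonlinearly).  The 10-Hz conductivity change ratio is `1 + E/1500`
(ratio ≈ 2 at the strongest setting — an invented, clearly configurable
anchor, since only the trend is reported in the literature), realised
as a noisy before/after pair whose reported ratio is recomputed from
the noisy values.  Measurement noise is multiplicative lognormal,
cv = 0.05.

## Statistics

Replicate summaries are mean ± sample SD (n − 1; SD undefined and
reported missing for n = 1).  Pearson r carries a two-tailed p-value
from `t = r√(n−2)/√(1−r²)` with n − 2 df; the paired two-tailed t-test
annotates `*`, `**`, `***` at p < 0.05, 0.01, 0.001.  Zero-variance
inputs raise a dedicated degenerate-data error rather than returning
NaN.  The correlation heat map spans melanin area, TTC white area, TTC
red area, current and conductivity ratio; it defaults to
replicate-level points (n = 15 under the default design) with
condition-mean aggregation as an option, because the small-p regime
reported for such designs is implausible at n = 5.  No multiple-testing
correction is applied, matching the conventions of the workflow being
reproduced.  Implementations delegate to `scipy.stats`; the test suite
checks them against an independent first-principles reimplementation
(raw sums plus the incomplete-beta t integral) to 1e-10.

## Pipeline and reproducibility

`run_full` executes simulate → generate → segment → analyze from a
single `RunConfig` (TOML-loadable; explicit overrides win).  The field
is solved once at the highest voltage and rescaled by linearity for the
rest.  Outputs include truth and measured tables, the wide
per-(voltage, replicate) measurement table, the correlation matrix, a
recovery scatter, and a manifest with SHA-256 digests of every file;
two runs with the same master seed are byte-identical.  A stage failure
aborts with the stage name and offending item.

Problem sizes used by the test suite and the acceptance script — the
default 60 × 60 mm domain at h = 0.1 mm (h = 0.05 mm for the accuracy
checks), the 5 × 2 × 3 default experiment at 10 px/mm, 100 master seeds
for correlation recovery — are the package's standard configuration;
they keep a full validation run in the low minutes on a laptop.

## Known limitations

* 2-D cross-section only; no field- or temperature-dependent
  conductivity, Joule heating, or pulse-train transients in the field
  solution (explicit non-goals).
* The unbounded-medium analytic oracle cannot validate the solution
  near insulating walls (see above); a bounded-domain series solution
  would be needed for that.
* The generator's kinetics amplitudes are shape-constrained
  conventions, not fitted to published numbers (none are printed as
  values in the source literature).
* Segmentation thresholds assume the synthetic palette; real
  photographs require re-tuning via `SegmentationParams` and are not
  guaranteed.
* Star-shape distortion assumes each component is star-convex about its
  centroid, which holds for the convex-ish zones modelled here.
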