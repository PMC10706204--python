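# Methods

## Problem and pipeline

Corneal fluorescein staining severity is graded on the Ocular Staining
Score (OSS): `oss_score(count, confluent, central, filament)` returns the
count-band base (0; 1–5 → 1; 6–30 → 2; >30 → 3) plus one point per present
modifier, capped at 5. Each modifier contributes exactly +1; simultaneous
modifiers add independently up to the cap. The automated pipeline
reproduces the clinical reading on the inferior cornea: localization →
segmentation → feature signature → classifier.

Coordinates are 0-based `(row, col)` with downward = increasing row; the
integrodifferential operator's `(x0, y0)` is stored as `(row, col)`
internally.

## Localization

**Cornea.** Otsu on the enhanced red channel separates the bright sclera;
the corneal radius and column come from the widest horizontal chord of the
largest non-sclera component. The chord width varies only quadratically
with the row near the center, so the argmax row is noise-sensitive; the
center row is instead taken as the midpoint of the component's vertical
extent. A bimodality guard (between-class variance fraction ≥ 0.5) turns
flat or unimodal images into a `LocalizationError` instead of a bogus
circle.

**Pupil.** Daugman's operator is evaluated on a discrete grid: candidate
centers fill a square box of side 0.35·R (R = corneal radius) centered on
the corneal center; candidate radii span 0.15·R–0.35·R inclusive in 1-px
steps. The circular mean intensity is sampled at 1° steps with bilinear
interpolation, smoothed along the radius with a Gaussian of σ = 2 px, and
differentiated with a central difference; the argmax of the absolute
derivative wins. The center grid is coarse (3 px) with a 1-px refinement
pass around the best coarse candidate; on synthetic eyes the recovered
center and radius sit within ~1 px of truth. A near-flat objective sets a
low-confidence flag rather than failing.

**Reflection removal** runs after the cornea is known, restricted to the
corneal disk: Otsu marks the bright class, accepted only when the histogram
is clearly bimodal (variance fraction ≥ 0.75) *and* the class is small
(≤ 8% of the region — specular highlights are spatially small; without the
cap the corneal background itself would be "bright" relative to the pupil).
Accepted pixels are filled with the median of a surrounding ring.

**ROI.** The sector apex sits at the pupil center; its radius is the
distance to the bottom corneal edge; it spans ±45° about the downward
vertical in image coordinates (so small head rotations do not move the
sector). The sector bounding box is resized bilinearly to the normalized
frame — 596×1104 at full 1944×2592 input, proportionally smaller frames for
smaller inputs so that structure sizes stay commensurate with the
segmentation's structuring element.

## Segmentation

Top-hat by reconstruction on the green ROI: `img − reconstruct_by_dilation
(marker = opening(img, disk(10)), mask = img)`. The result is non-negative,
exactly zero on flat fields, and removes smooth gradients, so detection is
invariant to illumination offsets. One caveat: on a finite domain the
opening of a ramp dips within one structuring-element radius of the
brightest border, so the "zero on smooth backgrounds" property holds on the
interior.

Binarization of the top-hat image is not standardized anywhere we know of;
the rule used: no staining when the top-hat peak is below a minimum
contrast (25 gray levels); otherwise Otsu restricted to the ROI, falling
back to 0.15 × peak when the top-hat histogram is unimodal (variance
fraction < 0.5). Regions smaller than 5 px are removed; components are
8-connected (diagonal fluorescein bridges count as confluent). Detected
regions overlapping the projected reflection mask are vetoed.

## Features (974)

**Texture (837).** 93 features on each of 9 forms of the green ROI:
original; LoG σ = 1, 2, 3; one-level Haar wavelet LL/LH/HL/HH;
rotation-invariant uniform LBP (P=8, R=1). Per form: 18 first-order
statistics and 75 gray-matrix features (GLCM 24, GLRLM 16, GLSZM 16, NGTDM
5, GLDM 14 — the standard radiomics families, totalling exactly 75).
Intensities are discretized to 32 equal-width bins over the masked range;
GLCM/GLRLM are direction-averaged over the four symmetric 2-D directions at
distance 1; GLDM uses dependence α = 0 with dependence size = dependent
neighbors + 1. Degenerate single-level images yield defined values (no
NaN): correlation 0, MCC 1, normalized nonuniformities 1. Texture is
computed over the full ROI mask, not per stain region. Feature names are
`texture-<form>-<idx>` with skewness at per-form index 15 and the GLSZM
large-area-low-gray-emphasis among the matrix features — the two published
anchor features are pinned by name.

**Morphology (9).** Per-region area, perimeter, circularity `4πA/P²`
(clipped at 1.5 — rasterization pushes tiny regions past 1), and
minimum-rotated-rectangle aspect ratio (short/long, via the convex hull's
minimum rotated rectangle), aggregated as: mean area, total area, mean and
total perimeter-to-area ratio (total = ΣP/ΣA), mean circularity, mean and
total perimeter, mean aspect ratio, region count. Empty maps give zeros —
which makes several features near-perfect "any staining" indicators on
grade-0 images; this is expected and documented behavior, not leakage.

**Topology (128).** Vertices are region centroids (fixed across scales).
At disk radius s, an edge joins two regions whose dilations share a pixel.
Dilation by a Euclidean disk is computed from one exact distance transform
per region: pixel p lies in the dilation iff `EDT(p) ≤ s`, so the minimal
connecting scale for a pair is `min_p max(EDT_u, EDT_v)` — pixel-identical
to explicit dilation with the disk footprint (the unit test proves this
against an independent rasterized oracle), but all 16 scales come from one
pass. Eight descriptors per scale, 16 scales (radii 4k, k = 1..16). On
disconnected graphs, eccentricities are computed within each vertex's
component (isolated vertex → 0) and the diameter is the maximum
eccentricity, so no infinite distances are emitted; degree-<2 vertices have
clustering 0; the empty graph returns all zeros. Edge sets nest as the
scale grows, so subgraph counts and isolated fractions are non-increasing
and mean degree and giant-component ratio non-decreasing — asserted as a
property test.

## Selection and grading

Four-stage cascade on the z-scored training split (all statistics frozen
before the test split is touched): one-way ANOVA across the five grades
(keep p < 0.05); greedy Pearson redundancy filter in descending-F order
(drop at |r| ≥ 0.9); backward elimination on the OLS fit of the numeric
grade (drop the largest p while > 0.05, stop at 2 features; exact
collinears removed first by greedy rank checks); gini-importance ranking.
Features with zero within-class variance give infinite F; these are capped
to keep orderings finite, with ties broken by name. The importance tree is
unrestricted in depth: a 4-split tree (the classifier's setting) can assign
nonzero importance to at most four features and cannot rank a ten-feature
signature; ties in importance break by ANOVA F, then name. Selection runs
once on the full training split rather than per CV fold — this mirrors a
single reported ranking and carries the usual optimistic bias for the CV
numbers (the held-out test metrics are unaffected).

Signatures: A-10 (overall top-10), NT-10, T-5, NT-5 (top-k within the
topological / non-topological name families). When a family has fewer
survivors than requested, the signature takes what exists and warns.

Models (protocol settings): SVM with RBF kernel, C = 1, γ = 1/(n·var),
one-vs-one multiclass, ROC scores from softmax-normalized one-vs-rest
decision values; decision tree with ≤ 4 splits (`max_leaf_nodes = 5`);
AdaBoost of such trees, 30 cycles; Gaussian naive Bayes; KNN k = 10; random
forest, 100 trees. Stratified 8:2 split; stratified 10-fold CV on the
training side with per-fold scaling; folds are reduced with a warning when
a class is rarer than the fold count.

Metrics: ACC = trace/total; SEN/PRE/SPE macro-averaged over one-vs-rest
classes (zero denominators contribute 0 with a warning); F = harmonic mean
of macro PRE and macro SEN; per-class and micro-averaged ROC AUC; Kendall
τ-b with tie correction (all-tied input is an error).

## Synthetic cohorts

The generator renders what a graded slit-lamp photograph shows: bright
sclera field, darker corneal disk with iris texture (a seed-determined
smooth random field, amplitude 4–9 gray levels, visible between pupil and
limbus), dark pupil, green Gaussian dots (half-peak radius = the nominal
dot radius; per-dot peak varying ±30% around 95–125), soft-edged elliptical
confluent patches, optional thin filament strokes (off by default — they
are clinically rare and absent from the model's grade range), specular
highlights in the superior cornea, per-image exposure gain (0.75–1.15),
offset (−15..+20), a lateral illumination ramp (≤12%), focus blur
(σ 0.3–1.2 px) and Gaussian sensor noise (σ 2.5–6). Ground truth is defined
on the pre-blur, pre-gain stain field at half of each element's peak, so
labels are independent of the light environment; dot placement enforces a
3.2-radius minimum separation so ground-truth regions stay disjoint.

Grade recipes realize each OSS grade through its clinically plausible
paths (e.g. grade 3 as >30 scattered dots *or* 6–29 dots plus a confluent
patch) and encode severity in the spatial arrangement: cluster tightness
increases monotonically with grade and grade ≥ 4 includes a horizontal band
of dots — the incomplete-blink exposure pattern of severe disease. "Central
staining" means within 0.35 × corneal radius of the pupil center. A region
at least `confluent_area` px² (default 120 at reference scale) also counts
as confluent; the dot-vs-patch boundary is exposed as that parameter
because no pixel criterion for "patch" is standard. The default cohort
frame is 324×432 px (the full-frame geometry scaled by 1/6) with all stain
geometry scaled by the corneal radius, chosen so that a 400-image
experiment runs on a laptop; `EyeSpec` defaults to the full 1944×2592
acquisition frame for full-scale work.

What the generator does **not** emulate: eyelid/eyelash occlusion,
tear-film break-up patterns, vignetting, motion blur, and — important for
interpreting results — the rich background clutter of real corneal
photographs. Passing tests therefore demonstrate algorithmic correctness
and recoverability under controlled nuisance conditions, not clinical
performance.

## Numerical conventions and edge cases

- Otsu-based decisions everywhere carry a bimodality guard (between-class
  variance fraction) so unimodal histograms never produce spurious masks.
- First-order skewness/kurtosis are 0 under zero variance; uniformity of a
  constant region is 1; energy and total energy coincide at unit pixel
  spacing.
- LoG of a constant image is ~1e-4 relative, not exactly zero (truncated
  Gaussian kernels); tests use matching tolerances.
- All randomness flows from explicit integer seeds (`numpy.random.
  default_rng`); cohorts derive per-image seeds from the master seed, and
  two runs with equal configuration are bit-identical.
- Tie-breaks (feature orderings, rankings) are always deterministic:
  statistic first, canonical name second.

## Known limitations

- Large low-contrast confluent patches are segmented only approximately;
  the structuring-element radius bounds the structure size the top-hat can
  isolate cleanly.
- The "central staining" modifier is positional, but every extracted
  feature family is translation-invariant, so grades that differ only by
  centrality are intrinsically confusable for the classifier.
- On synthetic cohorts the non-topological signature stays more competitive
  than it is clinically: with a renderer-clean background, zone-counting
  texture statistics (GLSZM/GLRLM) read out the staining load almost as
  well as explicit segmentation, whereas in clinical photographs background
  clutter buries that shortcut. Concretely, on the default 400-image
  cohort the top-5 topological signature reaches ~63–65% held-out accuracy
  (close to its ~65–75% ceiling over hand-picked topological sets) while
  the top-5 non-topological signature reaches ~76–82%; on clinical data the
  reported ordering is the reverse. The topological numbers transfer;
  the non-topological ones are optimistic on synthetic data. This is a
  fidelity limit of the renderer, documented rather than patched.
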