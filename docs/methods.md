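# Methods

## Scope and design

`lidmorph` dissects a periocular image into anatomy before it classifies
anything: segmentation → region decomposition → calibrated morphometry →
region-level abnormality findings → declarative diagnosis composition. The
intent is interpretability and expandability — every diagnosis cites the
findings, parameter values and thresholds that produced it, and adding a
disease means adding a YAML rule, not code. All conventions below are fixed
once, package-wide.

**Coordinates.** 0-based pixel indices, origin top-left, x rightward,
y downward. "Vertical" always means along image columns; MRD/PF are measured
along the true vertical rather than perpendicular to the inter-canthal chord,
which is appropriate for standardized frontal photographs where head tilt is
treated as noise (a chord-alignment rotation flag was considered and left
out of the default path).

**Laterality.** Under the frontal-photo convention, a blob whose centroid
lies in the left image half is the subject's right eye. The published
canthus definition refers to distance from the nasal midline; a monocular
patch has no midline, so laterality substitutes for it — the nasal side is
the image-centre side, and horizontal (x) distance is used. This is an
interpretation and is isolated in `anatomy.locate_canthi`.

## Synthetic scene model

The generator emulates the photographic protocol behind the pipeline
(primary gaze, frontal framing, 10 mm circular forehead fiducial) at cartoon
fidelity:

* **Lid margins** are quadratic arcs through the two canthi with a single
  extremum — the minimal smooth family matching clinical lid shape. With the
  canthi on a horizontal chord, margin ordinates are
  y(x) = y₀ ∓ 4h·t(1−t), t ∈ [0,1], giving closed-form heights and a
  closed-form arc-length integrand.
* **Cornea** is a disc clipped to the interpalpebral fissure. The corneal
  centre height above the chord, the margin apex/dip, and the derived truth
  MRD1 = apex − height and MRD2 = dip + height are template parameters.
* **Pathology textures** are deterministic: inward lash strokes above the
  upper margin (entropion/trichiasis), an everted red band under the lower
  margin (ectropion), and a skin-fold band medial to the inner canthus
  (epicanthus; an inversus fold sits below the canthus, mirroring its
  lower-lid origin, other folds above). Texture colours are chosen so their
  nearest palette class is skin: they perturb the image for the classifiers
  without touching the label geometry, and the fold never occludes the
  fissure, so canthus ground truth stays exact.
* **Noise** is additive Gaussian intensity noise (default σ = 3 grey levels)
  applied to the image only; masks are noise-free by construction.

Ground truth is computed analytically from the parameters — closed-form
margin geometry, adaptive quadrature with breakpoints at the circle/parabola
intersection kinks for the clipped-cornea areas — never from pixels.

Default study conditions (`data/scene_templates.yaml`): 0.2 mm/px scale,
ICD 27–30 mm, upper apex 4–5 mm, lower dip 2.6–3.4 mm, corneal radius
5.3–5.7 mm, so normal eyes have MRD1 ≈ 3.0–4.5 mm and MRD2 ≈ 3.1–4.4 mm.
Condition templates shift exactly the parameters that define the condition
(e.g. ptosis: MRD1 ∈ [0.6, 1.6] mm; BPES additionally ICD 19–22 mm with an
inversus fold), with uniform jitter so every template keeps ≥ 0.25 mm
clearance from its screening threshold. Values follow common oculoplastic
ranges; they are configuration, not code.

**What the synthetic scenes do not emulate:** photographic texture, shading
and specular reflexes, lash/brow clutter, skin-tone variation, head pose,
partial occlusion by spectacles, and camera blur. Passing tests therefore
demonstrate the correctness of the geometry, calibration, measurement and
rule-composition machinery under known ground truth — not the performance of
the baseline palette segmenter or texture classifiers on clinical
photographs, which would be replaced by learned models through the declared
`Segmenter`/`RegionClassifier` contracts.

## Segmentation and cleaning

The baseline segmenter assigns each pixel to the nearest colour in the
documented palette (texture shades alias to skin) and is exact on noiseless
renders. Images whose pixels are mostly far from every palette colour
(majority beyond 60 grey-level RGB distance) are declared out of domain and
return an all-background mask with a warning rather than garbage.

`clean_mask` keeps the K largest connected components per class and fills
holes. The component filter for the fissure operates on the joint eye region
(fissure ∪ cornea): the cornea routinely spans the full fissure height and
would otherwise split the fissure class into medial and lateral fragments.
K defaults are sized for ≤ 2 eyes per scene (eye 2, cornea 2, tumor 2,
marker 1) and are configurable per call. The operation is idempotent;
equal-size ties are broken by raster order for determinism.

## Morphometry

**Calibration.** mm/px = marker_diameter / d, with d = 2·√(area/π) the
equivalent-circle diameter of the cleaned marker component. Pixel-count area
is unbiased for discs at arbitrary sub-pixel alignment; measured accuracy is
well within 1% for radii 10–60 px under random alignment. At exactly
lattice-resonant alignments (integer/half-integer centres, radius ≲ 14 px)
the rasterized blob is identical across a ~1.5%-wide radius interval, so no
estimator can resolve the radius finer there; this is an intrinsic
quantization limit, not an estimator defect.

**Corneal centre.** Clinical MRD is referenced to the corneal light reflex;
a label mask has none, so a reproducible proxy is required. The default is a
least-squares (Kåsa) circle fit to the free limbus arc — cornea pixels
bordering the fissure — which recovers the full-disc centre to sub-pixel
accuracy even when the lids truncate the disc (as they do in most eyes).
The raw component centroid is available as `method="centroid"`; it drifts
toward the exposed part of a truncated disc by several tenths of a
millimetre at typical occlusions and is kept only as a documented fallback.

**The eight parameters.** On the axis column (corneal centre column, rounded):
MRD1 = (centre_y − upper margin y)·s and MRD2 = (lower margin y − centre_y)·s,
signed so that a margin crossing the centre yields a negative MRD (severe
ptosis remains representable); PF is defined as MRD1 + MRD2, making the
identity exact by construction. Areas are pixel counts × s²: visible cornea,
and the fissure-minus-cornea region split at the axis column into nasal
(medial) and temporal (lateral) parts, axis-column pixels counted medial —
the partition lateral + medial + cornea = total fissure area is pixel-exact.
The medial/lateral split rule is an explicit stand-in (the clinical source
for these area definitions is not public) and is isolated in one function.
Lid lengths are arc lengths of a quadratic fit to each margin chain,
integrated in closed form; the fit is essential because the raw rasterized
polyline overestimates a smooth margin's length by the staircase effect
(~8% at typical slopes, versus < 0.1 mm after the fit). A margin chain
spanning < 3 columns falls back to the raw polyline length.

Reports are timestampable and `report_delta` emits parameter differences
between visits for longitudinal monitoring.

## Abnormality detection and thresholds

Parametric screens use strict millimetre inequalities with configurable
thresholds (defaults: ptosis MRD1 < 2.0 mm, upper retraction MRD1 > 5.0 mm,
lower retraction MRD2 > 5.5 mm — common oculoplastic convention). Scores are
logistic in the signed threshold margin with a 0.5 mm slope, so score > 0.5
is exactly the threshold rule and the boundary value scores 0.5 without
firing. The tumor segmentator reports the largest lesion's calibrated area
and emits a finding when area ≥ 1.0 mm² (at exact equality the score is 0.5
by the same logistic; emission uses ≥, the one deliberate deviation from the
strict-inequality pattern). Region classifiers are pluggable callables
`patch → (label, probability)`; the shipped baselines measure the generator's
texture shades (coverage fraction and vertical placement for fold type,
texture pixel counts for margin changes). An admissibility table restricts
which change may be reported in which region; tumors are region-agnostic.

## Atlas and evaluation

Rules are data (YAML, versioned schema): each names a disease, required
(region, change) findings, optional millimetre predicates, a priority, and
optionally the component diseases it subsumes. Rules fire in descending
priority; a firing composite consumes its findings so components are not
co-reported — BPES is the one shipped composite, requiring ptosis +
epicanthus inversus + ICD < 30 mm, and the subsumption is logged in the
diagnosis notes. Both upper and lower lid retraction map to TAO. Epicanthus
labels are reported at change level. The engine is deterministic under
finding reordering (findings are canonicalized, rules ordered by priority
then name) and monotone under added findings except for logged subsumption.

Evaluation takes the eye as the unit: per-class one-vs-rest confusion
(ACC, sensitivity, specificity, F1), AUROC by rank statistic over per-disease
scores, aACC as the unweighted mean of per-class ACC, exact-match accuracy,
and per-eye categories — correct, over-detection (predicted ⊋ truth),
under-detection (predicted ⊊ truth), misdetection (any other mismatch).
AUROC is NaN for a class without both positives and negatives.

## Numerical choices and problem sizes

* Truth quadrature: `scipy.integrate.quad` with breakpoints at circle/margin
  intersections located by sign-scan + Brent root-finding; agreement with an
  independent quartic-root-based recomputation is at machine precision.
* Canthus square side uses round-half-to-even of ICD/3 (Python `round`).
* Tie-breaks: contour endpoint ambiguity resolves toward smaller y;
  component-size ties resolve in raster order.
* Degenerate inputs: a 1-px-tall fissure yields identical upper/lower
  chains; a clamped region patch losing > 50% of its nominal area is flagged;
  an axis column outside the fissure span (pathological occlusion) raises.
* Test and acceptance cohorts use 100 scenes for geometry checks, 200 for
  morphometry recovery, 50 per condition template for label recovery, and
  20 per class for the metric cohorts — sizes at which every tolerance above
  is comfortably resolved while the full suite runs in a few minutes on one
  CPU.

## Known limitations

The baseline segmenter and classifiers are oracles for the generator's
palette, not clinical models; real-photo performance is out of scope by
design and enters through the pluggable contracts. The medial/lateral area
split and the BPES criterion are documented stand-ins, each isolated behind
one function/rule so they can be swapped. Laterality inference assumes a
roughly centred face; a cropped single-eye photograph at the image edge can
be mis-lateralized, which flips the medial/lateral semantics. MRD is
centre-referenced rather than reflex-referenced; on real photographs with a
visible light reflex the two differ when gaze is off-primary.
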