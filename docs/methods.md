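# Methods

This note records what `fragmetrics` computes, the conventions it fixes,
the design choices that were genuinely open, and what validation on the
synthetic cohort does and does not establish.

## Inputs and conventions

The raw input is a per-slide **label mask**: a single-channel integer
raster with four tissue classes (default encoding background = 0,
tumor = 1, mucosa = 2, other = 3), an isotropic physical pixel size in
mm, a patient-level Mandard TRG label (2 or 3 — patients with no residual
tumor, TRG 1, are outside the cohort definition, and so are TRG 4–5), and
optionally an explicit luminal-surface polyline (GeoJSON, pixel units).
Coordinates are 0-based `(row, col)` with pixel-center semantics: all
distances are Euclidean distances between pixel centers, reported in mm.
Pixel size is configuration metadata, never read from image headers,
because header conventions vary across scanners.

## Per-slide measurements

**Fragments** are connected components of the tumor class under
8-connectivity. Components smaller than `min_area_mm2` (default
0.001 mm², roughly 2–3 pixels at the default 0.02 mm/px) are discarded
as rasterization/segmentation specks; this is well below the smallest
biologically reported fragment width (0.06 mm), so no real fragment is
at risk.

**Short-axis width** of a fragment is the diameter of its largest
inscribed disk: twice the maximum, over fragment pixels, of the exact
Euclidean distance to the nearest non-fragment pixel. For bent or
elongated fragments this measures local thickness, which is the quantity
that a technique's resolution must reach. The distance transform is the
two-pass Felzenszwalb–Huttenlocher algorithm, implemented as a numba
kernel so that per-fragment windows — and the test suite's exhaustive
enumeration of millions of small shapes — run without per-call overhead;
unit tests verify it against `scipy.ndimage.distance_transform_edt` as an
independent implementation. The EDT is evaluated on the fragment's
bounding box padded by one pixel: clamping any outside pixel
componentwise onto the padding ring yields a non-fragment pixel at no
greater distance, so the windowed transform is exact, and pixels of
*other* fragments inside the window correctly count as non-fragment.
A minimum-Feret estimator (rotating calipers over the convex hull of the
fragment's pixel squares) is selectable via `width_estimator:
min_feret`; it returns the global caliper width instead of local
thickness and is kept for comparison.

**Lumen distance** is the minimum pixel-center distance between the
fragment and the luminal surface (0 when the fragment reaches the
surface). When no annotation is supplied, the surface is inferred as the
tissue pixels 4-adjacent to the background component that shares the most
4-adjacent boundary with mucosa pixels — the lumen is the background
region lined by mucosa. Whether distances should be measured to the
mucosal lining or to the true lumen boundary is left to the caller: an
explicit annotated surface always takes precedence over the inference.

**Pattern classification** merges a patient's fragments by single
linkage: two fragments on the same slide join one cluster when their
edge-to-edge distance (minimum pairwise pixel distance, i.e. gap width,
not centroid distance) is *below* 3.0 mm; gaps of at least 3 mm keep them
apart, matching the convention that fragmentation requires ≥ 3 mm
between clusters. Fragments on different slides are never merged, since
serial sections carry no reliable out-of-plane geometry; the patient's
cluster count is the *maximum over slides* of the within-slide count, so
a single bulk visible on several serial slides remains one cluster.
(Counting clusters over the union of slides with cross-slide distances
treated as infinite would misclassify every multi-slide shrinkage patient
as fragmentation.) Two or more clusters ⇒ fragmentation; one ⇒
shrinkage. "Not forming a bulk" is not otherwise quantified; a dominance
criterion (one cluster holding most of the tumor area) would be a
plausible alternative reading and is not the default.

## Per-patient aggregation and statistics

Per patient: `max_width_mm` (widest fragment, or widest bulk for
shrinkage), `min_depth_mm` (shallowest lumen distance over all fragments
and slides), `central_slide_area_mm2` (largest single-slide tumor area,
pixel count × pixel area), and `volume_mm3` = Σ over slides of tumor
area × `slide_spacing_mm`. The slide spacing defaults to 3.0 mm, a
typical gross-sectioning interval; it is a required configuration value
because any slab-sum volume is only defined relative to it.

Group comparisons (TRG 2 vs TRG 3) follow the gate: Shapiro–Wilk on each
group at α = 0.05; both pass → pooled-variance unpaired two-sided
t-test; otherwise two-sided Mann–Whitney U, exact when min(n) ≤ 8 and
there are no ties, average-rank normal approximation otherwise. p ≤ 0.05
is flagged significant; no multiple-testing correction is applied. The
per-TRG table reports median and (min–max) per measure, with the
fragmentation-width row restricted to fragmentation patients and the
shrinkage-width row to shrinkage patients. "Smaller than" fractions use
strict inequality (configurable). ECDFs are right-continuous and
evaluated at the data points.

## Detectability

A modality is a `(resolution_mm, imaging_depth_mm)` pair. The default
**marginal** criterion calls a patient detectable when
`max_width ≥ resolution` and `min_depth ≤ imaging_depth`; these may be
satisfied by different fragments. The stricter **joint** criterion
requires a single fragment that is both wide enough and shallow enough.
Both are reported, because the cohort-level requirement pair
`(min over patients of max_width, max over patients of min_depth)` pairs
one patient's width with another patient's depth, and per patient the
marginal reading can be true while the joint one is false. Detection is
purely geometric; contrast between tumor and fibrosis is a separate,
unmodeled requirement, and the bundled modality specs are illustrative
order-of-magnitude values, not instrument characterizations.

## Synthetic cohort generator

The generator is the validation instrument: it renders cohorts whose
geometry is known exactly. Defaults encode the study conditions the
package targets: 30 patients, fragmentation probability 16/30, widths
log-uniform on 0.06–14.9 mm, depths log-uniform on 0.001–8.9 mm, 2–5
fragments for fragmentation patients, 3–10 serial slides (mean ≈ 6.5,
matching ≈ 198 slides/30 patients), 0.02 mm/px (the smallest 0.06 mm
fragment is 3 px wide), 3.0 mm slide spacing. Log-uniform sampling is a
stand-in, not an inference — only medians and ranges of the real
distributions are known — chosen because the ranges span more than two
decades and the submillimeter regime is the scientifically critical one.

Each slide stacks a background (lumen) band, the flat luminal surface
row (emitted as the ground-truth polyline), a 0.5 mm mucosa band, and
"other" tissue; fragments are filled capsules (segment ⊕ disk), so the
true short-axis width is the capsule diameter and the capsule's top
point sits exactly at the drawn depth below the surface row. Tilt is
uniform within ±25°, aspect ratio uniform on 1–2.5. Fragmentation
patients are laid out left-to-right with bounding-box gaps drawn from
3.2–6.0 mm; the horizontal gap lower-bounds the true edge-to-edge
distance, so the ≥ 3 mm constraint holds by construction, with a ≥ 10 px
margin from the threshold so that rasterization (≤ ~1 px per edge) can
never flip a pattern. Every fragment appears at full size on the
patient's central slide and scaled by 0.5–0.95 about its fixed center on
a contiguous run of neighboring slides (hence never shallower or wider
than its central rendering). Ground-truth per-slide areas and volumes
are recorded from the rendered rasters — the rasterized mask *is* the
input whose truth the pipeline should recover — while widths and depths
are recorded as the drawn continuous values, which is what makes the
±2 px recovery checks meaningful. Draws that would exceed the maximum
raster extent (4096 px) are rejected and redrawn a bounded number of
times. All randomness derives from `(seed, patient_index)`, so any
patient is reproducible in isolation.

What the generator does **not** emulate: irregular fragment shapes,
curved or ulcerated luminal surfaces, classifier segmentation errors,
touching/overlapping fragments, anisotropic pixels, and any 3-D
coherence beyond the scaled serial renderings. Passing recovery tests
therefore demonstrates that the measurement chain is correct on masks
whose truth is known — not that a tissue classifier's masks are accurate,
nor that real fragments are capsules.

## Numerical choices and degenerate inputs

* Width tolerance: rasterizing a capsule of width `w` yields a measured
  inscribed-disk diameter within 2 px of `w` (the digitization of the
  medial axis adds at most about one pixel of radius); the analytic-shape
  and recovery tests assert exactly this bound.
* A fragment filling its entire view, an empty fragment, an empty
  surface, a mask without background, and an empty cohort all raise
  `ValueError` with explicit messages rather than returning sentinels.
* Classification at exactly the threshold: merging requires distance
  strictly below `linkage_threshold_mm`, so a gap of exactly 3.0 mm
  counts as fragmentation ("at least 3 mm").
* Cluster ids are connected-component labels per slide; ties in the
  lumen-component inference resolve to the component with the greatest
  mucosa contact, then the largest.
* CSV tables are written with shortest round-trip float repr and read
  back with `float_precision="round_trip"`, making write→read lossless;
  the run log contains a configuration hash and no timestamps, so
  repeated runs are byte-identical.
* Exact Mann–Whitney is limited to min(n) ≤ 8 (the regime where SPSS-like
  exact behavior matters for small cohorts); above that, or with ties,
  the average-rank normal approximation is used.

## Problem sizes used in validation

The test suite validates the width estimator exhaustively on every
8-connected shape in a 5×5 grid (~1.5 × 10⁷ shapes) plus random blobs;
parameter recovery runs 10 seeds × 30 patients under the default study
conditions; the reproducibility check runs the full pipeline twice on a
30-patient cohort. The acceptance script reports on one 30-patient
cohort at the caller's seed. These sizes were chosen to mirror the
target study's scale (30 patients, ~200 slides) while keeping a full
validation run in the minutes range on a single CPU.

## Known limitations

* All distances are in-plane; no 3-D reconstruction across slides is
  attempted, so cross-slide fragment separation is undefined by design.
* Volume is a slab sum (area × spacing) with no interpolation between
  slides.
* The inferred luminal surface is a heuristic; curved lumina with
  multiple background components lined by mucosa resolve to the single
  component with the most mucosa contact.
* Vitality of tumor tissue is taken from the mask labels as given; no
  assessment of whether labeled tumor is viable is attempted.
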