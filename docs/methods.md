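# Methods

## The index

The Medial Temporal Atrophy index is a planimetric ratio computed per
hemisphere on one coronal slice at the level of the interpeduncular fossa:

    MTAi = (A − B) × 10 / C

where A is the area of the medial temporal lobe (MTL) region, B the
parenchymal area within it, and C the area of the body of the ipsilateral
lateral ventricle, all in mm². A − B is the CSF-filled fraction of the MTL
region — parenchyma already lost to atrophy — and C is a proxy for global,
disease-unspecific atrophy, so the ratio estimates the contribution of
medial temporal atrophy to overall brain atrophy. Because it is an
intra-patient ratio of areas measured on the same slice, it is invariant
under uniform scaling and requires no normalization to intracranial volume
and no age covariate. The ×10 factor is purely presentational.

The two hemispheric values are summarized by their median — for two values,
their arithmetic mean — and by the Index of Asymmetry

    IA = (lMTAi − rMTAi) / (lMTAi + rMTAi) × 100  [percent],

antisymmetric in its arguments and bounded in [−100, 100] for non-negative
indices. |IA| at or above a threshold (default 3%, configurable; the
published band is approximate, "~±3%") flags significant hemispheric
asymmetry, in which case reports must present the per-hemisphere values
prominently: the median is not a good representative of either side.

Between two dated studies (1 earlier, 2 later) the yearly rates are

    yrMTA  = [(A2 − B2) − (A1 − B1)] × 120 / months
    yrMTAr = [(A2 − B2) − (A1 − B1)] × 120 / [(C2 − C1) × months]

The source prints these formulas without bracketing the leading
difference; we adopt the grouping above because it is the only reading
under which the rate vanishes when the parenchymal loss does not change.
The ×120 factor is the ×10 index scale times 12 months/year. yrMTA carries
mm²-per-year units (on the ×10 scale); yrMTAr is dimensionless per year
and is undefined when C2 = C1 (no ventricular change to normalize
against) — the library raises in that case and the report writes `null`.
Calendar intervals are converted as months = days × 12 / 365.25.

### A documented inconsistency

The published worked example prints IA = −5.15% for hemispheric indices
5.85 and 6.59, but the IA formula gives (5.85 − 6.59)/(5.85 + 6.59) × 100
= −5.95%. This package follows the formula; the printed −5.15% cannot be
derived from the stated inputs and is not reproduced. Either way the case
is flagged asymmetric (|IA| > 3%).

### Rounding

All computation is unrounded; only reporting layers round, by default to
2 decimals (matching the published presentation, configurable via
`--decimals`). Consequently IA computed from unrounded indices (−5.98% in
the worked example) differs slightly from IA computed from the 2-decimal
presentation values (−5.95%); the acceptance script reports the latter,
since it derives the asymmetry from the two reported index values.

## Planimetry

Areas are computed with the shoelace formula on the implicitly closed
vertex list (via shapely) and scaled by the in-plane pixel spacing,
area_mm² = |signed area|_px × row_mm × col_mm, which is exact for polygons
and correct for anisotropic in-plane spacing. Vertices are 0-based pixel
coordinates at pixel centers, x = column, y = row. Validation rejects
contours with fewer than 3 vertices, repeated consecutive vertices (an
explicitly closed list should omit the duplicate final vertex), and
self-intersections — a figure-eight tracing is treated as a user error
rather than silently measured. The anatomical constraint B ≤ A is enforced
with a relative tolerance of 1e-6 so that tracing B coincident with A
(zero atrophy) survives floating-point noise.

## Volume handling

NIfTI volumes and DICOM series are reoriented to the canonical RAS+
convention before slice indexing, so "coronal slice k" is well defined
across storage layouts: the anterior-posterior axis is axis 1 of the
canonical array. For DICOM, the affine is assembled from
ImageOrientationPatient/ImagePositionPatient (slices sorted along the
slice normal) and converted from LPS to RAS. In-plane spacing always comes
from metadata; a volume without usable spacing is an error, never an
assumed 1 mm. The MRI sequence is not checked — the index is geometric and
contrast only affects the upstream manual tracing. Hemisphere labels are
stored explicitly in ROI files and never inferred from image side, which
sidesteps the radiological-vs-neurological display ambiguity.

## The phantom

The phantom emulates a traced coronal slice, not an MRI: per hemisphere it
places three elliptical polygon contours (MTL region, parenchyma inside
it, ventricle body) on a 128 × 128 mm field. An inscribed n-gon of an
ellipse with semi-axes (a, b) has area (n/2)·a·b·sin(2π/n); the generator
solves this for a·b given the target area, so polygon areas equal the
analytic truth *exactly* (to float precision) at any vertex count — the
truth object is an exact oracle, not an approximation. The parenchyma
ellipse shares its center, aspect ratio and sampling phase with the MTL
ellipse and is therefore a strictly smaller scaled copy, guaranteeing
geometric containment.

Atrophy model: medial temporal atrophy m ∈ [0, 1) shrinks the parenchyma,
B = B0·(1 − m), with the MTL region held at A0 to isolate the (A − B)
signal (an optional `mtl_region_shrinkage` lets A shrink too); global
atrophy g ≥ 0 enlarges the ventricle, C = C0·(1 + g). The analytic index
(A0 − B0(1 − m))·10/(C0(1 + g)) is strictly increasing in m and strictly
decreasing in g, which the recovery tests verify end to end through the
polygon pipeline on a 6 × 6 (m, g) grid. Baselines A0 = 330, B0 = 290,
C0 = 165 mm² give a baseline MTAi ≈ 2.42, near the illustrative
healthy-control reference mean — a plausibility anchor, not a claim of
anatomical realism. The seed only randomizes each contour's angular
sampling phase, which provably leaves polygon areas unchanged, so fixtures
are deterministic per seed and truth areas never depend on it.

What the phantom does not emulate: anatomical contour shapes, MRI noise
and bias fields, partial-volume effects, and human tracing variability.
Passing phantom tests therefore validates the geometry-to-index pipeline,
not the reproducibility of manual tracing on real scans.

Rasterization (for volume round-trip tests and QC) fills regions with
distinct intensities via scan-line polygon filling at the default 0.5 mm
spacing on a 256 × 256 raster; pixel-count areas then agree with the
analytic areas to better than 1%, the expected discretization error at
that resolution.

## Numerical and design choices

- Median of two values is their mean (forced for n = 2).
- IA sign convention: left minus right over the sum, negative when the
  right index dominates; "d" (dexter) in published notation is the right
  hemisphere.
- IA is undefined when both indices are zero (raised as a domain error);
  one-sided zero atrophy gives IA = ±100%.
- The asymmetry comparison is |IA| ≥ threshold, threshold default 3.0%.
- The areas CSV validator collects all invalid rows and reports them with
  1-based row numbers in one error; nothing is silently dropped.
- The illustrative reference table (7 diagnostic groups, group means of
  the median MTAi and IA) is packaged as data with a mandatory
  non-normative disclaimer; it provides no diagnostic cut-offs, which
  remain unvalidated.

## Limitations

- A single-slice measure gives a limited view of overall pathology;
  conditions that reshape the ventricles (e.g. hydrocephalus) will distort
  the index.
- Indices computed on different coronal slice levels are not comparable;
  the package records the slice index as provenance but cannot detect a
  level mismatch.
- Automated anatomical segmentation and automatic slice-level detection
  are out of scope: tracing and slice choice are upstream, manual steps.
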