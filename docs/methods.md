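# Methods

## Pipeline model

`choroidref` quantifies the choroid of a macular OCT volume scan relative
to the nulla, the deepest foveolar point. The input contract is a stack of
B-scans with per-pixel compartment labels (background/sclera, vitreous,
retina, choroid); how those labels were produced (deep learning, manual
annotation, simulation) is outside the package. The stages run in a fixed
order:

1. **Boundary extraction.** Per column of each B-scan, the ILM is the first
   retina pixel, the inner choroid boundary the first choroid pixel, and
   the outer choroid boundary the last choroid pixel + 1 (half-open
   intervals, so outer − inner is the column's choroid pixel count).
   A column whose retina or choroid is absent or split into multiple runs,
   or whose compartments are out of vertical order, is a hard error naming
   the B-scan and column: the landmark grid spans ±2000 µm and every
   parameter must be defined, so silent gaps are not acceptable.
2. **ILM smoothing.** A 2D moving average over the (B-scan × lateral pixel)
   grid, arithmetic mean over the window intersected with the grid (the
   window shrinks at borders rather than padding). Window (1, 1) is the
   identity, so per-B-scan-only smoothing is available as (1, w).
3. **Nulla detection.** Global maximum depth of the smoothed surface.
   Values within 1e-9 axial px of the maximum count as tied — exact-equality
   semantics, robust to float accumulation, matching the plateaus that
   integer-rasterized ILM data produce — and the unweighted centroid of the
   tied grid points is returned with the tie count. Fractional coordinates
   are kept; downstream offsets are measured from the fractional lateral
   position via linear interpolation.
4. **Landmark measurement** on the single B-scan containing the nulla
   (nearest integer B-scan; a half-way tie resolves toward the volume
   centre). Thickness is strictly axial: (outer − inner) boundary depth,
   linearly interpolated between lateral pixels, times the axial scale.
   Areas integrate that thickness with the trapezoid rule over every pixel
   node in the interval plus the fractional end segments — exact for the
   piecewise-linear boundary interpolant. The umbo areas are the integrals
   over the two 100 µm half-spans adjoining the nulla.
5. **Cohort statistics.** Summaries (mean/std/min/max, sample n−1 standard
   deviation throughout), CV = 100·sd/mean reported to one decimal, Pearson
   panels, per-side two-way type-II ANOVA of sex and origin without
   interaction, Bonferroni banding at 0.05/9 and 0.01/9. Left and right
   eyes are never pooled into one model (fellow eyes of one animal are not
   independent); eyes of unknown origin stay in summaries and correlations
   but are excluded from the ANOVAs.

## Coordinate and laterality conventions

Row 0 is the image top (vitreous side); depth increases downward, so the
"deepest" ILM point is the depth maximum. Indices are 0-based, intervals
half-open. The landmark axis runs nasal → temporal (T1 most nasal, T5 at
the nulla, T9 most temporal; A1–A8 left-to-right in that frame, A4/A5
flanking the nulla). The image direction of "nasal" is a configuration
flag: under the default `nasal_positive_od`, nasal is +x for right eyes and
−x for left eyes. Mirroring a volume and swapping the eye side therefore
reproduces identical named measurements — a tested invariant.

## Tunable parameters

| parameter | default | rationale |
|---|---|---|
| smoothing window | 3 B-scans × 31 lateral px (≈ 0.32 mm) | wide laterally to suppress segmentation jitter; only one slice either side across the 221 µm-spaced B-scans |
| landmark spacing / extent | 500 µm up to ±2000 µm | the reference-grid design |
| umbo offset | 100 µm | the central-bouquet sub-analysis distance |
| quality threshold | 25 | manufacturer-style score; inclusion is `quality ≥ 25`, boundary inclusive |
| tie tolerance | 1e-9 axial px | exact-tie semantics on rasterized data |

## Synthetic cohort generator

The generator emulates the acquisition protocol, not the optics. Per eye:

* **ILM**: a base depth plus an inverted 2D Gaussian pit (configurable
  depth, widths, optional flat bottom for tie tests); the pit centre is the
  unique true deepest point.
* **Inner choroid boundary**: flat. Retinal thickness then varies with the
  pit while the choroid band is controlled independently.
* **Choroid band**: thickness profile piecewise linear through the nine
  per-eye landmark targets, constant beyond ±2000 µm — the simplest profile
  whose 21 landmark truths are exact by construction (areas are trapezoids
  of a linear profile; umbo values interpolate toward T4/T6).
* **Rasterization**: profiles are evaluated at pixel-grid lateral positions
  and rounded to the nearest axial pixel, bounding the boundary error by
  one axial pixel and the measured-value error by the rasterization
  quantum: 2 axial px for thicknesses (≈ 7.7 µm at the default geometry)
  and 2 axial px × span for areas (2% of a typical 500 µm-span area at the
  default geometry). Tests assert recovery at these bounds.
* **Intensity**: per-compartment gray levels with multiplicative lognormal
  speckle; masks stay noise-free since segmentation is supplied, not
  simulated. Intensity rendering is skippable for large measurement-only
  runs.
* **Population model**: the nine landmark targets are independent normal
  draws per landmark (floored at 60 µm, ≈ 9 sd below the reference means);
  sex/origin/side are categorical draws; quality is uniform integer.
  The `paper_cohort` preset encodes the published cohort composition
  (39.3% female eyes; 53.21% Mauritius / 42.51% Asia / 4.28% unknown;
  50.27% right eyes), a nulla thickness distribution with mean 192.83 µm
  and CV 7.8%, neighbouring landmark means calibrated to the published
  subgroup tables, and quality ≥ 25 throughout (the published cohort is
  already quality-filtered).

What the generator does **not** emulate: choroidal vasculature texture,
pathology, eye motion, inter-landmark correlation structure (real adjacent
landmarks correlate ≈ 0.7; the generator draws them independently, which
the recovery targets do not depend on), diurnal variation, or ocular
magnification. Passing recovery tests therefore demonstrate the
correctness of the measurement arithmetic and geometry conventions on
well-formed segmentations — not robustness to segmentation failure modes
of real data.

The generator also houses the ground-truth bookkeeping of the segmentation
training stage: eye-level train/validation/test split arithmetic
(44 eyes × 25 B-scans split 27/9/8 → 675/225/200) and the
mirror-plus-rotation augmentation that triples a training set
(originals + vertical mirrors + one uniform random rotation in ±8° each,
675 → 2025). The ×3 composition is adopted because it reproduces the
published count.

## Statistical implementation notes

The type-II ANOVA is computed through statsmodels (`ols` +
`anova_lm(typ=2)`); the test suite cross-checks it against an independent
nested least-squares oracle (SS(A|B) = SSE(B) − SSE(A+B)) to 1e-8 and
verifies its null calibration (rejection rate at α = 0.05 within the
binomial 99% interval over 1000 no-effect replicates). Rank-deficient
designs (confounded factors, single-level factors) are explicit errors.
Boxplot five-number summaries use linear-interpolation quantiles and
1.5 × IQR whiskers extending to the last datum inside the fences.

## Problem sizes

The parameter-recovery suite runs the full image pipeline over the
374-eye reference cohort at native resolution without intensity rendering
(~80 s on one CPU); unit tests use a reduced geometry (256 × 248 px,
9 B-scans) at the same physical extent. Oracle comparisons use small grids
(nested-loop smoothing means, exhaustive nulla scans) and 1000-point dense
quadrature for areas.

## Known limitations

* Thickness is measured along image columns (a strict rectangular grid),
  not normal to the RPE; the inner reference is the segmented inner choroid
  boundary rather than an explicit RPE line.
* Nulla localization across B-scans is limited by the 221 µm slice spacing;
  no sub-B-scan interpolation beyond the tie centroid is attempted.
* Measurements are taken on the single nulla B-scan; no cross-B-scan
  averaging.
* No axial-length/magnification correction and no diurnal modelling.
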