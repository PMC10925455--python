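# Methods

This note documents the models, conventions and numerical choices behind
`zonescore`, in the order the pipeline runs.

## Input model

A case is a single-channel integer raster (`LabelMask`) in which each pixel
carries exactly one class: K17⁺ tumor, K17⁻ tumor, CD4, CD8, CD16⁺/CD163⁻
(M1), CD16⁺/CD163⁺ (M2), or background/stroma. The mapping from roles to
integers and the physical resolution (µm/pixel; 0.346 by default, the scan
resolution of the source whole-slide images) live in a YAML/JSON sidecar.
Pixels use 0-based row/column indices with pixel-center geometry: the
distance between two pixels is the Euclidean index distance times the
resolution. Because a pixel holds one label, "stroma" is operationally
*non-tumor, non-immune*, and immune–tumor overlap is representable only as
adjacency. Whole-slide masks arrive as tiled patches (conventionally
580 × 580 px); `stitch_patches` assembles them, requiring overlapping
pixels to agree and filling gaps with background. An optional binary ROI
(the pathologist's tumor-bed annotation, when available) restricts every
computation; without it the whole mask is analysed.

## Zone partition

* **Boundary definition.** "Distance to the tumor boundary" is realised as
  the exact Euclidean distance to the nearest tumor *pixel* of each K17
  class (`scipy.ndimage.distance_transform_edt`). For per-pixel masks this
  coincides with a contour definition up to half a pixel and is unambiguous.
* **Intratumoral** = tumor pixels, plus non-tumor pixels 8-adjacent to
  tumor ("direct contact"; connectivity configurable to 4), plus pixels
  enclosed in hole-filled tumor nests. The denominators of intratumoral
  densities therefore use the hole-filled nest area, so enclosed stroma
  dilutes the density rather than vanishing from it.
* **Peritumoral** = remaining non-tumor pixels whose nearest-tumor distance
  lies in (0, *d*]; *d* defaults to 25 µm, the depth at which between-class
  contrast is strongest (a sweep over 25–200 µm is built in).
* **Influence attribution.** Every intratumoral or peritumoral pixel takes
  the K17 class of its nearest tumor pixel. Exact ties go to K17⁺ by
  default: this biases *against* the hypothesis of interest (immune
  enrichment near K17⁻ tumor), so detected enrichment is conservative. The
  tie rule is configurable, and the relabeling-symmetry tests exploit that
  the partition under (swap labels, flip tie rule) is the exact mirror
  image.
* **Band-clipped distance fields.** A `ZonePartition` stores its distance
  fields clipped to the band depth (+∞ beyond). Nothing downstream uses
  beyond-band distances, and clipping makes tiled processing (tiles with a
  halo of ⌈d/resolution⌉ pixels, for rasters too large to transform whole)
  bit-identical to whole-image processing — verified by test. Pixels whose
  clipped distances are both infinite but that are intratumoral (deep nest
  interiors; contact pixels when d < one pixel step) are resolved exactly:
  contact pixels by their 8-neighborhood, enclosed pixels by a local exact
  distance transform on the padded bounding box of their hole-filled nest
  component, which always contains their true nearest tumor pixel.
  `tumor_distance_fields` remains available with exact, unclipped
  semantics. The entire partition (distances, influence classes, tie rule,
  contact and enclosure) is checked pixel-for-pixel against an exhaustive
  brute-force search on random masks.

## Zone scores

Immune quantification is purely pixel-based — no cell segmentation. For
marker *i* and zone *z*: `count = pixels(i, z) × resolution² / (π (D/2)²)`,
with D = 8 µm for lymphocytes (CD4, CD8) and 16 µm for macrophages (CD16,
CD163), both configurable. A blob straddling a zone border contributes its
pixels to each side proportionally. The Tumor/Stromal Zone Score is
`ZS = count / zone area`, kept internally in cells/µm² (multiply by 10⁶ for
the cells/mm² scale used in figures). The per-case ratio `ZS⁻/ZS⁺` is
defined only when both zones have positive area and `ZS⁺ > 0`; undefined
ratios are NaN sentinels with logged reasons, excluded (and counted) in
ratio summaries, while the underlying densities still enter paired tests.
The digital K17 score is the K17⁺ share of tumor area — the simplest
reading consistent with a manual/digital correlation analysis, and flagged
as an interpretation.

## Random-placement null

The null asks whether the observed K17⁻/K17⁺ imbalance of one marker
exceeds what uniform placement produces. Per replicate, N disks of the
marker's diameter are placed with centers uniform on the compartment's
pixels (the peritumoral band, or the hole-filled nests for intratumoral
tests — conditioning on total abundance isolates spatial preference), the
stamped pixels are tallied per zone with the same machinery as real masks
(pixels count once; pixels on tumor or outside the compartment never
count), and the log zone-score ratio is recomputed. The empirical two-sided
p-value uses the add-one correction,
`p = (1 + #{|null| ≥ |obs|}) / (n_reps + 1)` (default n_reps = 999), so
p > 0 always and identical inputs + seed give bit-identical results.

Two numerical choices matter for calibration, both found by the 1,000-seed
uniformity check:

* **N is a truncation-corrected placement estimate.** Dividing observed
  in-band pixels by the full disk area underestimates the number of placed
  cells, because disks near band and tumor edges lose pixels; replicates
  with too few disks produce a too-narrow null and inflated tails. N is
  therefore the observed in-band pixel count divided by the *expected
  in-band pixels per disk* (disk kernel convolved with the compartment
  indicator, averaged over eligible centers).
* **Empty zones are errors, not small p-values.** If either influence zone
  has zero area the statistic is undefined, and the literal formula would
  return the minimum possible p for every such case; `simulate_null`
  raises instead, and callers report the case as skipped.

With both in place, p-values under uniform truth are indistinguishable from
uniform (KS test across 1,000 generator seeds) in the regime of roughly 20+
cells per band. At very low counts (~10 cells) the discrete statistic
produces ties — notably ±∞ when one zone holds no marker pixels — and the
test becomes mildly conservative (mean p ≈ 0.53). That is a generic
property of empirical tests on discrete statistics, not an artefact of this
implementation.

## Cohort statistics

Paired two-sided t-tests compare `ZS⁻` and `ZS⁺` per case for one marker ×
compartment (densities, not ratios); t and p come from the exact t
distribution and are verified against numerical integration of the t
density to 1e-10. Degenerate all-zero differences give t = 0, p = 1. The
companion statistic is the fraction of cases with ratio > 1 among cases
with a defined ratio (the exclusion count is reported alongside). Spearman
correlation uses average ranks and the t-approximation p-value, verified
against a hand-rank oracle. Stratified analyses rerun the paired test per
stratum; strata with < 3 usable cases appear in the output as skipped,
never silently dropped. No multiple-testing correction is applied — every
result carries `multiplicity_adjusted=False` so downstream users can add
one.

## Synthetic cohorts

The generator emulates the data regime the analysis assumes, with known
ground truth:

* **Tumor geometry.** `n_nests` blobby nests: radial bumps of scale
  `nest_scale_um` (log-normal radius jitter), perturbed by smoothed
  Gaussian noise and thresholded, giving irregular, partially merging
  nests. Each nest seed is K17⁺ with probability `k17_pos_fraction`; tumor
  pixels take the status of their nearest seed, so merged blobs still show
  the mosaic K17 pattern of mixed tumors.
* **Immune placement.** Per marker and zone, cell numbers are Poisson with
  intensity `base_intensity × effect_ratio (K17⁻ zones) × L`, where L is a
  per-case log-normal factor (sd `case_random_sd`, shared by all zones of a
  case — so the planted per-case ratio is exactly `effect_ratio` while
  absolute densities vary). Intratumoral intensities are set so
  `intra_fraction` of a zone's expected cells fall inside nests. Cells are
  stamped as 8/16 µm disks; peritumoral disks are clipped where they touch
  tumor (tumor label wins, as in real single-label masks), intratumoral
  disks are clipped to the nests. Optional `decay_um` makes peritumoral
  intensity fall off exponentially with distance to tumor — the fixture
  for depth-sweep behaviour.
* **Geometry sharing.** Intensities are defined over the true partition
  computed by the zoning module on the tumor-only mask *before* placement,
  so ground truth and measurement share one geometry and recovery tests
  isolate estimation error.
* **Determinism.** Counter-based Philox streams keyed by (seed, case
  index): cohorts are platform-reproducible and a case is independent of
  cohort size. Metadata adds random clinical strata and a "manual" K17
  score = digital score + bounded Gaussian noise (sd 0.1).

Defaults are chosen once as realistic study conditions: 1160 × 1160 px at
0.346 µm/px (≈ 0.16 mm², two patches square), 8 nests of 50 µm,
`k17_pos_fraction` 0.5, baseline densities of 200–400 cells/mm² per marker
(the order reported for PDAC immune infiltrates), `case_random_sd` 0.3.
What the generator does **not** model: nucleus-level morphology, chromogen
appearance, segmentation errors of the upstream classifier, spatial
clustering beyond zone inhomogeneity, and marker co-expression. Passing
recovery tests therefore demonstrates correctness of the measurement chain
under the stated spatial model, not robustness to upstream segmentation
noise.

Test and calibration fixtures use down-scaled conditions (220–500 px at
1 µm/px, 4–7 nests of 30–40 µm, single-marker intensities of
600–1,500 cells/mm² where a specific statistic needs adequate counts) so
the full suite, including the 1,000-seed and 1,000-cohort calibration
studies, runs in minutes on one CPU; the planted-effect recovery criterion
runs at the full default conditions. Planted-effect recovery is asserted on
the peritumoral compartment: at the default `intra_fraction` the
intratumoral zones hold only a few cells per case and their ratio estimate
is dominated by small-count noise and boundary spillover (a known
limitation, visible in the wide intratumoral spread of recovered ratios).

## Pipeline

`run_score` / `run_sweep` / `run_null` / `run_synth` / `run_report` process
every case they can, log a structured reason per exclusion (e.g. "no K17⁻
tumor"), write deterministic CSVs (fixed column order, rows sorted by
case/marker/compartment, `NA` sentinels) and a JSON manifest with the
config hash and per-case status, and exit non-zero only when all cases
fail. Configuration is YAML; every study constant (band depth, cell
diameters, resolution, tie rule, connectivity, replicate count) is a
configurable default, never hard-coded.

## Known limitations

* Cell counts are area-equivalents, not segmented cells; markers whose true
  cell size departs from the 8/16 µm disks are proportionally mis-scaled
  (the ratio statistic is invariant to this).
* The influence partition ignores tissue anisotropy and treats the slide as
  a flat metric space.
* The placement null conditions on the estimated, not true, cell number;
  residual overlap bias in that estimate is second-order at realistic
  densities (~1–3 %).
* Stratified analyses inherit the cohort machinery's assumption of
  independent cases; no mixed-effects modelling is attempted.
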