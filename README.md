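# zonescore

Zone-based spatial quantification of the tumor–immune microenvironment in
multiplex-IHC label masks, relative to tumor-cell keratin 17 (K17) status.

In pancreatic ductal adenocarcinoma (PDAC), K17 marks an aggressive,
immune-cold basal tumor phenotype. Given per-pixel multi-class segmentation
masks of a tissue section — K17⁺ tumor, K17⁻ tumor, four immune markers
(CD8, CD4, CD16⁺/CD163⁻ "M1" and CD16⁺/CD163⁺ "M2" macrophages) and
background/stroma — `zonescore` answers a topographic question: *are immune
cells preferentially located near K17-negative rather than K17-positive
tumor?*

## The method

1. **Zone partitioning.** An exact Euclidean distance transform maps every
   pixel to its nearest K17⁺ and K17⁻ tumor pixel. Non-tumor pixels in
   direct contact with tumor (8-adjacency) or enclosed inside hole-filled
   tumor nests are **intratumoral**; remaining stroma pixels within a band
   depth *d* (default 25 µm) of the nearest tumor are **peritumoral**. Each
   zone pixel is attributed to the K17 *influence* class of its nearest
   tumor pixel.
2. **Zone scores.** For each immune marker *i* and compartment, the pixels
   of that marker falling in each influence zone are converted to a
   continuous cell-count estimate
   `CellCount = pixels × resolution² / (π (D/2)²)` with D = 8 µm for
   lymphocytes and 16 µm for macrophages, and normalised by the zone area:

   `ZS_i = CellCount_i / ZoneArea` (cells/µm²),

   the **Tumor/Stromal Zone Score**. The per-case effect measure is the
   ratio `ZS(K17⁻) / ZS(K17⁻⁺)`.
3. **Random-placement null.** The observed log-ratio for one marker is
   compared with the distribution obtained by re-placing the same number of
   simulated cells (disks of the marker's diameter) uniformly at random over
   the compartment, re-tallying with identical machinery;
   `p = (1 + #{|null| ≥ |obs|}) / (n_reps + 1)`.
4. **Cohort statistics.** Two-sided paired t-tests on per-case
   `ZS(K17⁻) − ZS(K17⁺)` differences, the fraction of cases with ratio > 1,
   Spearman correlation of digital vs. manual K17 scores, and stratified
   subgroup analyses (stage, grade, nodal status, neoadjuvant therapy,
   mutation status) with no multiplicity adjustment (flagged in output).

A fully tested synthetic-cohort generator (blobby tumor nests with mosaic
K17 labelling; immune cells placed by a zone-inhomogeneous Poisson disk
process with known effect ratios) stands in for the restricted clinical
whole-slide images, so every stage is testable end to end.

## Worked example

```python
import zonescore as zs

# a synthetic 50-case cohort with a 2x CD8 enrichment in K17- zones
spec = zs.SyntheticSpec(effect_ratio={"cd8": 2.0}, seed=0)
masks, meta = zs.generate_cohort(spec, 50)

rows = []
for mask in masks:
    partition = zs.classify_zones(mask)          # 25 um band by default
    rows.extend(zs.zone_scores(mask, partition))
scores = zs.scores_to_frame(rows)

cd8 = scores[(scores.marker == "cd8") & (scores.compartment == "peritumoral")]
result = zs.paired_test(cd8)
print(f"median ratio  {cd8.ratio_neg_over_pos.median():.2f}")
print(f"t = {result.t_statistic:.2f}, p = {result.p_value:.2g}")
print(f"ratio > 1 in {result.fraction_neg_dominant:.0%} of "
      f"{result.n_ratio_defined} cases")
```

prints

```
median ratio  2.11
t = 8.87, p = 1.1e-11
ratio > 1 in 89% of 47 cases
```

— the planted two-fold K17⁻ enrichment is recovered (median ratio ≈ 2),
the cohort-level paired test is decisively significant, and ~90 % of cases
are individually K17⁻-dominant. Cases whose geometry contains only one K17
class have an undefined ratio and are excluded from the fraction (counted
and reported), while their densities still enter the paired test when
defined.

## Command line

```sh
zonescore synth --out fixture --n-cases 5          # synthetic fixture dir
zonescore score --config run.yaml                  # per-case scores + tests
zonescore sweep --config run.yaml                  # 25-200 um depth sweep
zonescore null  --config run.yaml --seed 1         # placement null tests
zonescore report --scores out/zone_scores.csv \
    --metadata fixture/metadata.csv --group neoadjuvant --out strat
```

Every run writes deterministic CSVs plus a `manifest.json` recording the
configuration hash, package version and a per-case status with structured
exclusion reasons.

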