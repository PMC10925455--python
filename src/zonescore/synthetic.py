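"""Synthetic label-mask cohorts with known spatial ground truth.

The generator emulates the data regime the analysis expects: tumor nests
with irregular borders and a mosaic of K17-positive / K17-negative status,
surrounded by stroma in which the four immune markers are placed as disks
(8 um lymphocytes, 16 um macrophages) by an inhomogeneous Poisson process.
Placement intensities are defined over the *true* zone partition computed by
the zoning module on the tumor-only mask before any immune cell is placed,
so ground truth and measurement share one geometry and tests isolate
estimation error from geometric disagreement.

Each case's intensity in a zone is ``base_intensity[marker]`` (cells/mm^2,
K17+ peritumoral reference) times ``effect_ratio[marker]`` for K17-negative
zones, times a per-case lognormal factor (sd ``case_random_sd`` on the log
scale) shared by all zones of the case — so the planted K17-/K17+ ratio of a
case is exactly ``effect_ratio`` while absolute densities vary between
cases.  Intratumoral intensities are set so that ``intra_fraction`` of a
zone's expected cells fall inside the (hole-filled) nests.

Randomness uses counter-based Philox streams keyed by ``(seed, case
index)``, so cohorts are reproducible across platforms and a case does not
depend on how many cases are generated.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .mask_model import DEFAULT_SCHEME, IMMUNE_ROLES, ClassScheme, LabelMask
from .scoring import DEFAULT_GEOMETRY, digital_k17_score, disk_pixel_offsets
from .zoning import (
    INTRA_NEG, INTRA_POS, PERI_NEG, PERI_POS, ZONE_NAMES,
    DEFAULT_BAND_DEPTH_UM, ZonePartition, classify_zones,
)


def _per_marker(value, defaults: Mapping[str, float]) -> dict[str, float]:
    """Broadcast a scalar, or fill a partial per-marker mapping from defaults."""
    if isinstance(value, Mapping):
        return {m: float(value.get(m, defaults[m])) for m in IMMUNE_ROLES}
    return {m: float(value) for m in IMMUNE_ROLES}


_DEFAULT_BASE = {"cd4": 400.0, "cd8": 300.0, "cd16": 200.0, "cd163": 300.0}


@dataclass
class SyntheticSpec:
    """Generative parameters for a synthetic cohort.

    Intensities are in cells/mm^2 of zone area; defaults are in the range
    reported for immune infiltrates of pancreatic ductal adenocarcinoma
    (on the order of 10^2 cells/mm^2 per marker).
    """

    image_shape: tuple[int, int] = (1160, 1160)
    resolution_um_per_px: float = 0.346
    n_nests: int = 8
    nest_scale_um: float = 50.0
    k17_pos_fraction: float = 0.5
    base_intensity: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_BASE)
    )
    effect_ratio: dict[str, float] = field(
        default_factory=lambda: {m: 1.0 for m in IMMUNE_ROLES}
    )
    intra_fraction: dict[str, float] = field(
        default_factory=lambda: {m: 0.15 for m in IMMUNE_ROLES}
    )
    decay_um: float | None = None
    case_random_sd: float = 0.3
    band_depth_um: float = DEFAULT_BAND_DEPTH_UM
    manual_noise_sd: float = 0.1
    seed: int = 0
    scheme: ClassScheme = field(default_factory=lambda: DEFAULT_SCHEME)

    def __post_init__(self) -> None:
        self.base_intensity = _per_marker(self.base_intensity, _DEFAULT_BASE)
        self.effect_ratio = _per_marker(
            self.effect_ratio, {m: 1.0 for m in IMMUNE_ROLES}
        )
        self.intra_fraction = _per_marker(
            self.intra_fraction, {m: 0.15 for m in IMMUNE_ROLES}
        )
        if not 0.0 <= self.k17_pos_fraction <= 1.0:
            raise ValueError("k17_pos_fraction must lie in [0, 1]")
        if any(v < 0 for v in self.base_intensity.values()):
            raise ValueError("base intensities must be >= 0")
        if any(v < 0 for v in self.effect_ratio.values()):
            raise ValueError("effect ratios must be >= 0")
        if any(not 0.0 <= v < 1.0 for v in self.intra_fraction.values()):
            raise ValueError("intra fractions must lie in [0, 1)")
        if self.case_random_sd < 0:
            raise ValueError("case_random_sd must be >= 0")
        if not self.band_depth_um > 0:
            raise ValueError("band_depth_um must be > 0")


def _case_rng(spec: SyntheticSpec, stream: int) -> np.random.Generator:
    # Philox is counter-based: (seed, stream) keys give independent
    # reproducible substreams regardless of how many cases are drawn.
    return np.random.Generator(
        np.random.Philox(key=np.array([spec.seed, stream], dtype=np.uint64))
    )


def _tumor_field(
    spec: SyntheticSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean tumor mask (union of blobby nests with noisy borders) + nest centers."""
    h, w = spec.image_shape
    r_px = spec.nest_scale_um / spec.resolution_um_per_px
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    field = np.full((h, w), -np.inf)
    margin = min(r_px, h / 4, w / 4)
    centers = np.empty((spec.n_nests, 2))
    for i in range(spec.n_nests):
        cr = rng.uniform(margin, h - margin)
        cc = rng.uniform(margin, w - margin)
        radius = r_px * np.exp(rng.normal(0.0, 0.25))
        centers[i] = (cr, cc)
        d = np.sqrt((rows - cr) ** 2 + (cols - cc) ** 2)
        field = np.maximum(field, 1.0 - d / radius)
    noise = rng.standard_normal((h, w))
    sigma = max(r_px / 3.0, 1.0)
    noise = ndimage.gaussian_filter(noise, sigma=sigma)
    sd = noise.std()
    if sd > 0:
        noise /= sd
    return (field + 0.25 * noise) > 0.0, centers


def _assign_k17(
    tumor: np.ndarray, centers: np.ndarray, spec: SyntheticSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Mosaic K17 labelling: each nest is K17+ with prob ``k17_pos_fraction``.

    Tumor pixels take the status of the nearest nest seed, so nests that
    merged into one connected blob still show a K17+/K17- mosaic, as mixed
    tumors do.
    """
    is_pos_nest = rng.random(len(centers)) < spec.k17_pos_fraction
    rr, cc = np.nonzero(tumor)
    d2 = ((rr[:, None] - centers[None, :, 0]) ** 2
          + (cc[:, None] - centers[None, :, 1]) ** 2)
    nearest = np.argmin(d2, axis=1)
    pos = np.zeros(tumor.shape, dtype=bool)
    pos[rr, cc] = is_pos_nest[nearest]
    neg = tumor & ~pos
    return pos, neg


def _stamp_disks(canvas: np.ndarray, centers_flat: np.ndarray,
                 offsets: np.ndarray, label: int,
                 allowed: np.ndarray | None) -> None:
    """Stamp disk pixels (label wins over current canvas) at flat-index centers."""
    if centers_flat.size == 0:
        return
    h, w = canvas.shape
    cr, cc = np.divmod(centers_flat, w)
    rr = cr[:, None] + offsets[None, :, 0]
    cc2 = cc[:, None] + offsets[None, :, 1]
    ok = (rr >= 0) & (rr < h) & (cc2 >= 0) & (cc2 < w)
    rr, cc2 = rr[ok], cc2[ok]
    if allowed is not None:
        keep = allowed[rr, cc2]
        rr, cc2 = rr[keep], cc2[keep]
    canvas[rr, cc2] = label


def generate_case(
    spec: SyntheticSpec, case_index: int
) -> tuple[LabelMask, dict]:
    """One synthetic case: label mask plus its ground-truth record.

    The ground truth records, per marker and zone, the true Poisson
    intensity (cells/um^2) used for placement, plus the case's lognormal
    factor, planted effect ratios and digital K17 score of the tumor-only
    mask.  A parameter draw yielding zero tumor pixels retries on the next
    substream; ten failures raise.
    """
    scheme = spec.scheme
    for attempt in range(10):
        rng = _case_rng(spec, (case_index << 8) | attempt)
        tumor, centers = _tumor_field(spec, rng)
        if tumor.any():
            break
    else:
        raise RuntimeError(
            f"case {case_index}: no tumor pixels after 10 attempts"
        )
    pos, neg = _assign_k17(tumor, centers, spec, rng)

    h, w = spec.image_shape
    res = spec.resolution_um_per_px
    tumor_only = np.full((h, w), scheme.label("background"),
                         dtype=np.int64)
    tumor_only[pos] = scheme.label("tumor_k17pos")
    tumor_only[neg] = scheme.label("tumor_k17neg")
    case_id = f"case{case_index:03d}"
    tumor_mask = LabelMask(pixels=tumor_only, resolution_um_per_px=res,
                           case_id=case_id, scheme=scheme)
    truth_partition = classify_zones(tumor_mask, band_depth_um=spec.band_depth_um)
    zone = truth_partition.zone
    px_area_mm2 = (res ** 2) / 1e6   # mm^2 per pixel

    # distance weights for optional decay placement in the band
    dmin = np.minimum(truth_partition.dist_pos_um, truth_partition.dist_neg_um)

    case_factor = float(np.exp(rng.normal(0.0, spec.case_random_sd)))
    peri_canvas = np.zeros((h, w), dtype=np.int64)
    intra_canvas = np.zeros((h, w), dtype=np.int64)
    intra_region = (zone == INTRA_POS) | (zone == INTRA_NEG)

    truth = {
        "case_id": case_id,
        "case_factor": case_factor,
        "digital_k17_score": (digital_k17_score(tumor_mask)
                              if tumor.any() else np.nan),
    }
    zone_px = {z: np.flatnonzero(zone == z) for z in
               (PERI_POS, PERI_NEG, INTRA_POS, INTRA_NEG)}
    zone_area_mm2 = {z: zone_px[z].size * px_area_mm2 for z in zone_px}

    for marker in IMMUNE_ROLES:
        label = scheme.label(marker)
        kind = scheme.marker_kind[marker]
        offsets = disk_pixel_offsets(DEFAULT_GEOMETRY.diameter_um(kind), res)
        base = spec.base_intensity[marker] * case_factor      # cells/mm^2
        lam = {
            PERI_POS: base,
            PERI_NEG: base * spec.effect_ratio[marker],
        }
        share = spec.intra_fraction[marker]
        for peri_z, intra_z in ((PERI_POS, INTRA_POS), (PERI_NEG, INTRA_NEG)):
            expected_peri = lam[peri_z] * zone_area_mm2[peri_z]
            if zone_area_mm2[intra_z] > 0 and share > 0:
                lam[intra_z] = (share / (1.0 - share)) * expected_peri \
                    / zone_area_mm2[intra_z]
            else:
                lam[intra_z] = 0.0

        for z in (PERI_POS, PERI_NEG, INTRA_POS, INTRA_NEG):
            truth[f"lambda_{marker}_{ZONE_NAMES[z]}_per_mm2"] = lam[z]
            n_expect = lam[z] * zone_area_mm2[z]
            n_cells = int(rng.poisson(n_expect)) if n_expect > 0 else 0
            pixels = zone_px[z]
            if n_cells == 0 or pixels.size == 0:
                continue
            if spec.decay_um is not None and z in (PERI_POS, PERI_NEG):
                wgt = np.exp(-dmin.ravel()[pixels] / spec.decay_um)
                wgt /= wgt.sum()
                centers = rng.choice(pixels, size=n_cells, p=wgt)
            else:
                centers = pixels[rng.integers(0, pixels.size, n_cells)]
            if z in (PERI_POS, PERI_NEG):
                _stamp_disks(peri_canvas, centers, offsets, label,
                             allowed=~tumor)
            else:
                _stamp_disks(intra_canvas, centers, offsets, label,
                             allowed=intra_region)
        truth[f"true_ratio_{marker}"] = spec.effect_ratio[marker]

    final = tumor_only.copy()
    peri_sel = peri_canvas > 0
    final[peri_sel] = peri_canvas[peri_sel]
    intra_sel = intra_canvas > 0
    final[intra_sel] = intra_canvas[intra_sel]
    mask = LabelMask(pixels=final, resolution_um_per_px=res,
                     case_id=case_id, scheme=scheme)
    return mask, truth


def generate_cohort(
    spec: SyntheticSpec, n_cases: int
) -> tuple[list[LabelMask], pd.DataFrame]:
    """A cohort of independent cases plus a metadata/ground-truth table.

    Metadata columns include randomly assigned clinical strata (stage,
    grade, lymph_node, neoadjuvant, subtype, KRAS status) and a
    ``manual_k17_score`` — the digital score of the tumor-only mask plus
    bounded Gaussian noise (sd ``manual_noise_sd``), emulating a
    pathologist's semi-quantitative read.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    masks: list[LabelMask] = []
    records: list[dict] = []
    for i in range(n_cases):
        mask, truth = generate_case(spec, i)
        meta_rng = _case_rng(spec, (i << 8) | 0x80)
        truth["stage"] = meta_rng.choice(["I", "II", "III", "IV"])
        truth["grade"] = int(meta_rng.integers(1, 4))
        truth["lymph_node"] = meta_rng.choice(["negative", "positive"])
        truth["neoadjuvant"] = meta_rng.choice(["no", "yes"])
        truth["subtype"] = meta_rng.choice(["conventional", "basal"])
        truth["KRAS"] = meta_rng.choice(["WT", "Mutant"])
        noisy = truth["digital_k17_score"] + meta_rng.normal(
            0.0, spec.manual_noise_sd
        )
        truth["manual_k17_score"] = float(np.clip(noisy, 0.0, 1.0))
        masks.append(mask)
        records.append(truth)
    meta = pd.DataFrame(records)
    cols = ["case_id"] + [c for c in meta.columns if c != "case_id"]
    return masks, meta[cols]


def write_fixture(
    out_dir: str | Path, spec: SyntheticSpec, n_cases: int
) -> Path:
    """Materialise a cohort as a fixture directory loadable by the pipeline.

    Layout: ``masks/<case_id>.tif``, ``scheme.yaml``, ``metadata.csv``
    (clinical columns + manual score), ``ground_truth.csv`` (full record).
    """
    from .mask_model import write_mask

    out_dir = Path(out_dir)
    mask_dir = out_dir / "masks"
    mask_dir.mkdir(parents=True, exist_ok=True)
    masks, meta = generate_cohort(spec, n_cases)
    for m in masks:
        write_mask(m, mask_dir / f"{m.case_id}.tif")
    import yaml

    scheme_data = spec.scheme.to_dict()
    scheme_data["resolution_um_per_px"] = float(spec.resolution_um_per_px)
    (out_dir / "scheme.yaml").write_text(
        yaml.safe_dump(scheme_data, sort_keys=True)
    )
    clinical_cols = ["case_id", "stage", "grade", "lymph_node", "neoadjuvant",
                     "subtype", "KRAS", "manual_k17_score"]
    meta[clinical_cols].to_csv(out_dir / "metadata.csv", index=False,
                               na_rep="NA", lineterminator="\n")
    meta.to_csv(out_dir / "ground_truth.csv", index=False, na_rep="NA",
                lineterminator="\n")
    return out_dir
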