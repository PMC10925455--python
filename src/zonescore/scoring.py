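"""Tumor/Stromal Zone Scores: pixel tallies -> cell counts -> zone densities.

The estimation chain is purely pixel-based: for each immune marker and each
zone, the marker's pixels falling in that zone are counted, converted to a
physical area (``pixels x resolution^2``), and divided by the area of one
average cell — lymphocytes (CD4, CD8) are approximated as 8 um diameter
disks, macrophages (CD16, CD163) as 16 um disks.  The resulting continuous
cell-count estimate divided by the zone's area is the Tumor/Stromal Zone
Score ``ZS`` (cells per um^2; multiply by 1e6 for the cells/mm^2 scale used
in figures).  The K17-negative over K17-positive ratio of zone scores is the
normalised per-case effect measure.

No connected-component segmentation is attempted: an immune blob straddling
a zone boundary contributes its pixels to each side proportionally.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mask_model import IMMUNE_ROLES, LabelMask
from .zoning import (
    INTRA_NEG, INTRA_POS, PERI_NEG, PERI_POS, NoTumorError, ZonePartition,
)

logger = logging.getLogger(__name__)

#: conversion between internal cells/um^2 and reporting cells/mm^2
UM2_PER_MM2 = 1e6

COMPARTMENTS = ("intratumoral", "peritumoral")


@dataclass(frozen=True)
class CellGeometry:
    """Average immune-cell footprints used for pixel-to-count conversion."""

    lymphocyte_diameter_um: float = 8.0
    macrophage_diameter_um: float = 16.0

    def __post_init__(self) -> None:
        if self.lymphocyte_diameter_um <= 0 or self.macrophage_diameter_um <= 0:
            raise ValueError("cell diameters must be positive")

    def diameter_um(self, marker_kind: str) -> float:
        if marker_kind == "lymphocyte":
            return self.lymphocyte_diameter_um
        if marker_kind == "macrophage":
            return self.macrophage_diameter_um
        raise ValueError(f"unknown marker kind {marker_kind!r}")

    def cell_area_um2(self, marker_kind: str) -> float:
        d = self.diameter_um(marker_kind)
        return math.pi * (d / 2.0) ** 2


DEFAULT_GEOMETRY = CellGeometry()


def estimate_cell_count(
    pixel_count: float,
    marker_kind: str,
    resolution_um_per_px: float,
    geometry: CellGeometry = DEFAULT_GEOMETRY,
) -> float:
    """Continuous cell-count estimate from a raw pixel tally.

    ``count = pixel_count * resolution^2 / (pi * (diameter / 2)^2)`` —
    linear in the pixel count, quadratic in the resolution, no rounding.
    """
    if pixel_count < 0:
        raise ValueError("pixel_count must be non-negative")
    if resolution_um_per_px <= 0:
        raise ValueError("resolution must be positive")
    area_um2 = pixel_count * resolution_um_per_px ** 2
    return area_um2 / geometry.cell_area_um2(marker_kind)


@dataclass
class ZoneScore:
    """Per-case, per-marker, per-compartment zone score pair and ratio.

    ``zs_pos`` / ``zs_neg`` are densities in cells/um^2; they are ``nan``
    (undefined sentinel) when the corresponding zone has zero area.
    ``ratio_neg_over_pos`` is defined only when both zone areas are positive
    and ``zs_pos > 0``.
    """

    case_id: str
    marker: str
    compartment: str
    band_depth_um: float
    pixel_count_pos: int
    pixel_count_neg: int
    cell_count_pos: float
    cell_count_neg: float
    zone_area_pos_um2: float
    zone_area_neg_um2: float
    zs_pos: float
    zs_neg: float
    ratio_neg_over_pos: float
    ratio_defined: bool


def zone_scores(
    mask: LabelMask,
    partition: ZonePartition,
    geometry: CellGeometry = DEFAULT_GEOMETRY,
) -> list[ZoneScore]:
    """Tumor/Stromal Zone Scores for all four markers x two compartments.

    The partition must have been derived from the same mask (shapes are
    checked).  Undefined ratios (empty zone or zero positive-zone density)
    are emitted as ``nan`` with ``ratio_defined=False`` and a logged reason;
    the underlying densities still carry into cohort-level paired tests.
    """
    if partition.shape != mask.shape:
        raise ValueError(
            f"partition shape {partition.shape} does not match "
            f"mask shape {mask.shape}"
        )
    res = mask.resolution_um_per_px
    zone = partition.zone
    areas = partition.zone_areas_um2

    out: list[ZoneScore] = []
    for marker in IMMUNE_ROLES:
        kind = mask.scheme.marker_kind[marker]
        marker_px = mask.role_mask(marker)
        zone_counts = np.bincount(zone[marker_px], minlength=5)
        for compartment, (zp, zn) in (
            ("intratumoral", (INTRA_POS, INTRA_NEG)),
            ("peritumoral", (PERI_POS, PERI_NEG)),
        ):
            px_p = int(zone_counts[zp])
            px_n = int(zone_counts[zn])
            count_p = estimate_cell_count(px_p, kind, res, geometry)
            count_n = estimate_cell_count(px_n, kind, res, geometry)
            area_p = areas[zp]
            area_n = areas[zn]
            zs_p = count_p / area_p if area_p > 0 else np.nan
            zs_n = count_n / area_n if area_n > 0 else np.nan
            if area_p > 0 and area_n > 0 and zs_p > 0:
                ratio = zs_n / zs_p
                defined = True
            else:
                ratio = np.nan
                defined = False
                reason = ("empty K17+ zone" if area_p <= 0
                          else "empty K17- zone" if area_n <= 0
                          else "zero K17+ zone density")
                logger.info(
                    "case %s %s/%s: ratio undefined (%s)",
                    mask.case_id, marker, compartment, reason,
                )
            out.append(ZoneScore(
                case_id=mask.case_id, marker=marker, compartment=compartment,
                band_depth_um=partition.band_depth_um,
                pixel_count_pos=px_p, pixel_count_neg=px_n,
                cell_count_pos=count_p, cell_count_neg=count_n,
                zone_area_pos_um2=area_p, zone_area_neg_um2=area_n,
                zs_pos=zs_p, zs_neg=zs_n,
                ratio_neg_over_pos=ratio, ratio_defined=defined,
            ))
    return out


def scores_to_frame(scores: list[ZoneScore]) -> pd.DataFrame:
    """Long-format table of zone scores (one row per case x marker x compartment)."""
    import dataclasses

    df = pd.DataFrame([dataclasses.asdict(s) for s in scores])
    return df.rename(columns={"band_depth_um": "depth_um"})


def digital_k17_score(mask: LabelMask, roi: np.ndarray | None = None) -> float:
    """Digital K17 score: K17-positive tumor area as a fraction of tumor area."""
    pos = mask.role_mask("tumor_k17pos")
    neg = mask.role_mask("tumor_k17neg")
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        pos = pos & roi
        neg = neg & roi
    n_pos = int(np.count_nonzero(pos))
    n_neg = int(np.count_nonzero(neg))
    if n_pos + n_neg == 0:
        raise NoTumorError("no tumor present")
    return n_pos / (n_pos + n_neg)


def disk_pixel_offsets(diameter_um: float, resolution_um_per_px: float) -> np.ndarray:
    """(k, 2) row/col offsets of pixels whose centers lie within a disk.

    A pixel belongs to the disk when its center is within ``diameter / 2``
    of the disk center.  This is the shared rasterisation used both by the
    synthetic generator and by the random-placement null, so simulated disks
    tally exactly like generated ones.
    """
    r_px = (diameter_um / 2.0) / resolution_um_per_px
    n = int(math.floor(r_px))
    rows, cols = np.mgrid[-n:n + 1, -n:n + 1]
    keep = rows ** 2 + cols ** 2 <= r_px ** 2
    return np.stack([rows[keep], cols[keep]], axis=1)
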