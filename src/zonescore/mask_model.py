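"""Data model and I/O for multi-class label masks, class schemes and cohort metadata.

A :class:`LabelMask` is a single-channel integer raster in which every pixel
carries exactly one class label: K17-positive tumor, K17-negative tumor, one
of four immune markers (CD4, CD8, CD16+/CD163- "M1" macrophage,
CD16+/CD163+ "M2" macrophage) or background/stroma.  The mapping from those
semantic roles to raster integers is a :class:`ClassScheme`, normally stored
as a YAML/JSON sidecar next to the raster together with the physical pixel
size (micrometres per pixel).

Because one pixel holds one label, "stroma" is operationally everything that
is neither tumor nor immune within the analysed region, and tumor/immune
overlap can only be expressed through adjacency (handled downstream by the
zoning module).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

# Semantic roles -------------------------------------------------------------

TUMOR_ROLES = ("tumor_k17pos", "tumor_k17neg")
IMMUNE_ROLES = ("cd4", "cd8", "cd16", "cd163")
ALL_ROLES = TUMOR_ROLES + IMMUNE_ROLES + ("background",)

#: lymphocytes are tallied as 8 um disks, macrophages as 16 um disks
DEFAULT_MARKER_KIND = {
    "cd4": "lymphocyte",
    "cd8": "lymphocyte",
    "cd16": "macrophage",
    "cd163": "macrophage",
}

#: scanning resolution of the source whole-slide images, um per pixel
DEFAULT_RESOLUTION_UM_PER_PX = 0.346


class MaskValidationError(ValueError):
    """A raster/scheme pair violates the label-mask contract."""


class StitchConflictError(ValueError):
    """Two overlapping patches disagree on a pixel label."""


@dataclass(frozen=True)
class ClassScheme:
    """Mapping from semantic class roles to integer raster labels.

    Parameters
    ----------
    role_to_label
        One integer label per role in :data:`ALL_ROLES`; labels must be
        unique.
    marker_kind
        Immune role -> ``{"lymphocyte", "macrophage"}``.  CD4/CD8 are
        lymphocytes, CD16/CD163 macrophages; this drives the disk diameter
        used when pixel areas are converted to cell counts.
    """

    role_to_label: Mapping[str, int]
    marker_kind: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_MARKER_KIND)
    )

    def __post_init__(self) -> None:
        missing = [r for r in ALL_ROLES if r not in self.role_to_label]
        if missing:
            raise MaskValidationError(f"scheme is missing roles: {missing}")
        labels = [int(self.role_to_label[r]) for r in ALL_ROLES]
        if len(set(labels)) != len(labels):
            raise MaskValidationError(f"scheme labels are not unique: {labels}")
        for role, kind in (("cd4", "lymphocyte"), ("cd8", "lymphocyte"),
                           ("cd16", "macrophage"), ("cd163", "macrophage")):
            if self.marker_kind.get(role) != kind:
                raise MaskValidationError(
                    f"marker_kind[{role!r}] must be {kind!r}, "
                    f"got {self.marker_kind.get(role)!r}"
                )

    def label(self, role: str) -> int:
        return int(self.role_to_label[role])

    @property
    def declared_labels(self) -> frozenset[int]:
        return frozenset(int(v) for v in self.role_to_label.values())

    @property
    def tumor_labels(self) -> tuple[int, int]:
        """(K17-positive label, K17-negative label)."""
        return self.label("tumor_k17pos"), self.label("tumor_k17neg")

    @property
    def immune_labels(self) -> dict[str, int]:
        return {r: self.label(r) for r in IMMUNE_ROLES}

    def to_dict(self) -> dict:
        return {
            "roles": {r: int(self.role_to_label[r]) for r in ALL_ROLES},
            "marker_kind": dict(self.marker_kind),
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "ClassScheme":
        roles = data.get("roles", data)
        kind = data.get("marker_kind", DEFAULT_MARKER_KIND)
        return cls(role_to_label=dict(roles), marker_kind=dict(kind))


#: convenience scheme used by the synthetic generator and examples
DEFAULT_SCHEME = ClassScheme(
    role_to_label={
        "background": 0,
        "tumor_k17pos": 1,
        "tumor_k17neg": 2,
        "cd4": 3,
        "cd8": 4,
        "cd16": 5,
        "cd163": 6,
    }
)


@dataclass
class LabelMask:
    """A validated multi-class label raster with physical resolution.

    ``pixels`` uses 0-based row/column indices with pixel-center geometry:
    the physical distance between two pixel centers is the Euclidean index
    distance times ``resolution_um_per_px``.
    """

    pixels: np.ndarray
    resolution_um_per_px: float
    case_id: str
    scheme: ClassScheme

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise MaskValidationError(
                f"mask must be 2-D, got shape {self.pixels.shape}"
            )
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise MaskValidationError(
                f"mask must be an integer raster, got dtype {self.pixels.dtype}"
            )
        if not self.resolution_um_per_px > 0:
            raise MaskValidationError(
                f"resolution_um_per_px must be > 0, got {self.resolution_um_per_px}"
            )
        present = set(np.unique(self.pixels).tolist())
        undeclared = sorted(present - self.scheme.declared_labels)
        if undeclared:
            raise MaskValidationError(
                f"mask {self.case_id!r} contains label(s) {undeclared} "
                f"not declared in the class scheme"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def role_mask(self, role: str) -> np.ndarray:
        """Boolean mask of pixels carrying ``role``'s label."""
        return self.pixels == self.scheme.label(role)


# Raster I/O -----------------------------------------------------------------

def _read_raster(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        from PIL import Image

        arr = np.asarray(Image.open(path))
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise MaskValidationError(
            f"{path}: expected a single-channel raster, got shape {arr.shape}"
        )
    if not np.issubdtype(arr.dtype, np.integer):
        raise MaskValidationError(
            f"{path}: expected integer labels, got dtype {arr.dtype}"
        )
    return arr


def read_scheme(scheme_path: str | Path) -> tuple[ClassScheme, float | None]:
    """Read a scheme sidecar (YAML or JSON); returns (scheme, resolution or None)."""
    scheme_path = Path(scheme_path)
    text = scheme_path.read_text()
    data = (json.loads(text) if scheme_path.suffix.lower() == ".json"
            else yaml.safe_load(text))
    scheme = ClassScheme.from_dict(data)
    res = data.get("resolution_um_per_px")
    return scheme, (float(res) if res is not None else None)


def read_mask(path: str | Path, scheme_path: str | Path,
              case_id: str | None = None) -> LabelMask:
    """Load a single-channel integer raster and validate it against its scheme.

    The sidecar must declare ``resolution_um_per_px``; there is no silent
    default because every downstream distance and density is physical.
    """
    path = Path(path)
    scheme, res = read_scheme(scheme_path)
    if res is None:
        raise MaskValidationError(
            f"{scheme_path}: scheme sidecar does not declare resolution_um_per_px"
        )
    pixels = _read_raster(path)
    return LabelMask(
        pixels=pixels,
        resolution_um_per_px=res,
        case_id=case_id if case_id is not None else path.stem,
        scheme=scheme,
    )


def write_mask(mask: LabelMask, path: str | Path,
               scheme_path: str | Path | None = None) -> None:
    """Write a label mask as a single-channel TIFF/PNG (label-exact round trip)."""
    path = Path(path)
    arr = mask.pixels
    if arr.min() >= 0 and arr.max() <= 255:
        arr = arr.astype(np.uint8)
    elif arr.min() >= 0 and arr.max() <= 65535:
        arr = arr.astype(np.uint16)
    else:
        arr = arr.astype(np.int32)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, arr)
    else:
        from PIL import Image

        Image.fromarray(arr).save(path)
    if scheme_path is not None:
        data = mask.scheme.to_dict()
        data["resolution_um_per_px"] = float(mask.resolution_um_per_px)
        Path(scheme_path).write_text(yaml.safe_dump(data, sort_keys=True))


def read_roi(path: str | Path, shape: tuple[int, int]) -> np.ndarray:
    """Load a binary region-of-interest raster; nonzero = inside the region."""
    arr = _read_raster(Path(path))
    if arr.shape != tuple(shape):
        raise MaskValidationError(
            f"ROI shape {arr.shape} does not match mask shape {tuple(shape)}"
        )
    return arr > 0


# Patch stitching ------------------------------------------------------------

def stitch_patches(
    patches: Sequence[tuple[LabelMask, int, int]]
) -> LabelMask:
    """Assemble patch masks (with row/col offsets) into one contiguous mask.

    Unfilled areas become background; pixels covered by more than one patch
    must agree, otherwise a :class:`StitchConflictError` reports the first
    conflicting coordinate (row-major order).  The result is invariant to
    the order in which patches are supplied.
    """
    if not patches:
        raise ValueError("no patches to stitch")
    first = patches[0][0]
    scheme, res = first.scheme, first.resolution_um_per_px
    for m, _, _ in patches:
        if m.scheme.role_to_label != scheme.role_to_label:
            raise MaskValidationError("patches use different class schemes")
        if m.resolution_um_per_px != res:
            raise MaskValidationError("patches use different resolutions")
    n_rows = max(r + m.shape[0] for m, r, c in patches)
    n_cols = max(c + m.shape[1] for m, r, c in patches)
    if min(min(r, c) for _, r, c in patches) < 0:
        raise ValueError("patch offsets must be non-negative")

    background = scheme.label("background")
    canvas = np.full((n_rows, n_cols), -1, dtype=np.int64)
    # deterministic processing order so conflict reporting is reproducible
    ordered = sorted(range(len(patches)),
                     key=lambda i: (patches[i][1], patches[i][2]))
    for i in ordered:
        m, r, c = patches[i]
        window = canvas[r:r + m.shape[0], c:c + m.shape[1]]
        conflict = (window != -1) & (window != m.pixels)
        if conflict.any():
            rr, cc = np.argwhere(conflict)[0]
            raise StitchConflictError(
                f"overlapping patches disagree at pixel "
                f"({int(r + rr)}, {int(c + cc)}): "
                f"{int(window[rr, cc])} vs {int(m.pixels[rr, cc])}"
            )
        window[...] = m.pixels
    canvas[canvas == -1] = background
    return LabelMask(
        pixels=canvas.astype(first.pixels.dtype),
        resolution_um_per_px=res,
        case_id=first.case_id,
        scheme=scheme,
    )


# Tabular output -------------------------------------------------------------

_SORT_KEYS = ("case_id", "marker", "compartment", "depth_um", "stratum")


def write_table(records, path: str | Path) -> None:
    """Write results as delimited text with a stable column and row order.

    Rows are sorted by (case_id, marker, compartment, ...) where those
    columns exist; unknown values are emitted as ``NA``.  Writing the same
    records twice produces byte-identical files.
    """
    df = to_frame(records)
    if df.shape[1] == 0:
        raise ValueError("records have an empty schema")
    keys = [k for k in _SORT_KEYS if k in df.columns]
    if keys:
        df = df.sort_values(keys, kind="mergesort").reset_index(drop=True)
    df.to_csv(path, index=False, na_rep="NA", lineterminator="\n")


def to_frame(records) -> pd.DataFrame:
    """Coerce a DataFrame / list of dataclasses / list of dicts to a DataFrame."""
    if isinstance(records, pd.DataFrame):
        return records.copy()
    rows = []
    for rec in records:
        if hasattr(rec, "__dataclass_fields__"):
            import dataclasses

            rows.append(dataclasses.asdict(rec))
        else:
            rows.append(dict(rec))
    return pd.DataFrame(rows)


# Cohort metadata ------------------------------------------------------------

def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a cohort metadata CSV; ``case_id`` mandatory and unique.

    Unknown values stay as explicit NA (pandas missing values), never
    silently dropped.
    """
    df = pd.read_csv(path, dtype={"case_id": str})
    if "case_id" not in df.columns:
        raise ValueError(f"{path}: metadata must contain a case_id column")
    if df["case_id"].duplicated().any():
        dup = df["case_id"][df["case_id"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate case_id {dup!r}")
    if "manual_k17_score" in df.columns:
        bad = df["manual_k17_score"].dropna()
        if ((bad < 0) | (bad > 1)).any():
            raise ValueError(f"{path}: manual_k17_score must lie in [0, 1]")
    return df
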