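"""I/O: MRI volumes, the ROI JSON format, ImageJ .roi files, areas CSV.

Volumes (NIfTI files or DICOM series directories) are reoriented to the
canonical RAS+ convention before slice indexing, so "coronal slice k" means
the same plane regardless of how the file stores its axes: the coronal
(anterior-posterior) axis is axis 1 of the canonical array, and slice k is
``data[:, k, :]``.  In-plane pixel spacing comes from the volume metadata
and is never silently assumed.

The ROI JSON format is defined by this package::

    {
      "spacing": {"row_mm": 0.9, "col_mm": 0.9},
      "slice_index": 88,
      "rois": [
        {"label": "MTL_REGION", "hemisphere": "RIGHT",
         "vertices": [[x, y], ...]},
        ...
      ]
    }

Vertices round-trip bit-exact (JSON shortest-repr floats).  The areas CSV
has columns ``subject_id, study_date, hemisphere, A_mm2, B_mm2, C_mm2``
with ISO-8601 dates and hemisphere in {L, R}.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import MtaiError, TableValidationError, ValidationError
from .geometry import (
    Hemisphere,
    PixelSpacing,
    PolygonROI,
    RegionAreas,
    RoiLabel,
)

__all__ = [
    "CoronalSlice",
    "load_slice",
    "read_roi_file",
    "write_roi_file",
    "read_imagej_roi",
    "read_areas_table",
    "write_areas_table",
    "AREAS_CSV_COLUMNS",
]

logger = logging.getLogger(__name__)

AREAS_CSV_COLUMNS = (
    "subject_id",
    "study_date",
    "hemisphere",
    "A_mm2",
    "B_mm2",
    "C_mm2",
)


@dataclass(frozen=True)
class CoronalSlice:
    """One coronal plane extracted from a volume, with its provenance."""

    pixels: np.ndarray
    spacing: PixelSpacing
    slice_index: int
    source_id: str

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValidationError(
                f"slice must be a non-empty 2D grid, got shape {px.shape}"
            )
        object.__setattr__(self, "pixels", px)


# ---------------------------------------------------------------------------
# volume loading


def _dicom_series_to_nifti(series_dir: Path) -> nib.Nifti1Image:
    """Stack a single-series DICOM directory into an in-memory NIfTI.

    The affine is built from ImageOrientationPatient/ImagePositionPatient
    (LPS) and converted to NIfTI's RAS; slices are sorted by their
    projection onto the slice normal.
    """
    import pydicom

    files = sorted(p for p in series_dir.iterdir() if p.is_file())
    datasets = []
    for p in files:
        try:
            ds = pydicom.dcmread(p)
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            datasets.append(ds)
    if not datasets:
        raise MtaiError(f"no DICOM images found in {series_dir}")

    ref = datasets[0]
    try:
        iop = np.asarray(ref.ImageOrientationPatient, dtype=float)
        spacing_rc = np.asarray(ref.PixelSpacing, dtype=float)  # row, col
    except AttributeError as exc:
        raise MtaiError(
            f"DICOM series lacks orientation/spacing metadata: {exc}"
        ) from exc
    row_dir, col_dir = iop[:3], iop[3:]
    normal = np.cross(row_dir, col_dir)
    datasets.sort(
        key=lambda d: float(
            np.dot(np.asarray(d.ImagePositionPatient, float), normal)
        )
    )
    positions = [np.asarray(d.ImagePositionPatient, float) for d in datasets]
    if len(datasets) > 1:
        step = float(np.dot(positions[1] - positions[0], normal))
    else:
        step = float(getattr(ref, "SliceThickness", 0) or 0)
        if step == 0:
            raise MtaiError("cannot determine DICOM slice spacing")

    vol = np.stack([d.pixel_array.T for d in datasets], axis=-1)
    # columns vary along row_dir, rows along col_dir (pixel_array is [r, c])
    affine_lps = np.eye(4)
    affine_lps[:3, 0] = row_dir * spacing_rc[1]
    affine_lps[:3, 1] = col_dir * spacing_rc[0]
    affine_lps[:3, 2] = normal * step
    affine_lps[:3, 3] = positions[0]
    lps_to_ras = np.diag([-1.0, -1.0, 1.0, 1.0])
    return nib.Nifti1Image(vol.astype(np.float64), lps_to_ras @ affine_lps)


def load_slice(volume_source: "str | Path", slice_index: int) -> CoronalSlice:
    """Extract coronal slice ``slice_index`` from a NIfTI file or DICOM dir.

    The volume is reoriented to RAS+ first; the slice is taken along the
    anterior-posterior axis.  Raises on unreadable input, an out-of-bounds
    index, or missing/degenerate spacing metadata.
    """
    src = Path(volume_source)
    if not src.exists():
        raise MtaiError(f"volume source does not exist: {src}")
    if src.is_dir():
        img = _dicom_series_to_nifti(src)
    else:
        try:
            img = nib.load(src)
        except Exception as exc:
            raise MtaiError(f"cannot read volume {src}: {exc}") from exc

    canonical = nib.as_closest_canonical(img)
    data = np.asanyarray(canonical.dataobj)
    if data.ndim != 3:
        raise ValidationError(
            f"expected a 3D volume, got shape {data.shape}"
        )
    depth = data.shape[1]
    if not (0 <= slice_index < depth):
        raise ValidationError(
            f"slice index {slice_index} out of bounds for coronal depth "
            f"{depth}"
        )
    zooms = canonical.header.get_zooms()[:3]
    row_mm, col_mm = float(zooms[0]), float(zooms[2])
    if row_mm <= 0 or col_mm <= 0:
        raise MtaiError(
            f"volume {src} has missing or degenerate in-plane spacing "
            f"({row_mm}, {col_mm}); refusing to assume 1 mm"
        )
    return CoronalSlice(
        pixels=np.asarray(data[:, slice_index, :]),
        spacing=PixelSpacing(row_mm=row_mm, col_mm=col_mm),
        slice_index=int(slice_index),
        source_id=str(src),
    )


# ---------------------------------------------------------------------------
# ROI JSON


def write_roi_file(
    path: "str | Path",
    rois: Sequence[PolygonROI],
    spacing: PixelSpacing,
    slice_index: int,
) -> None:
    payload = {
        "spacing": {"row_mm": spacing.row_mm, "col_mm": spacing.col_mm},
        "slice_index": int(slice_index),
        "rois": [
            {
                "label": r.label.value,
                "hemisphere": r.hemisphere.value,
                "vertices": [[x, y] for x, y in r.vertices],
            }
            for r in rois
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_roi_file(
    path: "str | Path",
) -> tuple[list[PolygonROI], PixelSpacing, int]:
    """Parse an ROI JSON file; schema violations name the offending field."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"{path}: not valid JSON: {exc}") from exc

    def _require(obj: dict, key: str, where: str):
        if key not in obj:
            raise ValidationError(f"{path}: missing field {where}{key}")
        return obj[key]

    sp = _require(payload, "spacing", "")
    spacing = PixelSpacing(
        row_mm=float(_require(sp, "row_mm", "spacing.")),
        col_mm=float(_require(sp, "col_mm", "spacing.")),
    )
    slice_index = int(_require(payload, "slice_index", ""))
    rois = []
    for i, entry in enumerate(_require(payload, "rois", "")):
        where = f"rois[{i}]."
        rois.append(
            PolygonROI(
                label=_require(entry, "label", where),
                hemisphere=_require(entry, "hemisphere", where),
                vertices=_require(entry, "vertices", where),
            )
        )
    return rois, spacing, slice_index


# ---------------------------------------------------------------------------
# ImageJ .roi


def read_imagej_roi(
    path: "str | Path",
    label: "RoiLabel | str",
    hemisphere: "Hemisphere | str",
) -> PolygonROI:
    """Read a polygon-type ImageJ ``.roi`` file into a :class:`PolygonROI`.

    Only the polygon (0), freehand (3), and traced (4) ROI types are
    accepted.  ImageJ files carry no region label or laterality, so both
    are supplied by the caller.  Integer ImageJ coordinates map directly to
    this package's pixel-center convention.
    """
    raw = Path(path).read_bytes()
    if len(raw) < 64 or raw[:4] != b"Iout":
        raise ValidationError(f"{path}: not an ImageJ ROI file")
    roi_type = raw[6]
    if roi_type not in (0, 3, 4):  # polygon, freehand, traced
        raise ValidationError(
            f"{path}: ImageJ ROI type {roi_type} is not a polygon"
        )
    top, left, _bottom, _right, n = struct.unpack(">5h", raw[8:18])
    if n < 3:
        raise ValidationError(f"{path}: polygon has only {n} vertices")
    coords = struct.unpack(f">{2 * n}h", raw[64 : 64 + 4 * n])
    xs = [left + c for c in coords[:n]]
    ys = [top + c for c in coords[n:]]
    return PolygonROI(
        label=label, hemisphere=hemisphere, vertices=list(zip(xs, ys))
    )


# ---------------------------------------------------------------------------
# areas CSV


def write_areas_table(
    path: "str | Path",
    rows: Sequence[tuple[str, RegionAreas]],
) -> None:
    """Write (subject_id, RegionAreas) pairs as the areas CSV."""
    records = []
    for subject_id, areas in rows:
        records.append(
            {
                "subject_id": subject_id,
                "study_date": (
                    areas.study_date.isoformat() if areas.study_date else ""
                ),
                "hemisphere": "L"
                if areas.hemisphere is Hemisphere.LEFT
                else "R",
                "A_mm2": areas.A,
                "B_mm2": areas.B,
                "C_mm2": areas.C,
            }
        )
    pd.DataFrame(records, columns=list(AREAS_CSV_COLUMNS)).to_csv(
        path, index=False
    )


def read_areas_table(
    path: "str | Path",
) -> dict[str, list[RegionAreas]]:
    """Read and validate an areas CSV, grouped by subject.

    Each subject maps to its :class:`RegionAreas` rows sorted by study date
    (undated rows first, in file order).  All invalid rows are collected
    and reported together with their 1-based data-row numbers in a
    :class:`TableValidationError`; nothing is silently dropped.
    """
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        logger.warning("areas table %s is empty", path)
        return {}
    missing = [c for c in AREAS_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing column(s) {', '.join(missing)}"
        )
    if df.empty:
        logger.warning("areas table %s has no data rows", path)
        return {}

    result: dict[str, list[RegionAreas]] = {}
    errors: list[tuple[int, str]] = []
    for pos, (_, row) in enumerate(df.iterrows(), start=1):
        try:
            date: Optional[_dt.date] = None
            raw_date = row["study_date"]
            if isinstance(raw_date, str) and raw_date.strip():
                try:
                    date = _dt.date.fromisoformat(raw_date.strip())
                except ValueError:
                    raise ValidationError(
                        f"malformed date {raw_date!r} (expected ISO-8601)"
                    ) from None
            try:
                a, b, c = (
                    float(row["A_mm2"]),
                    float(row["B_mm2"]),
                    float(row["C_mm2"]),
                )
            except (TypeError, ValueError):
                raise ValidationError(
                    f"non-numeric area in row: "
                    f"{row['A_mm2']!r}, {row['B_mm2']!r}, {row['C_mm2']!r}"
                ) from None
            areas = RegionAreas(
                hemisphere=Hemisphere.parse(row["hemisphere"]),
                A=a,
                B=b,
                C=c,
                study_date=date,
            )
            result.setdefault(str(row["subject_id"]), []).append(areas)
        except ValidationError as exc:
            errors.append((pos, str(exc)))
    if errors:
        raise TableValidationError(errors)
    for rows_ in result.values():
        rows_.sort(key=lambda r: (r.study_date is not None, r.study_date or _dt.date.min))
    return result
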