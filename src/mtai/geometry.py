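"""Planimetry of manually traced ROIs on a single coronal MRI slice.

The MTAi protocol measures three regions per hemisphere on one coronal
slice at the level of the interpeduncular fossa:

* **A** — the medial temporal lobe (MTL) region, bounded inferiorly by the
  tentorium cerebelli, medially by the cerebral peduncles, superiorly by the
  roof of the temporal horn, and laterally by the collateral sulcus;
* **B** — the parenchyma within A (hippocampus + parahippocampal gyrus,
  excluding fimbria taenia and choroid plexus);
* **C** — the body of the ipsilateral lateral ventricle.

This module turns traced polygon contours (pixel coordinates) into physical
areas in mm² via the shoelace formula, with validation that rejects
degenerate or self-intersecting tracings and enforces the anatomical
constraint B ≤ A.

Coordinate convention: vertices are 0-based pixel coordinates at pixel
centers, ``x`` = column index, ``y`` = row index.  Physical area is the
pixel-grid shoelace area multiplied by ``row_mm × col_mm``.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from shapely.geometry import Polygon as _ShapelyPolygon

from .errors import GeometryError, ValidationError

__all__ = [
    "Hemisphere",
    "RoiLabel",
    "PixelSpacing",
    "PolygonROI",
    "RegionAreas",
    "polygon_area",
    "areas_from_rois",
]

# tolerance absorbing float noise when the B contour coincides with A
_B_LE_A_RTOL = 1e-6


class Hemisphere(str, Enum):
    LEFT = "LEFT"
    RIGHT = "RIGHT"

    @classmethod
    def parse(cls, value: "str | Hemisphere") -> "Hemisphere":
        """Accept 'LEFT'/'RIGHT' and the short CSV forms 'L'/'R'."""
        if isinstance(value, Hemisphere):
            return value
        key = str(value).strip().upper()
        aliases = {"L": "LEFT", "R": "RIGHT"}
        key = aliases.get(key, key)
        try:
            return cls[key]
        except KeyError:
            raise ValidationError(f"unknown hemisphere {value!r}") from None


class RoiLabel(str, Enum):
    """The three traced regions; values match the ROI JSON schema."""

    MTL_REGION = "MTL_REGION"       # region A
    PARENCHYMA = "PARENCHYMA"       # region B
    VENTRICLE_BODY = "VENTRICLE_BODY"  # region C

    @classmethod
    def parse(cls, value: "str | RoiLabel") -> "RoiLabel":
        if isinstance(value, RoiLabel):
            return value
        try:
            return cls[str(value).strip().upper()]
        except KeyError:
            raise ValidationError(f"unknown ROI label {value!r}") from None


@dataclass(frozen=True)
class PixelSpacing:
    """In-plane physical scaling of the slice, mm per pixel.

    ``row_mm`` is the spacing along image rows (the y/row direction) and
    ``col_mm`` along columns; anisotropic in-plane spacing is supported.
    """

    row_mm: float
    col_mm: float

    def __post_init__(self) -> None:
        if not (self.row_mm > 0 and self.col_mm > 0):
            raise ValidationError(
                f"pixel spacing must be positive, got "
                f"({self.row_mm}, {self.col_mm})"
            )

    @property
    def pixel_area_mm2(self) -> float:
        return self.row_mm * self.col_mm


@dataclass(frozen=True)
class PolygonROI:
    """A closed, simple planar contour traced on the slice.

    The vertex list is implicitly closed (the last vertex connects back to
    the first).  Validation rejects contours with fewer than 3 vertices,
    repeated consecutive vertices, or self-intersections — a figure-eight
    tracing is a user mistake, not a measurement.
    """

    label: RoiLabel
    hemisphere: Hemisphere
    vertices: tuple[tuple[float, float], ...]

    def __init__(
        self,
        label: "RoiLabel | str",
        hemisphere: "Hemisphere | str",
        vertices: Sequence[Sequence[float]],
    ) -> None:
        object.__setattr__(self, "label", RoiLabel.parse(label))
        object.__setattr__(self, "hemisphere", Hemisphere.parse(hemisphere))
        verts = tuple((float(x), float(y)) for x, y in vertices)
        object.__setattr__(self, "vertices", verts)
        self._validate()

    def _validate(self) -> None:
        verts = self.vertices
        if len(verts) < 3:
            raise ValidationError(
                f"polygon needs >= 3 vertices, got {len(verts)}"
            )
        n = len(verts)
        for i in range(n):
            if verts[i] == verts[(i + 1) % n]:
                raise ValidationError(
                    f"consecutive identical vertices at index {i}"
                )
        poly = _ShapelyPolygon(verts)
        # is_valid catches self-intersection and zero-area degeneracy
        if not poly.is_valid:
            raise GeometryError(
                "contour is not simple (self-intersecting or degenerate)"
            )
        if poly.area == 0.0:
            raise GeometryError("contour encloses zero area")

    def as_shapely(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.vertices)


@dataclass(frozen=True)
class RegionAreas:
    """The (A, B, C) area triple for one hemisphere of one study, in mm²."""

    hemisphere: Hemisphere
    A: float
    B: float
    C: float
    study_date: Optional[_dt.date] = field(default=None)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "hemisphere", Hemisphere.parse(self.hemisphere)
        )
        for name in ("A", "B", "C"):
            v = getattr(self, name)
            if not (v > 0):
                raise ValidationError(f"area {name} must be > 0, got {v}")
        if self.B > self.A * (1.0 + _B_LE_A_RTOL):
            raise ValidationError(
                f"parenchyma area B={self.B} exceeds its bounding MTL "
                f"region A={self.A}"
            )

    @property
    def parenchymal_loss(self) -> float:
        """A − B: the CSF-filled portion of the MTL region, mm²."""
        return self.A - self.B


def polygon_area(roi: PolygonROI, spacing: PixelSpacing) -> float:
    """Physical area of a traced contour, mm².

    Shoelace (Gauss) area of the implicitly closed vertex list in pixel
    units, scaled by ``row_mm × col_mm``.  The result is independent of
    winding direction and of which vertex starts the list.
    """
    return roi.as_shapely().area * spacing.pixel_area_mm2


def areas_from_rois(
    rois: Sequence[PolygonROI],
    spacing: PixelSpacing,
    study_date: Optional[_dt.date] = None,
) -> RegionAreas:
    """Build :class:`RegionAreas` from exactly one ROI per region label.

    All three ROIs must carry the same hemisphere tag.  Raises
    :class:`ValidationError` on missing/duplicate labels, mixed
    hemispheres, or B > A (the parenchyma cannot exceed its bounding
    region).
    """
    if len(rois) != 3:
        raise ValidationError(
            f"expected exactly 3 ROIs for one hemisphere, got {len(rois)}"
        )
    hemis = {r.hemisphere for r in rois}
    if len(hemis) != 1:
        raise ValidationError(
            f"ROIs span multiple hemispheres: {sorted(h.value for h in hemis)}"
        )
    by_label: dict[RoiLabel, PolygonROI] = {}
    for r in rois:
        if r.label in by_label:
            raise ValidationError(f"duplicate ROI label {r.label.value}")
        by_label[r.label] = r
    missing = set(RoiLabel) - set(by_label)
    if missing:
        raise ValidationError(
            "missing ROI label(s): "
            + ", ".join(sorted(m.value for m in missing))
        )
    return RegionAreas(
        hemisphere=hemis.pop(),
        A=polygon_area(by_label[RoiLabel.MTL_REGION], spacing),
        B=polygon_area(by_label[RoiLabel.PARENCHYMA], spacing),
        C=polygon_area(by_label[RoiLabel.VENTRICLE_BODY], spacing),
        study_date=study_date,
    )
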