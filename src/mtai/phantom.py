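"""Synthetic coronal-slice phantom with analytically known areas.

The phantom stands in for a traced clinical slice: per hemisphere it emits
three elliptical polygon ROIs — the MTL region (A), the parenchyma inside
it (B), and the ventricle body (C) — whose shoelace areas equal the
analytic target areas *exactly*.  An inscribed n-gon of an ellipse with
semi-axes (a, b) has area (n/2)·a·b·sin(2π/n); the generator solves that
relation for a·b, so the polygon area is the target by construction rather
than an O(1/n²) approximation of it.  This makes :class:`PhantomTruth` an
exact oracle for every downstream computation.

The atrophy model: medial temporal atrophy shrinks the parenchyma,
B = B0·(1 − m), with the bounding MTL region A fixed at A0 so the (A − B)
signal is isolated; global atrophy enlarges the ventricle, C = C0·(1 + g).
Hence the analytic index

    MTAi(m, g) = (A0 − B0·(1 − m)) × 10 / (C0·(1 + g)),

strictly increasing in m and strictly decreasing in g — medial temporal
loss raises the index, unspecific global atrophy dilutes it.  A variant
with a shrinking MTL region A(m) = A0 − mtl_region_shrinkage·m·B0 is
exposed as an option for callers who want the bounding region to follow.

Default baselines A0=330, B0=290, C0=165 mm² give a baseline MTAi ≈ 2.42,
anchored near the illustrative healthy-control reference mean — a
plausibility anchor, not a claim of anatomical realism; the shapes are
ellipses because an exact oracle beats realistic contours for testing a
planimetric index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
from skimage.draw import polygon as _fill_polygon

from .errors import ValidationError
from .geometry import (
    Hemisphere,
    PixelSpacing,
    PolygonROI,
    RoiLabel,
)
from .io import CoronalSlice

__all__ = [
    "PhantomParams",
    "PhantomTruth",
    "HemisphereTruth",
    "generate_phantom",
    "rasterize_phantom",
    "write_phantom_volume",
    "REGION_INTENSITY",
]

#: rasterized fill intensities (background stays 0)
REGION_INTENSITY = {
    RoiLabel.MTL_REGION: 80.0,
    RoiLabel.PARENCHYMA: 160.0,
    RoiLabel.VENTRICLE_BODY: 40.0,
}


@dataclass(frozen=True)
class PhantomParams:
    """Generator knobs; defaults emulate a symmetric healthy-control slice.

    ``mtl_atrophy_*`` are fractional parenchymal losses in [0, 1);
    ``global_atrophy`` is the fractional ventricular enlargement (≥ 0);
    baselines are in mm².  ``mtl_region_shrinkage`` ∈ [0, 1] optionally
    lets the MTL region A shrink with atrophy (0 = A fixed, the default).
    """

    mtl_atrophy_left: float = 0.0
    mtl_atrophy_right: float = 0.0
    global_atrophy: float = 0.0
    vertex_count: int = 256
    spacing: PixelSpacing = field(
        default_factory=lambda: PixelSpacing(0.5, 0.5)
    )
    seed: int = 0
    A0: float = 330.0
    B0: float = 290.0
    C0: float = 165.0
    mtl_region_shrinkage: float = 0.0

    def __post_init__(self) -> None:
        for name in ("mtl_atrophy_left", "mtl_atrophy_right"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValidationError(f"{name} must be in [0, 1), got {v}")
        if self.global_atrophy < 0:
            raise ValidationError(
                f"global_atrophy must be >= 0, got {self.global_atrophy}"
            )
        if self.vertex_count < 16:
            raise ValidationError(
                f"vertex_count must be >= 16, got {self.vertex_count}"
            )
        if not (0 < self.B0 <= self.A0) or self.C0 <= 0:
            raise ValidationError(
                f"baselines must satisfy 0 < B0 <= A0 and C0 > 0, got "
                f"A0={self.A0}, B0={self.B0}, C0={self.C0}"
            )
        if not (0.0 <= self.mtl_region_shrinkage <= 1.0):
            raise ValidationError(
                "mtl_region_shrinkage must be in [0, 1], got "
                f"{self.mtl_region_shrinkage}"
            )

    def analytic_areas(self, hemisphere: Hemisphere) -> tuple[float, float, float]:
        m = (
            self.mtl_atrophy_left
            if hemisphere is Hemisphere.LEFT
            else self.mtl_atrophy_right
        )
        B = self.B0 * (1.0 - m)
        A = self.A0 - self.mtl_region_shrinkage * m * self.B0
        C = self.C0 * (1.0 + self.global_atrophy)
        return A, B, C


@dataclass(frozen=True)
class HemisphereTruth:
    A: float
    B: float
    C: float
    mtai: float


@dataclass(frozen=True)
class PhantomTruth:
    """Analytic ground truth: areas (mm²), per-hemisphere MTAi, and IA."""

    left: HemisphereTruth
    right: HemisphereTruth
    ia_percent: float


def _ellipse_polygon(
    center_mm: tuple[float, float],
    target_area_mm2: float,
    aspect: float,
    n: int,
    phase: float,
    spacing: PixelSpacing,
) -> list[tuple[float, float]]:
    """Inscribed n-gon with physical shoelace area exactly ``target_area_mm2``.

    The contour is laid out in mm, where semi-axes satisfy
    a·b = 2·target/(n·sin(2π/n)) with a/b = aspect — the inscribed-polygon
    area (n/2)·a·b·sin(2π/n) is the target for any sampling phase — and is
    then mapped to pixel coordinates (x /= col_mm, y /= row_mm) so that
    pixel-grid area × pixel area recovers the target exactly even for
    anisotropic spacing.
    """
    ab = 2.0 * target_area_mm2 / (n * math.sin(2.0 * math.pi / n))
    a = math.sqrt(ab * aspect)
    b = math.sqrt(ab / aspect)
    cx, cy = center_mm
    theta = phase + 2.0 * math.pi * np.arange(n) / n
    return [
        (
            (cx + a * math.cos(t)) / spacing.col_mm,
            (cy + b * math.sin(t)) / spacing.row_mm,
        )
        for t in theta
    ]


def generate_phantom(
    params: PhantomParams,
) -> tuple[list[PolygonROI], PhantomTruth]:
    """Emit six polygon ROIs (three per hemisphere) plus analytic truth.

    The parenchyma ellipse is concentric with, and geometrically inside,
    its MTL ellipse (same aspect ratio, same sampling phase, strictly
    smaller).  Deterministic for a given seed: the seed only randomizes
    the sampling phase of each contour, which leaves areas untouched.
    """
    rng = np.random.default_rng(params.seed)
    n = params.vertex_count

    rois: list[PolygonROI] = []
    truths: dict[Hemisphere, HemisphereTruth] = {}
    # anatomical layout in mm on a 128x128 mm field (x=col, y=row mm):
    # MTL regions inferior-lateral, ventricle bodies superior to them; the
    # default 0.5 mm spacing places everything inside a 256x256 raster
    centers_mm = {
        Hemisphere.RIGHT: {"mtl": (44.0, 80.0), "vent": (54.0, 50.0)},
        Hemisphere.LEFT: {"mtl": (84.0, 80.0), "vent": (74.0, 50.0)},
    }
    for hemi in (Hemisphere.LEFT, Hemisphere.RIGHT):
        A, B, C = params.analytic_areas(hemi)
        mtai = (A - B) * 10.0 / C
        truths[hemi] = HemisphereTruth(A=A, B=B, C=C, mtai=mtai)

        phase_ab = float(rng.uniform(0, 2 * math.pi))
        phase_c = float(rng.uniform(0, 2 * math.pi))
        mtl_center = centers_mm[hemi]["mtl"]
        spacing = params.spacing
        # same center, aspect and phase: the B n-gon is the A n-gon scaled
        # by sqrt(B/A) < 1 about their common center, hence strictly inside
        rois.append(
            PolygonROI(
                RoiLabel.MTL_REGION,
                hemi,
                _ellipse_polygon(mtl_center, A, 2.0, n, phase_ab, spacing),
            )
        )
        rois.append(
            PolygonROI(
                RoiLabel.PARENCHYMA,
                hemi,
                _ellipse_polygon(mtl_center, B, 2.0, n, phase_ab, spacing),
            )
        )
        rois.append(
            PolygonROI(
                RoiLabel.VENTRICLE_BODY,
                hemi,
                _ellipse_polygon(
                    centers_mm[hemi]["vent"], C, 0.6, n, phase_c, spacing
                ),
            )
        )

    l, r = truths[Hemisphere.LEFT], truths[Hemisphere.RIGHT]
    if l.mtai + r.mtai > 0:
        ia = (l.mtai - r.mtai) / (l.mtai + r.mtai) * 100.0
    else:
        ia = float("nan")
    return rois, PhantomTruth(left=l, right=r, ia_percent=ia)


def rasterize_phantom(
    rois: list[PolygonROI],
    spacing: PixelSpacing,
    image_size: tuple[int, int] = (256, 256),
    slice_index: int = 0,
) -> CoronalSlice:
    """Fill the phantom ROIs into a synthetic intensity slice.

    Regions get the distinct intensities of :data:`REGION_INTENSITY`
    (parenchyma overwrites its bounding MTL fill); background stays 0.
    Raises if any vertex falls outside the image bounds.
    """
    rows, cols = image_size
    img = np.zeros((rows, cols), dtype=np.float64)
    order = [RoiLabel.MTL_REGION, RoiLabel.VENTRICLE_BODY, RoiLabel.PARENCHYMA]
    for label in order:
        for roi in (r for r in rois if r.label is label):
            xs = np.array([v[0] for v in roi.vertices])
            ys = np.array([v[1] for v in roi.vertices])
            if (
                xs.min() < 0
                or ys.min() < 0
                or xs.max() > cols - 1
                or ys.max() > rows - 1
            ):
                raise ValidationError(
                    f"ROI {roi.label.value}/{roi.hemisphere.value} exceeds "
                    f"image bounds {image_size}"
                )
            rr, cc = _fill_polygon(ys, xs, shape=img.shape)
            img[rr, cc] = REGION_INTENSITY[label]
    return CoronalSlice(
        pixels=img,
        spacing=spacing,
        slice_index=slice_index,
        source_id="phantom",
    )


def write_phantom_volume(
    slice_: CoronalSlice,
    path: "str | Path",
    depth: int = 16,
    slice_index: Optional[int] = None,
    slice_thickness_mm: float = 1.0,
) -> int:
    """Embed the phantom slice in a NIfTI stack, coronal at ``slice_index``.

    The volume is written in RAS+ with the anterior-posterior axis as axis
    1, so ``io.load_slice(path, k)`` returns the embedded plane with its
    spacing intact.  Returns the index used (defaults to the stack middle).
    """
    k = depth // 2 if slice_index is None else slice_index
    if not (0 <= k < depth):
        raise ValidationError(f"slice index {k} out of range for depth {depth}")
    rows, cols = slice_.pixels.shape
    vol = np.zeros((rows, depth, cols), dtype=np.float64)
    vol[:, k, :] = slice_.pixels
    affine = np.diag(
        [slice_.spacing.row_mm, slice_thickness_mm, slice_.spacing.col_mm, 1.0]
    )
    nib.save(nib.Nifti1Image(vol, affine), str(path))
    return k
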