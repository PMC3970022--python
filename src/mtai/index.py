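"""The Medial Temporal Atrophy index and its derived quantities.

Core formulas (areas in mm², per hemisphere on one coronal slice):

    MTAi   = (A − B) × 10 / C
    IA     = (lMTAi − rMTAi) / (lMTAi + rMTAi) × 100        [percent, signed]
    yrMTA  = [(A2 − B2) − (A1 − B1)] × 120 / months
    yrMTAr = [(A2 − B2) − (A1 − B1)] × 120 / [(C2 − C1) × months]

A − B is the CSF-filled fraction of the MTL region (how much parenchyma has
been lost); dividing by the ipsilateral ventricle-body area C normalizes
that medial-temporal signal against global, unspecific brain atrophy.  The
×10 is a presentation scale; ×120 = ×10 × 12 months/year carries it into
the yearly rates.

|IA| below ~3% means the two hemispheric indices agree and their median
(the mean, for two values) can stand alone; above it, per-hemisphere values
must be reported because the median hides the asymmetry.

All computation is unrounded; display layers round (2 decimals by default).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Optional

from .errors import DomainError, ValidationError
from .geometry import Hemisphere, RegionAreas

__all__ = [
    "DEFAULT_ASYMMETRY_THRESHOLD",
    "MtaiResult",
    "LongitudinalResult",
    "ReferenceRow",
    "compute_mtai",
    "compute_ia",
    "classify_asymmetry",
    "summarize_bilateral",
    "compute_yrmta",
    "compute_yrmtar",
    "summarize_longitudinal",
    "months_between",
    "reference_table",
    "REFERENCE_TABLE_DISCLAIMER",
]

#: |IA| at or above this percentage flags significant hemispheric asymmetry.
DEFAULT_ASYMMETRY_THRESHOLD = 3.0


@dataclass(frozen=True)
class MtaiResult:
    """Bilateral MTAi summary for one study.

    ``median_mtai`` is the median of the two hemispheric values, i.e. their
    arithmetic mean.  ``ia_percent`` is signed: negative exactly when the
    right index exceeds the left.  When ``asymmetric`` is true the median
    should not be reported alone.
    """

    left_mtai: float
    right_mtai: float
    median_mtai: float
    ia_percent: float
    asymmetric: bool
    threshold: float = DEFAULT_ASYMMETRY_THRESHOLD

    def as_dict(self, decimals: int = 2) -> dict:
        return {
            "left_mtai": round(self.left_mtai, decimals),
            "right_mtai": round(self.right_mtai, decimals),
            "median_mtai": round(self.median_mtai, decimals),
            "ia_percent": round(self.ia_percent, decimals),
            "asymmetric": self.asymmetric,
            "asymmetry_threshold_percent": self.threshold,
        }


@dataclass(frozen=True)
class LongitudinalResult:
    """Yearly atrophy rates between two dated studies of one hemisphere.

    ``yr_mta`` carries the ×10 index scale and mm² units of the area change;
    ``yr_mta_relative`` is dimensionless (None when C did not change, in
    which case the relative rate is undefined).
    """

    hemisphere: Hemisphere
    yr_mta: float
    yr_mta_relative: Optional[float]
    months_between: float

    def as_dict(self, decimals: int = 2) -> dict:
        return {
            "hemisphere": self.hemisphere.value,
            "yr_mta": round(self.yr_mta, decimals),
            "yr_mta_relative": (
                None
                if self.yr_mta_relative is None
                else round(self.yr_mta_relative, decimals)
            ),
            "months_between": round(self.months_between, decimals),
        }


@dataclass(frozen=True)
class ReferenceRow:
    """One diagnostic group of the illustrative reference table."""

    group: str
    mean_mmtai: float
    mean_ia: float


REFERENCE_TABLE_DISCLAIMER = (
    "Reference values are merely illustrative, not informative; "
    "they are not validated diagnostic cut-offs."
)

# Illustrative group means (median MTAi, IA %) from short pilot series;
# non-normative by construction and flagged as such in every rendering.
_REFERENCE_ROWS = (
    ReferenceRow("HealthyControl", 2.4, 1.8),
    ReferenceRow("MCI", 3.1, 2.4),
    ReferenceRow("MildAD", 4.6, 2.6),
    ReferenceRow("ModerateAD", 5.2, 2.8),
    ReferenceRow("SevereAD", 5.8, 3.4),
    ReferenceRow("FTLD", 3.8, 8.2),
    ReferenceRow("DLB", 2.7, 3.7),
)


def compute_mtai(areas: RegionAreas) -> float:
    """MTAi = (A − B) × 10 / C, unrounded.

    Pure ratio of areas: invariant under uniform scaling of (A, B, C),
    strictly increasing as B shrinks and strictly decreasing as C grows.
    """
    if not (areas.C > 0):
        raise DomainError(f"ventricle area C must be > 0, got {areas.C}")
    if areas.B > areas.A * (1 + 1e-6):
        raise DomainError(
            f"B={areas.B} > A={areas.A}: parenchyma exceeds MTL region"
        )
    return (areas.A - areas.B) * 10.0 / areas.C


def compute_ia(left_mtai: float, right_mtai: float) -> float:
    """Index of Asymmetry, percent: (l − r)/(l + r) × 100.

    Antisymmetric in its arguments and bounded in [−100, 100] for
    non-negative indices.  Undefined when both indices are zero.
    """
    if left_mtai < 0 or right_mtai < 0:
        raise DomainError(
            f"MTAi values must be non-negative, got "
            f"({left_mtai}, {right_mtai})"
        )
    total = left_mtai + right_mtai
    if total == 0:
        raise DomainError(
            "IA undefined: both hemispheric MTAi values are zero"
        )
    return (left_mtai - right_mtai) / total * 100.0


def classify_asymmetry(
    ia_percent: float, threshold: float = DEFAULT_ASYMMETRY_THRESHOLD
) -> bool:
    """True when |IA| reaches the significance threshold (default 3%)."""
    return abs(ia_percent) >= threshold


def summarize_bilateral(
    left: RegionAreas,
    right: RegionAreas,
    threshold: float = DEFAULT_ASYMMETRY_THRESHOLD,
) -> MtaiResult:
    """Compute both hemispheric indices, their median, IA and the flag."""
    if left.hemisphere is not Hemisphere.LEFT:
        raise ValidationError(
            f"first argument must be LEFT areas, got {left.hemisphere.value}"
        )
    if right.hemisphere is not Hemisphere.RIGHT:
        raise ValidationError(
            f"second argument must be RIGHT areas, got "
            f"{right.hemisphere.value}"
        )
    l_mtai = compute_mtai(left)
    r_mtai = compute_mtai(right)
    ia = compute_ia(l_mtai, r_mtai)
    return MtaiResult(
        left_mtai=l_mtai,
        right_mtai=r_mtai,
        median_mtai=(l_mtai + r_mtai) / 2.0,
        ia_percent=ia,
        asymmetric=classify_asymmetry(ia, threshold),
        threshold=threshold,
    )


def _check_longitudinal_pair(
    first: RegionAreas, second: RegionAreas, months: float
) -> None:
    if not (months > 0):
        raise DomainError(f"months_between must be > 0, got {months}")
    if first.hemisphere is not second.hemisphere:
        raise ValidationError(
            f"hemisphere mismatch: {first.hemisphere.value} vs "
            f"{second.hemisphere.value}"
        )


def compute_yrmta(
    first: RegionAreas, second: RegionAreas, months_between: float
) -> float:
    """Yearly rate of MTL atrophy between two studies of one hemisphere.

    [(A2 − B2) − (A1 − B1)] × 120 / months — the change in the CSF-filled
    MTL area, annualized, on the ×10 index scale.  Zero when the
    parenchymal loss did not change.
    """
    _check_longitudinal_pair(first, second, months_between)
    delta = second.parenchymal_loss - first.parenchymal_loss
    return delta * 120.0 / months_between


def compute_yrmtar(
    first: RegionAreas, second: RegionAreas, months_between: float
) -> float:
    """Yearly relative rate: the yrMTA numerator per unit of ventricular
    enlargement, [(A2 − B2) − (A1 − B1)] × 120 / [(C2 − C1) × months].

    Undefined (raises :class:`DomainError`) when C2 = C1 — there is no
    ventricular change to normalize against.
    """
    _check_longitudinal_pair(first, second, months_between)
    dC = second.C - first.C
    if dC == 0:
        raise DomainError(
            "yrMTAr undefined: no ventricular change (C2 = C1) to "
            "normalize against"
        )
    delta = second.parenchymal_loss - first.parenchymal_loss
    return delta * 120.0 / (dC * months_between)


def months_between(first: _dt.date, second: _dt.date) -> float:
    """Calendar interval in months: day count × 12 / 365.25."""
    days = (second - first).days
    if days <= 0:
        raise DomainError(
            f"second study ({second}) must postdate the first ({first})"
        )
    return days * 12.0 / 365.25


def summarize_longitudinal(
    first: RegionAreas,
    second: RegionAreas,
    months: Optional[float] = None,
) -> LongitudinalResult:
    """Both yearly rates for one hemisphere between two dated studies.

    ``months`` defaults to the interval between the two study dates.
    ``yr_mta_relative`` is None when the ventricle area did not change.
    """
    if months is None:
        if first.study_date is None or second.study_date is None:
            raise ValidationError(
                "months not given and study dates are missing"
            )
        months = months_between(first.study_date, second.study_date)
    yr = compute_yrmta(first, second, months)
    try:
        yrr: Optional[float] = compute_yrmtar(first, second, months)
    except DomainError:
        yrr = None
    return LongitudinalResult(
        hemisphere=first.hemisphere,
        yr_mta=yr,
        yr_mta_relative=yrr,
        months_between=months,
    )


def reference_table() -> list[ReferenceRow]:
    """The illustrative 7-group reference table (non-normative).

    Group means of the median MTAi and of the IA from short pilot series;
    every rendering must carry :data:`REFERENCE_TABLE_DISCLAIMER`.
    """
    return list(_REFERENCE_ROWS)
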