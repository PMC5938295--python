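"""Calibrated planimetry of carpal-bone regions of interest.

A region of interest (ROI) drawn around the capitate or hamate on a
posterior-anterior hand radiograph is an ordered polygon in pixel
coordinates. This module turns such polygons into physical areas:

* :func:`polygon_area` — shoelace area of a simple polygon;
* :func:`calibrate` — mm-per-pixel scale from a fiducial object of known
  diameter (a coin imaged under the same geometry);
* :func:`apply_calibration` — pixel² → mm² conversion;
* :func:`ch_score` — the capitohamate (CH) statistic, the sum of the
  capitate and hamate areas for one hand;
* :func:`consensus_area` — two-reviewer reconciliation under the
  ">10 % relative difference triggers re-measurement" rule.

Pixel coordinates are continuous planar points; polygons are implicitly
closed (last vertex connects back to the first).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon

HANDS = ("left", "right")
BONES = ("capitate", "hamate")

__all__ = [
    "RoiPolygon",
    "CalibrationFiducial",
    "AreaMeasurement",
    "ChScore",
    "ConsensusResult",
    "polygon_area",
    "validate_polygon",
    "calibrate",
    "apply_calibration",
    "ch_score",
    "consensus_area",
]


@dataclass(frozen=True)
class RoiPolygon:
    """One manually drawn bone outline for one subject/hand/reviewer.

    Vertices are in pixel units, ordered along the boundary, implicitly
    closed. Validity (>= 3 vertices, no repeated consecutive vertices,
    simple, i.e. non-self-intersecting) is checked at construction.
    """

    subject_id: str
    hand: str
    bone: str
    reviewer_id: str
    vertices: tuple = field(default=())

    def __post_init__(self) -> None:
        if self.hand not in HANDS:
            raise ValueError(f"hand must be one of {HANDS}, got {self.hand!r}")
        if self.bone not in BONES:
            raise ValueError(f"bone must be one of {BONES}, got {self.bone!r}")
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        validate_polygon(verts)
        object.__setattr__(self, "vertices", verts)

    def area_px2(self) -> float:
        return polygon_area(self.vertices)


def validate_polygon(vertices: Sequence[Sequence[float]]) -> None:
    """Raise ``ValueError`` unless *vertices* form a valid simple polygon."""
    if len(vertices) < 3:
        raise ValueError(f"polygon needs >= 3 vertices, got {len(vertices)}")
    arr = np.asarray(vertices, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("vertices must be an (n, 2) array of planar points")
    if not np.all(np.isfinite(arr)):
        raise ValueError("vertices contain non-finite coordinates")
    closed = np.vstack([arr, arr[:1]])
    if np.any(np.all(np.diff(closed, axis=0) == 0.0, axis=1)):
        raise ValueError("polygon has repeated consecutive vertices")
    if not _ShapelyPolygon(arr).is_simple:
        raise ValueError("polygon is self-intersecting")


def polygon_area(vertices: Sequence[Sequence[float]]) -> float:
    """Absolute area of a simple polygon by the shoelace formula.

    The result is in squared input units and is invariant to vertex-order
    reversal, cyclic rotation of the vertex list, and translation.
    """
    validate_polygon(vertices)
    arr = np.asarray(vertices, dtype=float)
    x, y = arr[:, 0], arr[:, 1]
    # centre first for numerical stability on far-from-origin ROIs
    x = x - x.mean()
    y = y - y.mean()
    cross = x * np.roll(y, -1) - np.roll(x, -1) * y
    return abs(0.5 * float(np.sum(cross)))


@dataclass(frozen=True)
class CalibrationFiducial:
    """A fiducial of known physical size imaged under study geometry.

    Either ``measured_diameter_mm`` (PACS readout, same units as truth —
    yields the relative measurement error) or ``measured_diameter_px``
    (raw pixels — yields the mm/px scale) may be given; both at once are
    allowed.
    """

    true_diameter_mm: float
    measured_diameter_mm: float | None = None
    measured_diameter_px: float | None = None

    def __post_init__(self) -> None:
        if self.true_diameter_mm <= 0:
            raise ValueError("true_diameter_mm must be positive")
        for name in ("measured_diameter_mm", "measured_diameter_px"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive")
        if self.measured_diameter_mm is None and self.measured_diameter_px is None:
            raise ValueError("at least one measured diameter is required")


def calibrate(fiducial: CalibrationFiducial) -> tuple[float | None, float | None]:
    """Return ``(scale_mm_per_px, relative_error_pct)`` from a fiducial.

    ``scale`` is true diameter (mm) / measured diameter (px); ``None`` if no
    pixel measurement was supplied.  ``relative_error`` is
    ``100 * |measured_mm - true_mm| / true_mm`` rounded to 2 decimals;
    ``None`` if no mm measurement was supplied.
    """
    scale = None
    if fiducial.measured_diameter_px is not None:
        scale = fiducial.true_diameter_mm / fiducial.measured_diameter_px
    rel_err = None
    if fiducial.measured_diameter_mm is not None:
        rel_err = round(
            100.0
            * abs(fiducial.measured_diameter_mm - fiducial.true_diameter_mm)
            / fiducial.true_diameter_mm,
            2,
        )
    return scale, rel_err


def apply_calibration(area_px2: float, scale_mm_per_px: float) -> float:
    """Convert a pixel-squared area to mm² (area scales with scale²)."""
    if scale_mm_per_px <= 0:
        raise ValueError("scale must be positive")
    if area_px2 < 0:
        raise ValueError("area cannot be negative")
    return float(area_px2) * scale_mm_per_px**2


@dataclass(frozen=True)
class AreaMeasurement:
    subject_id: str
    hand: str
    bone: str
    reviewer_id: str
    area_mm2: float

    def __post_init__(self) -> None:
        if self.area_mm2 <= 0:
            raise ValueError("area_mm2 must be positive")


@dataclass(frozen=True)
class ChScore:
    """Capitohamate score: capitate area + hamate area for one hand.

    ``ch_area_mm2`` equals the exact sum of the two inputs by construction.
    """

    subject_id: str
    hand: str
    source: str  # reviewer id or "consensus"
    capitate_area_mm2: float
    hamate_area_mm2: float
    ch_area_mm2: float


class MissingBoneError(ValueError):
    """A bone required for the CH score is absent (not yet ossified)."""


def ch_score(
    capitate_mm2: float | None,
    hamate_mm2: float | None,
    *,
    subject_id: str = "",
    hand: str = "left",
    source: str = "consensus",
) -> ChScore:
    """Sum the capitate and hamate areas into a :class:`ChScore`.

    Raises :class:`MissingBoneError` if either bone area is missing
    (unossified) and ``ValueError`` for non-positive areas.
    """
    for name, v in (("capitate", capitate_mm2), ("hamate", hamate_mm2)):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise MissingBoneError(f"{name} unossified: no CH score")
        if v <= 0:
            raise ValueError(f"{name} area must be positive, got {v}")
    return ChScore(
        subject_id=subject_id,
        hand=hand,
        source=source,
        capitate_area_mm2=float(capitate_mm2),
        hamate_area_mm2=float(hamate_mm2),
        ch_area_mm2=float(capitate_mm2) + float(hamate_mm2),
    )


@dataclass(frozen=True)
class ConsensusResult:
    """Outcome of the two-reviewer agreement rule for one area.

    If the relative difference (percent of the two-reviewer mean) is at
    most 10 %, ``value`` holds the arithmetic mean and
    ``needs_remeasure`` is False; otherwise ``value`` is None and a
    consensus re-measurement must be supplied by the caller.
    """

    value: float | None
    needs_remeasure: bool
    relative_difference_pct: float


def consensus_area(a1: float, a2: float, threshold_pct: float = 10.0) -> ConsensusResult:
    """Reconcile two reviewers' areas for the same ROI.

    Differences of at most *threshold_pct* percent (of the two-reviewer
    mean) are considered negligible and averaged; larger differences
    signal that the reviewers must re-measure to reach consensus.
    Symmetric in its two arguments.
    """
    if a1 <= 0 or a2 <= 0:
        raise ValueError("areas must be positive")
    mean = 0.5 * (a1 + a2)
    rel = 100.0 * abs(a1 - a2) / mean
    if rel <= threshold_pct:
        return ConsensusResult(value=mean, needs_remeasure=False, relative_difference_pct=rel)
    return ConsensusResult(value=None, needs_remeasure=True, relative_difference_pct=rel)
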