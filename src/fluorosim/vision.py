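"""Colored-marker detection and 2-D wire pose.

Two differently colored circular markers are fixed to the DHS guide-wire.
Segmentation is an axis-aligned box threshold in RGB (per-channel absolute
tolerance around a target color); the largest 8-connected component per
color gives the marker, and its unweighted pixel centroid the sub-pixel
marker position.  The wire tip is extrapolated from the two centroids by a
per-plane ``tip_offset`` calibration distance, with the markers treated as
rigidly collinear with the tip (operators are instructed not to bend the
wire or cover the markers).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from skimage import measure

from fluorosim.errors import (
    AmbiguousMarkerError,
    DegeneratePoseError,
    MarkersNotFoundError,
)

Role = Literal["proximal", "distal"]

#: Components smaller than this many pixels are treated as speckle noise.
DEFAULT_MIN_AREA = 10


@dataclass(frozen=True)
class ColorSpec:
    """Marker color target with per-channel absolute tolerance."""

    target: tuple[int, int, int]
    tol: int
    role: Role

    def __post_init__(self) -> None:
        if self.tol < 0:
            raise ValueError("tol must be >= 0")
        if not all(0 <= c <= 255 for c in self.target):
            raise ValueError("target channels must be in [0, 255]")
        if self.role not in ("proximal", "distal"):
            raise ValueError(f"role must be proximal/distal, got {self.role!r}")


@dataclass(frozen=True)
class MarkerDetection:
    """One detected marker: sub-pixel centroid (x, y), area, role."""

    centroid: tuple[float, float]
    area: int
    role: Role


@dataclass(frozen=True)
class WirePose2D:
    """Wire tip point and unit direction (proximal -> distal) in a frame."""

    tip: tuple[float, float]
    direction: tuple[float, float]

    def __post_init__(self) -> None:
        n = float(np.hypot(*self.direction))
        if abs(n - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")


def _validate_frame(frame: np.ndarray) -> np.ndarray:
    a = np.asarray(frame)
    if a.ndim != 3 or a.shape[2] != 3:
        raise ValueError("frame must be an H x W x 3 RGB array")
    if a.shape[0] < 16 or a.shape[1] < 16:
        raise ValueError("frame must be at least 16 x 16")
    return a


def segment_color(frame: np.ndarray, spec: ColorSpec) -> np.ndarray:
    """Boolean mask: True where every channel is within ``tol`` of target.

    An empty mask is a valid result (marker absent or occluded).
    """
    a = _validate_frame(frame).astype(np.int16)
    target = np.asarray(spec.target, dtype=np.int16)
    return np.all(np.abs(a - target) <= spec.tol, axis=-1)


def _largest_component(mask: np.ndarray, min_area: int, strict: bool):
    """Largest 8-connected component with area >= min_area, or None.

    Ties on area are broken by the smaller (row, col) of the component's
    top-left bounding-box corner, for determinism; in strict mode a tie
    raises :class:`AmbiguousMarkerError` instead.
    """
    labels = measure.label(mask, connectivity=2)
    props = [p for p in measure.regionprops(labels) if p.area >= min_area]
    if not props:
        return None
    best_area = max(p.area for p in props)
    winners = [p for p in props if p.area == best_area]
    if len(winners) > 1 and strict:
        raise AmbiguousMarkerError(
            f"{len(winners)} components tie at area {best_area}"
        )
    return min(winners, key=lambda p: (p.bbox[0], p.bbox[1]))


def locate_markers(
    frame: np.ndarray,
    specs: Sequence[ColorSpec],
    min_area: int = DEFAULT_MIN_AREA,
    strict: bool = False,
) -> list[MarkerDetection]:
    """Detect exactly one marker per role from its color segmentation.

    Raises
    ------
    MarkersNotFoundError
        If any role has no component of at least ``min_area`` pixels —
        the occlusion signal (e.g. a hand covering a tracking marker).
    AmbiguousMarkerError
        In ``strict`` mode, when two components of one color tie in area.
    """
    roles = sorted(s.role for s in specs)
    if roles != ["distal", "proximal"]:
        raise ValueError("specs must contain one proximal and one distal entry")
    out = []
    for spec in specs:
        comp = _largest_component(segment_color(frame, spec), min_area, strict)
        if comp is None:
            raise MarkersNotFoundError(
                f"no {spec.role} marker component >= {min_area} px "
                "(marker occluded or out of frame?)"
            )
        row, col = comp.centroid  # regionprops returns (row, col)
        out.append(
            MarkerDetection(centroid=(float(col), float(row)),
                            area=int(comp.area), role=spec.role)
        )
    return out


def wire_pose_from_markers(
    proximal: MarkerDetection,
    distal: MarkerDetection,
    tip_offset: float,
) -> WirePose2D:
    """Extrapolate the wire tip beyond the distal marker.

    ``direction`` is the unit vector from the proximal to the distal
    centroid; ``tip = distal + tip_offset * direction``.  ``tip_offset`` is
    the calibrated marker-to-tip distance in pixels for the current plane.

    Raises
    ------
    DegeneratePoseError
        If the centroids are within 1 px of each other.
    """
    p = np.asarray(proximal.centroid, dtype=float)
    d = np.asarray(distal.centroid, dtype=float)
    sep = float(np.linalg.norm(d - p))
    if sep <= 1.0:
        raise DegeneratePoseError(
            f"marker centroids separated by only {sep:.3g} px"
        )
    u = (d - p) / sep
    tip = d + tip_offset * u
    return WirePose2D(tip=(float(tip[0]), float(tip[1])),
                      direction=(float(u[0]), float(u[1])))
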