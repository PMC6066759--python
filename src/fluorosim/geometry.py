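"""Planar affine calibration between camera and radiograph coordinates.

During setup the operator clicks three points on the camera image and the
three matching points on the pre-loaded hip radiograph, once per imaging
plane (AP and cross-table lateral).  Three point correspondences exactly
determine the six parameters of a planar affine map, so the fit is a direct
linear solve — no least squares, no tolerance knobs.

Coordinate convention used throughout the package: 0-based, ``x`` is the
pixel column (grows rightward), ``y`` the pixel row (grows downward),
origin at the top-left pixel corner.  Files storing points carry this in a
``"coords"`` header field.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from fluorosim.errors import CollinearPointsError, SingularTransformError

Plane = Literal["AP", "CTL"]

#: Twice-signed-triangle-area threshold (px^2) below which the three source
#: points are treated as collinear.  Sub-pixel clicks on any realistic frame
#: never legitimately approach this.
COLLINEARITY_TOL = 1e-6

COORDS_CONVENTION = "xy-0-based-top-left"


def _as_point(p: Sequence[float]) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (2,) or not np.all(np.isfinite(a)):
        raise ValueError(f"expected a finite (x, y) point, got {p!r}")
    return a


@dataclass(frozen=True)
class AffineTransform2D:
    """Six-parameter planar map ``(x, y) -> (a x + b y + tx, c x + d y + ty)``.

    ``m`` is the 2x3 matrix ``[[a, b, tx], [c, d, ty]]``.
    """

    m: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.m, dtype=float)
        if m.shape != (2, 3) or not np.all(np.isfinite(m)):
            raise ValueError("affine matrix must be a finite 2x3 array")
        object.__setattr__(self, "m", m)

    @property
    def linear(self) -> np.ndarray:
        return self.m[:, :2]

    @property
    def translation(self) -> np.ndarray:
        return self.m[:, 2]

    @property
    def det(self) -> float:
        return float(np.linalg.det(self.linear))

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))


def triangle_area2(points: Sequence[Sequence[float]]) -> float:
    """Twice the signed area of the triangle spanned by three points."""
    (x0, y0), (x1, y1), (x2, y2) = (tuple(map(float, p)) for p in points)
    return (x1 - x0) * (y2 - y0) - (x2 - x0) * (y1 - y0)


@dataclass(frozen=True)
class CorrespondenceSet:
    """Three camera points matched to three radiograph points on one plane."""

    src: tuple
    dst: tuple
    plane: Plane = "AP"

    def __post_init__(self) -> None:
        src = tuple(tuple(_as_point(p)) for p in self.src)
        dst = tuple(tuple(_as_point(p)) for p in self.dst)
        if len(src) != 3 or len(dst) != 3:
            raise ValueError("exactly 3 correspondences are required")
        if self.plane not in ("AP", "CTL"):
            raise ValueError(f"plane must be 'AP' or 'CTL', got {self.plane!r}")
        object.__setattr__(self, "src", src)
        object.__setattr__(self, "dst", dst)


def fit_affine(c: CorrespondenceSet) -> AffineTransform2D:
    """Fit the affine transform taking ``c.src`` exactly onto ``c.dst``.

    Three non-collinear correspondences fully determine the 6 unknowns, so
    the map is found by solving two 3x3 linear systems (one per output
    coordinate) sharing the design matrix ``[x, y, 1]``.

    Raises
    ------
    CollinearPointsError
        If the source triangle's doubled area is below ``COLLINEARITY_TOL``.
    """
    if abs(triangle_area2(c.src)) < COLLINEARITY_TOL:
        raise CollinearPointsError(
            "source calibration points are collinear; pick a proper triangle"
        )
    A = np.array([[x, y, 1.0] for x, y in c.src])
    dst = np.asarray(c.dst, dtype=float)
    # rows of the 2x3 matrix: [a, b, tx] solves A @ row = dst_x, etc.
    row_x = np.linalg.solve(A, dst[:, 0])
    row_y = np.linalg.solve(A, dst[:, 1])
    return AffineTransform2D(np.vstack([row_x, row_y]))


def apply_affine(t: AffineTransform2D, p: Sequence[float]) -> tuple[float, float]:
    """Map a single point through the transform."""
    x, y = _as_point(p)
    out = t.linear @ (x, y) + t.translation
    return float(out[0]), float(out[1])


def apply_affine_many(t: AffineTransform2D, pts: Iterable[Sequence[float]]) -> np.ndarray:
    """Vectorized :func:`apply_affine` over an (n, 2) array of points."""
    a = np.asarray(list(pts), dtype=float).reshape(-1, 2)
    return a @ t.linear.T + t.translation


def invert_affine(t: AffineTransform2D) -> AffineTransform2D:
    """Inverse transform; ``compose_affine(t, invert_affine(t))`` is identity.

    Raises
    ------
    SingularTransformError
        If ``|det|`` of the linear part is below 1e-12.
    """
    if abs(t.det) < 1e-12:
        raise SingularTransformError("affine transform is singular")
    inv_lin = np.linalg.inv(t.linear)
    inv_tr = -inv_lin @ t.translation
    return AffineTransform2D(np.hstack([inv_lin, inv_tr[:, None]]))


def compose_affine(outer: AffineTransform2D, inner: AffineTransform2D) -> AffineTransform2D:
    """``compose_affine(s, t)`` maps ``p`` to ``s(t(p))``."""
    lin = outer.linear @ inner.linear
    tr = outer.linear @ inner.translation + outer.translation
    return AffineTransform2D(np.hstack([lin, tr[:, None]]))


# -- calibration file I/O ---------------------------------------------------

def calibration_to_dict(c: CorrespondenceSet, t: AffineTransform2D | None = None) -> dict:
    """JSON-ready calibration record; the matrix is always written."""
    if t is None:
        t = fit_affine(c)
    return {
        "coords": COORDS_CONVENTION,
        "plane": c.plane,
        "src": [list(p) for p in c.src],
        "dst": [list(p) for p in c.dst],
        "matrix": t.m.tolist(),
    }


def calibration_from_dict(d: dict) -> tuple[CorrespondenceSet, AffineTransform2D]:
    """Parse a calibration record; the matrix is recomputed when absent."""
    c = CorrespondenceSet(src=tuple(d["src"]), dst=tuple(d["dst"]), plane=d["plane"])
    if "matrix" in d and d["matrix"] is not None:
        t = AffineTransform2D(np.asarray(d["matrix"], dtype=float))
    else:
        t = fit_affine(c)
    return c, t


def save_calibration(path: str | Path, c: CorrespondenceSet,
                     t: AffineTransform2D | None = None) -> None:
    Path(path).write_text(json.dumps(calibration_to_dict(c, t), indent=2))


def load_calibration(path: str | Path) -> tuple[CorrespondenceSet, AffineTransform2D]:
    return calibration_from_dict(json.loads(Path(path).read_text()))
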