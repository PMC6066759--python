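"""Deterministic synthetic data generators.

Everything the pipeline consumes from hardware or from a study population
can be emulated here with seeded pseudo-randomness, so every module is
testable without cameras, mannequins or participants:

* camera frames with two colored circular markers on a plain background
  (exact rasterization ground truth attached);
* annotated hip radiographs (bright femoral-head disk, shaft band, apex
  and entry annotations);
* scripted wire trajectories interleaving move / expose / close events,
  with the expected counter values attached;
* participant cohorts whose per-cohort metric medians follow the study's
  cohort structure (novice TAD far above expert TAD, deterministic
  TAD -> cut-out coupling).

All generators are pure functions of (spec, seed): identical inputs give
bit-identical outputs.  Disk rasterization uses center-of-pixel inclusion
(pixel (row, col) belongs to the disk iff its center — at integer
coordinates x = col, y = row — lies within the radius), which makes the
ground-truth pixel counts and centroids exactly computable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from fluorosim.errors import (
    GeometryError,
    InvalidSpecError,
    MarkerOutOfFrameError,
    NonMonotoneTimeError,
)
from fluorosim.geometry import Plane
from fluorosim.scoring import cor_from_tad, default_cutout_curve
from fluorosim.simulator import Radiograph, SessionMetrics
from fluorosim.validity import ParticipantRecord

# -- camera frames ----------------------------------------------------------

DEFAULT_MARKER_COLORS = ((220, 40, 40), (40, 220, 40))  # proximal red, distal green
DEFAULT_BACKGROUND = (30, 30, 30)


@dataclass(frozen=True)
class FrameSpec:
    """Synthetic camera frame: two marker disks plus channel noise."""

    size: tuple[int, int] = (480, 640)  # (H, W)
    marker_centers: tuple = ((200.0, 240.0), (400.0, 260.0))  # (x, y) each
    marker_radius: float = 6.0
    marker_colors: tuple = DEFAULT_MARKER_COLORS
    background: tuple[int, int, int] = DEFAULT_BACKGROUND
    noise_sigma: float = 0.0
    seed: int = 0


def _rasterize_disk(shape: tuple[int, int], center: Sequence[float],
                    radius: float) -> np.ndarray:
    h, w = shape
    cx, cy = center
    yy, xx = np.mgrid[0:h, 0:w]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= radius ** 2


def make_frame(spec: FrameSpec) -> tuple[np.ndarray, dict]:
    """Render the frame and return it with exact rasterization ground truth.

    Ground truth per marker: the requested center, the rasterized pixel
    count and the rasterized centroid (mean of included pixel centers) —
    the quantity an unweighted-centroid detector should recover.
    """
    h, w = spec.size
    if spec.marker_radius < 2:
        raise InvalidSpecError("marker radius must be >= 2 px")
    for cx, cy in spec.marker_centers:
        if not (cx - spec.marker_radius >= 0 and cx + spec.marker_radius <= w - 1
                and cy - spec.marker_radius >= 0
                and cy + spec.marker_radius <= h - 1):
            raise MarkerOutOfFrameError(
                f"marker at ({cx}, {cy}) r={spec.marker_radius} exceeds frame"
            )
    frame = np.empty((h, w, 3), dtype=np.uint8)
    frame[:] = spec.background
    truth = {"markers": []}
    for center, color in zip(spec.marker_centers, spec.marker_colors):
        disk = _rasterize_disk((h, w), center, spec.marker_radius)
        frame[disk] = color
        rows, cols = np.nonzero(disk)
        truth["markers"].append({
            "center": tuple(map(float, center)),
            "color": tuple(color),
            "pixel_count": int(disk.sum()),
            "rasterized_centroid": (float(cols.mean()), float(rows.mean())),
        })
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        noisy = frame.astype(float) + rng.normal(0.0, spec.noise_sigma, frame.shape)
        frame = np.clip(noisy, 0, 255).astype(np.uint8)
    return frame, truth


# -- radiographs ------------------------------------------------------------

@dataclass(frozen=True)
class RadiographSpec:
    """Synthetic hip radiograph: femoral-head disk + shaft band.

    The apex annotation is placed on the head-disk boundary along the neck
    axis; the entry annotation sits on the lateral cortex where the wire
    crosses into the bone.
    """

    size: tuple[int, int] = (512, 512)
    head_center: tuple[float, float] = (200.0, 160.0)
    head_radius: float = 70.0
    neck_direction: tuple[float, float] = (-0.6, -0.8)  # entry -> apex, unit-ish
    entry: tuple[float, float] = (380.0, 400.0)
    plane: Plane = "AP"
    mm_per_px: float = 0.25
    noise_sigma: float = 0.0
    seed: int = 0


def make_radiograph(spec: RadiographSpec) -> Radiograph:
    """Grayscale radiograph with annotations carried through."""
    h, w = spec.size
    cx, cy = spec.head_center
    if spec.head_radius <= 0:
        raise GeometryError("head radius must be positive")
    if not (0 <= cx - spec.head_radius and cx + spec.head_radius <= w - 1
            and 0 <= cy - spec.head_radius and cy + spec.head_radius <= h - 1):
        raise GeometryError("femoral head disk exceeds image bounds")
    ex, ey = spec.entry
    if not (0 <= ex < w and 0 <= ey < h):
        raise GeometryError("entry point outside image bounds")
    if (ex - cx) ** 2 + (ey - cy) ** 2 <= spec.head_radius ** 2:
        raise GeometryError("entry point must lie outside the femoral head")
    d = np.asarray(spec.neck_direction, dtype=float)
    n = np.linalg.norm(d)
    if n < 1e-12:
        raise GeometryError("neck direction is a zero vector")
    d = d / n
    apex = (cx + spec.head_radius * d[0], cy + spec.head_radius * d[1])
    if not (0 <= apex[0] < w and 0 <= apex[1] < h):
        raise GeometryError("apex falls outside image bounds")

    img = np.full((h, w), 40.0)
    img[_rasterize_disk((h, w), spec.head_center, spec.head_radius)] = 160.0
    # shaft band: bright strip of half-width 25 px around the entry->head line
    yy, xx = np.mgrid[0:h, 0:w]
    v = np.array([cx - ex, cy - ey], dtype=float)
    vn = np.linalg.norm(v)
    u = v / vn
    px, py = xx - ex, yy - ey
    along = px * u[0] + py * u[1]
    perp = np.abs(px * -u[1] + py * u[0])
    band = (perp <= 25) & (along >= -10) & (along <= vn)
    img[band] = np.maximum(img[band], 120.0)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
    pixels = np.clip(img, 0, 255).astype(np.uint8)
    return Radiograph(pixels=pixels, plane=spec.plane, mm_per_px=spec.mm_per_px,
                      apex=apex, entry=spec.entry)


# -- trajectories -----------------------------------------------------------

def make_trajectory(
    waypoints: Sequence[tuple], events: Sequence[tuple]
) -> tuple[list[dict], dict]:
    """Merge wire waypoints and expose/close events into a replay table.

    ``waypoints`` are ``(t_s, plane, (tip_x, tip_y))`` move samples;
    ``events`` are ``(t_s, "expose", plane)`` or ``(t_s, "close")``.
    Expose rows inherit the most recent waypoint tip for their plane.
    Returns the row list (keys ``t_s, plane, tip_x, tip_y, event``) plus
    the ground-truth counters implied by the script: the exposure count
    and, when a close event exists, the procedure duration.

    Raises
    ------
    NonMonotoneTimeError
        If the merged timestamps are not strictly increasing.
    """
    tagged = [(float(t), "move", plane, tuple(tip)) for t, plane, tip in waypoints]
    for ev in events:
        if ev[1] == "expose":
            tagged.append((float(ev[0]), "expose", ev[2], None))
        elif ev[1] == "close":
            tagged.append((float(ev[0]), "close", None, None))
        else:
            raise ValueError(f"unknown event {ev[1]!r}")
    tagged.sort(key=lambda r: r[0])
    for (t0, *_), (t1, *_) in zip(tagged, tagged[1:]):
        if t1 <= t0:
            raise NonMonotoneTimeError("trajectory timestamps must strictly increase")

    rows: list[dict] = []
    last_tip: dict[str, tuple] = {}
    n_expose = 0
    close_t = None
    for t, event, plane, tip in tagged:
        if event == "move":
            last_tip[plane] = tip
            rows.append({"t_s": t, "plane": plane,
                         "tip_x": tip[0], "tip_y": tip[1], "event": "move"})
        elif event == "expose":
            if plane not in last_tip:
                raise ValueError(f"expose on plane {plane} before any waypoint")
            tx, ty = last_tip[plane]
            rows.append({"t_s": t, "plane": plane,
                         "tip_x": tx, "tip_y": ty, "event": "expose"})
            n_expose += 1
        else:
            rows.append({"t_s": t, "plane": "", "tip_x": "", "tip_y": "",
                         "event": "close"})
            close_t = t
    truth = {"n_radiographs": n_expose}
    if close_t is not None and tagged:
        truth["time_s"] = close_t - tagged[0][0]
    return rows, truth


def insertion_waypoints(
    radiograph: Radiograph,
    n_withdrawals: int,
    t0: float = 0.0,
    dt: float = 5.0,
    depth_in: float = 30.0,
    depth_out: float = -10.0,
    plane: Plane = "AP",
) -> tuple[list[tuple], float]:
    """Waypoints along the entry->apex axis scripting known retry cycles.

    The wire goes in to ``depth_in`` px, out to ``depth_out`` px,
    ``n_withdrawals`` times, then in once more and finally to the apex —
    so the expected retry count is exactly ``n_withdrawals``.  Returns the
    waypoint list and the timestamp after the last waypoint.
    """
    entry = np.asarray(radiograph.entry, dtype=float)
    axis = np.asarray(radiograph.apex, dtype=float) - entry
    axis = axis / np.linalg.norm(axis)

    def at_depth(depth: float) -> tuple[float, float]:
        p = entry + depth * axis
        return float(p[0]), float(p[1])

    t = t0
    pts: list[tuple] = []
    for _ in range(n_withdrawals):
        pts.append((t, plane, at_depth(depth_in))); t += dt
        pts.append((t, plane, at_depth(depth_out))); t += dt
    pts.append((t, plane, at_depth(depth_in))); t += dt
    pts.append((t, plane, tuple(map(float, radiograph.apex)))); t += dt
    return pts, t


# -- cohorts ----------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Synthetic study population with the cohort structure of the trial.

    Per-cohort target medians default to the study's reported values; TAD
    is log-normal with median equal to the target (mu = ln median, sigma =
    ``dispersion``), the cut-out rate is computed deterministically from
    each participant's TAD through the default logistic curve, procedural
    time is normal about its median, and the two counters are
    Poisson-shifted about theirs and clamped at zero.
    """

    n: dict = field(default_factory=lambda: {
        "novice": 8, "intermediate": 7, "expert": 11})
    tad_median: dict = field(default_factory=lambda: {
        "novice": 47.0, "intermediate": 28.0, "expert": 24.0})
    time_median: dict = field(default_factory=lambda: {
        "novice": 190.0, "intermediate": 206.0, "expert": 222.0})
    radiographs_median: dict = field(default_factory=lambda: {
        "novice": 16, "intermediate": 26, "expert": 28})
    retries_median: dict = field(default_factory=lambda: {
        "novice": 0, "intermediate": 1, "expert": 2})
    dispersion: float = 0.3
    likert_agree_prob: float = 0.85
    seed: int = 0


_DHS_RANGE = {"novice": (0, 9), "intermediate": (10, 39), "expert": (40, 120)}
_PGY_RANGE = {"novice": (2, 5), "intermediate": (4, 9), "expert": (7, 20)}


def make_cohort(spec: CohortSpec) -> list[ParticipantRecord]:
    """Generate one synthetic participant table."""
    for cohort in ("novice", "intermediate", "expert"):
        if spec.n.get(cohort, 0) < 1:
            raise InvalidSpecError(f"cohort {cohort!r} needs n >= 1")
        if spec.tad_median[cohort] <= 0 or spec.time_median[cohort] <= 0:
            raise InvalidSpecError("TAD and time medians must be positive")
    if spec.dispersion < 0:
        raise InvalidSpecError("dispersion must be >= 0")
    if not (0.0 <= spec.likert_agree_prob <= 1.0):
        raise InvalidSpecError("likert_agree_prob must be in [0, 1]")

    rng = np.random.default_rng(spec.seed)
    curve = default_cutout_curve()
    records: list[ParticipantRecord] = []
    for cohort in ("novice", "intermediate", "expert"):
        lo, hi = _DHS_RANGE[cohort]
        plo, phi = _PGY_RANGE[cohort]
        for i in range(spec.n[cohort]):
            tad = float(np.exp(np.log(spec.tad_median[cohort])
                               + spec.dispersion * rng.standard_normal()))
            cor = cor_from_tad(curve, tad).cor_pct
            time_s = max(0.0, spec.time_median[cohort]
                         * (1.0 + spec.dispersion * rng.standard_normal()))
            lam_r = spec.dispersion * spec.radiographs_median[cohort]
            n_radio = max(0, round(spec.radiographs_median[cohort]
                                   + (rng.poisson(lam_r) - lam_r if lam_r > 0 else 0)))
            lam_t = spec.dispersion * (spec.retries_median[cohort] + 1)
            n_retry = max(0, round(spec.retries_median[cohort]
                                   + (rng.poisson(lam_t) - lam_t if lam_t > 0 else 0)))
            likert = tuple(
                int(rng.integers(5, 8)) if rng.random() < spec.likert_agree_prob
                else int(rng.integers(1, 5))
                for _ in range(4)
            )
            records.append(ParticipantRecord(
                id=f"{cohort[:3]}{i:03d}",
                dhs_count=int(rng.integers(lo, hi + 1)),
                pgy=int(rng.integers(plo, phi + 1)),
                metrics=SessionMetrics(
                    tad_mm=tad, cor_pct=cor, time_s=time_s,
                    n_radiographs=int(n_radio), n_retries=int(n_retry),
                ),
                likert=likert,
            ))
    return records
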