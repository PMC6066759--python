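"""Simulation-session state machine and simulated radiograph production.

A session holds the per-plane affine calibrations and pre-loaded
radiographs for one guide-wire insertion attempt.  Three counters feed the
objective performance metrics:

* **exposures** — each simulated radiograph ("screening shot") increments
  the exposure counter; AP and CTL shots count toward one total.
* **retries** — a retry is one complete withdrawal and re-insertion of the
  wire.  It is detected by hysteresis on the signed insertion depth along
  the entry-point -> apex axis: the wire latches "inserted" when its depth
  exceeds ``depth_on`` (default +5 px past the lateral cortex) and a retry
  is counted each time an inserted wire falls back below ``depth_off``
  (default 0 px).  The gap debounces tremor right at the cortex.
* **time** — wall clock between session open and the participant-declared
  close; in scripted replay it is taken from trajectory timestamps.

The simulated screen is the radiograph with a short anti-aliased white
segment drawn ending at the mapped wire tip, mimicking the radio-opaque
wire on a fluoroscopy monitor.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage.draw import line_aa

from fluorosim.errors import (
    IncompleteSessionError,
    MissingCalibrationError,
    NonMonotoneTimeError,
    SessionClosedError,
)
from fluorosim.geometry import AffineTransform2D, Plane, apply_affine
from fluorosim.scoring import (
    CutoutCurve,
    TADInputs,
    compute_tad,
    cor_from_tad,
    default_cutout_curve,
)
from fluorosim.vision import WirePose2D

#: Hysteresis thresholds (px of signed depth along entry->apex).
DEPTH_ON = 5.0
DEPTH_OFF = 0.0

#: Cosmetic overlay style: drawn shaft length in px (ends at the tip).
WIRE_DRAW_LENGTH = 200.0


@dataclass(frozen=True)
class Radiograph:
    """Pre-loaded grayscale hip radiograph with clinical annotations.

    ``apex`` is the femoral-head apex (the ideal wire target) and
    ``entry`` the lateral-cortex entry point, both in (x, y) pixels.
    """

    pixels: np.ndarray
    plane: Plane
    mm_per_px: float
    apex: tuple[float, float]
    entry: tuple[float, float]

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("radiograph must be a 2-D grayscale array")
        if not (self.mm_per_px > 0 and math.isfinite(self.mm_per_px)):
            raise ValueError("mm_per_px must be finite and positive")
        h, w = px.shape
        for name, (x, y) in (("apex", self.apex), ("entry", self.entry)):
            if not (0 <= x < w and 0 <= y < h):
                raise ValueError(f"{name} annotation outside image bounds")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class SimulatedScreen:
    """One simulated exposure: radiograph copy with the wire drawn in."""

    image: np.ndarray
    plane: Plane
    exposure_index: int


@dataclass(frozen=True)
class SessionMetrics:
    """The five objective performance metrics of one attempt."""

    tad_mm: float
    cor_pct: float
    time_s: float
    n_radiographs: int
    n_retries: int

    def to_dict(self) -> dict:
        return {
            "tad_mm": self.tad_mm,
            "cor_pct": round(self.cor_pct, 1),
            "time_s": self.time_s,
            "n_radiographs": self.n_radiographs,
            "n_retries": self.n_retries,
        }


@dataclass
class Session:
    """Mutable state of one guide-wire insertion attempt."""

    radiographs: dict[str, Radiograph]
    calibrations: dict[str, AffineTransform2D]
    start_time: float = 0.0
    depth_on: float = DEPTH_ON
    depth_off: float = DEPTH_OFF
    exposure_count: int = 0
    retry_count: int = 0
    end_time: float | None = None
    wire_inserted: bool = False
    event_log: list = field(default_factory=list)
    last_tip: dict = field(default_factory=dict)  # plane -> (x, y) radiograph px
    _last_t: float = field(init=False)

    def __post_init__(self) -> None:
        self._last_t = self.start_time

    @property
    def closed(self) -> bool:
        return self.end_time is not None

    def _check_open(self) -> None:
        if self.closed:
            raise SessionClosedError("session is closed")

    def _advance_time(self, t: float) -> None:
        if t < self._last_t:
            raise NonMonotoneTimeError(
                f"timestamp {t} precedes previous event at {self._last_t}"
            )
        self._last_t = t

    def _log(self, t: float, event: str, payload: dict) -> None:
        self.event_log.append((t, event, payload))


def signed_depth(radiograph: Radiograph, tip: Sequence[float]) -> float:
    """Signed insertion depth of the tip along the entry->apex axis, in px.

    Zero at the cortical entry point, positive toward the apex (into the
    bone), negative outside the bone.
    """
    entry = np.asarray(radiograph.entry, dtype=float)
    axis = np.asarray(radiograph.apex, dtype=float) - entry
    axis /= np.linalg.norm(axis)
    return float(np.dot(np.asarray(tip, dtype=float) - entry, axis))


def take_radiograph(
    s: Session, plane: Plane, pose_camera: WirePose2D, t: float | None = None
) -> SimulatedScreen:
    """Simulate one exposure: overlay the wire and bump the counter.

    The camera-frame tip and direction are mapped through the plane's
    affine calibration; a fixed-length anti-aliased white segment ending at
    the mapped tip is drawn onto a copy of the radiograph.
    """
    s._check_open()
    if t is None:
        t = s._last_t
    s._advance_time(t)
    if plane not in s.calibrations:
        raise MissingCalibrationError(f"no calibration for plane {plane}")
    cal = s.calibrations[plane]
    radio = s.radiographs[plane]

    tip = np.asarray(apply_affine(cal, pose_camera.tip), dtype=float)
    # direction transforms through the linear part only
    d = cal.linear @ np.asarray(pose_camera.direction, dtype=float)
    norm = np.linalg.norm(d)
    d = d / norm if norm > 0 else np.array([1.0, 0.0])
    tail = tip - WIRE_DRAW_LENGTH * d

    img = np.asarray(radio.pixels, dtype=np.uint8).copy()
    h, w = img.shape
    r0, c0 = int(round(tail[1])), int(round(tail[0]))
    r1, c1 = int(round(tip[1])), int(round(tip[0]))
    rr, cc, val = line_aa(r0, c0, r1, c1)
    keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
    img[rr[keep], cc[keep]] = np.maximum(
        img[rr[keep], cc[keep]], (val[keep] * 255).astype(np.uint8)
    )

    s.exposure_count += 1
    s.last_tip[plane] = (float(tip[0]), float(tip[1]))
    s._log(t, "expose", {"plane": plane, "tip": [float(tip[0]), float(tip[1])]})
    return SimulatedScreen(image=img, plane=plane, exposure_index=s.exposure_count)


def update_wire_state(
    s: Session, tip_radiograph: Sequence[float], t: float, plane: Plane = "AP"
) -> Session:
    """Record a wire movement and run the retry hysteresis.

    ``tip_radiograph`` is the wire tip in the given plane's radiograph
    coordinates.  The insertion latch turns on when the signed depth along
    the entry->apex axis exceeds ``depth_on`` and a retry is counted at
    each inserted -> withdrawn transition (depth below ``depth_off``).
    """
    s._check_open()
    s._advance_time(t)
    depth = signed_depth(s.radiographs[plane], tip_radiograph)
    if not s.wire_inserted and depth > s.depth_on:
        s.wire_inserted = True
    elif s.wire_inserted and depth < s.depth_off:
        s.wire_inserted = False
        s.retry_count += 1
    s.last_tip[plane] = (float(tip_radiograph[0]), float(tip_radiograph[1]))
    s._log(t, "move", {"plane": plane,
                       "tip": [float(tip_radiograph[0]), float(tip_radiograph[1])],
                       "depth_px": depth})
    return s


def close_session(s: Session, t: float) -> Session:
    """Participant declares the final placement; session becomes immutable."""
    s._check_open()
    if t < s.start_time:
        raise NonMonotoneTimeError("close time precedes session start")
    s._advance_time(t)
    s.end_time = t
    s._log(t, "close", {})
    return s


def session_report(s: Session, curve: CutoutCurve | None = None) -> SessionMetrics:
    """Assemble the five objective metrics from a closed session.

    TAD uses the final wire tip and the annotated apex in each plane,
    scaled by that radiograph's ``mm_per_px``; COR is read off the
    cut-out curve (default: the curve through the standard anchors).
    """
    if not s.closed:
        raise SessionClosedError("close the session before reporting")
    if "AP" not in s.last_tip or "CTL" not in s.last_tip:
        raise IncompleteSessionError(
            "final wire pose missing in at least one plane"
        )
    if curve is None:
        curve = default_cutout_curve()
    tad = compute_tad(TADInputs(
        tip_ap=s.last_tip["AP"], apex_ap=s.radiographs["AP"].apex,
        tip_lat=s.last_tip["CTL"], apex_lat=s.radiographs["CTL"].apex,
        mm_per_px_ap=s.radiographs["AP"].mm_per_px,
        mm_per_px_lat=s.radiographs["CTL"].mm_per_px,
    ))
    cor = cor_from_tad(curve, tad.tad_mm)
    return SessionMetrics(
        tad_mm=tad.tad_mm,
        cor_pct=cor.cor_pct,
        time_s=s.end_time - s.start_time,
        n_radiographs=s.exposure_count,
        n_retries=s.retry_count,
    )


def write_event_log(s: Session, path: str | Path) -> None:
    """JSON-lines session log: one ``{"t", "event", "payload"}`` per line."""
    with open(path, "w") as fh:
        for t, event, payload in s.event_log:
            fh.write(json.dumps({"t": t, "event": event, "payload": payload}) + "\n")


def replay_trajectory(
    s: Session, rows: Sequence[dict], curve: CutoutCurve | None = None
) -> SessionMetrics:
    """Drive a session from a scripted trajectory and report its metrics.

    Each row is a dict with keys ``t_s``, ``plane``, ``tip_x``, ``tip_y``
    and an ``event`` field (``move`` / ``expose`` / ``close``; missing or
    empty means ``move``).  Tips are in radiograph coordinates, so replay
    sessions are normally built with identity calibrations; ``expose``
    rows draw the wire pointing from the entry point toward the tip.
    """
    for row in rows:
        t = float(row["t_s"])
        event = (row.get("event") or "move").strip() or "move"
        if event == "close":
            close_session(s, t)
            continue
        plane = row["plane"]
        tip = (float(row["tip_x"]), float(row["tip_y"]))
        if event == "move":
            update_wire_state(s, tip, t, plane=plane)
        elif event == "expose":
            update_wire_state(s, tip, t, plane=plane)
            entry = np.asarray(s.radiographs[plane].entry, dtype=float)
            v = np.asarray(tip, dtype=float) - entry
            n = np.linalg.norm(v)
            direction = tuple(v / n) if n > 1e-12 else (1.0, 0.0)
            take_radiograph(s, plane, WirePose2D(tip=tip, direction=direction), t=t)
        else:
            raise ValueError(f"unknown trajectory event {event!r}")
    return session_report(s, curve=curve)
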