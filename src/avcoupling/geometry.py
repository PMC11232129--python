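"""Per-frame geometric measurements on chamber contours.

The hydraulic-force estimate rests on chamber *cross-sectional areas*
measured at the maximal transverse dimension perpendicular to the long
axis joining the LV and LA centers of mass.  This module provides the
primitives — polygon area/centroid, the per-frame long axis, maximal
perpendicular chord by station scanning — and assembles them into
per-chamber area-vs-time curves.

Conventions: input coordinates in mm (y-down image plane), areas returned
in cm², lengths/diameters in mm.  LV long-axis contours arrive open
(base→apex→base); all area/centroid computations close them with the
mitral chord, while ``contour_length(..., closed=False)`` excludes it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

from .io import ContourSequence

MM2_PER_CM2 = 100.0
DEFAULT_STATION_STEP = 0.25  # mm, spacing of perpendicular section lines
AREA_MODES = ("biplane_ellipse", "single_plane")


class GeometryError(ValueError):
    """Degenerate or invalid geometric input."""


def _poly(points: np.ndarray) -> Polygon:
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(points) < 3:
        raise GeometryError(f"polygon needs >= 3 points, got {len(points)}")
    p = Polygon(points)
    if not p.is_valid or p.area <= 1e-9:
        raise GeometryError("polygon is self-intersecting or degenerate")
    return p


def polygon_area(points: np.ndarray) -> float:
    """Enclosed (shoelace) area of a simple polygon, in cm²."""
    return _poly(points).area / MM2_PER_CM2


def centroid(points: np.ndarray) -> np.ndarray:
    """Area-weighted polygon centroid (not the vertex mean), in mm."""
    c = _poly(points).centroid
    return np.array([c.x, c.y])


def long_axis(lv_points: np.ndarray, la_points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Long axis through the LV and LA centers of mass.

    Returns ``(direction, anchor)`` where *direction* is the unit vector
    oriented LA→LV and *anchor* is the LA centroid.  Raises when the
    centroids are closer than 1 mm (corrupt contours).
    """
    c_lv = centroid(lv_points)
    c_la = centroid(la_points)
    delta = c_lv - c_la
    dist = float(np.hypot(*delta))
    if dist < 1.0:
        raise GeometryError(
            f"LV and LA centroids are {dist:.3f} mm apart (< 1 mm): corrupt contours"
        )
    return delta / dist, c_la


def max_transverse_diameter(
    points: np.ndarray,
    axis_direction: np.ndarray,
    step: float = DEFAULT_STATION_STEP,
) -> float:
    """Maximal chord of the polygon perpendicular to *axis_direction*, in mm.

    Perpendicular section lines ("stations") are scanned at spacing *step*
    along the axis; at each station the span of the polygon boundary
    crossings is measured, and the maximum over stations is returned.
    This mirrors a caliper placed perpendicular to the LV–LA long axis.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) < 3:
        raise GeometryError("need >= 3 points")
    u = np.asarray(axis_direction, dtype=float)
    norm = np.hypot(*u)
    if not np.isfinite(norm) or norm < 1e-12:
        raise GeometryError("axis direction must be a nonzero vector")
    u = u / norm
    v = np.array([-u[1], u[0]])  # transverse direction

    a = pts @ u  # axial coordinate of each vertex
    b = pts @ v  # transverse coordinate
    lo, hi = float(a.min()), float(a.max())
    if hi - lo <= step:
        raise GeometryError("polygon extent along axis smaller than station step")
    # offset stations half a step from the extremes to avoid vertex-grazing
    stations = np.arange(lo + step / 2.0, hi, step)

    a0, a1 = a, np.roll(a, -1)
    b0, b1 = b, np.roll(b, -1)
    da = a1 - a0
    # edge e crosses station s when s lies between a0 and a1 (strict in u)
    s = stations[:, None]
    crosses = ((a0[None, :] - s) * (a1[None, :] - s) <= 0.0) & (np.abs(da)[None, :] > 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (s - a0[None, :]) / da[None, :]
    bc = b0[None, :] + t * (b1 - b0)[None, :]
    bc = np.where(crosses, bc, np.nan)
    span = np.nanmax(bc, axis=1) - np.nanmin(bc, axis=1)
    valid = np.sum(crosses, axis=1) >= 2
    if not valid.any():
        raise GeometryError("no station line intersects the polygon")
    return float(np.nanmax(span[valid]))


def cross_sectional_area(
    d_2ch: float | None = None,
    d_4ch: float | None = None,
    mode: str = "biplane_ellipse",
) -> float:
    """Chamber cross-sectional area (cm²) from transverse diameters (mm).

    ``biplane_ellipse`` combines the two orthogonal long-axis views as an
    ellipse, A = π·d₂·d₄/4; ``single_plane`` assumes a circular section
    from whichever single diameter is given.
    """
    if mode not in AREA_MODES:
        raise GeometryError(f"unknown area mode {mode!r}")
    if mode == "biplane_ellipse":
        if d_2ch is None or d_4ch is None:
            raise GeometryError("biplane_ellipse mode needs both 2ch and 4ch diameters")
        if d_2ch <= 0 or d_4ch <= 0:
            raise GeometryError("diameters must be positive")
        return np.pi * d_2ch * d_4ch / 4.0 / MM2_PER_CM2
    d = d_4ch if d_4ch is not None else d_2ch
    if d is None or d <= 0:
        raise GeometryError("single_plane mode needs one positive diameter")
    return np.pi * d * d / 4.0 / MM2_PER_CM2


def contour_length(points: np.ndarray, closed: bool) -> float:
    """Polyline length in mm; the closing segment is included iff *closed*."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) < 2:
        raise GeometryError("need >= 2 points for a length")
    seg = np.diff(pts, axis=0)
    total = float(np.hypot(seg[:, 0], seg[:, 1]).sum())
    if closed:
        total += float(np.hypot(*(pts[0] - pts[-1])))
    return total


def chamber_length(points: np.ndarray, axis_direction: np.ndarray) -> float:
    """Chamber extent (mm) projected on the long axis (for area-length volumes)."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    u = np.asarray(axis_direction, dtype=float)
    u = u / np.hypot(*u)
    proj = pts @ u
    return float(proj.max() - proj.min())


@dataclass
class FrameGeometry:
    frame_index: int
    centroid: np.ndarray
    transverse_diameter_2ch: float | None
    transverse_diameter_4ch: float | None
    cross_sectional_area: float  # cm²
    contour_length: float  # mm (mitral chord excluded for open contours)
    polygon_area: float  # cm²


@dataclass
class AreaCurve:
    """Per-frame cross-sectional area (and transverse diameters) of one chamber."""

    chamber: str  # "LV" | "LA"
    areas: np.ndarray  # cm²
    times: np.ndarray  # ms
    diameters_2ch: np.ndarray | None
    diameters_4ch: np.ndarray | None
    frames: list[FrameGeometry] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return len(self.areas)


def frame_times(n_frames: int, rr_interval: float) -> np.ndarray:
    """Frame times in ms; the cycle spans the RR interval over n−1 steps."""
    return np.linspace(0.0, rr_interval, n_frames)


def _per_view_diameters(
    target: ContourSequence,
    other: ContourSequence,
    step: float,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Transverse diameters of *target* per frame, long axis recomputed each
    frame from that frame's LV and LA centroids."""
    n = target.n_frames
    if other.n_frames != n:
        raise GeometryError(
            f"frame-count mismatch: {target.label()} has {n}, {other.label()} has {other.n_frames}"
        )
    diam = np.empty(n)
    cents = []
    for i in range(n):
        tp, op = target.frames[i].points, other.frames[i].points
        if target.chamber.startswith("LV"):
            direction, _ = long_axis(tp, op)
        else:
            direction, _ = long_axis(op, tp)
        diam[i] = max_transverse_diameter(tp, direction, step=step)
        cents.append(centroid(tp))
    return diam, cents


def area_curve(
    target_2ch: ContourSequence | None,
    target_4ch: ContourSequence | None,
    other_2ch: ContourSequence | None,
    other_4ch: ContourSequence | None,
    mode: str = "biplane_ellipse",
    station_step: float = DEFAULT_STATION_STEP,
) -> AreaCurve:
    """Cross-sectional area curve of one chamber.

    *target* sequences are the chamber being measured, *other* the opposite
    chamber in the same view (needed to define the long axis).  In
    ``biplane_ellipse`` mode both views are required; in ``single_plane``
    mode one view suffices and the missing view's diameter fields stay empty.
    """
    views = []
    if target_2ch is not None:
        if other_2ch is None:
            raise GeometryError("2ch view needs both chambers to define the long axis")
        views.append(("2ch", target_2ch, other_2ch))
    if target_4ch is not None:
        if other_4ch is None:
            raise GeometryError("4ch view needs both chambers to define the long axis")
        views.append(("4ch", target_4ch, other_4ch))
    if not views:
        raise GeometryError("at least one long-axis view is required")
    if mode == "biplane_ellipse" and len(views) < 2:
        raise GeometryError("biplane_ellipse mode requires both 2ch and 4ch views")

    chamber = "LV" if views[0][1].chamber.startswith("LV") else "LA"
    n = views[0][1].n_frames
    rr = views[0][1].rr_interval
    results: dict[str, np.ndarray] = {}
    cents = None
    for name, tgt, oth in views:
        if tgt.n_frames != n:
            raise GeometryError(f"frame-count mismatch between views for {tgt.label()}")
        results[name], cents = _per_view_diameters(tgt, oth, station_step)

    d2 = results.get("2ch")
    d4 = results.get("4ch")
    areas = np.empty(n)
    frames = []
    primary = views[-1][1]  # 4ch when present
    for i in range(n):
        areas[i] = cross_sectional_area(
            None if d2 is None else d2[i],
            None if d4 is None else d4[i],
            mode=mode,
        )
        frames.append(
            FrameGeometry(
                frame_index=i,
                centroid=cents[i],
                transverse_diameter_2ch=None if d2 is None else float(d2[i]),
                transverse_diameter_4ch=None if d4 is None else float(d4[i]),
                cross_sectional_area=float(areas[i]),
                contour_length=contour_length(primary.frames[i].points, primary.closed),
                polygon_area=polygon_area(primary.frames[i].points),
            )
        )
    return AreaCurve(
        chamber=chamber,
        areas=areas,
        times=frame_times(n, rr),
        diameters_2ch=d2,
        diameters_4ch=d4,
        frames=frames,
    )


def chamber_area_curves(
    lv_2ch: ContourSequence | None,
    la_2ch: ContourSequence | None,
    lv_4ch: ContourSequence | None,
    la_4ch: ContourSequence | None,
    mode: str = "biplane_ellipse",
    station_step: float = DEFAULT_STATION_STEP,
) -> tuple[AreaCurve, AreaCurve]:
    """Area curves for both chambers sharing the per-frame long axis."""
    lv = area_curve(lv_2ch, lv_4ch, la_2ch, la_4ch, mode=mode, station_step=station_step)
    la = area_curve(la_2ch, la_4ch, lv_2ch, lv_4ch, mode=mode, station_step=station_step)
    return lv, la
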