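"""Contour-sequence and cohort-table I/O.

The contour-sequence file is a versioned JSON document (``format_version: 1``)
holding tracked endocardial/epicardial contours: one sequence per
(view, chamber) — long-axis two-chamber (``2ch``) and four-chamber (``4ch``)
views plus short-axis (``sax``) slices — each sequence an ordered list of
frames of (x, y) points in millimetres, image-plane convention (y increases
downward), frame 0 = end-diastole (R-wave trigger of retrospective gating).

Validation distinguishes *schema* errors (missing/ill-typed fields) from
*geometry* errors (self-intersection, inconsistent point counts), and every
message names the offending sequence and frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import LinearRing

FORMAT_VERSION = 1
VIEWS = ("2ch", "4ch", "sax")
CHAMBERS = ("LV_endo", "LV_epi", "LA_endo")

#: columns every cohort CSV must provide (echo columns may hold missing values)
COHORT_REQUIRED = ("subject_id", "age", "sex", "height", "weight")
COHORT_NUMERIC = (
    "age", "height", "weight", "bmi", "sbp", "dbp", "hr", "E", "A", "Eprime",
)
#: echo-derived ratios are always recomputed, never trusted from the file
COHORT_DERIVED = ("E_over_A", "E_over_Eprime")


class ContourSchemaError(ValueError):
    """The file does not conform to the documented JSON schema."""


class ContourGeometryError(ValueError):
    """Contours violate a geometric invariant (self-intersection, counts…)."""


class CohortTableError(ValueError):
    """The cohort CSV violates a table invariant."""


def _signed_area_mm2(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def ensure_ccw(points: np.ndarray) -> np.ndarray:
    """Return the point list ordered so the closed signed area is positive."""
    if _signed_area_mm2(points) < 0:
        return points[::-1].copy()
    return points


@dataclass
class ContourFrame:
    """One tracked contour at one cardiac frame (points in mm)."""

    frame_index: int
    points: np.ndarray  # shape (n, 2)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.size:
            self.points = self.points.reshape(-1, 2)
        else:
            self.points = self.points.reshape(0, 2)


@dataclass
class ContourSequence:
    """A per-view, per-chamber contour tracked over the cardiac cycle.

    LA contours are closed simple polygons; LV long-axis contours are open
    base→apex→base curves (``closed=False``) whose implicit closing segment
    is the mitral-plane chord.  Short-axis (``sax``) sequences carry slice
    metadata; a sax frame may hold an *empty* point list when the structure
    has moved out of the slice (through-plane motion of the base), which
    downstream volumetry counts as zero area.
    """

    subject_id: str
    view: str
    chamber: str
    closed: bool
    rr_interval: float  # ms
    frames: list[ContourFrame] = field(default_factory=list)
    slice_location: float | None = None  # mm, sax only
    slice_thickness: float | None = None  # mm, sax only

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def point_array(self) -> np.ndarray:
        """Stack frames into an (n_frames, n_points, 2) array."""
        return np.stack([f.points for f in self.frames])

    def label(self) -> str:
        loc = "" if self.slice_location is None else f"@{self.slice_location:g}mm"
        return f"{self.subject_id}/{self.view}{loc}/{self.chamber}"


def _is_simple_closed(points: np.ndarray) -> bool:
    if len(points) < 3:
        return False
    try:
        return bool(LinearRing(points).is_simple)
    except Exception:
        return False


def validate_sequence(seq: ContourSequence, min_points: int = 16) -> None:
    """Enforce all sequence invariants, raising schema/geometry errors."""
    if seq.view not in VIEWS:
        raise ContourSchemaError(f"{seq.label()}: unknown view {seq.view!r}")
    if seq.chamber not in CHAMBERS:
        raise ContourSchemaError(f"{seq.label()}: unknown chamber {seq.chamber!r}")
    if seq.rr_interval <= 0:
        raise ContourSchemaError(f"{seq.label()}: rr_interval must be > 0 ms")
    if seq.view == "sax":
        if seq.slice_location is None or seq.slice_thickness is None:
            raise ContourSchemaError(
                f"{seq.label()}: sax sequences require slice_location and slice_thickness"
            )
    elif seq.slice_location is not None or seq.slice_thickness is not None:
        raise ContourSchemaError(
            f"{seq.label()}: slice metadata is only allowed on sax sequences"
        )
    if not seq.frames:
        raise ContourSchemaError(f"{seq.label()}: sequence has no frames")

    counts = {len(f.points) for f in seq.frames if len(f.points)}
    if len(counts) > 1:
        bad = next(
            f.frame_index
            for f in seq.frames
            if len(f.points) and len(f.points) != len(seq.frames[0].points)
        )
        raise ContourGeometryError(
            f"{seq.label()}: inconsistent point counts across frames "
            f"(first mismatch at frame {bad}: {sorted(counts)})"
        )
    indices = [f.frame_index for f in seq.frames]
    if indices != list(range(len(indices))):
        raise ContourSchemaError(
            f"{seq.label()}: frame_index values must be 0..n-1 without gaps, got {indices[:5]}…"
        )
    for f in seq.frames:
        pts = f.points
        if len(pts) == 0:
            if seq.view != "sax":
                raise ContourGeometryError(
                    f"{seq.label()} frame {f.frame_index}: empty frames are only "
                    "valid for sax slices (structure out of plane)"
                )
            continue
        if len(pts) < min_points:
            raise ContourGeometryError(
                f"{seq.label()} frame {f.frame_index}: {len(pts)} points < {min_points}"
            )
        if np.any(np.all(np.isclose(pts, np.roll(pts, -1, axis=0), atol=1e-9), axis=1)[:-1]):
            raise ContourGeometryError(
                f"{seq.label()} frame {f.frame_index}: consecutive duplicate points"
            )
        if not _is_simple_closed(pts):
            raise ContourGeometryError(
                f"{seq.label()} frame {f.frame_index}: polygon is self-intersecting or degenerate"
            )
        f.points = ensure_ccw(pts)


def _round4(x: float) -> float:
    return round(float(x), 4)


def _seq_to_dict(seq: ContourSequence) -> dict:
    d: dict = {
        "subject_id": seq.subject_id,
        "view": seq.view,
        "chamber": seq.chamber,
        "closed": bool(seq.closed),
        "rr_interval_ms": _round4(seq.rr_interval),
        "frames": [
            {
                "frame_index": int(f.frame_index),
                "points": [[_round4(x), _round4(y)] for x, y in f.points],
            }
            for f in seq.frames
        ],
    }
    if seq.view == "sax":
        d["slice_location_mm"] = _round4(seq.slice_location)
        d["slice_thickness_mm"] = _round4(seq.slice_thickness)
    return d


def write_contour_file(sequences: Iterable[ContourSequence], path: str | Path) -> None:
    """Write sequences as canonical JSON (sorted keys, 4-decimal mm).

    Identical inputs produce byte-identical files.
    """
    doc = {
        "format_version": FORMAT_VERSION,
        "sequences": [_seq_to_dict(s) for s in sequences],
    }
    text = json.dumps(doc, sort_keys=True, separators=(",", ":"))
    Path(path).write_text(text + "\n", encoding="utf-8")


def read_contour_file(path: str | Path) -> list[ContourSequence]:
    """Read and fully validate a contour-sequence file."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as e:
        raise ContourSchemaError(f"{path}: not valid JSON ({e})") from e
    if not isinstance(doc, dict) or "sequences" not in doc:
        raise ContourSchemaError(f"{path}: missing 'sequences' field")
    if doc.get("format_version") != FORMAT_VERSION:
        raise ContourSchemaError(
            f"{path}: unsupported format_version {doc.get('format_version')!r}"
        )
    out: list[ContourSequence] = []
    for i, sd in enumerate(doc["sequences"]):
        for key in ("subject_id", "view", "chamber", "closed", "rr_interval_ms", "frames"):
            if key not in sd:
                raise ContourSchemaError(f"{path}: sequence {i} missing field {key!r}")
        frames = []
        for fd in sd["frames"]:
            if "frame_index" not in fd or "points" not in fd:
                raise ContourSchemaError(
                    f"{path}: sequence {i} frame record missing frame_index/points"
                )
            frames.append(ContourFrame(int(fd["frame_index"]), np.asarray(fd["points"], dtype=float)))
        seq = ContourSequence(
            subject_id=str(sd["subject_id"]),
            view=str(sd["view"]),
            chamber=str(sd["chamber"]),
            closed=bool(sd["closed"]),
            rr_interval=float(sd["rr_interval_ms"]),
            frames=frames,
            slice_location=sd.get("slice_location_mm"),
            slice_thickness=sd.get("slice_thickness_mm"),
        )
        validate_sequence(seq)
        out.append(seq)
    return out


# ---------------------------------------------------------------------------
# cohort tables


def recompute_echo_ratios(table: pd.DataFrame) -> pd.DataFrame:
    """(Re)derive E/A and E/E' from the raw velocities, in place-safe copy."""
    table = table.copy()
    if {"E", "A"}.issubset(table.columns):
        table["E_over_A"] = table["E"] / table["A"]
    if {"E", "Eprime"}.issubset(table.columns):
        table["E_over_Eprime"] = table["E"] / table["Eprime"]
    return table


def validate_cohort(table: pd.DataFrame) -> None:
    missing = [c for c in COHORT_REQUIRED if c not in table.columns]
    if missing:
        raise CohortTableError(f"cohort table missing required columns: {missing}")
    ids = table["subject_id"].astype(str)
    dup = ids[ids.duplicated()]
    if len(dup):
        raise CohortTableError(f"duplicate subject_id: {sorted(set(dup))}")
    for col in COHORT_NUMERIC:
        if col in table.columns:
            try:
                pd.to_numeric(table[col])
            except (ValueError, TypeError) as e:
                raise CohortTableError(f"non-numeric value in column {col!r}: {e}") from e
    for col in ("E", "A", "Eprime"):
        if col in table.columns:
            vals = pd.to_numeric(table[col])
            if (vals.dropna() <= 0).any():
                bad = table.loc[vals <= 0, "subject_id"].iloc[0]
                raise CohortTableError(f"{col} must be > 0 when present (subject {bad})")


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV; validates invariants and recomputes derived ratios.

    Unknown columns are preserved verbatim; empty echo cells become NaN and
    are excluded pairwise by the statistics layer.
    """
    table = pd.read_csv(path)
    validate_cohort(table)
    for col in COHORT_NUMERIC:
        if col in table.columns:
            table[col] = pd.to_numeric(table[col])
    table["subject_id"] = table["subject_id"].astype(str)
    return recompute_echo_ratios(table)


def write_cohort_csv(table: pd.DataFrame, path: str | Path) -> None:
    validate_cohort(table)
    recompute_echo_ratios(table).to_csv(path, index=False, float_format="%.6g")


def sequences_by_key(
    sequences: Sequence[ContourSequence],
) -> dict[tuple[str, str], list[ContourSequence]]:
    """Index sequences as {(view, chamber): [seq, …]}; sax lists sorted by depth."""
    index: dict[tuple[str, str], list[ContourSequence]] = {}
    for s in sequences:
        index.setdefault((s.view, s.chamber), []).append(s)
    for (view, _), group in index.items():
        if view == "sax":
            group.sort(key=lambda s: s.slice_location)
    return index
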