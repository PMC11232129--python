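"""LV global strains and LA tri-phasic longitudinal strain.

All strains are Lagrangian (engineering) strains referenced to frame 0
(end-diastole): S(t) = 100·(L(t) − L₀)/L₀.  LV GLS is the most negative
value of the endocardial contour-length strain, averaged over the 2- and
4-chamber views; GCS is the analogous perimeter strain on mid-ventricular
short-axis slices, and GRS the peak relative wall thickening measured on
radial rays from the endocardial centroid.  LA longitudinal strain is the
closed endocardial perimeter strain averaged over the two long-axis views
and decomposed into reservoir (SL_R), conduit (SL_C) and booster (SL_B)
components at the frames of maximal strain and of pre-atrial contraction:

    SL_R = S(t_max),  SL_C = S(t_max) − S(t_preA),  SL_B = S(t_preA) − S(end)

so SL_C + SL_B + S(end) = SL_R exactly (S(end), the end-of-cycle residual,
is zero for a perfectly periodic tracking).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class StrainError(ValueError):
    pass


def strain_curve(lengths: np.ndarray, ref_frame: int = 0) -> np.ndarray:
    """Lagrangian strain (%) of a length-vs-time signal."""
    lengths = np.asarray(lengths, dtype=float)
    if np.any(lengths <= 0):
        raise StrainError("lengths must be strictly positive")
    if not 0 <= ref_frame < len(lengths):
        raise StrainError(f"ref_frame {ref_frame} outside 0..{len(lengths) - 1}")
    l0 = lengths[ref_frame]
    return 100.0 * (lengths - l0) / l0


def lv_gls(
    endo_2ch_lengths: np.ndarray | None,
    endo_4ch_lengths: np.ndarray | None,
) -> tuple[float, dict]:
    """Global longitudinal strain (%) from open-contour lengths.

    Per-view GLS is the minimum of the strain curve; the reported value is
    the mean of the two views.  With a single view available the result
    carries a ``single_view`` flag.
    """
    per_view = {}
    for name, lengths in (("2ch", endo_2ch_lengths), ("4ch", endo_4ch_lengths)):
        if lengths is not None:
            per_view[name] = strain_curve(lengths)
    if not per_view:
        raise StrainError("at least one long-axis view is required for GLS")
    values = [float(c.min()) for c in per_view.values()]
    info = {"curves": per_view, "flags": [] if len(values) == 2 else ["single_view"]}
    return float(np.mean(values)), info


def lv_gcs(sax_endo_perimeters: np.ndarray) -> tuple[float, np.ndarray]:
    """Global circumferential strain (%) from mid-ventricular slice perimeters.

    *sax_endo_perimeters* is (n_slices, n_frames); the per-frame strain is
    averaged over slices and GCS is its minimum.
    """
    perims = np.asarray(sax_endo_perimeters, dtype=float)
    if perims.ndim != 2 or perims.shape[0] < 1:
        raise StrainError("need a (n_slices, n_frames) perimeter array")
    curves = np.stack([strain_curve(p) for p in perims])
    mean_curve = curves.mean(axis=0)
    return float(mean_curve.min()), mean_curve


def _ray_boundary_distance(points: np.ndarray, origin: np.ndarray, directions: np.ndarray) -> np.ndarray:
    """Distance from *origin* to the polygon boundary along each unit ray."""
    p0 = np.asarray(points, dtype=float)
    p1 = np.roll(p0, -1, axis=0)
    e = p1 - p0  # edge vectors
    w = p0 - origin
    d = directions  # (r, 2)
    # solve origin + t*d = p0 + s*e  per (ray, edge) via 2x2 cross products
    denom = d[:, None, 0] * (-e)[None, :, 1] - d[:, None, 1] * (-e)[None, :, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (w[None, :, 0] * (-e)[None, :, 1] - w[None, :, 1] * (-e)[None, :, 0]) / denom
        s = (d[:, None, 0] * w[None, :, 1] - d[:, None, 1] * w[None, :, 0]) / denom
    hit = (np.abs(denom) > 1e-12) & (s >= -1e-9) & (s <= 1 + 1e-9) & (t > 1e-9)
    t = np.where(hit, t, np.inf)
    dist = t.min(axis=1)
    if not np.all(np.isfinite(dist)):
        raise StrainError("a radial ray does not intersect the contour")
    return dist


def wall_thickness(
    endo_points: np.ndarray, epi_points: np.ndarray, n_rays: int = 64
) -> float:
    """Mean radial endo–epi distance (mm) over rays from the endo centroid."""
    from .geometry import centroid  # local import avoids cycle at module load

    origin = centroid(endo_points)
    ang = np.linspace(0.0, 2.0 * np.pi, n_rays, endpoint=False)
    rays = np.column_stack([np.cos(ang), np.sin(ang)])
    r_endo = _ray_boundary_distance(endo_points, origin, rays)
    r_epi = _ray_boundary_distance(epi_points, origin, rays)
    th = r_epi - r_endo
    if np.any(th <= 0):
        raise StrainError("epicardial contour lies inside the endocardial contour on a ray")
    return float(th.mean())


def lv_grs(
    sax_endo: list[np.ndarray], sax_epi: list[np.ndarray], n_rays: int = 64
) -> tuple[float, np.ndarray]:
    """Global radial strain (%): peak relative wall thickening.

    *sax_endo* / *sax_epi* are per-slice lists of (n_frames, n_points, 2)
    contour stacks for mid-ventricular slices.
    """
    if len(sax_endo) != len(sax_epi) or not sax_endo:
        raise StrainError("need matching, non-empty endo and epi slice lists")
    n_frames = sax_endo[0].shape[0]
    th = np.zeros(n_frames)
    for endo, epi in zip(sax_endo, sax_epi):
        th += np.array(
            [wall_thickness(endo[i], epi[i], n_rays=n_rays) for i in range(n_frames)]
        )
    th /= len(sax_endo)
    curve = 100.0 * (th - th[0]) / th[0]
    return float(curve.max()), curve


def mid_third_slice_indices(n_slices: int) -> list[int]:
    """Indices of the mid-ventricular third of a short-axis stack."""
    lo = n_slices // 3
    hi = max(lo + 1, int(np.ceil(2 * n_slices / 3)))
    return list(range(lo, hi))


def la_phasic_strain(
    la_strain_curve: np.ndarray, t_max: int, t_preA: int
) -> tuple[float, float, float, float]:
    """Decompose an LA strain curve into (SL_R, SL_C, SL_B, end_residual)."""
    s = np.asarray(la_strain_curve, dtype=float)
    n = len(s)
    if not (0 < t_max < t_preA < n):
        raise StrainError(
            f"need 0 < t_max ({t_max}) < t_preA ({t_preA}) < n_frames ({n})"
        )
    sl_r = float(s[t_max])
    sl_c = float(s[t_max] - s[t_preA])
    sl_b = float(s[t_preA] - s[n - 1])
    residual = float(s[n - 1])
    return sl_r, sl_c, sl_b, residual


@dataclass
class StrainResult:
    lv_gls: float
    lv_gcs: float
    lv_grs: float
    la_slr: float
    la_slc: float
    la_slb: float
    la_end_residual: float
    t_max: int
    t_preA: int
    curves: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)
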