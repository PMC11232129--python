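"""Synthetic cine-contour cohort generator with analytic ground truth.

The generator emulates the output of a feature-tracking step on long-axis
and short-axis cine MRI of the left heart, using a geometry simple enough
that every downstream measure has a closed-form oracle:

* the LV endocardium is a half-ellipsoid (half-ellipse in the long-axis
  views, circles on short-axis slices) truncated at the mitral plane; the
  epicardium is a concentric shell whose thickness increases with
  contraction;
* the LA is an ellipsoid (ellipse in the long-axis views) sitting above
  the mitral plane;
* chamber motion is a uniform per-frame scale factor following a
  piecewise-cosine waveform with four phases — systole (35 % of the
  cycle), early filling, an exactly flat diastasis plateau, and the
  atrial kick — with the apex held fixed so the base descends toward the
  apex during systole (through-plane motion of basal short-axis slices);
* cohort structure: ages drawn uniformly, transverse LV shrinkage and LA
  dilation linear in age, an E/A analog (`filling_ratio`) and LA phasic
  strain amplitudes declining with age, echo velocities tied to the same
  latent diastolic-function trend, and optional Gaussian contour-point
  jitter along the local outward normal.

Every subject carries a :class:`GroundTruth` record (true area curves,
diastasis window, HyF, strains, volumes) so recovery tests can compare the
measurement pipeline against programmed values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .io import ContourFrame, ContourSequence, validate_sequence
from .strain import mid_third_slice_indices

MM3_PER_ML = 1000.0
SEX_SIZE_FACTOR_F = 0.92  # multiplicative semiaxis factor for female subjects
MITRAL_LA_GAP = 6.0  # mm between mitral plane and LA basal pole
MIN_SAX_RADIUS = 0.8  # mm; smaller sections count as "out of slice"


class SyntheticError(ValueError):
    pass


@dataclass
class SubjectParams:
    """Everything needed to generate one subject deterministically."""

    subject_id: str
    age: float  # years
    sex: str  # "M" | "F"
    height: float  # cm
    weight: float  # kg
    hr: float  # bpm
    n_frames: int
    lv_base_semiaxes: tuple[float, float] = (82.0, 21.0)  # (long a, transverse b), mm
    la_base_semiaxes: tuple[float, float] = (26.0, 15.0)
    filling_ratio: float = 1.5  # early/late inflow amplitude ratio (E/A analog)
    diastasis_fraction: float = 0.35  # fraction of diastole on the plateau
    noise_sd: float = 0.0  # mm contour-point jitter
    seed: int = 0
    # kinematic amplitudes
    lv_shortening: float = 0.16  # peak fractional scale reduction (|GLS|/100)
    la_reservoir: float = 0.30  # peak LA strain / 100
    la_conduit: float = 0.185  # conduit component / 100
    grs_peak: float = 0.57  # peak relative wall thickening
    wall_thickness: float = 9.0  # mm end-diastolic
    systole_fraction: float = 0.35
    # sampling
    n_points: int = 64
    n_sax_points: int = 48
    n_sax_slices: int = 12
    sax_thickness: float = 8.0  # mm, no gap

    def __post_init__(self) -> None:
        if not 30 <= self.n_frames <= 60:
            raise SyntheticError(f"n_frames must be in [30, 60], got {self.n_frames}")
        if min(*self.lv_base_semiaxes, *self.la_base_semiaxes) <= 0:
            raise SyntheticError("all semiaxes must be positive")
        if not 0 < self.diastasis_fraction < 1:
            raise SyntheticError("diastasis_fraction must be in (0, 1)")
        if self.filling_ratio <= 0:
            raise SyntheticError("filling_ratio must be positive")
        if self.sex not in ("M", "F"):
            raise SyntheticError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if not 0 < self.la_conduit < self.la_reservoir:
            raise SyntheticError("need 0 < la_conduit < la_reservoir")
        if not 0 < self.lv_shortening < 0.5:
            raise SyntheticError("lv_shortening must be in (0, 0.5)")

    @property
    def bmi(self) -> float:
        return self.weight / (self.height / 100.0) ** 2

    @property
    def rr_interval(self) -> float:
        return 60000.0 / self.hr


@dataclass
class GroundTruth:
    true_lv_area_curve: np.ndarray  # cm²
    true_la_area_curve: np.ndarray  # cm²
    true_diastasis_window: tuple[int, int]
    true_hyf: float  # cm²
    true_strains: dict  # lv_gls, lv_gcs, lv_grs, la_slr, la_slc, la_slb
    true_volumes: dict  # lv_edv/esv/ef/mass, la_edv/esv/ef
    t_max: int  # frame of LA maximal strain
    t_preA: int  # frame of pre-atrial contraction (plateau end)


@dataclass
class SubjectDataset:
    params: SubjectParams
    sequences: list[ContourSequence]
    echo: dict  # E, A, Eprime (cm/s)
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# waveforms


def phase_landmarks(
    n_frames: int, diastasis_fraction: float, systole_fraction: float = 0.35
) -> dict:
    """Frame indices of the four cardiac phases.

    The cycle spans frames 0..n−1 with frame n−1 duplicating frame 0
    (retrospective gating).  Returns end-systole ``ts``, the inclusive
    plateau window, and the pre-atrial-contraction frame ``t_preA``.
    """
    if n_frames < 8:
        raise SyntheticError(
            f"n_frames={n_frames} cannot represent four phases (need >= 8)"
        )
    if not 0 < diastasis_fraction < 1:
        raise SyntheticError("diastasis_fraction must be in (0, 1)")
    L = n_frames - 1
    ts = max(2, round(systole_fraction * L))
    D = L - ts  # diastolic steps
    if D < 5:
        raise SyntheticError("too few diastolic frames for early/plateau/kick phases")
    P = max(1, round(diastasis_fraction * D))
    P = min(P, D - 4)  # keep >= 2 steps for each filling wave
    E = max(2, round(0.55 * (D - P)))
    K = D - P - E
    if K < 2:
        E -= 2 - K
        K = 2
    t0 = ts + E
    return {
        "ts": ts,
        "plateau": (t0, t0 + P),
        "t_preA": t0 + P,
        "early_steps": E,
        "kick_steps": K,
    }


def _cosine_ramp(v0: float, v1: float, steps: int) -> np.ndarray:
    """C⁰ cosine segment over *steps* intervals, endpoints included."""
    u = np.linspace(0.0, 1.0, steps + 1)
    return v0 + (v1 - v0) * (1.0 - np.cos(np.pi * u)) / 2.0


def waveform_scales(
    role: str,
    n_frames: int,
    filling_ratio: float = 1.5,
    diastasis_fraction: float = 0.35,
    systole_fraction: float = 0.35,
    lv_shortening: float = 0.16,
    la_reservoir: float = 0.30,
    la_conduit: float = 0.185,
) -> np.ndarray:
    """Per-frame scale factors for one chamber (frame 0 = end-diastole = 1.0).

    LV: falls to its end-systolic minimum, rises in two steps (early wave,
    diastasis plateau, atrial kick back to the end-diastolic value).  The
    early-to-late rise amplitude ratio equals *filling_ratio*.  LA: the
    mirror image — rises to its reservoir maximum at ventricular
    end-systole, then a two-step descent.  First and last frames are equal.
    """
    if role not in ("LV", "LA"):
        raise SyntheticError(f"role must be 'LV' or 'LA', got {role!r}")
    lm = phase_landmarks(n_frames, diastasis_fraction, systole_fraction)
    ts, (p0, p1) = lm["ts"], lm["plateau"]
    E, K = lm["early_steps"], lm["kick_steps"]
    w = np.empty(n_frames)
    if role == "LV":
        s_min = 1.0 - lv_shortening
        f = filling_ratio
        s_dias = (s_min + f) / (1.0 + f)  # early/late amplitude ratio = f
        w[: ts + 1] = _cosine_ramp(1.0, s_min, ts)
        w[ts : p0 + 1] = _cosine_ramp(s_min, s_dias, E)
        w[p0 : p1 + 1] = s_dias
        w[p1:] = _cosine_ramp(s_dias, 1.0, K)
    else:
        s_max = 1.0 + la_reservoir
        s_preA = s_max - la_conduit
        w[: ts + 1] = _cosine_ramp(1.0, s_max, ts)
        w[ts : p0 + 1] = _cosine_ramp(s_max, s_preA, E)
        w[p0 : p1 + 1] = s_preA
        w[p1:] = _cosine_ramp(s_preA, 1.0, K)
    return w


def chamber_waveform(role: str, params: SubjectParams) -> np.ndarray:
    return waveform_scales(
        role,
        params.n_frames,
        filling_ratio=params.filling_ratio,
        diastasis_fraction=params.diastasis_fraction,
        systole_fraction=params.systole_fraction,
        lv_shortening=params.lv_shortening,
        la_reservoir=params.la_reservoir,
        la_conduit=params.la_conduit,
    )


# ---------------------------------------------------------------------------
# contour construction


def _ellipse_points(
    center: np.ndarray, a_axial: float, b_trans: float, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Closed ellipse (transverse semiaxis along x, axial along y) and its
    outward unit normals."""
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    pts = np.column_stack([b_trans * np.cos(th), a_axial * np.sin(th)]) + center
    nrm = np.column_stack([np.cos(th) / b_trans, np.sin(th) / a_axial])
    nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
    return pts, nrm


def _half_ellipse_points(
    base_y: float, a_axial: float, b_trans: float, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Open base→apex→base half-ellipse below the mitral plane (y-down)."""
    phi = np.linspace(0.0, np.pi, n)
    pts = np.column_stack([b_trans * np.cos(phi), base_y + a_axial * np.sin(phi)])
    nrm = np.column_stack([np.cos(phi) / b_trans, np.sin(phi) / a_axial])
    nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
    return pts, nrm


def _jitter(pts: np.ndarray, normals: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    if sd <= 0:
        return pts
    return pts + normals * rng.normal(0.0, sd, size=(len(pts), 1))


def _lv_kinematics(params: SubjectParams):
    """Per-frame LV geometry: scale w, base depth y_b, wall thickness."""
    w = chamber_waveform("LV", params)
    a, b = params.lv_base_semiaxes
    y_b = a * (1.0 - w)  # apex fixed at depth a; base descends during systole
    g = (1.0 - w) / params.lv_shortening  # 0 at ED, 1 at end-systole
    th = params.wall_thickness * (1.0 + params.grs_peak * g)
    return w, y_b, th


def _sax_radii(params: SubjectParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analytic endo/epi radii per (slice, frame); NaN where out of slice."""
    w, y_b, th = _lv_kinematics(params)
    a, b = params.lv_base_semiaxes
    depth = (np.arange(params.n_sax_slices) + 0.5) * params.sax_thickness
    xi = (depth[:, None] - y_b[None, :])
    with np.errstate(invalid="ignore"):
        r_endo = b * w * np.sqrt(1.0 - (xi / (a * w)) ** 2)
        a_epi = a * w + th
        r_epi = (b * w + th) * np.sqrt(1.0 - (xi / a_epi) ** 2)
    # near-vanishing apical sections are not contoured; the floor scales with
    # the jitter level so noisy points cannot cross the slice centre
    r_min = max(MIN_SAX_RADIUS, 5.0 * params.noise_sd)
    r_endo = np.where((xi >= 0) & (xi <= a * w) & (r_endo > r_min), r_endo, np.nan)
    r_epi = np.where((xi >= 0) & (xi <= a_epi) & (r_epi > r_min), r_epi, np.nan)
    return depth, r_endo, r_epi


def _ground_truth(params: SubjectParams) -> GroundTruth:
    a_lv, b_lv = params.lv_base_semiaxes
    a_la, b_la = params.la_base_semiaxes
    w_lv = chamber_waveform("LV", params)
    w_la = chamber_waveform("LA", params)
    lm = phase_landmarks(params.n_frames, params.diastasis_fraction, params.systole_fraction)
    window = lm["plateau"]

    # cross-sectional areas at the maximal transverse dimension (both views
    # share the same transverse semiaxis, so the biplane ellipse is a circle)
    lv_area = np.pi * (b_lv * w_lv) ** 2 / 100.0
    la_area = np.pi * (b_la * w_la) ** 2 / 100.0
    diff = lv_area - la_area
    true_hyf = float(diff[window[0] : window[1] + 1].mean())

    # strains: uniform scaling makes length strains exact in the scale factor
    s_min = 1.0 - params.lv_shortening
    _, r_endo, r_epi = _sax_radii(params)
    mid = mid_third_slice_indices(params.n_sax_slices)
    gcs_curve = 100.0 * (r_endo[mid] / r_endo[mid, :1] - 1.0).mean(axis=0)
    thickness = (r_epi[mid] - r_endo[mid]).mean(axis=0)
    grs_curve = 100.0 * (thickness / thickness[0] - 1.0)
    strains = {
        "lv_gls": -100.0 * params.lv_shortening,
        "lv_gcs": float(gcs_curve.min()),
        "lv_grs": float(grs_curve.max()),
        "la_slr": 100.0 * params.la_reservoir,
        "la_slc": 100.0 * params.la_conduit,
        "la_slb": 100.0 * (params.la_reservoir - params.la_conduit),
    }

    th0 = params.wall_thickness
    lv_vol = (2.0 / 3.0) * np.pi * a_lv * b_lv**2 / MM3_PER_ML
    epi_vol = (2.0 / 3.0) * np.pi * (a_lv + th0) * (b_lv + th0) ** 2 / MM3_PER_ML
    la_vol = (4.0 / 3.0) * np.pi * a_la * b_la**2 / MM3_PER_ML
    s_max = 1.0 + params.la_reservoir
    volumes = {
        "lv_edv": lv_vol,
        "lv_esv": lv_vol * s_min**3,
        "lv_ef": 100.0 * (1.0 - s_min**3),
        "lv_mass": (epi_vol - lv_vol) * 1.05,
        "la_edv": la_vol * s_max**3,
        "la_esv": la_vol,
        "la_ef": 100.0 * (1.0 - s_max**-3),
    }
    return GroundTruth(
        true_lv_area_curve=lv_area,
        true_la_area_curve=la_area,
        true_diastasis_window=window,
        true_hyf=true_hyf,
        true_strains=strains,
        true_volumes=volumes,
        t_max=lm["ts"],
        t_preA=lm["t_preA"],
    )


def _echo_record(params: SubjectParams, rng: np.random.Generator) -> dict:
    """Echo velocities tied to age and to the subject's filling ratio."""
    a_wave = max(25.0, 37.7 + 0.547 * params.age + rng.normal(0.0, 8.0))
    e_wave = params.filling_ratio * a_wave * (1.0 + rng.normal(0.0, 0.02))
    eprime = float(np.clip(24.6 - 0.236 * params.age + rng.normal(0.0, 2.0), 3.0, 40.0))
    return {"E": float(e_wave), "A": float(a_wave), "Eprime": eprime}


def generate_subject(params: SubjectParams, include_contours: bool = True) -> SubjectDataset:
    """Generate one subject's contour sequences, echo record and ground truth.

    Deterministic for a fixed seed; with ``noise_sd=0`` every contour lies
    exactly on the model surface.
    """
    rng = np.random.default_rng(params.seed)
    echo = _echo_record(params, rng)
    truth = _ground_truth(params)
    if not include_contours:
        return SubjectDataset(params, [], echo, truth)

    a_lv, b_lv = params.lv_base_semiaxes
    a_la, b_la = params.la_base_semiaxes
    w_lv, y_b, th = _lv_kinematics(params)
    w_la = chamber_waveform("LA", params)
    rr = params.rr_interval
    n = params.n_frames
    sd = params.noise_sd

    sequences: list[ContourSequence] = []
    for view in ("2ch", "4ch"):
        lv_endo, lv_epi, la_endo = [], [], []
        for i in range(n):
            pts, nrm = _half_ellipse_points(y_b[i], a_lv * w_lv[i], b_lv * w_lv[i], params.n_points)
            lv_endo.append(ContourFrame(i, _jitter(pts, nrm, sd, rng)))
            pts, nrm = _half_ellipse_points(
                y_b[i], a_lv * w_lv[i] + th[i], b_lv * w_lv[i] + th[i], params.n_points
            )
            lv_epi.append(ContourFrame(i, _jitter(pts, nrm, sd, rng)))
            center = np.array([0.0, y_b[i] - MITRAL_LA_GAP - a_la * w_la[i]])
            pts, nrm = _ellipse_points(center, a_la * w_la[i], b_la * w_la[i], params.n_points)
            la_endo.append(ContourFrame(i, _jitter(pts, nrm, sd, rng)))
        for chamber, closed, frames in (
            ("LV_endo", False, lv_endo),
            ("LV_epi", False, lv_epi),
            ("LA_endo", True, la_endo),
        ):
            sequences.append(
                ContourSequence(params.subject_id, view, chamber, closed, rr, frames)
            )

    depth, r_endo, r_epi = _sax_radii(params)
    for j in range(params.n_sax_slices):
        for chamber, radii in (("LV_endo", r_endo[j]), ("LV_epi", r_epi[j])):
            frames = []
            for i in range(n):
                if np.isnan(radii[i]):
                    frames.append(ContourFrame(i, np.empty((0, 2))))
                    continue
                pts, nrm = _ellipse_points(
                    np.zeros(2), radii[i], radii[i], params.n_sax_points
                )
                frames.append(ContourFrame(i, _jitter(pts, nrm, sd, rng)))
            sequences.append(
                ContourSequence(
                    params.subject_id,
                    "sax",
                    chamber,
                    True,
                    rr,
                    frames,
                    slice_location=float(depth[j]),
                    slice_thickness=params.sax_thickness,
                )
            )
    for seq in sequences:  # reject parameter sets yielding invalid polygons
        validate_sequence(seq)
    return SubjectDataset(params, sequences, echo, truth)


# ---------------------------------------------------------------------------
# cohort


@dataclass
class CohortConfig:
    n_subjects: int
    age_range: tuple[float, float] = (20.0, 81.0)
    age_effect_lv: float = -0.6  # mm/decade on the LV transverse semiaxis
    age_effect_la: float = 0.4  # mm/decade on the LA transverse semiaxis
    age_effect_filling: float = 0.18  # per-decade decrease of filling_ratio
    age_effect_reservoir: float = 0.021  # per-decade decrease (strain fraction)
    age_effect_conduit: float = 0.024  # per-decade decrease (strain fraction)
    echo_noise_sd: float = 1.0  # scale on echo residuals
    contour_noise_sd: float = 0.0  # mm
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise SyntheticError("n_subjects must be >= 2")
        lo, hi = self.age_range
        if not (18.0 <= lo < hi <= 90.0):
            raise SyntheticError("age_range must be increasing and within [18, 90]")


@dataclass
class CohortDataset:
    config: CohortConfig
    subjects: list[SubjectDataset]
    cohort: pd.DataFrame  # demographics + echo, one row per subject
    truth: pd.DataFrame  # ground-truth indices, one row per subject


def subject_seed(master_seed: int, index: int) -> int:
    """Deterministic per-subject seed derived from the master seed."""
    return int(np.random.SeedSequence((master_seed, index)).generate_state(1)[0] % 2**31)


def _draw_params(config: CohortConfig, index: int, rng: np.random.Generator) -> SubjectParams:
    lo, hi = config.age_range
    age = float(rng.uniform(lo, hi))
    sex = "M" if rng.random() < 0.5 else "F"
    height = float(rng.normal(175.0 if sex == "M" else 162.0, 6.5))
    bmi = float(np.clip(21.1 + 0.056 * age + rng.normal(0.0, 2.5), 17.0, 38.0))
    weight = float(np.clip(bmi * (height / 100.0) ** 2, 40.0, 160.0))
    dec = (age - 50.0) / 10.0
    size = SEX_SIZE_FACTOR_F if sex == "F" else 1.0
    # latent diastolic-function score: age-independent remodeling shared by
    # chamber size, filling pattern and conduit strain, so echo indices stay
    # associated with HyF after adjusting for age
    u = rng.normal(0.0, 1.0)
    # semiaxis spread sets the between-subject HyF SD (a couple of cm², as in
    # healthy adult cohorts)
    b_lv = max(12.0, (21.0 + config.age_effect_lv * dec - 0.6 * u + rng.normal(0.0, 1.1)) * size)
    b_la = max(9.0, (15.0 + config.age_effect_la * dec + 0.9 * u + rng.normal(0.0, 1.0)) * size)
    a_lv = max(60.0, (82.0 + rng.normal(0.0, 3.0)) * size)
    a_la = max(18.0, (26.0 + rng.normal(0.0, 1.5)) * size)
    filling = float(
        np.clip(
            1.24 - config.age_effect_filling * dec - 0.12 * u + rng.normal(0.0, 0.08),
            0.45,
            2.5,
        )
    )
    reservoir = float(
        np.clip(0.272 - config.age_effect_reservoir * dec + rng.normal(0.0, 0.02), 0.10, 0.45)
    )
    conduit = float(
        np.clip(
            0.145 - config.age_effect_conduit * dec - 0.012 * u + rng.normal(0.0, 0.012),
            0.03,
            reservoir - 0.03,
        )
    )
    return SubjectParams(
        subject_id=f"S{index:04d}",
        age=age,
        sex=sex,
        height=height,
        weight=weight,
        hr=float(np.clip(rng.normal(69.0, 9.5), 45.0, 100.0)),
        n_frames=int(rng.integers(30, 61)),
        lv_base_semiaxes=(a_lv, b_lv),
        la_base_semiaxes=(a_la, b_la),
        filling_ratio=filling,
        diastasis_fraction=float(np.clip(rng.normal(0.35, 0.06), 0.15, 0.55)),
        noise_sd=config.contour_noise_sd,
        seed=subject_seed(config.master_seed, index),
        lv_shortening=float(np.clip(rng.normal(0.165, 0.015), 0.10, 0.25)),
        la_reservoir=reservoir,
        la_conduit=conduit,
        grs_peak=float(np.clip(0.59 - 0.0018 * (age - 20.0) + rng.normal(0.0, 0.05), 0.3, 0.9)),
    )


def generate_cohort(config: CohortConfig, include_contours: bool = True) -> CohortDataset:
    """Generate the full cohort: subject datasets + cohort and truth tables."""
    rng = np.random.default_rng(config.master_seed)
    subjects: list[SubjectDataset] = []
    cohort_rows, truth_rows = [], []
    for i in range(config.n_subjects):
        params = _draw_params(config, i, rng)
        try:
            subj = generate_subject(params, include_contours=include_contours)
        except Exception as e:
            raise SyntheticError(f"subject {params.subject_id}: {e}") from e
        subjects.append(subj)
        cohort_rows.append(
            {
                "subject_id": params.subject_id,
                "age": round(params.age, 2),
                "sex": params.sex,
                "height": round(params.height, 1),
                "weight": round(params.weight, 1),
                "bmi": round(params.bmi, 2),
                "sbp": round(96.5 + 0.35 * params.age + rng.normal(0.0, 8.0) * config.echo_noise_sd, 1),
                "dbp": round(59.0 + 0.22 * params.age + rng.normal(0.0, 7.0) * config.echo_noise_sd, 1),
                "hr": round(params.hr, 1),
                "E": round(subj.echo["E"], 1),
                "A": round(subj.echo["A"], 1),
                "Eprime": round(subj.echo["Eprime"], 1),
                "seed": params.seed,
            }
        )
        truth_rows.append(
            {
                "subject_id": params.subject_id,
                "age": params.age,
                "true_hyf": subj.ground_truth.true_hyf,
                "true_diastasis_start": subj.ground_truth.true_diastasis_window[0],
                "true_diastasis_end": subj.ground_truth.true_diastasis_window[1],
                **{f"true_{k}": v for k, v in subj.ground_truth.true_strains.items()},
                **{f"true_{k}": v for k, v in subj.ground_truth.true_volumes.items()},
            }
        )
    return CohortDataset(
        config=config,
        subjects=subjects,
        cohort=pd.DataFrame(cohort_rows),
        truth=pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------------------
# analytic phantoms (validation fixtures for the measurement pipeline)


def sphere_phantom(
    radius: float = 20.0,
    separation: float = 60.0,
    n_frames: int = 30,
    n_points: int = 64,
    rr_interval: float = 1000.0,
) -> dict[tuple[str, str], ContourSequence]:
    """Two static spheres ("LV" below, "LA" above) seen as circles in both
    long-axis views; the great-circle area πr² is the expected
    cross-sectional area in every frame and mode."""
    out = {}
    for view in ("2ch", "4ch"):
        for chamber, cy in (("LV_endo", separation / 2.0), ("LA_endo", -separation / 2.0)):
            frames = [
                ContourFrame(i, _ellipse_points(np.array([0.0, cy]), radius, radius, n_points)[0])
                for i in range(n_frames)
            ]
            out[(view, chamber)] = ContourSequence(
                "phantom", view, chamber, True, rr_interval, frames
            )
    return out


def ellipsoid_slice_areas(a: float, b: float, c: float, n_slices: int) -> tuple[np.ndarray, float]:
    """Slice areas (cm², one frame) and thickness (mm) of an ellipsoid with
    semiaxes (a, b, c) mm sliced along a — Simpson-summation phantom."""
    thickness = 2.0 * a / n_slices
    x = -a + (np.arange(n_slices) + 0.5) * thickness
    areas = np.pi * b * c * (1.0 - (x / a) ** 2) / 100.0
    return areas.reshape(-1, 1), thickness


def annulus_phantom(
    r_endo: Iterable[float], r_epi: Iterable[float], n_points: int = 48
) -> tuple[np.ndarray, np.ndarray]:
    """Concentric circular endo/epi contour stacks (n_frames, n, 2) with
    programmed radii — oracle for wall-thickness and radial strain."""
    endo = np.stack([_ellipse_points(np.zeros(2), r, r, n_points)[0] for r in r_endo])
    epi = np.stack([_ellipse_points(np.zeros(2), r, r, n_points)[0] for r in r_epi])
    return endo, epi


def with_noise(params: SubjectParams, noise_sd: float, seed: int | None = None) -> SubjectParams:
    """Convenience: same subject re-measured with different contour jitter."""
    return replace(params, noise_sd=noise_sd, seed=params.seed if seed is None else seed)
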