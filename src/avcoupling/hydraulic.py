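"""Hydraulic-force estimation: LV−LA area difference and diastasis detection.

The hydraulic force acting on the atrioventricular plane is estimated
geometrically as HyF (cm²) = A_LV − A_LA, the difference between the LV and
LA cross-sectional areas, evaluated during diastasis — the mid-diastolic
plateau when the transmitral pressure gradient is minimal, so the pressure
component can be neglected.  Diastasis is detected on the LV area-rate
curve: diastole runs from the LV area minimum to the cycle end; the early
(E) and atrial (A) filling waves are the two dA/dt maxima, and the
diastasis window is the longest contiguous run between them where the
filling rate falls below a fraction θ of the E-wave peak.  The scalar HyF
is the mean of the difference curve over that window, preserving sign
(negative when the LA section exceeds the LV section, the pattern of the
aged heart).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_THETA = 0.2  # fraction of the E-wave peak rate defining "plateau"


class HydraulicError(ValueError):
    pass


def hyf_curve(lv_area_curve: np.ndarray, la_area_curve: np.ndarray) -> np.ndarray:
    """Per-frame LV−LA cross-sectional area difference (cm²)."""
    lv = np.asarray(lv_area_curve, dtype=float)
    la = np.asarray(la_area_curve, dtype=float)
    if lv.shape != la.shape:
        raise HydraulicError(f"curve length mismatch: {lv.shape} vs {la.shape}")
    return lv - la


def _unique_period(a: np.ndarray) -> int:
    n = len(a)
    if n > 2 and abs(a[0] - a[-1]) <= 1e-12 * (np.ptp(a) + 1e-30):
        return n - 1
    return n


def _periodic_rate(curve: np.ndarray, dt: float = 1.0) -> np.ndarray:
    """Central-difference derivative with periodic wrap (retrospective gating
    implies a closed cycle; when the first and last samples duplicate the
    trigger frame the wrap uses the unique period)."""
    a = np.asarray(curve, dtype=float)
    n = len(a)
    p = _unique_period(a)
    base = a[:p]
    rate_p = (np.roll(base, -1) - np.roll(base, 1)) / (2.0 * dt)
    return rate_p[np.arange(n) % p]


_SMOOTH_KERNEL = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


def _periodic_smooth(curve: np.ndarray) -> np.ndarray:
    """Binomial low-pass on the periodic cycle.  Tracked area curves are
    temporally smooth; filtering before differentiation keeps the plateau
    detector stable under contour measurement noise."""
    a = np.asarray(curve, dtype=float)
    n = len(a)
    p = _unique_period(a)
    base = a[:p]
    sm = sum(w * np.roll(base, k - 2) for k, w in enumerate(_SMOOTH_KERNEL))
    return sm[np.arange(n) % p]


@dataclass
class DiastasisResult:
    t_start: int
    t_end: int
    e_peak_frame: int
    a_peak_frame: int | None
    qc_flags: list = field(default_factory=list)


def detect_diastasis(
    lv_area_curve: np.ndarray,
    times: np.ndarray | None = None,
    theta: float = DEFAULT_THETA,
) -> DiastasisResult:
    """Locate the diastasis plateau on an LV area curve.

    Returns the inclusive frame window plus the early- and late-filling
    peak frames; atypical curves get QC flags rather than hard failures,
    except when no diastolic limb exists at all.
    """
    a = np.asarray(lv_area_curve, dtype=float)
    n = len(a)
    if n < 8:
        raise HydraulicError(f"curve too short ({n} frames) to resolve diastole")
    if theta < 0:
        raise HydraulicError("theta must be >= 0")
    dt = 1.0
    if times is not None:
        times = np.asarray(times, dtype=float)
        dt = float(np.median(np.diff(times)))
    rate = _periodic_rate(_periodic_smooth(a), dt)
    rate_raw = _periodic_rate(a, dt)

    m = int(np.argmin(a))
    if m == 0 or m >= n - 2:
        raise HydraulicError(
            "no diastolic limb: the area minimum is at the cycle boundary "
            "(monotone or time-reversed curve?)"
        )
    flags: list[str] = []
    dia = np.arange(m, n)  # diastole: minimum-area frame to cycle end
    half = m + max(1, len(dia) // 2)

    e_slice = rate[m:half]
    e_peak = m + int(np.argmax(e_slice))
    if rate[e_peak] <= 0:
        # no recognizable early filling wave — fall back to quietest late frame
        flags.append("no_filling_wave")
        late = np.arange(half, n)
        t = int(late[np.argmin(np.abs(rate[late]))])
        return DiastasisResult(t, t, e_peak, None, flags)

    a_lo = max(e_peak + 1, half)
    a_slice = rate[a_lo:n]
    a_peak = a_lo + int(np.argmax(a_slice)) if len(a_slice) else None
    # a late wave below 5% of the early peak is no atrial kick at all
    if a_peak is None or rate[a_peak] <= 0.05 * rate[e_peak] or a_peak <= e_peak + 1:
        # atrial-fibrillation analog: no late filling wave
        flags.append("no_atrial_kick")
        late = np.arange(half, n)
        t = int(late[np.argmin(np.abs(rate[late]))])
        return DiastasisResult(t, t, e_peak, a_peak, flags)

    # threshold against the unfiltered E-wave peak: the low-pass attenuates
    # the narrow peak more than the plateau, which would bias theta
    thresh = theta * max(rate[e_peak], float(rate_raw[m:half].max()))
    between = np.arange(e_peak + 1, a_peak)
    quiet = np.abs(rate[between]) < thresh
    # close gaps of up to two frames: isolated noisy frames do not end diastasis
    run = 0
    for i, q in enumerate(quiet):
        if q:
            if 0 < run <= 2 and i - run - 1 >= 0 and quiet[i - run - 1]:
                quiet[i - run : i] = True
            run = 0
        else:
            run += 1
    # longest contiguous quiet run
    best_len, best_start, cur_len, cur_start = 0, None, 0, None
    for idx, q in zip(between, quiet):
        if q:
            if cur_len == 0:
                cur_start = idx
            cur_len += 1
            if cur_len > best_len:
                best_len, best_start = cur_len, cur_start
        else:
            cur_len = 0
    if best_len == 0:
        flags.append("short_diastasis")
        t = int(between[np.argmin(np.abs(rate[between]))]) if len(between) else e_peak + 1
        return DiastasisResult(t, t, e_peak, a_peak, flags)
    return DiastasisResult(best_start, best_start + best_len - 1, e_peak, a_peak, flags)


def hydraulic_force(
    lv_area_curve: np.ndarray,
    la_area_curve: np.ndarray,
    window: tuple[int, int],
) -> float:
    """Scalar HyF (cm²): mean LV−LA area difference over the window frames."""
    diff = hyf_curve(lv_area_curve, la_area_curve)
    t0, t1 = int(window[0]), int(window[1])
    if not (0 <= t0 <= t1 < len(diff)):
        raise HydraulicError(f"window {window} outside curve range 0..{len(diff) - 1}")
    return float(diff[t0 : t1 + 1].mean())


@dataclass
class HyFResult:
    diff_curve: np.ndarray  # cm² per frame
    diastasis_window: tuple[int, int]
    hyf: float  # cm²
    e_peak_frame: int
    a_peak_frame: int | None
    lv_area_diastasis: float  # cm², window mean
    la_area_diastasis: float  # cm², window mean
    qc_flags: list = field(default_factory=list)


def hyf_analysis(
    lv_area_curve: np.ndarray,
    la_area_curve: np.ndarray,
    times: np.ndarray | None = None,
    theta: float = DEFAULT_THETA,
) -> HyFResult:
    """Full HyF analysis: difference curve, diastasis detection, scalar HyF."""
    lv = np.asarray(lv_area_curve, dtype=float)
    la = np.asarray(la_area_curve, dtype=float)
    diff = hyf_curve(lv, la)
    dia = detect_diastasis(lv, times=times, theta=theta)
    window = (dia.t_start, dia.t_end)
    return HyFResult(
        diff_curve=diff,
        diastasis_window=window,
        hyf=hydraulic_force(lv, la, window),
        e_peak_frame=dia.e_peak_frame,
        a_peak_frame=dia.a_peak_frame,
        lv_area_diastasis=float(lv[dia.t_start : dia.t_end + 1].mean()),
        la_area_diastasis=float(la[dia.t_start : dia.t_end + 1].mean()),
        qc_flags=list(dia.qc_flags),
    )
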