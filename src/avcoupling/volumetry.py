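"""Chamber volumetry: Simpson LV volumes, biplane area-length LA volumes,
ejection fractions, LV mass, and BSA indexing.

LV volumes come from the short-axis stack by Simpson summation (slice area
times slice spacing); slices whose endocardial area is zero at a frame —
through-plane motion of the base — simply contribute nothing, with no
partial-slice correction.  LA volumes use the biplane area-length rule
V = (8/3π)·A₂·A₄/L, which is exact on ellipsoids.  EDV/ESV are the
volume-curve extrema rather than fixed frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MYOCARDIAL_DENSITY = 1.05  # g/ml
BSA_FORMULAS = ("dubois", "mosteller")


class VolumetryError(ValueError):
    pass


def lv_volume_simpson(
    slice_areas: np.ndarray,
    thickness: float,
    gap: float = 0.0,
) -> np.ndarray:
    """Simpson volume per frame in ml.

    *slice_areas* is (n_slices, n_frames) in cm²; effective slice spacing is
    thickness + gap in mm.  1 cm²·mm = 0.1 ml.
    """
    areas = np.asarray(slice_areas, dtype=float)
    if areas.ndim != 2:
        raise VolumetryError("slice_areas must be a (n_slices, n_frames) array")
    if areas.shape[0] < 3:
        raise VolumetryError(f"need >= 3 slices, got {areas.shape[0]}")
    if thickness <= 0:
        raise VolumetryError("slice thickness must be positive")
    return areas.sum(axis=0) * (thickness + gap) * 0.1


def lv_mass(epi_volume: float, endo_volume: float, density: float = MYOCARDIAL_DENSITY) -> float:
    """Myocardial mass (g) from the epicardial/endocardial volume shell."""
    if epi_volume <= endo_volume:
        raise VolumetryError(
            f"epicardial volume ({epi_volume:.1f} ml) must exceed endocardial ({endo_volume:.1f} ml)"
        )
    return (epi_volume - endo_volume) * density


def la_volume_biplane(
    area_2ch: float, area_4ch: float, length_2ch: float, length_4ch: float
) -> float:
    """Biplane area-length volume in ml (areas cm², lengths mm).

    V = (8/3π) · A₂ · A₄ / L with L the shorter of the two view lengths.
    """
    if min(area_2ch, area_4ch) <= 0:
        raise VolumetryError("areas must be positive")
    l_min = min(length_2ch, length_4ch)
    if l_min <= 0:
        raise VolumetryError("chamber length must be positive")
    return (8.0 / (3.0 * np.pi)) * area_2ch * area_4ch / (l_min / 10.0)


def ejection_fraction(edv: float, esv: float) -> float:
    """EF in percent; flags (rather than clips) ESV > EDV."""
    if edv <= 0:
        raise VolumetryError("EDV must be positive")
    if esv < 0 or esv > edv:
        raise VolumetryError(f"ESV ({esv:.1f}) outside [0, EDV={edv:.1f}]")
    return 100.0 * (edv - esv) / edv


def bsa(height: float, weight: float, formula: str = "dubois") -> float:
    """Body surface area (m²) from height (cm) and weight (kg)."""
    if not (100.0 < height < 230.0):
        raise VolumetryError(f"height {height} cm outside sanity bounds (100, 230)")
    if not (25.0 < weight < 250.0):
        raise VolumetryError(f"weight {weight} kg outside sanity bounds (25, 250)")
    if formula == "dubois":
        return 0.007184 * weight**0.425 * height**0.725
    if formula == "mosteller":
        return float(np.sqrt(height * weight / 3600.0))
    raise VolumetryError(f"unknown BSA formula {formula!r}")


@dataclass
class VolumeResult:
    """Chamber volumes (ml), EFs (%), mass (g) and BSA-indexed variants."""

    lv_edv: float
    lv_esv: float
    lv_ef: float
    lv_mass: float
    la_edv: float
    la_esv: float
    la_ef: float
    bsa: float | None = None

    def indexed(self) -> dict[str, float]:
        if self.bsa is None:
            raise VolumetryError("BSA is required for indexed volumes")
        return {
            "lv_edvi": self.lv_edv / self.bsa,
            "lv_esvi": self.lv_esv / self.bsa,
            "la_edvi": self.la_edv / self.bsa,
            "la_esvi": self.la_esv / self.bsa,
            "lv_massi": self.lv_mass / self.bsa,
        }


def volume_result(
    lv_volume_curve: np.ndarray,
    epi_volume_curve: np.ndarray,
    la_volume_curve: np.ndarray,
    bsa_value: float | None = None,
) -> VolumeResult:
    """Assemble EDV/ESV/EF/mass from per-frame volume curves.

    EDV and ESV are the extrema of each chamber's own curve; LV mass is
    measured at the LV end-diastolic frame.
    """
    lv = np.asarray(lv_volume_curve, dtype=float)
    epi = np.asarray(epi_volume_curve, dtype=float)
    la = np.asarray(la_volume_curve, dtype=float)
    ed_frame = int(np.argmax(lv))
    return VolumeResult(
        lv_edv=float(lv.max()),
        lv_esv=float(lv.min()),
        lv_ef=ejection_fraction(float(lv.max()), float(lv.min())),
        lv_mass=lv_mass(float(epi[ed_frame]), float(lv[ed_frame])),
        la_edv=float(la.max()),
        la_esv=float(la.min()),
        la_ef=ejection_fraction(float(la.max()), float(la.min())),
        bsa=bsa_value,
    )
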