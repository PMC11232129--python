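"""End-to-end orchestration: per-subject analysis, cohort runs, reproducibility.

``run_subject`` turns one subject's contour sequences into a flat record of
derived indices (areas, HyF, strains, volumes); ``run_cohort`` maps it over
a cohort with QC-based exclusions and hands the survivors to the statistics
layer; ``run_reproducibility`` emulates repeated operator measurements by
re-running the HyF pipeline on independently jittered contours and reports
intra-/inter-operator ICCs.  Every result record echoes the resolved
configuration so outputs are traceable.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry, hydraulic, strain, volumetry
from .io import (
    ContourSequence,
    read_cohort_csv,
    read_contour_file,
    recompute_echo_ratios,
    sequences_by_key,
)
from .stats import ICC_MODEL_LABEL, ICCResult, StatsReport, build_report, icc
from .synthetic import CohortDataset, SubjectDataset

log = logging.getLogger("avcoupling")


@dataclass
class PipelineConfig:
    area_mode: str = "biplane_ellipse"  # or "single_plane"
    diastasis_theta: float = hydraulic.DEFAULT_THETA
    station_step: float = geometry.DEFAULT_STATION_STEP
    bsa_formula: str = "dubois"
    icc_model: str = ICC_MODEL_LABEL
    seed: int = 0
    log_level: str = "INFO"

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _lengths(seq: ContourSequence) -> np.ndarray:
    return np.array([geometry.contour_length(f.points, seq.closed) for f in seq.frames])


def _slice_areas(slices: list[ContourSequence]) -> np.ndarray:
    """(n_slices, n_frames) polygon areas in cm²; empty frames count as 0."""
    n_frames = slices[0].n_frames
    out = np.zeros((len(slices), n_frames))
    for j, seq in enumerate(slices):
        for i, f in enumerate(seq.frames):
            if len(f.points):
                out[j, i] = geometry.polygon_area(f.points)
    return out


def _la_volume_curve(
    la_2ch: ContourSequence,
    la_4ch: ContourSequence,
    lv_2ch: ContourSequence,
    lv_4ch: ContourSequence,
) -> np.ndarray:
    n = la_2ch.n_frames
    vols = np.empty(n)
    for i in range(n):
        pairs = []
        for la, lv in ((la_2ch, lv_2ch), (la_4ch, lv_4ch)):
            axis, _ = geometry.long_axis(lv.frames[i].points, la.frames[i].points)
            pairs.append(
                (
                    geometry.polygon_area(la.frames[i].points),
                    geometry.chamber_length(la.frames[i].points, axis),
                )
            )
        (a2, l2), (a4, l4) = pairs
        vols[i] = volumetry.la_volume_biplane(a2, a4, l2, l4)
    return vols


def run_subject(
    data: SubjectDataset | list[ContourSequence] | str | Path,
    config: PipelineConfig | None = None,
    height: float | None = None,
    weight: float | None = None,
) -> dict:
    """Analyze one subject; missing inputs leave fields empty with QC flags."""
    config = config or PipelineConfig()
    if isinstance(data, (str, Path)):
        sequences = read_contour_file(data)
    elif isinstance(data, SubjectDataset):
        sequences = data.sequences
        if height is None:
            height, weight = data.params.height, data.params.weight
    else:
        sequences = data
    if not sequences:
        raise ValueError("no contour sequences provided")
    idx = sequences_by_key(sequences)
    subject_id = sequences[0].subject_id
    flags: list[str] = []

    def get(view: str, chamber: str) -> ContourSequence | None:
        group = idx.get((view, chamber))
        return group[0] if group else None

    lv2, lv4 = get("2ch", "LV_endo"), get("4ch", "LV_endo")
    la2, la4 = get("2ch", "LA_endo"), get("4ch", "LA_endo")
    if config.area_mode == "biplane_ellipse":
        if not (lv2 and lv4 and la2 and la4):
            raise ValueError(
                f"{subject_id}: biplane analysis needs LV_endo and LA_endo in both "
                "long-axis views"
            )
        use = dict(lv_2ch=lv2, la_2ch=la2, lv_4ch=lv4, la_4ch=la4)
    else:
        if lv4 and la4:
            use = dict(lv_2ch=None, la_2ch=None, lv_4ch=lv4, la_4ch=la4)
        elif lv2 and la2:
            use = dict(lv_2ch=lv2, la_2ch=la2, lv_4ch=None, la_4ch=None)
        else:
            raise ValueError(f"{subject_id}: need LV_endo and LA_endo in one view")

    lv_curve, la_curve = geometry.chamber_area_curves(
        **use, mode=config.area_mode, station_step=config.station_step
    )
    hyf = hydraulic.hyf_analysis(
        lv_curve.areas, la_curve.areas, times=lv_curve.times, theta=config.diastasis_theta
    )
    flags.extend(hyf.qc_flags)

    record: dict = {
        "subject_id": subject_id,
        "n_frames": lv_curve.n_frames,
        "hyf": hyf.hyf,
        "diastasis_start": hyf.diastasis_window[0],
        "diastasis_end": hyf.diastasis_window[1],
        "e_peak_frame": hyf.e_peak_frame,
        "a_peak_frame": hyf.a_peak_frame,
        "lv_area_diastasis": hyf.lv_area_diastasis,
        "la_area_diastasis": hyf.la_area_diastasis,
    }

    # --- strains -----------------------------------------------------------
    gls, gls_info = strain.lv_gls(
        None if use["lv_2ch"] is None else _lengths(use["lv_2ch"]),
        None if use["lv_4ch"] is None else _lengths(use["lv_4ch"]),
    )
    flags.extend(gls_info["flags"])
    record["lv_gls"] = gls

    la_views = [s for s in (use["la_2ch"], use["la_4ch"]) if s is not None]
    la_strain_curve = np.mean([strain.strain_curve(_lengths(s)) for s in la_views], axis=0)
    t_max = int(np.argmax(la_strain_curve))
    t_preA = hyf.diastasis_window[1]  # onset of the atrial kick
    try:
        slr, slc, slb, resid = strain.la_phasic_strain(la_strain_curve, t_max, t_preA)
        record.update(
            la_slr=slr, la_slc=slc, la_slb=slb, la_end_residual=resid,
            t_max=t_max, t_preA=t_preA,
        )
    except strain.StrainError:
        flags.append("la_phase_order")
        record.update(
            la_slr=float(la_strain_curve.max()), la_slc=np.nan, la_slb=np.nan,
            la_end_residual=float(la_strain_curve[-1]), t_max=t_max, t_preA=t_preA,
        )

    sax_endo = idx.get(("sax", "LV_endo"), [])
    sax_epi = idx.get(("sax", "LV_epi"), [])
    if sax_endo:
        mid = strain.mid_third_slice_indices(len(sax_endo))
        mid_endo = [sax_endo[j] for j in mid if j < len(sax_endo)]
        full = [s for s in mid_endo if all(len(f.points) for f in s.frames)]
        if full:
            perims = np.stack([_lengths(s) for s in full])
            gcs, _ = strain.lv_gcs(perims)
            record["lv_gcs"] = gcs
        else:
            flags.append("no_complete_mid_slice")
            record["lv_gcs"] = np.nan
        if sax_epi and len(sax_epi) == len(sax_endo):
            endo_stacks, epi_stacks = [], []
            for j in mid:
                e, p = sax_endo[j], sax_epi[j]
                if all(len(f.points) for f in e.frames) and all(len(f.points) for f in p.frames):
                    endo_stacks.append(e.point_array())
                    epi_stacks.append(p.point_array())
            if endo_stacks:
                grs, _ = strain.lv_grs(endo_stacks, epi_stacks)
                record["lv_grs"] = grs
            else:
                record["lv_grs"] = np.nan
        else:
            flags.append("no_epicardial_stack")
            record["lv_grs"] = np.nan
    else:
        flags.append("no_sax_stack")
        record["lv_gcs"] = np.nan
        record["lv_grs"] = np.nan

    # --- volumes -----------------------------------------------------------
    if sax_endo:
        endo_areas = _slice_areas(sax_endo)
        thickness = sax_endo[0].slice_thickness
        lv_vol = volumetry.lv_volume_simpson(endo_areas, thickness)
        epi_vol = (
            volumetry.lv_volume_simpson(_slice_areas(sax_epi), thickness)
            if sax_epi
            else None
        )
        la_vol = (
            _la_volume_curve(la2, la4, lv2, lv4) if (la2 and la4 and lv2 and lv4) else None
        )
        if epi_vol is not None and la_vol is not None:
            bsa_val = (
                volumetry.bsa(height, weight, config.bsa_formula)
                if height is not None and weight is not None
                else None
            )
            vr = volumetry.volume_result(lv_vol, epi_vol, la_vol, bsa_val)
            record.update(
                lv_edv=vr.lv_edv, lv_esv=vr.lv_esv, lv_ef=vr.lv_ef, lv_mass=vr.lv_mass,
                la_edv=vr.la_edv, la_esv=vr.la_esv, la_ef=vr.la_ef, bsa=vr.bsa,
            )
            if bsa_val is not None:
                record.update(vr.indexed())
            else:
                flags.append("no_anthropometrics")
    else:
        flags.append("no_volumes")

    record["qc_flags"] = ";".join(flags)
    record["config"] = config.as_dict()
    return record


EXCLUSIONARY = (ValueError,)  # geometry/schema/detection failures drop the subject


@dataclass
class CohortResults:
    results: pd.DataFrame
    report: StatsReport
    exclusions: list = field(default_factory=list)
    config: PipelineConfig = field(default_factory=PipelineConfig)


def _iter_cohort(source) -> tuple[pd.DataFrame, list]:
    """Yield (cohort table, [(subject_id, data), …]) from a dataset or directory."""
    if isinstance(source, CohortDataset):
        return source.cohort, [(s.params.subject_id, s) for s in source.subjects]
    root = Path(source)
    cohort = read_cohort_csv(root / "cohort.csv")
    items = [(sid, root / f"{sid}.json") for sid in cohort["subject_id"]]
    return cohort, items


def run_cohort(source, config: PipelineConfig | None = None) -> CohortResults:
    """Analyze every subject, exclude QC failures, run the statistics layer."""
    config = config or PipelineConfig()
    cohort, items = _iter_cohort(source)
    records, exclusions = [], []
    for sid, data in items:
        try:
            row = cohort.loc[cohort["subject_id"] == sid]
            h = float(row["height"].iloc[0]) if len(row) else None
            wt = float(row["weight"].iloc[0]) if len(row) else None
            records.append(run_subject(data, config, height=h, weight=wt))
        except EXCLUSIONARY as e:
            log.warning("excluding %s: %s", sid, e)
            exclusions.append({"subject_id": sid, "reason": str(e)})
    if not records:
        raise ValueError("no subjects survived QC exclusion")
    results = pd.DataFrame.from_records(records).drop(columns=["config"])
    merged = recompute_echo_ratios(cohort).merge(results, on="subject_id", how="inner")
    report = build_report(merged)
    report.meta.update(
        config=config.as_dict(),
        n_excluded=len(exclusions),
        excluded=[e["subject_id"] for e in exclusions],
    )
    return CohortResults(results=merged, report=report, exclusions=exclusions, config=config)


def _smooth_perturbation(points: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Radial low-order (Fourier k ≤ 2) displacement field with pointwise SD
    *sd* mm — emulates smooth operator re-contouring variability."""
    center = points.mean(axis=0)
    rel = points - center
    ang = np.arctan2(rel[:, 1], rel[:, 0])
    c = rng.normal(0.0, sd / np.sqrt(3.0), size=5)
    d = c[0] + c[1] * np.cos(ang) + c[2] * np.sin(ang) + c[3] * np.cos(2 * ang) + c[4] * np.sin(2 * ang)
    radial = rel / (np.linalg.norm(rel, axis=1, keepdims=True) + 1e-12)
    return points + radial * d[:, None]


def _measure_hyf_with_jitter(
    subject: SubjectDataset, jitter_sd: float, rng: np.random.Generator,
    config: PipelineConfig,
) -> float:
    """One 'operator measurement': HyF from independently perturbed contours."""
    idx = sequences_by_key(subject.sequences)

    def jittered(view: str, chamber: str) -> ContourSequence:
        seq = idx[(view, chamber)][0]
        if jitter_sd <= 0:
            return seq
        frames = [
            type(f)(f.frame_index, _smooth_perturbation(f.points, jitter_sd, rng))
            for f in seq.frames
        ]
        return dataclasses.replace(seq, frames=frames)

    lv_curve, la_curve = geometry.chamber_area_curves(
        jittered("2ch", "LV_endo"), jittered("2ch", "LA_endo"),
        jittered("4ch", "LV_endo"), jittered("4ch", "LA_endo"),
        mode="biplane_ellipse", station_step=config.station_step,
    )
    return hydraulic.hyf_analysis(
        lv_curve.areas, la_curve.areas, times=lv_curve.times, theta=config.diastasis_theta
    ).hyf


def run_reproducibility(
    subjects: list[SubjectDataset],
    jitter_sd: float = 0.5,
    n_subjects: int = 20,
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> dict:
    """Intra- and inter-operator ICC of HyF under contour perturbation.

    Re-measures HyF three times per subject with independent contour jitter
    (operator 1 twice, operator 2 once) and returns the two ICC(2,1) values
    with their agreement categories.
    """
    config = config or PipelineConfig()
    if len(subjects) < 5:
        raise ValueError("need at least 5 subjects for a meaningful ICC")
    rng = np.random.default_rng(seed)
    chosen = list(subjects)
    if len(chosen) > n_subjects:
        pick = rng.choice(len(chosen), size=n_subjects, replace=False)
        chosen = [chosen[int(i)] for i in pick]
    op1a, op1b, op2 = [], [], []
    for subj in chosen:
        op1a.append(_measure_hyf_with_jitter(subj, jitter_sd, rng, config))
        op1b.append(_measure_hyf_with_jitter(subj, jitter_sd, rng, config))
        op2.append(_measure_hyf_with_jitter(subj, jitter_sd, rng, config))
    intra: ICCResult = icc(np.column_stack([op1a, op1b]))
    inter: ICCResult = icc(np.column_stack([op1a, op2]))
    return {
        "icc_intra": intra.icc,
        "icc_intra_category": intra.category,
        "icc_inter": inter.icc,
        "icc_inter_category": inter.category,
        "n_subjects": len(chosen),
        "jitter_sd_mm": jitter_sd,
        "model": config.icc_model,
        "config": config.as_dict(),
    }
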