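# avcoupling

Left atrioventricular coupling analysis from cine-MRI feature-tracking
contours: hydraulic force, chamber strain, volumetry, and cohort
statistics.

## The problem

During diastole the atrioventricular plane behaves like a piston between
two blood columns of different cross-section. When the left ventricle's
cross-section exceeds the left atrium's, a net axial *hydraulic force*
pushes the plane toward the atrium and assists ventricular filling. With
aging the LV shrinks transversely while the LA dilates, eroding — and
eventually reversing — this force. Feature-tracking software already
produces time-resolved LV/LA endocardial contours for strain analysis;
this package reuses those contours to quantify the coupling:

* **HyF (cm²) = A_LV − A_LA**, the chamber cross-sectional area
  difference measured at the maximal transverse dimension perpendicular
  to the LV–LA long axis, averaged over the automatically detected
  diastasis plateau (where the transmitral pressure gradient is minimal);
* LV global strains (GLS, GCS, GRS) and the LA tri-phasic longitudinal
  strain S(t) decomposed into reservoir, conduit and booster components
  (SL_R = SL_C + SL_B + end-residual, exactly);
* Simpson short-axis LV volumes, biplane area-length LA volumes
  (V = 8/(3π)·A₂·A₄/L), ejection fractions, LV mass, BSA indexing;
* cohort statistics: Wilcoxon comparison of age groups (< 50 vs ≥ 50 y),
  univariate R² and age/sex/BMI-adjusted linear models, and ICC(2,1)
  operator reproducibility.

Because clinical contour data are not redistributable, the package ships
a synthetic cine-contour cohort generator (`avcoupling.synthetic`) whose
subjects carry exact analytic ground truth — every pipeline stage is
validated against closed-form oracles. See `docs/methods.md` for the full
model description and its limitations.

## Worked example

```python
from avcoupling.pipeline import run_subject
from avcoupling.synthetic import SubjectParams, generate_subject

subject = generate_subject(SubjectParams(
    subject_id="demo", age=35, sex="M", height=178, weight=75,
    hr=70, n_frames=40, seed=7,
))
rec = run_subject(subject)
print(f"HyF {rec['hyf']:.2f} cm2 over frames "
      f"{rec['diastasis_start']}-{rec['diastasis_end']}")
print(f"GLS {rec['lv_gls']:.1f}%  SL_R {rec['la_slr']:.1f}% "
      f"= SL_C {rec['la_slc']:.1f}% + SL_B {rec['la_slb']:.1f}%")
print(f"true HyF {subject.ground_truth.true_hyf:.2f} cm2")
```

prints

```
HyF 3.35 cm2 over frames 23-32
GLS -16.0%  SL_R 30.0% = SL_C 18.5% + SL_B 11.5%
true HyF 3.35 cm2
```

— the measured hydraulic force matches the generator's programmed value
(here a healthy 35-year-old: LV section exceeds LA section by ~3.4 cm²
throughout diastasis), and the LA strain decomposition is exact.

The cohort-scale analysis lives in numbered scripts:

```bash
python analysis/01_simulate_cohort.py     # 119 subjects -> scratch/, results/
python analysis/02_measure_subjects.py    # per-subject indices -> measurements.csv
python analysis/03_cohort_statistics.py   # report.md / report.json
python analysis/04_reproducibility.py     # intra-/inter-operator ICC
python analysis/05_export_curves.py       # example area-curve figures
```

On the default simulated cohort this prints a mean HyF of 4.9 ± 2.6 cm²
below age 50 versus 0.5 ± 2.9 cm² at 50+ (Wilcoxon p < 0.0001), an
HyF–age R² of 0.47, and excellent operator ICCs — the young hearts keep a
ventricular-dominant cross-section while the older ones approach or cross
zero. A command-line interface mirrors the scripts
(`avcoupling simulate|subject|cohort|repro --help`).

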