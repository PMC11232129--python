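# Methods

## The measurement model

The package analyzes left atrioventricular coupling from *tracked* cine-MRI
contours; everything upstream (image acquisition, feature tracking) is out
of scope and enters only as time-resolved point lists.

**Hydraulic force.** In a piston view of the left heart, the
atrioventricular plane separates two blood columns of different
cross-section; a net axial force proportional to the LV−LA cross-sectional
area difference acts on the plane and assists diastolic filling. We
estimate it geometrically as

    HyF (cm²) = A_LV − A_LA,

where each chamber's cross-sectional area is measured at its maximal
transverse dimension perpendicular to the long axis joining the LV and LA
centers of mass. The scalar HyF is the mean of the per-frame difference
over the diastasis window, when the transmitral pressure gradient is
minimal and the pressure contribution can be neglected. The sign is
preserved: a dilated atrium can drive HyF negative, the typical pattern
above 50 years.

**Cross-sectional areas.** Per frame and per view, the long axis is the
line through the two chamber centroids (area-weighted polygon centroids,
recomputed every frame because both centroids move through the cycle). The
maximal transverse dimension is the largest chord perpendicular to that
axis, found by scanning perpendicular section lines at 0.25 mm spacing
(configurable) — the numerical analog of a caliper on the image. The
default 2-D→area rule combines the 2- and 4-chamber diameters as an
ellipse, A = π·d₂·d₄/4 (`biplane_ellipse`); a single-view circular rule
(`single_plane`, A = π·d²/4) is available when only one view exists. The
choice is echoed in every output record.

**Diastasis detection.** On the LV area curve: diastole runs from the area
minimum to the cycle end; dA/dt is computed by central differences with
periodic wrap (retrospective gating closes the cycle). The early (E) and
atrial (A) filling waves are the two dA/dt maxima in the first and second
halves of diastole; the diastasis window is the longest contiguous run
between them with |dA/dt| below θ times the E-peak rate (θ = 0.2,
configurable). Numerical choices made for robustness to contour
measurement noise, verified not to move the detected window by more than
one frame on noise-free inputs:

* the area curve is low-pass filtered with a periodic 5-point binomial
  kernel before differentiation (tracked area curves are temporally
  smooth; the raw station-scan maximum is not);
* the θ threshold is taken against the *unfiltered* E-peak rate, because
  the low-pass attenuates the narrow E peak more than the plateau;
* gaps of ≤ 2 frames inside an otherwise quiet run are closed;
* a late wave below 5 % of the E peak counts as "no atrial kick".

Degenerate curves (monotone, missing waves, empty window) receive QC flags
— `short_diastasis`, `no_atrial_kick`, `no_filling_wave` — with a
single-frame fallback window rather than hard failure, so cohort runs
complete with an exclusion report.

**Strain.** All strains are Lagrangian, referenced to frame 0
(end-diastole), the feature-tracking convention consistent with typical
printed magnitudes. LV GLS uses the open endocardial contour length
(mitral chord excluded), per-view minimum, averaged over the two long-axis
views. GCS is the perimeter strain of mid-ventricular short-axis slices
(middle third of the stack); GRS is the peak relative wall thickening,
thickness measured as the mean endo→epi distance along 64 rays from the
endocardial centroid. LA longitudinal strain is the closed endocardial
perimeter strain averaged over the two views; since the stored LA contour
is a single closed polygon, no mitral segment is identified or excluded.
The tri-phasic decomposition uses the frame of maximal LA strain (t_max)
and the end of the detected diastasis window as the pre-atrial-contraction
frame (t_preA) — no ECG P-wave is available, and tying t_preA to the
area-rate event keeps the strain and HyF analyses consistent:

    SL_R = S(t_max), SL_C = S(t_max) − S(t_preA), SL_B = S(t_preA) − S(end),

so SL_C + SL_B + S(end) = SL_R exactly; the end-of-cycle residual S(end)
is reported.

**Volumetry.** LV volumes by Simpson summation of short-axis slice areas
times slice spacing; slices with zero endocardial area at a frame
(through-plane motion of the base) contribute nothing and no partial-slice
correction is applied. LV mass is the epi−endo volume shell at the LV
end-diastolic frame times 1.05 g/ml. LA volumes use the biplane
area-length rule V = (8/3π)·A₂·A₄/L_min, exact on ellipsoids. EDV/ESV are
volume-curve extrema, not fixed frames. BSA defaults to Du Bois
(0.007184·W^0.425·H^0.725; Mosteller optional), the usual choice in
cardiac MRI normative work.

**Statistics.** Age groups split at 50 years (exactly 50 → older group).
Group differences use the unpaired Wilcoxon rank-sum test: exact p by
enumeration for ≤ 12 observations without ties, otherwise the normal
approximation with tie and continuity corrections. Associations are
ordinary least squares; univariate R² equals the squared Pearson
correlation, and adjusted models add age, sex (F=0, M=1) and BMI, with
complete-case deletion per analysis and an explicit rank-deficiency error
naming the collinear column. Because the convention for a multivariate R²
is ambiguous, the report emits both the full-model R² and the predictor's
partial R². No multiple-testing correction is applied, matching common
clinical reporting; Holm correction can be bolted on by the user.
Reproducibility uses ICC(2,1) — two-way random effects, absolute
agreement, single measure — computed directly from the ANOVA mean squares,
with categories excellent (> 0.74), good (0.60–0.74), moderate
(0.40–0.60), poor (< 0.40); the printed bands leave 0.74 and (0.59, 0.60)
ambiguous, resolved as good at 0.74 and moderate on [0.40, 0.60).

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
images: the LV endocardium is a half-ellipsoid truncated at the mitral
plane, the epicardium a concentric shell, the LA an ellipsoid above the
plane. Chamber motion is a uniform per-frame scale factor following a
piecewise-cosine waveform — systole (35 % of the cycle), early filling,
an *exactly flat* diastasis plateau (a configurable fraction of diastole),
and an atrial kick returning to the end-diastolic value, with the
early-to-late rise amplitude ratio equal to the subject's E/A analog. The
apex is held fixed, so the base descends during systole and basal
short-axis slices empty — the clinical basal slice problem, which is why
sax frames may legitimately hold zero points. The short-axis stack uses 12
slices of 8 mm (within the usual 10–14-slice clinical range) so the
epicardial apex stays covered and mass recovery is limited by the midpoint
rule, not coverage.

Default amplitudes (reservoir strain 30 %, conduit 18.5 %, LV shortening
16 %, wall thickening 57 %, LV/LA transverse semiaxes 21/15 mm at age 50,
LV−LA age effects −0.6/+0.4 mm per decade, E/A analog falling 0.18 per
decade) were set once to the magnitudes typical of healthy adult cohorts
and produce diastasis areas near 12–13 (young) and 10–11 cm² (old) with
group HyF SDs of 2–3 cm². A per-subject latent diastolic-function score
couples atrial dilation, filling ratio and conduit strain independently of
age, so echo indices remain associated with HyF after age adjustment; its
within-cohort LV–LA area correlation is an explicit free parameter of the
generator, not an asserted fact. Female subjects carry a 0.92
multiplicative size factor on all semiaxes, providing a real covariate for
the adjusted models. Contour noise is Gaussian jitter along the local
outward normal; per-subject seeds derive deterministically from the master
seed and are recorded in the cohort CSV.

Every subject carries ground truth: analytic area curves
(A = π·b²·w(t)² for transverse semiaxis b and scale w), the programmed
plateau window, HyF, the six strain scalars, and closed-form
half-ellipsoid/ellipsoid volumes — the oracles for all recovery tests.

**What the generator does not emulate.** Uniform scaling ties all strain
components together, so the LV ejection fraction implied by a 16 %
shortening is ~40 %, below the clinical ~60 % produced by radial-dominant
real kinematics; volumes and EF are internally consistent but not
clinically distributed. Chamber cross-sections are exactly elliptical, so
the biplane rules are exact up to polygon discretization; real shape
irregularity would add method error that passing tests cannot speak to.
Operator variability in the reproducibility module is a smooth low-order
(Fourier k ≤ 2) radial field — pointwise-independent jitter would produce
self-intersecting "hand-drawn" contours — and at 0.5 mm it yields ICCs
near 0.99, higher than real inter-operator agreement; only the
variance-ratio mechanics (jitter vs between-subject spread) are
meaningful, not the absolute ICC level. No arrhythmia, variable RR,
pericardial constraint or regional wall-motion abnormality is modeled.

## Numerical tolerances and degenerate inputs

* Station scan 0.25 mm, stations offset half a step from the polygon's
  axial extremes to avoid vertex-grazing degeneracies; chord accuracy on
  smooth convex shapes ≈ 10⁻⁶ relative.
* Polygon validity via shapely (`is_valid`/`is_simple`); orientation
  normalized counter-clockwise at load so signed areas are positive in
  the y-down image frame.
* Contour files round floats to 4 decimals (0.1 µm), making writes
  canonical and byte-reproducible.
* LV–LA centroids closer than 1 mm abort the long-axis construction
  (corrupt contours).
* Zero-noise recovery on synthetic subjects: HyF and strains within 1 %,
  LV EDV/mass and LA volumes within 2 %. LV ESV is biased low by the
  uncorrected basal partial slice at end-systole (≈ 5–7 % with the default
  geometry); tests assert 10 % there, and the bias is inherent to the
  stated no-partial-slice rule, not a defect of the generator.
* Near-vanishing apical short-axis sections (radius below max(0.8 mm,
  5× the jitter SD)) are treated as out-of-slice rather than contoured.

## Problem sizes

The analysis scripts and the acceptance run use 119 subjects aged 20–81
with 30–60 frames per cycle, 0.5 mm contour noise, and 20 subjects for
the reproducibility ICC — a full cohort pass takes on the order of a
minute. Property tests use 50-polygon oracle batches, 100-seed window
stability, 100-replicate CI coverage and 200-replicate null calibrations.
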