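#!/usr/bin/env python
"""Export example area-curve figures.

Plots the LV/LA cross-sectional area curves and the LV−LA difference with
the detected diastasis window shaded, for one young and one old subject.
"""

from pathlib import Path

from avcoupling.geometry import chamber_area_curves
from avcoupling.hydraulic import hyf_analysis
from avcoupling.io import read_cohort_csv, read_contour_file, sequences_by_key
from avcoupling.plotting import plot_subject_curves

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cohort_dir = ROOT / "scratch" / "cohort"
    if not (cohort_dir / "cohort.csv").exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    out = ROOT / "results" / "figures"
    out.mkdir(parents=True, exist_ok=True)

    table = read_cohort_csv(cohort_dir / "cohort.csv").sort_values("age")
    for row in (table.iloc[0], table.iloc[-1]):
        sid = row["subject_id"]
        idx = sequences_by_key(read_contour_file(cohort_dir / f"{sid}.json"))
        lv, la = chamber_area_curves(
            idx[("2ch", "LV_endo")][0],
            idx[("2ch", "LA_endo")][0],
            idx[("4ch", "LV_endo")][0],
            idx[("4ch", "LA_endo")][0],
        )
        res = hyf_analysis(lv.areas, la.areas, times=lv.times)
        path = out / f"{sid}_age{row['age']:.0f}_curves.png"
        plot_subject_curves(lv, la, res, path, title=f"{sid} (age {row['age']:.0f} y)")
        print(f"{sid}: age {row['age']:.0f}, HyF {res.hyf:.2f} cm² -> {path.name}")


if __name__ == "__main__":
    main()
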