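#!/usr/bin/env python
"""Cohort statistics.

Splits the measured cohort at 50 years, compares every derived index
between age groups (Wilcoxon rank-sum), regresses HyF on age and on the
diastolic-function indices (univariate and adjusted for age/sex/BMI), and
writes the report as markdown + JSON.
"""

from pathlib import Path

import pandas as pd

from avcoupling.stats import build_report, split_age_groups

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    out = ROOT / "results"
    path = out / "measurements.csv"
    if not path.exists():
        raise SystemExit("run analysis/02_measure_subjects.py first")
    df = pd.read_csv(path)

    report = build_report(df)
    (out / "report.json").write_text(report.to_json())
    (out / "report.md").write_text(report.to_markdown())

    g1, g2 = split_age_groups(df)
    print(f"G1 (<50 y): n={len(g1)}, HyF {g1['hyf'].mean():.2f} ± {g1['hyf'].std():.2f} cm²")
    print(f"G2 (>=50 y): n={len(g2)}, HyF {g2['hyf'].mean():.2f} ± {g2['hyf'].std():.2f} cm²")
    for pred, r in report.univariate.items():
        print(f"  HyF ~ {pred}: R² = {r['r_squared']:.2f}, p = {r['p_value']:.2g}")
    for pred, r in report.adjusted.items():
        print(
            f"  adjusted {pred}: full R² = {r['full_r_squared']:.2f}, "
            f"predictor p = {r['p_value']:.2g}"
        )
    print(f"-> {out / 'report.md'}")


if __name__ == "__main__":
    main()
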