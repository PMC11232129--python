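#!/usr/bin/env python
"""Per-subject measurement pass.

Reads the simulated contour files, measures chamber cross-sectional area
curves (biplane ellipse at the maximal transverse dimension perpendicular
to the per-frame LV–LA long axis), detects diastasis, and derives HyF,
strains and volumes for every subject.  Writes results/measurements.csv
and an exclusion list for subjects failing QC.
"""

import json
from pathlib import Path

from avcoupling.pipeline import PipelineConfig, run_cohort

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cohort_dir = ROOT / "scratch" / "cohort"
    if not (cohort_dir / "cohort.csv").exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    out = ROOT / "results"
    out.mkdir(exist_ok=True)

    res = run_cohort(cohort_dir, PipelineConfig())
    res.results.to_csv(out / "measurements.csv", index=False)
    (out / "exclusions.json").write_text(json.dumps(res.exclusions, indent=2))

    df = res.results
    print(f"analyzed {len(df)} subjects, excluded {len(res.exclusions)}")
    print(f"  HyF: {df['hyf'].mean():.2f} ± {df['hyf'].std():.2f} cm²")
    print(f"  LV GLS {df['lv_gls'].mean():.1f}%, LA SL_R {df['la_slr'].mean():.1f}%")
    print(f"  -> {out / 'measurements.csv'}")


if __name__ == "__main__":
    main()
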