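"""Basic curve export: chamber area curves with the diastasis window shaded."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .geometry import AreaCurve
from .hydraulic import HyFResult


def plot_subject_curves(
    lv_curve: AreaCurve,
    la_curve: AreaCurve,
    hyf: HyFResult,
    path: str | Path,
    title: str = "",
) -> None:
    """Area-vs-time curves for both chambers plus the LV−LA difference."""
    t = lv_curve.times / 1000.0
    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(6, 6))
    ax1.plot(t, lv_curve.areas, color="tab:orange", label="LV")
    ax1.plot(t, la_curve.areas, color="tab:blue", label="LA")
    ax2.plot(t, hyf.diff_curve, color="tab:green", label="LV − LA")
    ax2.axhline(0.0, color="0.7", lw=0.8)
    t0, t1 = hyf.diastasis_window
    for ax in (ax1, ax2):
        ax.axvspan(t[t0], t[t1], alpha=0.2, color="tab:blue", label="diastasis")
        ax.legend(loc="best", fontsize=8)
    ax1.set_ylabel("cross-sectional area (cm²)")
    ax2.set_ylabel("area difference (cm²)")
    ax2.set_xlabel("time (s)")
    if title:
        ax1.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
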