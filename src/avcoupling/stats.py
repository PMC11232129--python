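"""Cohort statistics: age-group comparison, regressions, ICC reproducibility.

The analysis splits the cohort at 50 years (G1 < 50, G2 ≥ 50), compares
derived indices between groups with the unpaired Wilcoxon rank-sum test,
quantifies associations by univariate ordinary least squares (R² = squared
Pearson correlation) and by multivariate models adjusted for age, sex and
BMI, and assesses measurement reproducibility with the two-way random
effects, absolute-agreement, single-measure intraclass correlation
ICC(2,1), categorized as excellent (> 0.74), good (0.60–0.74), moderate
(0.40–0.59) or poor (< 0.40).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

AGE_SPLIT = 50.0
EXACT_MAX_N = 12  # exact rank-sum p by enumeration up to this total n, no ties


class StatsError(ValueError):
    pass


def split_age_groups(cohort: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """G1 (< 50 years) and G2 (≥ 50 years); missing ages are an error."""
    if "age" not in cohort.columns:
        raise StatsError("cohort table has no 'age' column")
    age = pd.to_numeric(cohort["age"])
    if age.isna().any():
        bad = cohort.loc[age.isna(), "subject_id"].tolist()
        raise StatsError(f"missing age for subjects: {bad}")
    return cohort[age < AGE_SPLIT], cohort[age >= AGE_SPLIT]


def wilcoxon_ranksum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Unpaired two-sided Wilcoxon rank-sum test.

    Returns (W, p) where W is the rank-sum of the first sample (midranks
    for ties).  The p-value is exact by enumeration over rank assignments
    when n_x + n_y ≤ 12 with no ties, otherwise the normal approximation
    with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        raise StatsError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w = float(ranks[: len(x)].sum())
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= EXACT_MAX_N and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return w, float(res.pvalue)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    covariate_pvalues: dict | None = None
    full_r_squared: float | None = None
    partial_r_squared: float | None = None


def linreg_univariate(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """OLS of y on x with pairwise deletion of missing values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise StatsError(f"need >= 3 complete pairs, got {len(x)}")
    if np.ptp(x) == 0:
        raise StatsError("predictor has zero variance")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        p_value=float(model.pvalues[1]),
        n=len(x),
    )


def linreg_adjusted(
    data: pd.DataFrame,
    y: str,
    predictor: str,
    adjusters: tuple[str, ...] = ("age", "sex_code", "bmi"),
) -> RegressionResult:
    """OLS of *y* on [predictor, adjusters] with complete-case deletion.

    Reports the predictor's partial p-value, the full-model R², and the
    predictor's partial R² (variance explained beyond the adjusters alone).
    Sex must arrive as a binary indicator column (F=0, M=1).
    """
    cols = [y, predictor, *adjusters]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise StatsError(f"columns missing from table: {missing}")
    if predictor in adjusters:
        raise StatsError(f"predictor {predictor!r} duplicated among adjusters")
    sub = data[cols].apply(pd.to_numeric).dropna()
    k = 1 + len(adjusters)
    if len(sub) < k + 2:
        raise StatsError(f"need >= {k + 2} complete cases, got {len(sub)}")
    design = sub[[predictor, *adjusters]].to_numpy(dtype=float)
    names = [predictor, *adjusters]
    xmat = sm.add_constant(design, has_constant="add")
    rank = np.linalg.matrix_rank(xmat)
    if rank < xmat.shape[1]:
        # find the first column that adds no rank
        culprit = "const"
        for j in range(1, xmat.shape[1]):
            if np.linalg.matrix_rank(xmat[:, : j + 1]) == np.linalg.matrix_rank(xmat[:, :j]):
                culprit = names[j - 1]
                break
        raise StatsError(f"rank-deficient design: column {culprit!r} is collinear")
    yvec = sub[y].to_numpy(dtype=float)
    full = sm.OLS(yvec, xmat).fit()
    reduced = sm.OLS(
        yvec, sm.add_constant(sub[list(adjusters)].to_numpy(dtype=float), has_constant="add")
    ).fit()
    sse_f, sse_r = float(full.ssr), float(reduced.ssr)
    partial_r2 = (sse_r - sse_f) / sse_r if sse_r > 0 else 0.0
    return RegressionResult(
        slope=float(full.params[1]),
        intercept=float(full.params[0]),
        r_squared=float(full.rsquared),
        p_value=float(full.pvalues[1]),
        n=len(sub),
        covariate_pvalues={nm: float(p) for nm, p in zip(names, full.pvalues[1:])},
        full_r_squared=float(full.rsquared),
        partial_r_squared=float(partial_r2),
    )


# ---------------------------------------------------------------------------
# intraclass correlation


ICC_MODEL_LABEL = "two-way random, absolute agreement, single measure (ICC(2,1))"


@dataclass
class ICCResult:
    icc: float
    model: str
    category: str
    n_subjects: int
    n_raters: int


def icc(ratings: np.ndarray) -> ICCResult:
    """ICC(2,1) from the two-way ANOVA mean squares.

    *ratings* is (n_subjects, n_raters), complete.  ICC =
    (MS_R − MS_E) / (MS_R + (k−1)·MS_E + (k/n)·(MS_C − MS_E)).
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise StatsError("ratings must be (n_subjects, n_raters) with >= 2 raters")
    if np.isnan(x).any():
        raise StatsError("ratings matrix has missing cells")
    n, k = x.shape
    if n < 5:
        warnings.warn(f"only {n} subjects; ICC estimate will be unstable", stacklevel=2)
    grand = x.mean()
    ss_r = k * float(((x.mean(axis=1) - grand) ** 2).sum())
    ss_c = n * float(((x.mean(axis=0) - grand) ** 2).sum())
    ss_t = float(((x - grand) ** 2).sum())
    ss_e = ss_t - ss_r - ss_c
    ms_r = ss_r / (n - 1)
    ms_c = ss_c / (k - 1)
    ms_e = ss_e / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    value = 1.0 if abs(denom) < 1e-300 else (ms_r - ms_e) / denom
    return ICCResult(
        icc=float(value),
        model=ICC_MODEL_LABEL,
        category=icc_classify(float(value)),
        n_subjects=n,
        n_raters=k,
    )


def icc_classify(icc_value: float) -> str:
    """Agreement category: > 0.74 excellent, [0.60, 0.74] good,
    [0.40, 0.60) moderate, < 0.40 poor."""
    if not np.isfinite(icc_value):
        raise StatsError("ICC value must be finite")
    if icc_value > 0.74:
        return "excellent"
    if icc_value >= 0.60:
        return "good"
    if icc_value >= 0.40:
        return "moderate"
    return "poor"


# ---------------------------------------------------------------------------
# report assembly


P_FLOOR = 1e-4  # printed as "<0.0001", matching clinical-table convention

#: variables summarized per age group, with display names
GROUP_VARIABLES = [
    ("age", "Age (years)"),
    ("bmi", "BMI (kg/m²)"),
    ("bsa", "BSA (m²)"),
    ("hr", "HR (bpm)"),
    ("sbp", "Brachial SBP (mmHg)"),
    ("dbp", "Brachial DBP (mmHg)"),
    ("E", "E (cm/s)"),
    ("A", "A (cm/s)"),
    ("E_over_A", "E/A"),
    ("Eprime", "E' (cm/s)"),
    ("E_over_Eprime", "E/E'"),
    ("lv_massi", "LV mass_i (g/m²)"),
    ("lv_edvi", "LV EDVi (ml/m²)"),
    ("lv_esvi", "LV ESVi (ml/m²)"),
    ("lv_ef", "LV EF (%)"),
    ("la_edvi", "LA EDVi (ml/m²)"),
    ("la_esvi", "LA ESVi (ml/m²)"),
    ("la_ef", "LA EF (%)"),
    ("lv_gls", "LV GLS (%)"),
    ("lv_gcs", "LV GCS (%)"),
    ("lv_grs", "LV GRS (%)"),
    ("la_slr", "LA SL_R (%)"),
    ("la_slc", "LA SL_C (%)"),
    ("la_slb", "LA SL_B (%)"),
    ("lv_area_diastasis", "LV cross-sectional area (cm²)"),
    ("la_area_diastasis", "LA cross-sectional area (cm²)"),
    ("hyf", "HyF (cm²)"),
]

#: univariate associations of HyF
UNIVARIATE_PREDICTORS = ["age", "Eprime", "E_over_A", "E_over_Eprime", "la_slc"]
#: predictors retested with adjustment for age, sex and BMI
ADJUSTED_PREDICTORS = ["E_over_A", "la_slc"]


def format_p(p: float) -> str:
    return "<0.0001" if p < P_FLOOR else f"{p:.4g}"


@dataclass
class StatsReport:
    group_comparison: dict = field(default_factory=dict)
    univariate: dict = field(default_factory=dict)
    adjusted: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "meta": self.meta,
                "group_comparison": self.group_comparison,
                "univariate": self.univariate,
                "adjusted": self.adjusted,
            },
            indent=2,
            sort_keys=True,
            default=float,
        )

    def to_markdown(self) -> str:
        lines = ["# Cohort statistics report", ""]
        gc = self.group_comparison
        lines.append("## Age-group comparison (G1 < 50 y vs G2 ≥ 50 y)")
        lines.append("")
        if not gc.get("applicable", False):
            lines.append("Not applicable: only one age group present.")
        else:
            lines.append(f"n: G1 = {gc['n_g1']}, G2 = {gc['n_g2']}")
            lines.append("")
            lines.append("| Variable | G1 mean ± SD | G2 mean ± SD | Wilcoxon p |")
            lines.append("|---|---|---|---|")
            for row in gc["variables"]:
                lines.append(
                    f"| {row['label']} | {row['g1_mean']:.2f} ± {row['g1_sd']:.2f} "
                    f"| {row['g2_mean']:.2f} ± {row['g2_sd']:.2f} | {format_p(row['p'])} |"
                )
        lines += ["", "## Univariate associations of HyF", ""]
        lines.append("| Predictor | slope | R² | p | n |")
        lines.append("|---|---|---|---|---|")
        for name, r in self.univariate.items():
            lines.append(
                f"| {name} | {r['slope']:.4g} | {r['r_squared']:.2f} "
                f"| {format_p(r['p_value'])} | {r['n']} |"
            )
        lines += ["", "## Adjusted models (HyF ~ predictor + age + sex + BMI)", ""]
        lines.append("| Predictor | full R² | partial R² | predictor p | n |")
        lines.append("|---|---|---|---|---|")
        for name, r in self.adjusted.items():
            lines.append(
                f"| {name} | {r['full_r_squared']:.2f} | {r['partial_r_squared']:.2f} "
                f"| {format_p(r['p_value'])} | {r['n']} |"
            )
        lines.append("")
        return "\n".join(lines)


def _sex_code(series: pd.Series) -> pd.Series:
    return series.map({"F": 0, "M": 1, 0: 0, 1: 1}).astype(float)


def build_report(cohort_results: pd.DataFrame, outcome: str = "hyf") -> StatsReport:
    """Assemble the full statistics report from an analyzed cohort table."""
    df = cohort_results.copy()
    if outcome not in df.columns:
        raise StatsError(f"results table is missing the outcome column {outcome!r}")
    if "sex" in df.columns and "sex_code" not in df.columns:
        df["sex_code"] = _sex_code(df["sex"])

    report = StatsReport(meta={"outcome": outcome, "n_total": int(len(df))})

    g1, g2 = split_age_groups(df)
    gc: dict = {"applicable": bool(len(g1) and len(g2))}
    if gc["applicable"]:
        gc["n_g1"], gc["n_g2"] = int(len(g1)), int(len(g2))
        rows = []
        for col, label in GROUP_VARIABLES:
            if col not in df.columns:
                continue
            a = pd.to_numeric(g1[col]).dropna()
            b = pd.to_numeric(g2[col]).dropna()
            if len(a) == 0 or len(b) == 0:
                continue
            _, p = wilcoxon_ranksum(a.to_numpy(), b.to_numpy())
            rows.append(
                {
                    "variable": col,
                    "label": label,
                    "g1_mean": float(a.mean()),
                    "g1_sd": float(a.std(ddof=1)) if len(a) > 1 else 0.0,
                    "g2_mean": float(b.mean()),
                    "g2_sd": float(b.std(ddof=1)) if len(b) > 1 else 0.0,
                    "p": float(p),
                }
            )
        gc["variables"] = rows
    report.group_comparison = gc

    for pred in UNIVARIATE_PREDICTORS:
        if pred not in df.columns:
            continue
        try:
            r = linreg_univariate(
                pd.to_numeric(df[pred]).to_numpy(), pd.to_numeric(df[outcome]).to_numpy()
            )
        except StatsError:
            continue
        report.univariate[pred] = {
            "slope": r.slope,
            "intercept": r.intercept,
            "r_squared": r.r_squared,
            "p_value": r.p_value,
            "n": r.n,
        }

    for pred in ADJUSTED_PREDICTORS:
        if pred not in df.columns:
            continue
        try:
            r = linreg_adjusted(df, outcome, pred)
        except StatsError:
            continue
        report.adjusted[pred] = {
            "full_r_squared": r.full_r_squared,
            "partial_r_squared": r.partial_r_squared,
            "p_value": r.p_value,
            "covariate_pvalues": r.covariate_pvalues,
            "n": r.n,
        }
    return report
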