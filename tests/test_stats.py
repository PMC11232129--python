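"""Statistics layer: group split, rank-sum test, regressions, ICC, report."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from avcoupling.stats import (
    StatsError,
    build_report,
    icc,
    icc_classify,
    linreg_adjusted,
    linreg_univariate,
    split_age_groups,
    wilcoxon_ranksum,
)


def cohort_frame(ages, **cols):
    n = len(ages)
    base = {"subject_id": [f"S{i}" for i in range(n)], "age": ages}
    base.update(cols)
    return pd.DataFrame(base)


class TestAgeSplit:
    def test_group_assignment(self):
        df = cohort_frame([32.5, 61.3, 50.0, 49.99])
        g1, g2 = split_age_groups(df)
        assert list(g1["age"]) == [32.5, 49.99]
        assert list(g2["age"]) == [61.3, 50.0]  # exactly 50 -> G2

    def test_missing_age_rejected(self):
        with pytest.raises(StatsError, match="S1"):
            split_age_groups(cohort_frame([40.0, np.nan]))


def enumeration_oracle(x, y):
    """Exact two-sided rank-sum p by full enumeration of rank assignments."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w_obs = ranks[: len(x)].sum()
    ws = np.array([sum(c) for c in itertools.combinations(ranks, len(x))])
    return min(1.0, 2.0 * min((ws <= w_obs).mean(), (ws >= w_obs).mean()))


class TestWilcoxon:
    def test_two_vs_two_exact(self):
        w, p = wilcoxon_ranksum([1.0, 2.0], [3.0, 4.0])
        assert w == 3.0
        assert p == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_identical_samples(self):
        _, p = wilcoxon_ranksum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_matches_enumeration_for_all_small_sizes(self):
        rng = np.random.default_rng(8)
        for nx in range(1, 10):
            for ny in range(1, 10):
                if nx + ny > 10:
                    continue
                x, y = rng.normal(size=nx), rng.normal(size=ny)
                _, p = wilcoxon_ranksum(x, y)
                assert p == pytest.approx(enumeration_oracle(x, y), abs=1e-12)

    def test_power_under_large_shift(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.0, 1.0, 60)
        y = rng.normal(2.0, 1.0, 60)
        _, p = wilcoxon_ranksum(x, y)
        assert p < 1e-3

    def test_empty_group_rejected(self):
        with pytest.raises(StatsError):
            wilcoxon_ranksum([], [1.0])


class TestUnivariate:
    def test_collinear(self):
        r = linreg_univariate(np.array([1.0, 2.0, 3.0]), np.array([2.0, 4.0, 6.0]))
        assert r.slope == pytest.approx(2.0, abs=1e-12)
        assert r.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_r2_equals_squared_pearson(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=200)
        y = 0.5 * x + rng.normal(size=200)
        r = linreg_univariate(x, y)
        assert r.r_squared == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2, abs=1e-12)

    def test_pairwise_deletion(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        y = np.array([1.1, np.nan, 3.0, 4.2, 5.1])
        assert linreg_univariate(x, y).n == 3

    def test_null_p_uniform(self):
        """Under the null the slope p-value is U(0,1) (K-S check)."""
        rng = np.random.default_rng(12)
        ps = []
        for _ in range(200):
            x = rng.normal(size=1000)
            y = rng.normal(size=1000)
            ps.append(linreg_univariate(x, y).p_value)
        _, ks_p = sps.kstest(ps, "uniform")
        assert ks_p > 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(StatsError):
            linreg_univariate(np.ones(10), np.arange(10.0))


class TestAdjusted:
    @staticmethod
    def frame(rng, n=150, beta=2.0, gamma=0.5):
        age = rng.uniform(20, 80, n)
        sex = rng.integers(0, 2, n).astype(float)
        bmi = rng.normal(24, 3, n)
        pred = rng.normal(size=n)
        y = beta * pred + gamma * age + rng.normal(size=n)
        return pd.DataFrame(
            {"y": y, "pred": pred, "age": age, "sex_code": sex, "bmi": bmi}
        )

    def test_independent_adjusters_leave_p_close_to_univariate(self):
        # modest effect keeps p in a range where log-ratios are meaningful
        rng = np.random.default_rng(5)
        ratios = []
        for _ in range(50):
            df = self.frame(rng, beta=0.15, gamma=0.0)
            adj = linreg_adjusted(df, "y", "pred")
            uni = linreg_univariate(df["pred"].to_numpy(), df["y"].to_numpy())
            ratios.append(np.log(adj.p_value / uni.p_value))
        assert np.median(np.abs(ratios)) < 0.7

    def test_slope_recovery_coverage(self):
        rng = np.random.default_rng(6)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            df = self.frame(rng)
            import statsmodels.api as sm

            model = sm.OLS(
                df["y"], sm.add_constant(df[["pred", "age", "sex_code", "bmi"]])
            ).fit()
            lo, hi = model.conf_int().loc["pred"]
            hits += lo <= 2.0 <= hi
        assert hits >= 0.9 * n_rep

    def test_recovers_programmed_slope(self):
        rng = np.random.default_rng(7)
        df = self.frame(rng, n=4000)
        r = linreg_adjusted(df, "y", "pred")
        assert r.slope == pytest.approx(2.0, abs=0.1)
        assert r.p_value < 1e-10

    def test_duplicated_predictor_rank_deficiency(self):
        rng = np.random.default_rng(8)
        df = self.frame(rng)
        df["dup"] = df["pred"]
        with pytest.raises(StatsError, match="dup"):
            linreg_adjusted(df, "y", "pred", adjusters=("dup", "age"))

    def test_single_sex_cohort_collinear(self):
        rng = np.random.default_rng(9)
        df = self.frame(rng)
        df["sex_code"] = 1.0
        with pytest.raises(StatsError, match="sex_code"):
            linreg_adjusted(df, "y", "pred")


def icc_bruteforce(x):
    """ICC(2,1) via explicit double-loop ANOVA sums of squares."""
    n, k = x.shape
    grand = x.mean()
    row_means = [np.mean([x[i, j] for j in range(k)]) for i in range(n)]
    col_means = [np.mean([x[i, j] for i in range(n)]) for j in range(k)]
    ss_r = sum(k * (rm - grand) ** 2 for rm in row_means)
    ss_c = sum(n * (cm - grand) ** 2 for cm in col_means)
    ss_t = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ms_r = ss_r / (n - 1)
    ms_c = ss_c / (k - 1)
    ms_e = (ss_t - ss_r - ss_c) / ((n - 1) * (k - 1))
    return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + k / n * (ms_c - ms_e))


class TestICC:
    def test_identical_columns(self):
        x = np.tile(np.arange(8.0)[:, None], (1, 2))
        res = icc(x)
        assert res.icc == pytest.approx(1.0, abs=1e-12)
        assert res.category == "excellent"

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(10)
        x = rng.integers(0, 20, size=(6, 2)).astype(float)
        assert icc(x).icc == pytest.approx(icc_bruteforce(x), abs=1e-10)
        x = rng.normal(size=(12, 3))
        assert icc(x).icc == pytest.approx(icc_bruteforce(x), abs=1e-10)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(11)
        x = rng.normal(10, 3, size=(10, 3)) + rng.normal(0, 1, size=(10, 1))
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(10), 3),
                "rater": np.tile(np.arange(3), 10),
                "score": x.ravel(),
            }
        )
        ref = pg.intraclass_corr(long, "subject", "rater", "score")
        # two-way random, absolute agreement, single measure
        mask = ref["Type"].isin(["ICC2", "ICC(A,1)"])
        ref_icc2 = float(ref.loc[mask, "ICC"].iloc[0])
        assert icc(x).icc == pytest.approx(ref_icc2, abs=1e-9)

    def test_rater_offset_penalized(self):
        rng = np.random.default_rng(12)
        base = rng.normal(size=(15, 1))
        x = np.hstack([base, base])
        shifted = np.hstack([base, base + 1.5])
        assert icc(shifted).icc < icc(x).icc

    def test_few_subjects_warn_but_compute(self):
        x = np.array([[1.0, 1.1], [2.0, 2.1], [3.0, 3.2], [4.0, 3.9]])
        with pytest.warns(UserWarning, match="unstable"):
            res = icc(x)
        assert 0.9 < res.icc <= 1.0

    def test_missing_cells_rejected(self):
        x = np.array([[1.0, np.nan]] * 6)
        with pytest.raises(StatsError):
            icc(x)

    @pytest.mark.parametrize(
        "value,category",
        [
            (0.82, "excellent"),
            (0.80, "excellent"),
            (0.75, "excellent"),
            (0.74, "good"),
            (0.60, "good"),
            (0.59, "moderate"),
            (0.40, "moderate"),
            (0.39, "poor"),
            (-0.2, "poor"),
        ],
    )
    def test_classification_bands(self, value, category):
        assert icc_classify(value) == category


class TestReport:
    @staticmethod
    def results_frame(rng, n=60, with_g2=True):
        ages = rng.uniform(20, 49, n) if not with_g2 else rng.uniform(20, 80, n)
        df = cohort_frame(
            ages,
            sex=rng.choice(["M", "F"], n),
            bmi=rng.normal(24, 3, n),
            hyf=rng.normal(3, 2, n),
            E_over_A=rng.normal(1.2, 0.3, n),
            Eprime=rng.normal(13, 4, n),
            E_over_Eprime=rng.normal(6, 1.5, n),
            la_slc=rng.normal(15, 4, n),
        )
        return df

    def test_full_report_sections(self):
        rng = np.random.default_rng(13)
        rep = build_report(self.results_frame(rng))
        assert rep.group_comparison["applicable"]
        assert set(rep.univariate) == {"age", "Eprime", "E_over_A", "E_over_Eprime", "la_slc"}
        assert set(rep.adjusted) == {"E_over_A", "la_slc"}
        md = rep.to_markdown()
        assert "Age-group comparison" in md and "Adjusted models" in md

    def test_single_group_cohort(self):
        rng = np.random.default_rng(14)
        rep = build_report(self.results_frame(rng, with_g2=False))
        assert not rep.group_comparison["applicable"]
        assert "Not applicable" in rep.to_markdown()
        assert rep.univariate  # regressions still run

    def test_deterministic_markdown(self):
        rng = np.random.default_rng(15)
        df = self.results_frame(rng)
        assert build_report(df).to_markdown() == build_report(df.copy()).to_markdown()

    def test_p_floor_formatting(self):
        from avcoupling.stats import format_p

        assert format_p(2e-6) == "<0.0001"
        assert format_p(0.0234).startswith("0.023")

    def test_null_effects_false_positive_rate(self):
        """With no real associations, flags appear at the nominal alpha."""
        rng = np.random.default_rng(16)
        n_sig, n_tests = 0, 0
        for _ in range(30):
            rep = build_report(self.results_frame(rng, n=80))
            for r in rep.univariate.values():
                n_tests += 1
                n_sig += r["p_value"] < 0.05
        bound = sps.binom.ppf(0.999, n_tests, 0.05)
        assert n_sig <= bound

    def test_missing_outcome_column(self):
        rng = np.random.default_rng(17)
        df = self.results_frame(rng).drop(columns=["hyf"])
        with pytest.raises(StatsError, match="hyf"):
            build_report(df)
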