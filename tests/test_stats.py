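"""t tests, ANOVA, ICC and cohort summaries against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from craniosym.errors import CraniosymError
from craniosym.stats import (
    class_distribution,
    icc_agreement,
    one_way_anova,
    summarize_cohort,
    two_sample_t,
    two_sample_t_from_stats,
)


class TestTwoSampleT:
    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = two_sample_t(x, x.copy())
        assert res.t == pytest.approx(0.0) and res.p == pytest.approx(1.0)

    def test_constant_equal_samples_convention(self):
        res = two_sample_t([2.0, 2.0, 2.0], [2.0, 2.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_printed_summary_statistics(self):
        """Pooled t on the printed class-I upper-lip-height summaries by
        sex reproduces the reported p = 0.007."""
        res = two_sample_t_from_stats(38, 20.54, 1.90, 36, 19.15, 2.42)
        assert round(res.p, 3) == 0.007
        assert res.df == 72

    def test_welch_close_to_pooled_here(self):
        pooled = two_sample_t_from_stats(38, 20.54, 1.90, 36, 19.15, 2.42, "pooled")
        welch = two_sample_t_from_stats(38, 20.54, 1.90, 36, 19.15, 2.42, "welch")
        assert welch.p == pytest.approx(pooled.p, abs=0.002)

    def test_against_permutation_oracle(self):
        """Small-sample t-test p agrees with an exhaustive-ish permutation
        test within Monte-Carlo error."""
        rng = np.random.default_rng(0)
        x = rng.normal(0.0, 1.0, 8)
        y = rng.normal(1.0, 1.0, 7)
        res = two_sample_t(x, y)
        pooled = np.concatenate([x, y])
        n_perm = 20000
        count = 0
        obs = abs(x.mean() - y.mean())
        for _ in range(n_perm):
            rng.shuffle(pooled)
            if abs(pooled[:8].mean() - pooled[8:].mean()) >= obs - 1e-12:
                count += 1
        p_perm = count / n_perm
        assert res.p == pytest.approx(p_perm, abs=0.02)

    def test_insufficient_n(self):
        with pytest.raises(CraniosymError):
            two_sample_t([1.0], [2.0, 3.0])


class TestAnova:
    def test_identical_constant_groups(self):
        res = one_way_anova([[3.0, 3.0], [3.0, 3.0, 3.0]])
        assert res.F == 0.0 and res.p == 1.0

    def test_two_group_F_equals_t_squared(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            x = rng.normal(0, 1, 12)
            y = rng.normal(0.5, 1, 9)
            t = two_sample_t(x, y, "pooled")
            a = one_way_anova([x, y])
            assert a.F == pytest.approx(t.t**2, abs=1e-9)
            assert a.p == pytest.approx(t.p, abs=1e-9)

    def test_matches_scipy(self):
        from scipy.stats import f_oneway

        rng = np.random.default_rng(2)
        groups = [rng.normal(m, 1, n) for m, n in ((0, 10), (0.3, 12), (0.6, 8))]
        res = one_way_anova(groups)
        ref = f_oneway(*groups)
        assert res.F == pytest.approx(ref.statistic, abs=1e-9)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_power_against_noncentral_F_oracle(self):
        """Rejection rate for three groups drawn at the published male
        mid-face offsets matches the analytic noncentral-F power."""
        from scipy.stats import f as fdist
        from scipy.stats import ncf

        means, sds, ns = (6.49, 6.76, 4.62), (1.84, 1.76, 1.50), (38, 24, 4)
        grand = np.average(means, weights=ns)
        sigma2 = np.average(np.square(sds), weights=[n - 1 for n in ns])
        lam = sum(n * (m - grand) ** 2 for n, m in zip(ns, means)) / sigma2
        df1, df2 = 2, sum(ns) - 3
        crit = fdist.ppf(0.95, df1, df2)
        power = ncf.sf(crit, df1, df2, lam)
        rng = np.random.default_rng(3)
        rejections = 0
        reps = 500
        for _ in range(reps):
            groups = [
                rng.normal(m, s, n) for m, s, n in zip(means, sds, ns)
            ]
            if one_way_anova(groups).p < 0.05:
                rejections += 1
        rate = rejections / reps
        mc_err = 3 * np.sqrt(power * (1 - power) / reps)
        assert abs(rate - power) < mc_err + 0.02

    def test_degenerate_groups_rejected(self):
        with pytest.raises(CraniosymError):
            one_way_anova([[1.0, 2.0]])


def icc21_oracle(Y):
    """Independent two-way ANOVA mean-squares decomposition."""
    n, k = Y.shape
    grand = Y.mean()
    msr = k * ((Y.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((Y.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    sse = ((Y - Y.mean(axis=1, keepdims=True) - Y.mean(axis=0) + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def test_perfect_agreement(self):
        y = np.random.default_rng(4).normal(0, 1, 12)
        assert icc_agreement(np.column_stack([y, y])) == pytest.approx(1.0)

    def test_against_mean_squares_oracle(self):
        rng = np.random.default_rng(5)
        Y = rng.normal(0, 1, (5, 2)) + rng.normal(0, 0.3, (5, 1))
        assert icc_agreement(Y) == pytest.approx(icc21_oracle(Y), abs=1e-9)

    def test_against_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(6)
        truth = rng.normal(50, 5, 20)
        Y = truth[:, None] + rng.normal(0, 1.5, (20, 3))
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(20), 3),
                "rater": np.tile(np.arange(3), 20),
                "score": Y.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(
            df, targets="subject", raters="rater", ratings="score"
        ).set_index("Type")
        # absolute-agreement single-rater and consistency single-rater forms
        icc2 = ref.loc["ICC(A,1)", "ICC"] if "ICC(A,1)" in ref.index else ref.loc["ICC2", "ICC"]
        icc3 = ref.loc["ICC(C,1)", "ICC"] if "ICC(C,1)" in ref.index else ref.loc["ICC3", "ICC"]
        assert icc_agreement(Y, "ICC2") == pytest.approx(icc2, abs=1e-9)
        assert icc_agreement(Y, "ICC3") == pytest.approx(icc3, abs=1e-9)

    def test_shift_and_scale_invariance(self):
        rng = np.random.default_rng(7)
        Y = rng.normal(0, 1, (15, 2)) + rng.normal(0, 0.4, (15, 1))
        base = icc_agreement(Y)
        assert icc_agreement(Y + 100.0) == pytest.approx(base, abs=1e-9)
        assert icc_agreement(Y * 3.5) == pytest.approx(base, abs=1e-9)

    def test_constant_ratings_undefined(self):
        with pytest.raises(CraniosymError):
            icc_agreement(np.full((6, 2), 3.0))

    def test_shape_requirements(self):
        with pytest.raises(CraniosymError):
            icc_agreement(np.zeros((3, 2)))


def toy_cohort(rng, n_per_cell=8, constant=None):
    rows = []
    i = 0
    for cls in ("I", "II", "III"):
        for sex in ("M", "F"):
            for _ in range(n_per_cell):
                i += 1
                value = constant if constant is not None else rng.normal(50, 4)
                rows.append(
                    {"id": f"S{i}", "cls": cls, "sex": sex, "age": 9, "N_Gn": value}
                )
    return pd.DataFrame(rows)


class TestCohortSummary:
    def test_constant_cohort_all_p_one(self):
        df = toy_cohort(np.random.default_rng(8), constant=100.0)
        summary = summarize_cohort(df, parameters=["N_Gn"])
        total = summary.table.loc[("N_Gn", "Total")]
        assert total["sd_I"] == 0.0
        for col in ("p_omnibus", "p_I_II", "p_I_III", "p_II_III"):
            assert total[col] == pytest.approx(1.0)

    def test_total_uses_raw_values(self):
        rng = np.random.default_rng(9)
        df = toy_cohort(rng)
        summary = summarize_cohort(df, parameters=["N_Gn"])
        got = summary.table.loc[("N_Gn", "Total"), "mean_I"]
        expected = df[df.cls == "I"]["N_Gn"].mean()
        assert got == pytest.approx(expected, abs=1e-12)

    def test_small_cell_marked_na_with_warning(self):
        rng = np.random.default_rng(10)
        df = toy_cohort(rng)
        df = df[~((df.cls == "III") & (df.sex == "M"))]
        single = pd.DataFrame(
            [{"id": "X", "cls": "III", "sex": "M", "age": 9, "N_Gn": 50.0}]
        )
        df = pd.concat([df, single])
        with pytest.warns(UserWarning, match="n < 2"):
            summary = summarize_cohort(df, parameters=["N_Gn"])
        assert np.isnan(summary.table.loc[("N_Gn", "M"), "mean_III"])


class TestClassDistribution:
    def test_study_roster_percentages(self):
        rows = []
        for cls, n_m, n_f in (("I", 38, 36), ("II", 24, 26), ("III", 4, 11)):
            for i in range(n_m):
                rows.append({"id": f"{cls}m{i}", "cls": cls, "sex": "M"})
            for i in range(n_f):
                rows.append({"id": f"{cls}f{i}", "cls": cls, "sex": "F"})
        dist = class_distribution(pd.DataFrame(rows))
        assert dist.set_index("cls").loc["I", "pct"] == 53.2
        assert dist.set_index("cls").loc["II", "pct"] == 36.0
        assert dist.set_index("cls").loc["III", "pct"] == 10.8

    def test_single_class(self):
        df = pd.DataFrame(
            [{"id": f"S{i}", "cls": "I", "sex": "M"} for i in range(5)]
        )
        dist = class_distribution(df)
        assert dist["pct"].iloc[0] == 100.0

    def test_counts_against_tally_loop(self):
        rng = np.random.default_rng(11)
        df = toy_cohort(rng, n_per_cell=5)
        dist = class_distribution(df).set_index("cls")
        for cls in ("I", "II", "III"):
            tally = sum(1 for _, row in df.iterrows() if row["cls"] == cls)
            assert dist.loc[cls, "n"] == tally

    def test_empty_roster_rejected(self):
        with pytest.raises(CraniosymError):
            class_distribution(pd.DataFrame(columns=["id", "cls", "sex"]))


class TestTypeIError:
    def test_null_rejection_rate(self):
        """Three null groups: the ANOVA rejects at the nominal 5% rate."""
        rng = np.random.default_rng(12)
        reps = 1000
        rejections = 0
        for _ in range(reps):
            groups = [rng.normal(0, 1, n) for n in (38, 24, 4)]
            if one_way_anova(groups).p < 0.05:
                rejections += 1
        rate = rejections / reps
        assert abs(rate - 0.05) < 0.025
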