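"""Cohort statistics: t tests, one-way ANOVA, ICC and table-shaped summaries.

The comparison design mirrors a three-group observational study: unpaired
two-sample t tests between occlusion classes and between sexes, a one-way
fixed-effects ANOVA across the three classes, and an intraclass correlation
coefficient (two-way random effects, absolute agreement, single
measurement — ICC(2,1)) for inter-rater reliability.  Significance is
assessed at p <= 0.05 without multiple-testing correction, matching the
study design this package reproduces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .anthropometry import PARAMETER_CODES
from .errors import CraniosymError

__all__ = [
    "TTestResult",
    "AnovaResult",
    "two_sample_t",
    "two_sample_t_from_stats",
    "one_way_anova",
    "icc_agreement",
    "summarize_cohort",
    "class_distribution",
    "GroupSummary",
    "CLASSES",
    "SEXES",
]

CLASSES = ("I", "II", "III")
SEXES = ("M", "F")


@dataclass
class TTestResult:
    t: float
    df: float
    p: float


@dataclass
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float


def two_sample_t(x, y, variant: str = "pooled") -> TTestResult:
    """Unpaired two-sample t test, two-sided.

    ``variant`` is 'pooled' (Student, equal variances) or 'welch'.
    Two identical zero-variance samples return t = 0, p = 1 by convention.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise CraniosymError("each sample needs at least 2 observations")
    # Degenerate-data convention: two constant samples with equal means.
    # The comparison is at round-off scale, since the mean of identical
    # doubles can differ from them by an ulp.
    scale = max(np.abs(x).max(), np.abs(y).max(), 1.0)
    tol = 1e-12 * scale
    if x.std(ddof=1) < tol and y.std(ddof=1) < tol and abs(x.mean() - y.mean()) < tol:
        df = len(x) + len(y) - 2
        return TTestResult(0.0, float(df), 1.0)
    res = sps.ttest_ind(x, y, equal_var=(variant == "pooled"))
    df = float(res.df) if hasattr(res, "df") else len(x) + len(y) - 2
    return TTestResult(float(res.statistic), df, float(res.pvalue))


def two_sample_t_from_stats(
    n1, mean1, sd1, n2, mean2, sd2, variant: str = "pooled"
) -> TTestResult:
    """Two-sample t test from printed summary statistics (n, mean, SD)."""
    if n1 < 2 or n2 < 2:
        raise CraniosymError("each group needs at least n = 2")
    res = sps.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=(variant == "pooled")
    )
    if variant == "pooled":
        df = n1 + n2 - 2
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return TTestResult(float(res.statistic), float(df), float(res.pvalue))


def one_way_anova(groups) -> AnovaResult:
    """Fixed-effects one-way ANOVA across two or more groups.

    With exactly two groups F equals the square of the pooled t statistic.
    All-identical constant groups give F = 0, p = 1.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise CraniosymError("ANOVA needs >= 2 groups with >= 2 values each")
    n_tot = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1 = len(groups) - 1
    df2 = n_tot - len(groups)
    # Round-off-scale threshold so constant groups are treated as such.
    scale = max(abs(grand), max(np.abs(g).max() for g in groups), 1.0)
    ss_tol = n_tot * (1e-12 * scale) ** 2
    if ss_within <= ss_tol:
        if ss_between <= ss_tol:
            return AnovaResult(0.0, df1, df2, 1.0)
        return AnovaResult(float("inf"), df1, df2, 0.0)
    F = (ss_between / df1) / (ss_within / df2)
    p = float(sps.f.sf(F, df1, df2))
    return AnovaResult(float(F), df1, df2, p)


def icc_agreement(ratings, form: str = "ICC2") -> float:
    """Intraclass correlation for a subjects x raters matrix.

    ``form`` 'ICC2' is the two-way random-effects, absolute-agreement,
    single-measurement coefficient (the default reliability index here);
    'ICC3' is the two-way mixed, consistency form.  Computed from the
    two-way ANOVA mean squares.
    """
    Y = np.asarray(ratings, float)
    if Y.ndim != 2:
        raise CraniosymError("ratings must be a 2D subjects x raters matrix")
    n, k = Y.shape
    if k < 2 or n < 5:
        raise CraniosymError("need >= 2 raters and >= 5 subjects")
    if np.any(~np.isfinite(Y)):
        raise CraniosymError("missing cells are not supported")
    grand = Y.mean()
    subj_means = Y.mean(axis=1)
    rater_means = Y.mean(axis=0)
    ss_rows = k * ((subj_means - grand) ** 2).sum()
    ss_cols = n * ((rater_means - grand) ** 2).sum()
    ss_tot = ((Y - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if form == "ICC2":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif form == "ICC3":
        denom = msr + (k - 1) * mse
    else:
        raise CraniosymError(f"unknown ICC form {form!r}")
    if denom == 0:
        raise CraniosymError("ICC undefined for constant ratings")
    return float((msr - mse) / denom)


# ---------------------------------------------------------------------------
# Cohort table summaries


@dataclass
class GroupSummary:
    """Per-parameter class x sex summary in the study's table layout.

    ``table`` rows: one per (parameter, row) where row is 'M', 'F',
    'p_MF' or 'Total'; class columns carry mean/SD/n, plus the four
    p-value columns on the Total row and the per-sex omnibus p.
    """

    table: pd.DataFrame
    n_by_cell: pd.Series

    def formatted(self, decimals: int = 2) -> pd.DataFrame:
        """Human-readable mean +/- SD strings, p values to 2-3 decimals."""
        rows = []
        for (param, row), rec in self.table.iterrows():
            out = {"parameter": param, "row": row}
            for cls in CLASSES:
                m, s = rec.get(f"mean_{cls}"), rec.get(f"sd_{cls}")
                if np.isfinite(m):
                    out[f"class_{cls}"] = f"{m:.{decimals}f} ± {s:.{decimals}f}"
                else:
                    out[f"class_{cls}"] = "NA"
            for col in ("p_omnibus", "p_I_II", "p_I_III", "p_II_III"):
                p = rec.get(col)
                if np.isfinite(p):
                    out[col] = f"{p:.3f}" + (" *" if p <= 0.05 else "")
                else:
                    out[col] = ""
            rows.append(out)
        return pd.DataFrame(rows)


def _cell(df, cls=None, sex=None):
    sel = df
    if cls is not None:
        sel = sel[sel["cls"] == cls]
    if sex is not None:
        sel = sel[sel["sex"] == sex]
    return sel


def summarize_cohort(
    df: pd.DataFrame,
    parameters=None,
    variant: str = "pooled",
) -> GroupSummary:
    """Build the per-parameter class x sex summary with its p-value columns.

    Totals are computed from raw per-subject values, never from rounded
    subgroup summaries.  Cells with fewer than 2 subjects are marked NA
    with a warning rather than failing the whole table.
    """
    import warnings

    parameters = list(parameters) if parameters is not None else [
        p for p in PARAMETER_CODES if p in df.columns
    ]
    records = {}
    for param in parameters:
        for sex in SEXES + (None,):
            row = "Total" if sex is None else sex
            rec = {}
            groups = []
            for cls in CLASSES:
                vals = _cell(df, cls, sex)[param].dropna().to_numpy()
                rec[f"n_{cls}"] = len(vals)
                if len(vals) >= 2:
                    rec[f"mean_{cls}"] = vals.mean()
                    rec[f"sd_{cls}"] = vals.std(ddof=1)
                    groups.append(vals)
                else:
                    warnings.warn(
                        f"cell class {cls}/{row} for {param} has n < 2; marked NA"
                    )
                    rec[f"mean_{cls}"] = np.nan
                    rec[f"sd_{cls}"] = np.nan
            if len(groups) >= 2:
                rec["p_omnibus"] = one_way_anova(groups).p
            else:
                rec["p_omnibus"] = np.nan
            if sex is None:
                for pair in (("I", "II"), ("I", "III"), ("II", "III")):
                    a = _cell(df, pair[0])[param].dropna().to_numpy()
                    b = _cell(df, pair[1])[param].dropna().to_numpy()
                    key = f"p_{pair[0]}_{pair[1]}"
                    if len(a) >= 2 and len(b) >= 2:
                        rec[key] = two_sample_t(a, b, variant).p
                    else:
                        rec[key] = np.nan
            records[(param, row)] = rec
        # Sex contrast within each class.
        rec = {}
        for cls in CLASSES:
            a = _cell(df, cls, "M")[param].dropna().to_numpy()
            b = _cell(df, cls, "F")[param].dropna().to_numpy()
            if len(a) >= 2 and len(b) >= 2:
                rec[f"mean_{cls}"] = two_sample_t(a, b, variant).p
            else:
                rec[f"mean_{cls}"] = np.nan
            rec[f"sd_{cls}"] = np.nan
            rec[f"n_{cls}"] = 0
        records[(param, "p_MF")] = rec

    table = pd.DataFrame.from_dict(records, orient="index")
    table.index = pd.MultiIndex.from_tuples(table.index, names=["parameter", "row"])
    n_by_cell = df.groupby(["cls", "sex"]).size()
    return GroupSummary(table, n_by_cell)


def class_distribution(df: pd.DataFrame) -> pd.DataFrame:
    """Counts and one-decimal percentages per occlusion class and sex."""
    if len(df) == 0:
        raise CraniosymError("empty roster")
    total = len(df)
    rows = []
    for cls in CLASSES:
        sub = df[df["cls"] == cls]
        if len(sub) == 0:
            continue
        rows.append(
            {
                "cls": cls,
                "n": len(sub),
                "pct": round(100.0 * len(sub) / total, 1),
                "n_male": int((sub["sex"] == "M").sum()),
                "n_female": int((sub["sex"] == "F").sum()),
            }
        )
    return pd.DataFrame(rows)
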