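"""Cohort-level statistical protocol over per-signal landscape profiles.

The sampling unit is the *signal* (one nocturnal recording); subjects
contribute several signals at different months after surgery.  The protocol
comprises:

- group comparison of an index between the F (free of complications) and NF
  (not free) arms by Kruskal-Wallis one-way ANOVA on ranks (with per-group
  median and quartiles);
- paired dynamical-dependence tests per group: one-sided tests of
  S_T < H1, H2 < 2·H1, H3 < 3·H1 and a two-sided test of sTE = 0, using a
  paired t-test when the differences pass a Shapiro-Wilk normality check and
  a Wilcoxon signed-rank test otherwise;
- in-sample logistic-regression classification counts per group;
- ordinary least-squares regression of an index on months after surgery
  (slope reported per 12 months), with Pearson R and the slope t-test p;
- an equal-slopes (one-way ANCOVA) test via the group × time interaction;
- leave-one-subject-out refits to check slope robustness.

Because subjects contribute repeated signals, group tests pooled over
signals carry a repeated-measures caveat; ``compare_groups`` offers a
subject-median aggregation as a sensitivity option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

#: months-per-year used to scale regression slopes
MONTHS_PER_YEAR = 12.0

#: quantile convention for the descriptive tables
QUANTILE_METHOD = "median_unbiased"


@dataclass
class GroupComparison:
    index: str
    statistic: float
    p: float
    summaries: dict          # group -> (median, q25, q75, n)


@dataclass
class DependenceTest:
    hypothesis: str          # e.g. "S_T < H1"
    group: str
    test_used: str           # "paired-t" | "signed-rank" | "degenerate"
    statistic: float
    p: float
    n: int


@dataclass
class RegressionResult:
    index: str
    group: str
    slope: float             # per 12 months
    stderr: float
    intercept: float
    r: float                 # Pearson correlation
    p: float                 # slope t-test
    n: int


@dataclass
class LOSOResult:
    index: str
    group: str
    fits: list               # (left-out subject, RegressionResult)
    slope_range: float = field(init=False)

    def __post_init__(self) -> None:
        slopes = [f.slope for _, f in self.fits]
        self.slope_range = max(slopes) - min(slopes) if slopes else float("nan")


def _group_values(table: pd.DataFrame, index: str, group: str,
                  aggregate: str = "signals") -> np.ndarray:
    sel = table[table["group"] == group]
    if aggregate == "subjects":
        vals = sel.groupby("subject_id")[index].median().to_numpy()
    else:
        vals = sel[index].to_numpy()
    return vals[np.isfinite(vals)]


def compare_groups(table: pd.DataFrame, index: str,
                   groups: tuple[str, str] = ("F", "NF"),
                   aggregate: str = "signals") -> GroupComparison:
    """Kruskal-Wallis comparison of an index between two groups."""
    samples = [_group_values(table, index, g, aggregate) for g in groups]
    for g, v in zip(groups, samples):
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values for {index}")
    if all(np.array_equal(v, samples[0]) for v in samples[1:]) or \
            len(np.unique(np.concatenate(samples))) == 1:
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.kruskal(*samples)
    summaries = {
        g: (float(np.median(v)),
            float(np.quantile(v, 0.25, method=QUANTILE_METHOD)),
            float(np.quantile(v, 0.75, method=QUANTILE_METHOD)),
            len(v))
        for g, v in zip(groups, samples)
    }
    return GroupComparison(index=index, statistic=float(stat), p=float(p),
                           summaries=summaries)


def _paired_test(diff: np.ndarray, alternative: str,
                 normality_alpha: float = 0.05) -> tuple[str, float, float]:
    """Choose paired t vs signed-rank by a normality check on the differences."""
    diff = np.asarray(diff, dtype=float)
    if np.allclose(diff, 0.0):
        return "degenerate", 0.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        norm_p = stats.shapiro(diff).pvalue if 3 <= len(diff) <= 5000 else 0.0
    if norm_p >= normality_alpha:
        res = stats.ttest_1samp(diff, 0.0, alternative=alternative)
        return "paired-t", float(res.statistic), float(res.pvalue)
    res = stats.wilcoxon(diff, alternative=alternative)
    return "signed-rank", float(res.statistic), float(res.pvalue)


#: dependence hypotheses: name -> (difference columns, one-sided direction)
_HYPOTHESES = {
    "S_T < H1": (lambda t: t["S_T"] - t["H1"], "less"),
    "H2 < 2*H1": (lambda t: t["H2"] - 2.0 * t["H1"], "less"),
    "H3 < 3*H1": (lambda t: t["H3"] - 3.0 * t["H1"], "less"),
    "sTE != 0": (lambda t: t["sTE"], "two-sided"),
}


def paired_dependence_tests(table: pd.DataFrame,
                            groups: tuple[str, ...] = ("F", "NF"),
                            min_pairs: int = 5) -> list[DependenceTest]:
    """Per-group tests of the independence relations of the entropy profile.

    Under independent increments S_T = H1, H2 = 2·H1, H3 = 3·H1 and sTE = 0;
    rejecting the one-sided hypotheses demonstrates genuine short-term
    dynamical dependence.
    """
    results = []
    for g in groups:
        sub = table[table["group"] == g]
        if len(sub) < min_pairs:
            raise ValueError(f"group {g!r} has fewer than {min_pairs} signals")
        for name, (diff_fn, alternative) in _HYPOTHESES.items():
            diff = diff_fn(sub).to_numpy()
            used, stat, p = _paired_test(diff, alternative)
            results.append(DependenceTest(hypothesis=name, group=g,
                                          test_used=used, statistic=stat,
                                          p=p, n=len(diff)))
    return results


def classification_counts(table: pd.DataFrame, features: list[str],
                          groups: tuple[str, str] = ("F", "NF"),
                          ridge_penalty: float = 1e-4) -> dict:
    """In-sample logistic-regression classification counts per group.

    The binary group label is regressed on the features; signals are
    classified at predicted probability 0.5 and the number classified
    correctly is reported per group.  Under perfect separation (or any
    maximum-likelihood failure) a ridge-penalised fit keeps the counts
    defined.
    """
    if not features:
        raise ValueError("need at least one feature")
    sub = table[table["group"].isin(groups)].dropna(subset=list(features))
    y = (sub["group"] == groups[1]).to_numpy(dtype=float)
    X = sm.add_constant(sub[list(features)].to_numpy(dtype=float), has_constant="add")
    prob = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            if np.all(np.isfinite(fit.params)):
                prob = fit.predict(X)
        except Exception:
            prob = None
    if prob is None or not np.all(np.isfinite(prob)):
        from sklearn.linear_model import LogisticRegression
        clf = LogisticRegression(C=1.0 / ridge_penalty, max_iter=2000)
        clf.fit(X[:, 1:], y)
        prob = clf.predict_proba(X[:, 1:])[:, 1]
    pred = (np.asarray(prob) >= 0.5).astype(float)
    out = {}
    for g, code in zip(groups, (0.0, 1.0)):
        mask = y == code
        out[g] = (int(np.sum(pred[mask] == code)), int(mask.sum()))
    return out


def regress_time(table: pd.DataFrame, index: str, group: str) -> RegressionResult:
    """OLS of an index on years after surgery, pooled over a group's signals."""
    sub = table[table["group"] == group].dropna(subset=[index])
    if len(sub) < 3:
        raise ValueError(f"group {group!r} has fewer than 3 signals for {index}")
    x = sub["months_post_htx"].to_numpy(dtype=float) / MONTHS_PER_YEAR
    yv = sub[index].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("all time points identical; slope undefined")
    X = sm.add_constant(x)
    fit = sm.OLS(yv, X).fit()
    r = float(stats.pearsonr(x, yv).statistic) if np.ptp(yv) > 0 else 0.0
    return RegressionResult(index=index, group=group,
                            slope=float(fit.params[1]), stderr=float(fit.bse[1]),
                            intercept=float(fit.params[0]), r=r,
                            p=float(fit.pvalues[1]), n=len(sub))


@dataclass
class EqualSlopesResult:
    index: str
    p: float                 # p-value of the group × time interaction
    slope_difference: float  # per 12 months, second group minus first
    stderr: float

    def __float__(self) -> float:
        return self.p

    def __lt__(self, other) -> bool:
        return self.p < float(other)

    def __gt__(self, other) -> bool:
        return self.p > float(other)


def equal_slopes_test(table: pd.DataFrame, index: str,
                      groups: tuple[str, str] = ("F", "NF")) -> EqualSlopesResult:
    """ANCOVA-style equal-slopes test via the group × time interaction."""
    sub = table[table["group"].isin(groups)].dropna(subset=[index])
    for g in groups:
        if (sub["group"] == g).sum() < 3:
            raise ValueError(f"group {g!r} too small for the equal-slopes test")
    x = sub["months_post_htx"].to_numpy(dtype=float) / MONTHS_PER_YEAR
    z = (sub["group"] == groups[1]).to_numpy(dtype=float)
    yv = sub[index].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(x), x, z, x * z])
    fit = sm.OLS(yv, X).fit()
    return EqualSlopesResult(index=index, p=float(fit.pvalues[3]),
                             slope_difference=float(fit.params[3]),
                             stderr=float(fit.bse[3]))


def loso_slopes(table: pd.DataFrame, index: str, group: str) -> LOSOResult:
    """Leave-one-subject-out refits of the time regression."""
    sub = table[table["group"] == group]
    subjects = sub["subject_id"].unique()
    if len(subjects) < 3:
        raise ValueError("need at least 3 subjects for leave-one-subject-out")
    fits = []
    for s in subjects:
        reduced = sub[sub["subject_id"] != s]
        fits.append((s, regress_time(reduced, index, group)))
    return LOSOResult(index=index, group=group, fits=fits)


def validate_table(table: pd.DataFrame, indices: list[str] | None = None) -> None:
    """Check the per-signal table has the required columns and no empty groups."""
    required = {"subject_id", "months_post_htx", "group"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    if len(table) == 0:
        raise ValueError("cohort table is empty; statistics refuse to run")
    if indices:
        absent = [i for i in indices if i not in table.columns]
        if absent:
            raise ValueError(f"cohort table missing index columns: {absent}")
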