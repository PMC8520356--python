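"""Cohort-level statistics for two-group ventricular-index tables.

Implements the evaluation battery a two-group neonatal morphometry study
needs: independent two-sample t-tests (pooled or Welch, one- or two-tailed,
from raw values or published summary statistics), the Pearson chi-square
test on a 2x2 count table, the two-way random-effects absolute-agreement
single-measurement intraclass correlation ICC(2,1) for two raters,
empirical (non-parametric) ROC analysis with the Mann-Whitney AUC, and the
Youden-optimal cutoff.  A closed-form binormal AUC is included as an
analytic oracle for simulation checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


class StatsError(ValueError):
    """Raised for degenerate statistical inputs."""


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    tails: str  # "one" | "two"
    method: str  # "pooled" | "welch" | "chi2" | "chi2_yates"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise StatsError("p-value outside [0, 1]")


@dataclass(frozen=True)
class IccResult:
    icc: float
    n_subjects: int
    n_raters: int
    model: str = "two-way-random-absolute-agreement-single"


@dataclass(frozen=True)
class RocResult:
    cutoffs: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_cutoff: float
    youden_value: float


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------


def _check_tails_method(tails: str, method: str) -> None:
    if tails not in ("one", "two"):
        raise StatsError("tails must be 'one' or 'two'")
    if method not in ("pooled", "welch"):
        raise StatsError("method must be 'pooled' or 'welch'")


def t_two_sample(
    x: Sequence[float],
    y: Sequence[float],
    tails: str = "one",
    method: str = "pooled",
) -> TestResult:
    """Independent two-sample t-test on raw values.

    The one-tailed p-value is the upper-tail probability for the
    hypothesized direction ``x > y``.
    """
    _check_tails_method(tails, method)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise StatsError("each group needs at least two values")
    return t_from_summary(
        float(x.mean()),
        float(x.std(ddof=1)),
        x.size,
        float(y.mean()),
        float(y.std(ddof=1)),
        y.size,
        tails=tails,
        method=method,
    )


def t_from_summary(
    m1: float,
    s1: float,
    n1: int,
    m2: float,
    s2: float,
    n2: int,
    tails: str = "one",
    method: str = "pooled",
) -> TestResult:
    """t-test from group summary statistics (mean, SD, n).

    Pooled: ``t = (m1 - m2) / (s_p sqrt(1/n1 + 1/n2))`` with
    ``df = n1 + n2 - 2``; Welch uses per-group variances with
    Welch-Satterthwaite degrees of freedom.  Zero variance in both groups is
    tolerated only when the means are equal (t = 0).
    """
    _check_tails_method(tails, method)
    if n1 < 2 or n2 < 2:
        raise StatsError("each group needs n >= 2")
    if s1 < 0 or s2 < 0:
        raise StatsError("SDs must be non-negative")

    if method == "pooled":
        df = float(n1 + n2 - 2)
        sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    else:
        v1, v2 = s1**2 / n1, s2**2 / n2
        se = np.sqrt(v1 + v2)
        if v1 + v2 > 0:
            df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
        else:
            df = float(n1 + n2 - 2)

    if se == 0:
        if m1 == m2:
            t = 0.0
        else:
            raise StatsError("zero variance with unequal means: t undefined")
    else:
        t = float((m1 - m2) / se)

    if tails == "one":
        p = float(stats.t.sf(t, df))
    else:
        p = float(2.0 * stats.t.sf(abs(t), df))
    return TestResult(statistic=t, df=float(df), p_value=p, tails=tails, method=method)


# ---------------------------------------------------------------------------
# chi-square on a 2x2 table
# ---------------------------------------------------------------------------


def chi2_2x2(a: int, b: int, c: int, d: int, yates: bool = False) -> TestResult:
    """Pearson chi-square test on the 2x2 table [[a, b], [c, d]], df = 1."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0):
        raise StatsError("counts must be non-negative")
    if table.sum() <= 0:
        raise StatsError("empty table")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise StatsError("zero marginal: chi-square undefined")
    res = stats.chi2_contingency(table, correction=yates)
    return TestResult(
        statistic=float(res.statistic),
        df=1.0,
        p_value=float(res.pvalue),
        tails="two",
        method="chi2_yates" if yates else "chi2",
    )


# ---------------------------------------------------------------------------
# intraclass correlation
# ---------------------------------------------------------------------------


def icc_two_rater(pairs: np.ndarray | Sequence[Sequence[float]]) -> IccResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rating.

    From the two-way ANOVA mean squares (subjects = rows, raters = columns):

        ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

    Absolute agreement: a constant between-rater bias lowers the ICC even
    when the rank orderings agree perfectly.
    """
    X = np.asarray(pairs, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise StatsError("need an n x k matrix with k >= 2 raters")
    n, k = X.shape
    if n < 3:
        raise StatsError("need at least 3 subjects")
    grand = X.mean()
    if np.allclose(X, grand):
        raise StatsError("zero total variance: ICC undefined")
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((X - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    if denom == 0:
        raise StatsError("degenerate ANOVA decomposition: ICC undefined")
    return IccResult(icc=float((ms_r - ms_e) / denom), n_subjects=n, n_raters=k)


# ---------------------------------------------------------------------------
# ROC / Youden
# ---------------------------------------------------------------------------


def roc_empirical(
    scores: Sequence[float],
    labels: Sequence[int],
    positive_direction: str = "high",
) -> RocResult:
    """Empirical ROC over the distinct observed scores.

    A case is called positive when ``score > cutoff`` (direction "high"; for
    "low" the scale is negated internally and cutoffs reported on the
    original scale with calls ``score < cutoff``).  The AUC is the
    Mann-Whitney probability of concordance with ties credited 1/2,
    computed from midranks.  The Youden-optimal cutoff (maximizing
    sensitivity + specificity - 1, smallest on ties) is attached.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise StatsError("scores and labels must be matching 1-D arrays")
    if positive_direction not in ("high", "low"):
        raise StatsError("positive_direction must be 'high' or 'low'")
    pos = y.astype(bool)
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise StatsError("both classes must be present")

    flip = positive_direction == "low"
    w = -s if flip else s

    ranks = stats.rankdata(w)  # midranks: ties get 1/2 credit in the AUC
    auc = float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))

    cutoffs_w = np.unique(w)
    pos_sorted = np.sort(w[pos])
    neg_sorted = np.sort(w[~pos])
    # sens(c) = P(score > c | pos);  spec(c) = P(score <= c | neg)
    sens = 1.0 - np.searchsorted(pos_sorted, cutoffs_w, side="right") / n_pos
    spec = np.searchsorted(neg_sorted, cutoffs_w, side="right") / n_neg

    j = sens + spec - 1.0
    best = int(np.argmax(j))  # first (= smallest cutoff) on ties
    cutoffs = -cutoffs_w if flip else cutoffs_w
    return RocResult(
        cutoffs=cutoffs,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        youden_cutoff=float(cutoffs[best]),
        youden_value=float(j[best]),
    )


def youden_optimal(roc: RocResult) -> tuple[float, float]:
    """(cutoff, J) maximizing Youden's J = sens + spec - 1; smallest on ties."""
    j = roc.sensitivity + roc.specificity - 1.0
    order = np.argsort(roc.cutoffs, kind="stable")
    j_sorted = j[order]
    best = int(np.argmax(j_sorted))
    return float(roc.cutoffs[order][best]), float(j_sorted[best])


def binormal_auc(m1: float, s1: float, m2: float, s2: float) -> float:
    """Closed-form ROC area when both classes are Gaussian.

    ``Phi((m1 - m2) / sqrt(s1^2 + s2^2))`` with group 1 the positive class.
    """
    if s1 <= 0 or s2 <= 0:
        raise StatsError("SDs must be positive")
    return float(stats.norm.cdf((m1 - m2) / np.hypot(s1, s2)))


# ---------------------------------------------------------------------------
# cohort-level report
# ---------------------------------------------------------------------------

INDEX_COLUMNS = ("f_ratio", "d_ratio", "c_ratio", "evans")


def stats_report(
    cohort: pd.DataFrame,
    positive_group: str = "CHD",
    tails: str = "one",
    method: str = "pooled",
    indices: Sequence[str] = INDEX_COLUMNS,
) -> dict:
    """Per-index two-group comparison: means/SDs, t-test, ROC AUC, Youden.

    ``positive_group`` is both the hypothesized larger-mean group for the
    one-tailed t-test and the ROC positive class.  When the cohort carries
    ``rater1``/``rater2`` columns, their ICC(2,1) is included.
    """
    if len(cohort) == 0:
        raise StatsError("empty cohort")
    groups = cohort["group"].unique().tolist()
    if positive_group not in groups or len(groups) != 2:
        raise StatsError("cohort must contain exactly two groups incl. the positive")
    negative_group = next(g for g in groups if g != positive_group)
    report: dict = {
        "groups": {"positive": positive_group, "negative": negative_group},
        "indices": {},
    }
    is_pos = (cohort["group"] == positive_group).to_numpy()
    for col in indices:
        v = cohort[col].to_numpy(dtype=float)
        ok = np.isfinite(v)
        x, y = v[ok & is_pos], v[ok & ~is_pos]
        t_res = t_two_sample(x, y, tails=tails, method=method)
        roc = roc_empirical(v[ok], is_pos[ok].astype(int))
        report["indices"][col] = {
            "mean_positive": float(x.mean()),
            "sd_positive": float(x.std(ddof=1)),
            "mean_negative": float(y.mean()),
            "sd_negative": float(y.std(ddof=1)),
            "t": t_res.statistic,
            "df": t_res.df,
            "p": t_res.p_value,
            "auc": roc.auc,
            "youden_cutoff": roc.youden_cutoff,
            "youden_value": roc.youden_value,
        }
    if {"rater1", "rater2"}.issubset(cohort.columns):
        pairs = cohort[["rater1", "rater2"]].to_numpy(dtype=float)
        report["icc"] = icc_two_rater(pairs).icc
    return report
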