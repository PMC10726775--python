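"""Cohort-level statistics: pixel counts and questionnaire exact tests.

Fisher's exact test here reports the *conditional maximum-likelihood*
odds ratio: with both margins of a 2x2 table fixed, the count in the
top-left cell follows Fisher's noncentral hypergeometric distribution
with parameter psi (the odds ratio), and the estimate solves
``E_psi[X] = x``.  The exact 95% CI inverts the one-sided tail tests at
2.5% each side.  Root searches follow the reference implementation's
scheme — Brent's zeroin at tolerance eps^0.25, bracketing on (0, 1] and
the reciprocal scale — so values printed in the applied literature are
reproduced digit-for-digit; pass a small ``tol`` for tight inversion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .raster_model import PainDrawing

__all__ = [
    "ContingencyTable",
    "ExactTestResult",
    "PixelCountSummary",
    "pixel_count_comparison",
    "fisher_exact_2x2",
    "chi_squared",
    "welch_t",
    "questionnaire_summary",
]

_EPS = float(np.finfo(float).eps)
#: uniroot-style default tolerance (matches the reference implementation)
DEFAULT_CI_TOL = _EPS**0.25


# ---------------------------------------------------------------------------
# Brent's zeroin (classic formulation, as used by the reference software)
# ---------------------------------------------------------------------------

def _zeroin(f, ax: float, bx: float, tol: float, maxit: int = 1000) -> float:
    a, b = ax, bx
    fa, fb = f(a), f(b)
    c, fc = a, fa
    for _ in range(maxit):
        prev_step = b - a
        if abs(fc) < abs(fb):
            a, b, c = b, c, b
            fa, fb, fc = fb, fc, fb
        tol_act = 2 * _EPS * abs(b) + tol / 2
        new_step = (c - b) / 2
        if abs(new_step) <= tol_act or fb == 0:
            return b
        if abs(prev_step) >= tol_act and abs(fa) > abs(fb):
            cb = c - b
            if a == c:
                t1 = fb / fa
                p = cb * t1
                q = 1 - t1
            else:
                q = fa / fc
                t1 = fb / fc
                t2 = fb / fa
                p = t2 * (cb * q * (q - t1) - (b - a) * (t1 - 1))
                q = (q - 1) * (t1 - 1) * (t2 - 1)
            if p > 0:
                q = -q
            else:
                p = -p
            if p < (0.75 * cb * q - abs(tol_act * q) / 2) and p < abs(prev_step * q / 2):
                new_step = p / q
        if abs(new_step) < tol_act:
            new_step = tol_act if new_step > 0 else -tol_act
        a, fa = b, fb
        b += new_step
        fb = f(b)
        if (fb > 0 and fc > 0) or (fb < 0 and fc < 0):
            c, fc = a, fa
    return b


# ---------------------------------------------------------------------------
# Contingency tables
# ---------------------------------------------------------------------------

@dataclass
class ContingencyTable:
    """2xK table of response counts with explicit row/column labels."""

    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != 2:
            raise ValueError("counts must be a 2xK array")
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("labels do not match count dimensions")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    def drop_column(self, label: str) -> "ContingencyTable":
        if label not in self.col_labels:
            return self
        keep = [i for i, c in enumerate(self.col_labels) if c != label]
        return ContingencyTable(
            row_labels=list(self.row_labels),
            col_labels=[self.col_labels[i] for i in keep],
            counts=self.counts[:, keep],
            name=self.name,
        )


@dataclass
class ExactTestResult:
    """Fisher exact test: two-sided p, conditional-MLE OR, exact 95% CI."""

    p_value: float
    odds_ratio: float | None
    ci_low: float | None
    ci_high: float | None
    method: str = "fisher-exact-cmle"
    conf_level: float = 0.95


def _cond_dist(table: np.ndarray):
    """Support and log binomial-coefficient weights of the conditional law."""
    a, b = int(table[0, 0]), int(table[0, 1])
    c, d = int(table[1, 0]), int(table[1, 1])
    m1, m2, n1 = a + b, c + d, a + c
    lo, hi = max(0, n1 - m2), min(n1, m1)
    xs = np.arange(lo, hi + 1)
    logdc = (
        gammaln(m1 + 1) - gammaln(xs + 1) - gammaln(m1 - xs + 1)
        + gammaln(m2 + 1) - gammaln(n1 - xs + 1) - gammaln(m2 - n1 + xs + 1)
    )
    return a, lo, hi, xs, logdc


def _pmf(psi: float, xs: np.ndarray, logdc: np.ndarray) -> np.ndarray:
    if psi == 0.0:  # degenerate law: all mass at the support minimum
        p = np.zeros(len(xs))
        p[0] = 1.0
        return p
    w = logdc + xs * np.log(psi)
    w -= w.max()
    p = np.exp(w)
    return p / p.sum()


def fisher_exact_2x2(table: ContingencyTable | np.ndarray,
                     conf_level: float = 0.95,
                     tol: float = DEFAULT_CI_TOL) -> ExactTestResult:
    """Fisher's exact test with conditional-MLE odds ratio and exact CI.

    The two-sided p-value sums the hypergeometric point probabilities not
    exceeding that of the observed table (point-probability rule).  With a
    zero margin there is no information about association: p = 1 and the
    odds ratio is reported as missing.
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    if counts.shape != (2, 2):
        raise ValueError("fisher_exact_2x2 requires a 2x2 table")
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        return ExactTestResult(p_value=1.0, odds_ratio=None,
                               ci_low=None, ci_high=None,
                               method="fisher-exact-cmle (degenerate margin)",
                               conf_level=conf_level)
    x, lo, hi, xs, logdc = _cond_dist(counts)

    pmf1 = _pmf(1.0, xs, logdc)
    p_two = float(min(1.0, pmf1[pmf1 <= pmf1[x - lo] * (1 + 1e-7)].sum()))

    def mean(psi: float) -> float:
        return float((xs * _pmf(psi, xs, logdc)).sum())

    def p_geq(psi: float) -> float:  # P(X >= x; psi)
        return float(_pmf(psi, xs, logdc)[xs >= x].sum())

    def p_leq(psi: float) -> float:  # P(X <= x; psi)
        return float(_pmf(psi, xs, logdc)[xs <= x].sum())

    # conditional MLE: solve E_psi[X] = x, bracketing as the reference does
    if x == lo:
        mle: float = 0.0
    elif x == hi:
        mle = float("inf")
    else:
        mu1 = mean(1.0)
        if mu1 > x:
            mle = _zeroin(lambda t: mean(t) - x, 0.0, 1.0, tol)
        elif mu1 < x:
            mle = 1.0 / _zeroin(lambda t: mean(1.0 / t) - x, _EPS, 1.0, tol)
        else:
            mle = 1.0

    alpha = (1.0 - conf_level) / 2.0

    def lower_bound() -> float:
        if x == lo:
            return 0.0
        if p_geq(1.0) > alpha:
            return _zeroin(lambda t: p_geq(t) - alpha, 0.0, 1.0, tol)
        if p_geq(1.0) < alpha:
            return 1.0 / _zeroin(lambda t: p_geq(1.0 / t) - alpha, _EPS, 1.0, tol)
        return 1.0

    def upper_bound() -> float:
        if x == hi:
            return float("inf")
        if p_leq(1.0) < alpha:
            return _zeroin(lambda t: p_leq(t) - alpha, 0.0, 1.0, tol)
        if p_leq(1.0) > alpha:
            return 1.0 / _zeroin(lambda t: p_leq(1.0 / t) - alpha, _EPS, 1.0, tol)
        return 1.0

    return ExactTestResult(p_value=p_two, odds_ratio=mle,
                           ci_low=lower_bound(), ci_high=upper_bound(),
                           conf_level=conf_level)


def chi_squared(table: ContingencyTable | np.ndarray):
    """Pearson chi-squared on a 2xK table, no continuity correction.

    Zero-sum columns are dropped with a warning; a warning is also raised
    when any expected cell count falls below 5 (the usual validity rule
    of thumb).  Returns ``(statistic, df, p_value)``.
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    if counts.ndim != 2 or counts.shape[0] != 2 or counts.shape[1] < 2:
        raise ValueError("chi_squared requires a 2xK table with K >= 2")
    col_sums = counts.sum(axis=0)
    if (col_sums == 0).any():
        warnings.warn("dropping zero-sum column(s) from chi-squared table",
                      stacklevel=2)
        counts = counts[:, col_sums > 0]
        if counts.shape[1] < 2:
            raise ValueError("fewer than 2 informative columns remain")
    res = stats.chi2_contingency(counts, correction=False)
    if (res.expected_freq < 5).any():
        warnings.warn("chi-squared approximation: expected cell count < 5",
                      stacklevel=2)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def welch_t(sample_a, sample_b):
    """Two-sided Welch t-test (Satterthwaite df) on two samples.

    Returns ``(statistic, df, p_value)``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, float(len(a) + len(b) - 2), 1.0
        raise ValueError("both samples have zero variance with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


# ---------------------------------------------------------------------------
# Pixel counts
# ---------------------------------------------------------------------------

@dataclass
class PixelCountSummary:
    """Per-drawing marked-pixel counts and tests on their log10 values."""

    group_a: str
    group_b: str
    counts_a: np.ndarray
    counts_b: np.ndarray
    log10_a: np.ndarray
    log10_b: np.ndarray
    summary_a: dict[str, float]
    summary_b: dict[str, float]
    rank_sum_w: float          # sum of group-A ranks in the pooled sample
    u_statistic: float         # Mann-Whitney U of group A (the "W" many
                               # statistics packages print)
    rank_sum_p: float
    t_statistic: float
    t_p: float
    n_excluded: int = 0
    notes: list[str] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for g, counts, logs in ((self.group_a, self.counts_a, self.log10_a),
                                (self.group_b, self.counts_b, self.log10_b)):
            for c in counts:
                rows.append({"group": g, "n_marked": int(c),
                             "log10": float(np.log10(c)) if c > 0 else np.nan})
        return pd.DataFrame(rows)


def _log_summary(vals: np.ndarray) -> dict[str, float]:
    return {
        "min": float(np.min(vals)),
        "max": float(np.max(vals)),
        "mean": float(np.mean(vals)),
        "median": float(np.median(vals)),
        "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan"),
        "n": int(len(vals)),
    }


def pixel_count_comparison(group_a: list[PainDrawing],
                           group_b: list[PainDrawing]) -> PixelCountSummary:
    """Compare per-drawing marked-pixel counts between two groups.

    Counts are log10-transformed, then compared with a two-sided Wilcoxon
    rank-sum test (midrank ties, continuity-corrected normal
    approximation) and a two-sided two-sample t-test.  Drawings with zero
    marked pixels have no log10 value and are excluded with a warning.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    counts_a = np.array([d.n_marked for d in group_a], dtype=np.int64)
    counts_b = np.array([d.n_marked for d in group_b], dtype=np.int64)
    n_zero = int((counts_a == 0).sum() + (counts_b == 0).sum())
    notes = []
    if n_zero:
        warnings.warn(f"excluding {n_zero} zero-count drawing(s) from log10 "
                      "analyses", stacklevel=2)
        notes.append(f"{n_zero} zero-count drawing(s) excluded from log10 tests")
    log_a = np.log10(counts_a[counts_a > 0].astype(float))
    log_b = np.log10(counts_b[counts_b > 0].astype(float))
    if len(log_a) == 0 or len(log_b) == 0:
        raise ValueError("a group has no positive pixel counts")

    mwu = stats.mannwhitneyu(log_a, log_b, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    pooled = np.concatenate([log_a, log_b])
    ranks = stats.rankdata(pooled)  # midranks for ties
    rank_sum_w = float(ranks[: len(log_a)].sum())

    if len(log_a) > 1 and len(log_b) > 1:
        tt = stats.ttest_ind(log_a, log_b, equal_var=True)
        t_stat, t_p = float(tt.statistic), float(tt.pvalue)
        if np.isnan(t_stat):  # zero pooled variance: identical samples
            t_stat, t_p = 0.0, 1.0
    else:
        t_stat, t_p = float("nan"), float("nan")
        notes.append("t-test skipped: fewer than 2 positive counts in a group")

    return PixelCountSummary(
        group_a=group_a[0].group_label, group_b=group_b[0].group_label,
        counts_a=counts_a, counts_b=counts_b,
        log10_a=log_a, log10_b=log_b,
        summary_a=_log_summary(log_a), summary_b=_log_summary(log_b),
        rank_sum_w=rank_sum_w, u_statistic=float(mwu.statistic),
        rank_sum_p=float(mwu.pvalue), t_statistic=t_stat, t_p=t_p,
        n_excluded=n_zero, notes=notes,
    )


# ---------------------------------------------------------------------------
# Questionnaire report
# ---------------------------------------------------------------------------

def questionnaire_summary(tables: dict[str, ContingencyTable],
                          drop_label: str = "no opinion") -> pd.DataFrame:
    """Run the questionnaire test battery over a set of response tables.

    For each named 2xK table: response percentages per column, overall
    and per group, over all respondents (``drop_label`` answers count in
    the denominator, matching how response rates are usually reported);
    a Fisher exact test (conditional-MLE OR + exact CI) on 2x2 tables —
    after dropping the ``drop_label`` column where present — and a
    chi-squared test on wider tables.  Tables left with an empty row
    after the drop are reported untested.
    """
    rows = []
    for name, table in tables.items():
        tab = table.drop_column(drop_label)
        n_all = int(table.counts.sum())
        entry: dict[str, object] = {
            "question": name,
            "n": n_all,
            "n_tested": int(tab.counts.sum()),
            "rows": "/".join(tab.row_labels),
            "cols": "/".join(tab.col_labels),
        }
        for j, col in enumerate(table.col_labels):
            csum = int(table.counts[:, j].sum())
            entry[f"pct_{col}"] = round(100.0 * csum / n_all, 2) if n_all else np.nan
            for i, rowlab in enumerate(table.row_labels):
                rsum = int(table.counts[i].sum())
                entry[f"pct_{col}_{rowlab}"] = (
                    round(100.0 * table.counts[i, j] / rsum, 2) if rsum else np.nan
                )
        if (tab.counts.sum(axis=1) == 0).any():
            entry["test"] = "skipped"
            entry["note"] = f"empty group after dropping {drop_label!r}"
        elif tab.counts.shape[1] == 2:
            res = fisher_exact_2x2(tab)
            entry.update(test="fisher", p_value=res.p_value,
                         odds_ratio=res.odds_ratio,
                         ci_low=res.ci_low, ci_high=res.ci_high)
        else:
            stat, df, p = chi_squared(tab)
            entry.update(test="chi-squared", statistic=stat, df=df, p_value=p)
        rows.append(entry)
    return pd.DataFrame(rows)
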