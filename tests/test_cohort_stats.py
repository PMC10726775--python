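"""Exact tests, chi-squared, Welch t, and pixel-count comparisons."""

import numpy as np
import pytest
from scipy import stats

from paindraw import (ContingencyTable, chi_squared, fisher_exact_2x2,
                      pixel_count_comparison, questionnaire_summary, welch_t)
from paindraw.datasets import load_questionnaire_counts

from conftest import make_tiny_drawing

TIGHT = 1e-12


# ---------------------------------------------------------------------------
# Fisher exact, conditional MLE OR, exact CI
# ---------------------------------------------------------------------------

def test_identical_rows_show_no_association():
    res = fisher_exact_2x2(np.array([[7, 5], [7, 5]]))
    assert res.p_value == 1.0
    assert res.odds_ratio == pytest.approx(1.0, abs=1e-3)
    assert res.ci_low < 1.0 < res.ci_high


def test_simultaneous_row_and_column_swap_is_invariant():
    t = np.array([[12, 5], [3, 9]])
    swapped = t[::-1, ::-1]
    a = fisher_exact_2x2(t, tol=TIGHT)
    b = fisher_exact_2x2(swapped, tol=TIGHT)
    assert a.p_value == pytest.approx(b.p_value, abs=1e-12)
    assert a.odds_ratio == pytest.approx(b.odds_ratio, rel=1e-8)
    assert a.ci_low == pytest.approx(b.ci_low, rel=1e-6)
    assert a.ci_high == pytest.approx(b.ci_high, rel=1e-6)


def test_row_swap_inverts_odds_ratio_and_mirrors_ci():
    t = np.array([[12, 5], [3, 9]])
    a = fisher_exact_2x2(t, tol=TIGHT)
    b = fisher_exact_2x2(t[::-1], tol=TIGHT)
    assert b.odds_ratio == pytest.approx(1.0 / a.odds_ratio, rel=1e-8)
    assert b.ci_low == pytest.approx(1.0 / a.ci_high, rel=1e-6)
    assert b.ci_high == pytest.approx(1.0 / a.ci_low, rel=1e-6)


def test_ci_endpoints_invert_the_onesided_tests():
    """At the tight tolerance each CI bound solves its tail equation to 1e-6."""
    from paindraw.cohort_stats import _cond_dist, _pmf

    for table in (np.array([[21, 2], [22, 3]]), np.array([[14, 8], [9, 16]]),
                  np.array([[3, 11], [9, 2]])):
        res = fisher_exact_2x2(table, tol=TIGHT)
        x, lo, hi, xs, logdc = _cond_dist(table)
        p_geq_at_low = _pmf(res.ci_low, xs, logdc)[xs >= x].sum()
        p_leq_at_high = _pmf(res.ci_high, xs, logdc)[xs <= x].sum()
        assert p_geq_at_low == pytest.approx(0.025, abs=1e-6)
        assert p_leq_at_high == pytest.approx(0.025, abs=1e-6)


def test_cmle_solves_conditional_score_equation():
    from paindraw.cohort_stats import _cond_dist, _pmf

    table = np.array([[14, 8], [9, 16]])
    res = fisher_exact_2x2(table, tol=TIGHT)
    x, lo, hi, xs, logdc = _cond_dist(table)
    mean = (xs * _pmf(res.odds_ratio, xs, logdc)).sum()
    assert mean == pytest.approx(x, abs=1e-8)


def test_degenerate_margin_reports_missing_or():
    res = fisher_exact_2x2(np.array([[0, 0], [5, 3]]))
    assert res.p_value == 1.0
    assert res.odds_ratio is None
    assert res.ci_low is None


def test_zero_cell_gives_boundary_estimate_and_onesided_ci():
    res = fisher_exact_2x2(np.array([[0, 8], [7, 2]]))
    assert res.odds_ratio == 0.0
    assert res.ci_low == 0.0
    assert np.isfinite(res.ci_high)


def test_p_value_agrees_with_scipy_point_probability_rule():
    rng = np.random.default_rng(0)
    for _ in range(25):
        t = rng.integers(0, 15, size=(2, 2))
        if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
            continue
        assert fisher_exact_2x2(t).p_value == pytest.approx(
            stats.fisher_exact(t).pvalue, abs=1e-10)


# ---------------------------------------------------------------------------
# chi-squared
# ---------------------------------------------------------------------------

def test_chi_squared_identical_rows():
    stat, df, p = chi_squared(np.array([[5, 5, 5], [5, 5, 5]]))
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert df == 2
    assert p == pytest.approx(1.0)


def test_chi_squared_matches_hand_oracle_on_2x2():
    obs = np.array([[10, 20], [30, 40]], dtype=float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row * col / obs.sum()
    hand = ((obs - expected) ** 2 / expected).sum()
    stat, df, p = chi_squared(obs.astype(int))
    assert stat == pytest.approx(hand)
    assert df == 1


def test_chi_squared_drops_zero_columns_and_warns_small_expected():
    with pytest.warns(UserWarning, match="zero-sum"):
        stat, df, p = chi_squared(np.array([[3, 0, 9], [4, 0, 2]]))
    assert df == 1
    with pytest.warns(UserWarning, match="expected"):
        chi_squared(np.array([[1, 9], [2, 8]]))


# ---------------------------------------------------------------------------
# Welch t
# ---------------------------------------------------------------------------

def test_welch_identical_samples():
    t, df, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert t == 0.0
    assert p == pytest.approx(1.0)


def test_welch_matches_textbook_formula():
    rng = np.random.default_rng(1)
    a, b = rng.normal(0, 1, 12), rng.normal(0.8, 2, 9)
    t, df, p = welch_t(a, b)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t_hand = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df_hand = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    assert t == pytest.approx(t_hand)
    assert df == pytest.approx(df_hand)
    assert p == pytest.approx(2 * stats.t.sf(abs(t_hand), df_hand))


def test_welch_rejects_tiny_samples():
    with pytest.raises(ValueError, match="at least 2"):
        welch_t([1.0], [2.0, 3.0])


# ---------------------------------------------------------------------------
# pixel counts
# ---------------------------------------------------------------------------

def drawings_with_counts(counts, group):
    out = []
    for i, c in enumerate(counts):
        marks = np.zeros(600, dtype=bool)
        marks[:c] = True
        out.append(make_tiny_drawing(marks.reshape(20, 30),
                                     drawing_id=f"{group}{i}", group=group))
    return out


def test_identical_count_multisets_are_not_distinguished():
    a = drawings_with_counts([10, 50, 200], "a")
    b = drawings_with_counts([10, 50, 200], "b")
    s = pixel_count_comparison(a, b)
    assert s.t_p == pytest.approx(1.0)
    assert s.rank_sum_p > 0.9


def test_log10_summaries_hand_example():
    s = pixel_count_comparison(drawings_with_counts([10, 100], "a"),
                               drawings_with_counts([10, 100], "b"))
    assert sorted(s.log10_a.tolist()) == [1.0, 2.0]
    assert s.summary_a["mean"] == pytest.approx(1.5)
    assert s.summary_a["sd"] == pytest.approx(np.sqrt(0.5), abs=1e-4)


def test_rank_sum_matches_bruteforce_ranks():
    rng = np.random.default_rng(4)
    ca = list(rng.integers(1, 500, size=9))
    cb = list(rng.integers(1, 500, size=7))
    cb[0] = ca[0]  # force a tie -> midranks
    s = pixel_count_comparison(drawings_with_counts(ca, "a"),
                               drawings_with_counts(cb, "b"))
    pooled = [np.log10(v) for v in ca + cb]
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        midrank = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = midrank
        i = j + 1
    w_hand = sum(ranks[: len(ca)])
    assert s.rank_sum_w == pytest.approx(w_hand)
    assert s.u_statistic == pytest.approx(w_hand - len(ca) * (len(ca) + 1) / 2)


def test_zero_count_drawings_are_excluded_with_warning():
    a = drawings_with_counts([10, 100], "a")
    empty = make_tiny_drawing(np.zeros((20, 30), dtype=bool),
                              drawing_id="a_empty", group="a")
    with pytest.warns(UserWarning, match="zero-count"):
        s = pixel_count_comparison(a + [empty],
                                   drawings_with_counts([20, 80], "b"))
    assert s.n_excluded == 1
    assert len(s.log10_a) == 2


# ---------------------------------------------------------------------------
# questionnaire battery
# ---------------------------------------------------------------------------

def test_questionnaire_summary_percentages_and_tests():
    report = questionnaire_summary(load_questionnaire_counts())
    rows = report.set_index("question")
    assert rows.loc["q1_suitability", "pct_yes"] == pytest.approx(89.58)
    assert rows.loc["q2_sexless", "pct_yes_sexless"] == pytest.approx(63.64)
    assert rows.loc["q1_suitability", "test"] == "fisher"
    assert rows.loc["q3_features", "test"] == "chi-squared"
    # no-opinion answers are dropped before testing q4/q5
    assert rows.loc["q4_importance", "n_tested"] == 43
    assert rows.loc["q5_disturbance", "n_tested"] == 38


def test_questionnaire_skips_tables_empty_after_drop():
    tables = {
        "all_no_opinion": ContingencyTable(
            row_labels=["a", "b"], col_labels=["yes", "no", "no opinion"],
            counts=[[0, 0, 5], [0, 0, 4]]),
    }
    report = questionnaire_summary(tables)
    assert report.loc[0, "test"] == "skipped"
    assert "no opinion" in report.loc[0, "note"]
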