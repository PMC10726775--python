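"""Ruzicka similarity, pain profiles, and pairwise structure."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from paindraw import (build_profile, export_boxplots, export_heatmap,
                      pairwise_similarity, ruzicka, summarize_groups)

from conftest import make_tiny_drawing

nonneg_vectors = arrays(float, st.integers(1, 20),
                        elements=st.floats(0, 10, allow_nan=False,
                                           width=32)).map(np.abs)


def brute_force_ruzicka(x, y):
    """Independent elementwise oracle: explicit loop over pixels."""
    num = den = 0.0
    for xi, yi in zip(np.ravel(x), np.ravel(y)):
        num += min(xi, yi)
        den += max(xi, yi)
    return num / den if den else 1.0


# ---------------------------------------------------------------------------
# ruzicka
# ---------------------------------------------------------------------------

def test_ruzicka_hand_example():
    assert ruzicka(np.array([1.0, 0.0, 0.5]),
                   np.array([0.5, 0.0, 1.0])) == pytest.approx(0.5)


def test_ruzicka_identity_and_disjoint():
    x = np.array([0.2, 0.0, 0.7])
    assert ruzicka(x, x) == 1.0
    assert ruzicka(np.array([1.0, 0.0]), np.array([0.0, 2.0])) == 0.0


def test_ruzicka_empty_inputs_warn_and_return_one():
    with pytest.warns(UserWarning, match="all-zero"):
        assert ruzicka(np.zeros(4), np.zeros(4)) == 1.0


def test_ruzicka_rejects_negative_and_mismatched():
    with pytest.raises(ValueError, match="nonnegative"):
        ruzicka(np.array([-1.0, 0.0]), np.array([0.0, 1.0]))
    with pytest.raises(ValueError, match="shape"):
        ruzicka(np.zeros(3), np.zeros(4))


@settings(max_examples=200, derandomize=True, deadline=None)
@given(nonneg_vectors, st.data())
def test_ruzicka_matches_bruteforce_and_is_symmetric(x, data):
    y = data.draw(arrays(float, len(x),
                         elements=st.floats(0, 10, allow_nan=False,
                                            width=32)).map(np.abs))
    if np.maximum(x, y).sum() == 0:
        return
    r = ruzicka(x, y)
    assert r == pytest.approx(brute_force_ruzicka(x, y), abs=1e-12)
    assert r == pytest.approx(ruzicka(y, x), abs=0)
    assert 0.0 <= r <= 1.0


@settings(max_examples=100, derandomize=True, deadline=None)
@given(arrays(bool, st.integers(1, 20)), st.data())
def test_ruzicka_equals_jaccard_on_binary(x, data):
    y = data.draw(arrays(bool, len(x)))
    if not (x | y).any():
        return
    jaccard = (x & y).sum() / (x | y).sum()
    assert ruzicka(x.astype(float), y.astype(float)) == pytest.approx(jaccard)


@settings(max_examples=100, derandomize=True, deadline=None)
@given(arrays(bool, 15), arrays(bool, 15), st.integers(0, 14))
def test_ruzicka_monotonicity(x, y, idx):
    """A commonly-added pixel never lowers RZI; a one-sided one never raises it."""
    if not (x | y).any():
        return
    base = ruzicka(x.astype(float), y.astype(float))
    both_x, both_y = x.copy(), y.copy()
    both_x[idx] = both_y[idx] = True
    assert ruzicka(both_x.astype(float), both_y.astype(float)) >= base - 1e-12
    one_x = x.copy()
    one_x[idx] = True
    if not y[idx]:
        assert ruzicka(one_x.astype(float), y.astype(float)) <= base + 1e-12


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

def test_profile_of_single_drawing_is_its_raster():
    d = make_tiny_drawing([[1, 0], [0, 1]])
    prof = build_profile([d])
    assert np.array_equal(prof.proportions, d.marks.astype(float))
    assert prof.n == 1


def test_profile_halves_a_uniquely_marked_pixel():
    d1 = make_tiny_drawing([[1, 1]])
    d2 = make_tiny_drawing([[1, 0]])
    prof = build_profile([d1, d2])
    assert prof.proportions.tolist() == [[1.0, 0.5]]


def test_profile_of_identical_drawings_is_idempotent():
    ds = [make_tiny_drawing([[1, 0, 1]]) for _ in range(5)]
    assert np.array_equal(build_profile(ds).proportions,
                          ds[0].marks.astype(float))


def test_profile_conserves_mass():
    rng = np.random.default_rng(0)
    ds = [make_tiny_drawing(rng.random((6, 6)) < 0.4) for _ in range(7)]
    prof = build_profile(ds)
    assert prof.proportions.sum() * prof.n == pytest.approx(
        sum(d.n_marked for d in ds))


def test_profile_rejects_empty_and_mixed_templates():
    with pytest.raises(ValueError, match="empty"):
        build_profile([])
    a = make_tiny_drawing([[1]], template_id="t1")
    b = make_tiny_drawing([[1, 0]], template_id="t2")
    with pytest.raises(ValueError, match="shape"):
        build_profile([a, b])


# ---------------------------------------------------------------------------
# pairwise similarity + summaries
# ---------------------------------------------------------------------------

def test_pairwise_identical_drawings_give_all_ones():
    ds = [make_tiny_drawing([[1, 1, 0]], drawing_id=f"d{i}") for i in range(3)]
    m = pairwise_similarity(ds)
    assert np.allclose(m.values, 1.0)


def test_pairwise_disjoint_drawings_give_zero_offdiagonal():
    a = make_tiny_drawing([[1, 0]], drawing_id="a")
    b = make_tiny_drawing([[0, 1]], drawing_id="b")
    m = pairwise_similarity([a, b])
    assert m.values[0, 1] == 0.0
    assert m.values[0, 0] == 1.0


def test_pairwise_matches_bruteforce_jaccard_oracle():
    rng = np.random.default_rng(11)
    ds = [make_tiny_drawing(rng.random((4, 5)) < 0.5, drawing_id=f"d{i}",
                            group="a" if i < 3 else "b") for i in range(6)]
    m = pairwise_similarity(ds)
    by_id = {d.drawing_id: d for d in ds}
    for i, idi in enumerate(m.drawing_ids):
        for j, idj in enumerate(m.drawing_ids):
            expected = brute_force_ruzicka(by_id[idi].marks.astype(float),
                                           by_id[idj].marks.astype(float))
            assert m.values[i, j] == pytest.approx(expected, abs=1e-12)


def test_pairwise_orders_group_blocks():
    ds = [make_tiny_drawing([[1]], drawing_id=f"d{i}",
                            group="b" if i % 2 else "a") for i in range(4)]
    m = pairwise_similarity(ds)
    assert m.group_labels == ["a", "a", "b", "b"]


def test_group_summary_identical_within_disjoint_between():
    ds = ([make_tiny_drawing([[1, 0]], drawing_id=f"a{i}", group="A")
           for i in range(3)]
          + [make_tiny_drawing([[0, 1]], drawing_id=f"b{i}", group="B")
             for i in range(2)])
    s = summarize_groups(pairwise_similarity(ds))
    assert s.classes["within_A"]["mean"] == 1.0
    assert s.classes["within_B"]["mean"] == 1.0
    assert s.classes["between"]["mean"] == 0.0
    assert s.classes["within_A"]["n_pairs"] == 3
    assert s.classes["within_B"]["n_pairs"] == 1
    assert s.classes["between"]["n_pairs"] == 6


def test_group_summary_duplicated_cohort_is_symmetric():
    rng = np.random.default_rng(2)
    base = [rng.random((3, 3)) < 0.5 for _ in range(3)]
    ds = ([make_tiny_drawing(b, drawing_id=f"a{i}", group="A")
           for i, b in enumerate(base)]
          + [make_tiny_drawing(b, drawing_id=f"b{i}", group="B")
             for i, b in enumerate(base)])
    s = summarize_groups(pairwise_similarity(ds))
    assert sorted(s.pair_values["within_A"]) == sorted(s.pair_values["within_B"])


def test_group_summary_matches_bruteforce_recomputation():
    rng = np.random.default_rng(9)
    ds = [make_tiny_drawing(rng.random((5, 5)) < 0.4, drawing_id=f"d{i}",
                            group="A" if i < 4 else "B") for i in range(7)]
    m = pairwise_similarity(ds)
    s = summarize_groups(m)
    vals = []
    for i in range(4):
        for j in range(i + 1, 4):
            vals.append(brute_force_ruzicka(ds[i].marks.astype(float),
                                            ds[j].marks.astype(float)))
    assert s.classes["within_A"]["mean"] == pytest.approx(np.mean(vals))
    assert s.classes["within_A"]["sd"] == pytest.approx(np.std(vals, ddof=1))
    assert s.classes["within_A"]["median"] == pytest.approx(np.median(vals))


def test_group_summary_single_member_group_reports_missing():
    ds = [make_tiny_drawing([[1]], drawing_id="a", group="A"),
          make_tiny_drawing([[1]], drawing_id="b1", group="B"),
          make_tiny_drawing([[1]], drawing_id="b2", group="B")]
    s = summarize_groups(pairwise_similarity(ds))
    assert s.classes["within_A"] is None
    assert s.classes["within_B"] is not None


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def test_exports_are_deterministic_and_handle_extremes(tmp_path):
    ds = ([make_tiny_drawing([[1, 0]], drawing_id=f"a{i}", group="A")
           for i in range(2)]
          + [make_tiny_drawing([[0, 1]], drawing_id=f"b{i}", group="B")
             for i in range(2)])
    m = pairwise_similarity(ds)  # contains exact zeros -> log floor path
    s = summarize_groups(m)
    h1, h2 = tmp_path / "h1.png", tmp_path / "h2.png"
    export_heatmap(m, h1)
    export_heatmap(m, h2)
    assert h1.read_bytes() == h2.read_bytes()
    b1, b2 = tmp_path / "b1.png", tmp_path / "b2.png"
    export_boxplots(s, b1)
    export_boxplots(s, b2)
    assert b1.read_bytes() == b2.read_bytes()

    ones = [make_tiny_drawing([[1, 1]], drawing_id=f"c{i}", group="A" if i < 2 else "B")
            for i in range(4)]
    export_heatmap(pairwise_similarity(ones), tmp_path / "const.png")
    assert (tmp_path / "const.png").exists()
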