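"""MRMR ranking, top-fraction retention and correlation filtering."""

import numpy as np
import pandas as pd
import pytest

from petfuse.select import (
    correlation_filter,
    discretize_feature,
    mrmr_rank,
    mutual_information,
    select_features,
    select_top_fraction,
)


def _binary_table(n=12, seed=0):
    """12-row table: A perfectly predictive, B = copy of A, C = noise."""
    rng = np.random.default_rng(seed)
    labels = np.array([0, 1] * (n // 2))
    a = labels.astype(float)
    b = a.copy()
    c = rng.normal(size=n)
    return pd.DataFrame({"A": a, "B": b, "C": c}), labels


def test_single_feature_ranked_first_with_its_mi():
    labels = np.array([0, 0, 1, 1, 0, 1, 0, 1, 1, 0])
    x = labels.astype(float)
    table = pd.DataFrame({"only": x})
    ranking, scores, relevance = mrmr_rank(table, labels)
    assert ranking == ["only"]
    expected = mutual_information(discretize_feature(x), labels)
    assert scores["only"] == pytest.approx(expected)
    assert relevance["only"] == pytest.approx(1.0)  # perfectly predictive: H(label)=1 bit


def test_duplicate_feature_penalized_below_noise():
    table, labels = _binary_table()
    ranking, scores, relevance = mrmr_rank(table, labels)
    assert ranking[0] == "A"  # tie with B broken by column order
    da, db, dc = (discretize_feature(table[c].to_numpy()) for c in "ABC")
    score_b = relevance["B"] - mutual_information(db, da)
    score_c = relevance["C"] - mutual_information(dc, da)
    assert score_b <= score_c


def test_row_permutation_leaves_ranking_unchanged():
    table, labels = _binary_table()
    r1, _, _ = mrmr_rank(table, labels)
    perm = np.random.default_rng(5).permutation(len(table))
    r2, _, _ = mrmr_rank(table.iloc[perm].reset_index(drop=True), labels[perm])
    assert r1 == r2


def test_constant_feature_never_first_all_constant_raises():
    labels = np.array([0, 1, 0, 1, 0, 1])
    table = pd.DataFrame({"const": np.ones(6), "real": labels.astype(float)})
    ranking, scores, relevance = mrmr_rank(table, labels)
    assert ranking[0] == "real"
    assert relevance["const"] == 0.0
    with pytest.raises(ValueError):
        mrmr_rank(pd.DataFrame({"c1": np.ones(6), "c2": np.zeros(6)}), labels)


@pytest.mark.parametrize(
    "n_features,fraction,expected",
    [(215, 0.10, 21), (10, 1.0, 10), (7, 0.10, 1)],
)
def test_top_fraction_counts(n_features, fraction, expected):
    ranking = [f"f{i}" for i in range(n_features)]
    assert len(select_top_fraction(ranking, fraction)) == expected


def test_top_fraction_empty_ranking_rejected():
    with pytest.raises(ValueError):
        select_top_fraction([], 0.1)


def test_identical_columns_keep_only_first():
    x = np.arange(6.0)
    table = pd.DataFrame({"A": x, "B": x.copy()})
    assert correlation_filter(table, ["A", "B"], 0.30) == ["A"]


def test_orthogonal_columns_all_kept():
    table = pd.DataFrame(
        {"A": [1, 1, -1, -1], "B": [1, -1, 1, -1], "C": [1, -1, -1, 1]}, dtype=float
    )
    r = table.corr().to_numpy()
    assert np.allclose(r - np.eye(3), 0, atol=1e-12)
    assert correlation_filter(table, ["A", "B", "C"], 0.30) == ["A", "B", "C"]


def test_constructed_correlations_keep_a_and_c():
    """Pairwise r = {AB: 0.5, AC: 0.1, BC: 0.1} -> kept {A, C} at r < 0.3."""
    rng = np.random.default_rng(7)
    basis, _ = np.linalg.qr(rng.normal(size=(6, 3)))
    e0, e1, e2 = basis.T
    e0 = e0 - e0.mean()
    e1 = e1 - e1.mean() - e0 * (e0 @ e1) / (e0 @ e0)
    e2 = e2 - e2.mean() - e0 * (e0 @ e2) / (e0 @ e0) - e1 * (e1 @ e2) / (e1 @ e1)
    e0, e1, e2 = (e / np.linalg.norm(e) for e in (e0, e1, e2))
    a = e0
    b = 0.5 * e0 + np.sqrt(1 - 0.25) * e1
    g2 = (0.1 - 0.5 * 0.1) / np.sqrt(0.75)
    c = 0.1 * e0 + g2 * e1 + np.sqrt(1 - 0.01 - g2**2) * e2
    table = pd.DataFrame({"A": a, "B": b, "C": c})
    r = table.corr()
    assert r.loc["A", "B"] == pytest.approx(0.5, abs=1e-9)
    assert r.loc["A", "C"] == pytest.approx(0.1, abs=1e-9)
    assert r.loc["B", "C"] == pytest.approx(0.1, abs=1e-9)
    assert correlation_filter(table, ["A", "B", "C"], 0.30) == ["A", "C"]


def test_zero_variance_feature_dropped_but_not_blocking():
    table = pd.DataFrame({"Z": np.ones(6), "A": np.arange(6.0)})
    assert correlation_filter(table, ["Z", "A"], 0.30) == ["A"]


def test_full_selection_contract_on_synthetic_table(rng):
    """215-feature table: final set <= 21 features, all pairwise |r| < 0.30."""
    n = 60
    labels = np.array(["control"] * 30 + ["demented"] * 30)
    signal = (labels == "demented").astype(float)
    cols = {}
    for i in range(215):
        w = rng.random() * 0.5
        cols[f"f{i:03d}"] = w * signal + rng.normal(0, 1, n)
    table = pd.DataFrame(cols)
    res = select_features(table, labels, fraction=0.10, r_threshold=0.30)
    assert len(res.retained_after_mrmr) == 21
    assert len(res.final_features) <= 21
    assert set(res.final_features) <= set(res.retained_after_mrmr)
    r = table[res.final_features].corr().to_numpy()
    off = r[~np.eye(len(r), dtype=bool)]
    assert (np.abs(off) < 0.30).all()
    # determinism
    res2 = select_features(table, labels, fraction=0.10, r_threshold=0.30)
    assert res.final_features == res2.final_features


def test_duplicated_column_does_not_change_surviving_originals():
    rng = np.random.default_rng(3)
    n = 40
    labels = np.array([0, 1] * (n // 2))
    table = pd.DataFrame(
        {f"f{i}": 0.5 * i / 10 * labels + rng.normal(0, 1, n) for i in range(10)}
    )
    base = select_features(table, labels, fraction=1.0, r_threshold=0.30)
    dup = table.copy()
    dup["f0_copy"] = table["f0"].to_numpy()
    with_dup = select_features(dup, labels, fraction=1.0, r_threshold=0.30)
    originals = [f for f in with_dup.final_features if f != "f0_copy"]
    assert set(originals) == set(base.final_features)
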