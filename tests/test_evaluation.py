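"""Confusion/metrics definitions and the cohort rank statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as _st

from panmorph import (
    confusion,
    correlate,
    kruskal_wallis,
    load_species_table,
    metrics,
    pairwise_contrasts,
    species_table_summaries,
)
from panmorph.evaluation import PRED_COLUMNS


def pairs_from_counts(counts):
    """counts: dict (true, pred) -> n  ->  long-format pair table."""
    rows = []
    for (t, p), n in counts.items():
        rows += [{"true_cls": t, "pred_cls": p}] * n
    return pd.DataFrame(rows)


def test_confusion_conserves_counts():
    pairs = pairs_from_counts(
        {("cancer", "cancer"): 8, ("cancer", "missed"): 2, ("lymphocyte", "other"): 5}
    )
    cm = confusion(pairs)
    assert cm.values.sum() == 15
    assert list(cm.columns) == list(PRED_COLUMNS)


def test_perfect_predictions_diagonal():
    pairs = pairs_from_counts(
        {(c, c): 10 for c in ("cancer", "lymphocyte", "stromal")}
    )
    cm = confusion(pairs)
    assert np.trace(cm.iloc[:, :3].values) == 30
    rep = metrics(cm)
    assert rep.overall_bcacc == pytest.approx(1.0)
    assert all(m["f1"] == pytest.approx(1.0) for m in rep.per_class.values())


def test_all_predicted_other():
    pairs = pairs_from_counts({(c, "other"): 5 for c in ("cancer", "lymphocyte", "stromal")})
    cm = confusion(pairs)
    assert cm["other"].sum() == 15
    assert cm.iloc[:, :3].values.sum() == 0


def test_everything_predicted_cancer_forces_bcacc_half():
    pairs = pairs_from_counts(
        {("cancer", "cancer"): 10, ("lymphocyte", "cancer"): 10, ("stromal", "cancer"): 10}
    )
    rep = metrics(confusion(pairs))
    m = rep.per_class["cancer"]
    assert m["sensitivity"] == pytest.approx(1.0)
    assert m["specificity"] == pytest.approx(0.0)
    assert m["bcacc"] == pytest.approx(0.5)


def test_hand_confusion_bcacc():
    """3x3 confusion [[8,1,1],[2,7,1],[1,1,8]]: BCAcc_cancer = 0.825."""
    cm = confusion(
        pairs_from_counts(
            {
                ("cancer", "cancer"): 8, ("cancer", "lymphocyte"): 1, ("cancer", "stromal"): 1,
                ("lymphocyte", "cancer"): 2, ("lymphocyte", "lymphocyte"): 7, ("lymphocyte", "stromal"): 1,
                ("stromal", "cancer"): 1, ("stromal", "lymphocyte"): 1, ("stromal", "stromal"): 8,
            }
        )
    )
    rep = metrics(cm)
    assert rep.per_class["cancer"]["bcacc"] == pytest.approx((0.8 + (1 - 3 / 20)) / 2)


def test_missing_class_excluded_with_warning():
    pairs = pairs_from_counts({("cancer", "cancer"): 5, ("lymphocyte", "lymphocyte"): 5})
    with pytest.warns(UserWarning, match="stromal"):
        rep = metrics(confusion(pairs))
    assert rep.undefined_classes == ["stromal"]
    assert set(rep.per_class) == {"cancer", "lymphocyte"}


def test_empty_confusion_errors():
    with pytest.raises(ValueError, match="no annotation"):
        confusion(pd.DataFrame(columns=["true_cls", "pred_cls"]))


def test_random_classifier_bcacc_near_half(rng):
    classes = ("cancer", "lymphocyte", "stromal")
    true = rng.choice(classes, size=6000)
    pred = rng.choice(classes, size=6000)
    rep = metrics(confusion(pd.DataFrame({"true_cls": true, "pred_cls": pred})))
    assert rep.overall_bcacc == pytest.approx(0.5, abs=0.02)


# --- Kruskal-Wallis --------------------------------------------------------


def test_kw_hand_case_no_ties():
    res = kruskal_wallis([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3, n_boot=0)
    assert res.H == pytest.approx(3.857, abs=1e-3)
    assert res.df == 1


def test_kw_all_constant_is_zero():
    res = kruskal_wallis([5.0] * 6, ["a", "a", "b", "b", "c", "c"], n_boot=0)
    assert res.H == 0.0


def test_kw_matches_scipy_with_ties(rng):
    vals = rng.integers(0, 4, size=30).astype(float)
    groups = rng.choice(["a", "b", "c"], size=30)
    res = kruskal_wallis(vals, groups, n_boot=0)
    ref = _st.kruskal(*[vals[groups == g] for g in ("a", "b", "c")])
    assert res.H == pytest.approx(ref.statistic)
    assert res.p == pytest.approx(ref.pvalue)


def _oracle_h(values, codes, k):
    """Definition-level H with tie correction, written independently."""
    values = np.asarray(values, float)
    N = len(values)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(N)
    i = 0
    sv = values[order]
    while i < N:
        j = i
        while j < N and sv[j] == sv[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    H = 12 / (N * (N + 1)) * sum(
        ranks[codes == g].sum() ** 2 / (codes == g).sum() for g in range(k)
    ) - 3 * (N + 1)
    ties = sum(
        (np.sum(sv == u) ** 3 - np.sum(sv == u)) for u in np.unique(sv)
    )
    denom = 1 - ties / (N**3 - N)
    return 0.0 if denom == 0 else H / denom


def test_kw_exhaustive_small_n():
    """H agrees with a from-definition oracle on every dataset with N <= 8."""
    checked = 0
    for N in (4, 6, 8):
        for values in itertools.product((0.0, 1.0, 2.0), repeat=N):
            codes = np.array([0] * (N // 2) + [1] * (N - N // 2))
            res = kruskal_wallis(values, codes, n_boot=0)
            assert res.H == pytest.approx(_oracle_h(values, codes, 2), abs=1e-10)
            checked += 1
    assert checked == 3**4 + 3**6 + 3**8


def test_kw_bootstrap_ci_brackets_estimate():
    df = load_species_table()
    res = kruskal_wallis(df["bcacc"], df["tumour_type"], n_boot=500, seed=0)
    lo, hi = res.eta_sq_ci
    assert lo < hi
    assert res.eta_sq == pytest.approx((res.H - 4) / 15)


# --- contrasts -------------------------------------------------------------


def test_contrasts_identical_groups():
    out = pairwise_contrasts([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
    (c,) = out
    assert c.estimate == pytest.approx(0.0)
    assert c.ci[0] <= 0 <= c.ci[1]
    assert not c.significant


def test_contrasts_forced_separation():
    vals = [1, 2, 3, 4, 5, 101, 102, 103, 104, 105]
    out = pairwise_contrasts(vals, ["a"] * 5 + ["b"] * 5)
    (c,) = out
    assert c.significant
    assert c.p_adj < 0.05
    assert not (c.ci[0] <= 0 <= c.ci[1])


def test_contrast_estimates_are_mean_rank_differences(rng):
    vals = rng.normal(size=15)
    groups = np.repeat(["a", "b", "c"], 5)
    ranks = _st.rankdata(vals)
    expected = {
        (a, b): ranks[groups == a].mean() - ranks[groups == b].mean()
        for a, b in itertools.combinations(("a", "b", "c"), 2)
    }
    for c in pairwise_contrasts(vals, groups):
        assert c.estimate == pytest.approx(expected[(c.group_a, c.group_b)])


# --- correlations ----------------------------------------------------------


def test_correlate_identity():
    x = [1.0, 2.0, 3.0, 4.0]
    for method in ("spearman", "pearson"):
        assert correlate(x, x, method).rho == pytest.approx(1.0)


def test_correlate_rank_monotone():
    x = np.arange(1.0, 11.0)
    y = x**2
    assert correlate(x, y, "spearman").rho == pytest.approx(1.0)
    assert correlate(x, y, "pearson").rho < 1.0


def test_correlate_zero_variance_errors():
    with pytest.raises(ValueError, match="zero-variance"):
        correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# --- cohort summaries ------------------------------------------------------


def test_species_summaries_headline_counts():
    s = species_table_summaries(load_species_table(), n_boot=0)
    assert s["n_bcacc_ge_070"] == 19
    assert s["n_bcacc_ge_080"] == 12
    assert s["mean_bcacc"] == pytest.approx(0.815)
    assert (s["min_bcacc"], s["max_bcacc"]) == (0.57, 0.94)
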