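"""Classifier scoring and cohort-level statistics.

Predictions are scored against pathologist annotations through a confusion
matrix whose rows are the three annotated classes (cancer, lymphocyte,
stromal) and whose columns add an ``other`` prediction column and a
``missed`` pseudo-column for annotations with no detected cell nearby.
Balanced classification accuracy (BCAcc) per class is the mean of
one-vs-rest sensitivity and specificity; the overall BCAcc averages the
three per-class values.

Cohort statistics: tie-corrected Kruskal–Wallis with the rank
epsilon-squared effect size ``(H - k + 1)/(N - k)`` and a bootstrap CI,
rank-based pairwise z contrasts with Benjamini–Hochberg adjustment, and
Spearman/Pearson correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st
from statsmodels.stats.multitest import multipletests

from .datamodel import CORE_CLASSES, SlideTable
from .morphometry import Pairing

PRED_COLUMNS: tuple[str, ...] = ("cancer", "lymphocyte", "stromal", "other", "missed")


def confusion(pairs: pd.DataFrame) -> pd.DataFrame:
    """Confusion matrix from matched (true, predicted) class pairs.

    ``pairs`` needs columns ``true_cls`` and ``pred_cls``; ``pred_cls``
    may be ``"missed"`` for annotations without a matched detection.
    Rows are the three annotated classes, columns the four prediction
    classes plus ``missed``; counts conserve the number of annotations.
    """
    if len(pairs) == 0:
        raise ValueError("no annotation/prediction pairs to score")
    bad = set(pairs["true_cls"]) - set(CORE_CLASSES)
    if bad:
        raise ValueError(f"annotations must be one of {CORE_CLASSES}; got {sorted(bad)}")
    bad = set(pairs["pred_cls"]) - set(PRED_COLUMNS)
    if bad:
        raise ValueError(f"unknown predicted label(s): {sorted(bad)}")
    cm = pd.crosstab(pairs["true_cls"], pairs["pred_cls"])
    cm = cm.reindex(index=CORE_CLASSES, columns=PRED_COLUMNS, fill_value=0)
    cm.index.name = "true"
    cm.columns.name = "predicted"
    return cm


def confusion_from_matching(
    annotations: SlideTable,
    predictions: SlideTable,
    pairing: Pairing,
    pred_classes: Mapping | None = None,
) -> pd.DataFrame:
    """Build the confusion matrix from a centroid matching.

    ``pairing.matches["cell_label"]`` must identify prediction records:
    either via ``pred_classes`` (label -> class) or, by default, by
    prediction ``cell_id``.
    """
    if pred_classes is None:
        pred_classes = {c.cell_id: c.cls for c in predictions.cells}
    true_cls = {c.cell_id: c.cls for c in annotations.cells}
    rows = [
        {"true_cls": true_cls[m.annotation_id], "pred_cls": pred_classes[m.cell_label]}
        for m in pairing.matches.itertuples(index=False)
    ]
    rows += [
        {"true_cls": true_cls[a], "pred_cls": "missed"}
        for a in pairing.unmatched_annotations
    ]
    return confusion(pd.DataFrame(rows))


@dataclass
class MetricsReport:
    """Per-class and overall classification metrics.

    ``per_class`` maps each annotated class to a dict with sensitivity,
    specificity, precision, f1 and bcacc; ``overall_bcacc`` is the
    arithmetic mean of the available per-class BCAcc values.
    """

    per_class: dict[str, dict[str, float]]
    overall_bcacc: float
    confusion: pd.DataFrame
    undefined_classes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_class": self.per_class,
            "overall_bcacc": self.overall_bcacc,
            "confusion": self.confusion.to_dict(),
            "undefined_classes": self.undefined_classes,
        }


def metrics(cm: pd.DataFrame) -> MetricsReport:
    """One-vs-rest metrics from a confusion matrix.

    Misses and ``other`` predictions count against the sensitivity of the
    true class; neither is a positive prediction for any annotated class,
    so both land among the negatives of every one-vs-rest split.  A class
    with zero annotated cells is reported as undefined and excluded from
    the overall mean, with a warning.
    """
    total = float(cm.values.sum())
    per_class: dict[str, dict[str, float]] = {}
    undefined: list[str] = []
    for c in CORE_CLASSES:
        pos = float(cm.loc[c].sum())
        if pos == 0:
            undefined.append(c)
            continue
        tp = float(cm.loc[c, c])
        fp = float(cm[c].sum() - tp)  # predictions of c on other true classes
        fn = pos - tp
        tn = total - pos - fp
        sens = tp / pos
        spec = tn / (tn + fp) if (tn + fp) > 0 else np.nan
        prec = tp / (tp + fp) if (tp + fp) > 0 else 0.0
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
        per_class[c] = {
            "sensitivity": sens,
            "specificity": spec,
            "precision": prec,
            "f1": f1,
            "bcacc": (sens + spec) / 2.0,
        }
    if undefined:
        warnings.warn(
            f"class(es) without annotations excluded from overall BCAcc: {undefined}",
            stacklevel=2,
        )
    overall = float(np.mean([m["bcacc"] for m in per_class.values()]))
    return MetricsReport(per_class, overall, cm, undefined)


# --- rank statistics ------------------------------------------------------


@dataclass
class GroupTestResult:
    H: float
    df: int
    p: float
    eta_sq: float
    eta_sq_ci: tuple[float, float] | None
    n: int
    k: int


def _kw_h(values: np.ndarray, codes: np.ndarray, k: int) -> float:
    """Tie-corrected Kruskal–Wallis H; defined as 0 for all-constant data."""
    N = len(values)
    ranks = _st.rankdata(values)
    ss = 0.0
    for g in range(k):
        r = ranks[codes == g]
        ss += r.sum() ** 2 / len(r)
    H = 12.0 / (N * (N + 1)) * ss - 3.0 * (N + 1)
    _, counts = np.unique(values, return_counts=True)
    tie_den = 1.0 - (counts**3 - counts).sum() / (N**3 - N)
    if tie_den == 0.0:  # all observations identical
        return 0.0
    return H / tie_den


def kruskal_wallis(
    values: Sequence[float],
    groups: Sequence,
    n_boot: int = 2000,
    seed: int = 0,
) -> GroupTestResult:
    """Tie-corrected Kruskal–Wallis test with rank epsilon-squared effect size.

    eta_sq = (H - k + 1)/(N - k); its 95% CI comes from a percentile
    bootstrap resampling subjects within groups (``n_boot`` replicates,
    seeded).  Set ``n_boot=0`` to skip the bootstrap.
    """
    values = np.asarray(values, dtype=float)
    labels, codes = np.unique(np.asarray(groups), return_inverse=True)
    k = len(labels)
    N = len(values)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if len(values) != len(codes):
        raise ValueError("values and groups must align")
    H = _kw_h(values, codes, k)
    p = float(_st.chi2.sf(H, k - 1))
    eta = (H - k + 1) / (N - k)
    ci = None
    if n_boot:
        rng = np.random.default_rng(seed)
        idx_by_group = [np.nonzero(codes == g)[0] for g in range(k)]
        boots = np.empty(n_boot)
        for b in range(n_boot):
            take = np.concatenate(
                [rng.choice(ix, size=len(ix), replace=True) for ix in idx_by_group]
            )
            bcodes = np.concatenate(
                [np.full(len(ix), g) for g, ix in enumerate(idx_by_group)]
            )
            Hb = _kw_h(values[take], bcodes, k)
            boots[b] = (Hb - k + 1) / (N - k)
        ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    return GroupTestResult(H=float(H), df=k - 1, p=p, eta_sq=float(eta), eta_sq_ci=ci, n=N, k=k)


@dataclass
class PairwiseContrast:
    group_a: str
    group_b: str
    estimate: float  # mean-rank difference (a - b)
    se: float
    z: float
    p_adj: float
    ci: tuple[float, float]
    significant: bool
    flagged: bool = False  # singleton group → inflated SE


def pairwise_contrasts(
    values: Sequence[float],
    groups: Sequence,
    adjust: str = "fdr_bh",
    alpha: float = 0.05,
) -> list[PairwiseContrast]:
    """Dunn-style rank z contrasts for all group pairs.

    The estimate is the difference in mean ranks; the SE uses the
    tie-corrected Kruskal–Wallis variance.  P values are adjusted with
    Benjamini–Hochberg by default; the CI is estimate ± z_{alpha/2}·SE,
    and a pair is significant iff its CI excludes 0 (equivalently
    p_adj < alpha only before adjustment; significance here follows the
    CI, which is unadjusted, while p values are reported adjusted).
    """
    values = np.asarray(values, dtype=float)
    labels, codes = np.unique(np.asarray(groups), return_inverse=True)
    N = len(values)
    ranks = _st.rankdata(values)
    _, counts = np.unique(values, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (N - 1)) if N > 1 else 0.0
    var_unit = N * (N + 1) / 12.0 - tie_term
    mean_ranks = {g: ranks[codes == i].mean() for i, g in enumerate(labels)}
    sizes = {g: int((codes == i).sum()) for i, g in enumerate(labels)}
    zcrit = float(_st.norm.ppf(1 - alpha / 2))
    raw = []
    for a, b in combinations(labels, 2):
        est = mean_ranks[a] - mean_ranks[b]
        se = float(np.sqrt(var_unit * (1.0 / sizes[a] + 1.0 / sizes[b])))
        z = est / se if se > 0 else 0.0
        pval = 2 * float(_st.norm.sf(abs(z)))
        raw.append((a, b, est, se, z, pval))
    padj = multipletests([r[5] for r in raw], method=adjust)[1] if raw else []
    out = []
    for (a, b, est, se, z, _), pa in zip(raw, padj):
        ci = (est - zcrit * se, est + zcrit * se)
        out.append(
            PairwiseContrast(
                group_a=str(a),
                group_b=str(b),
                estimate=float(est),
                se=se,
                z=float(z),
                p_adj=float(pa),
                ci=ci,
                significant=not (ci[0] <= 0.0 <= ci[1]),
                flagged=sizes[a] < 2 or sizes[b] < 2,
            )
        )
    return out


@dataclass
class CorrelationResult:
    method: str
    rho: float
    p: float
    n: int


def correlate(x: Sequence[float], y: Sequence[float], method: str = "spearman") -> CorrelationResult:
    """Spearman (tie-handled ranks) or Pearson correlation with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    if method == "spearman":
        rho, p = _st.spearmanr(x, y)
    elif method == "pearson":
        rho, p = _st.pearsonr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(method=method, rho=float(rho), p=float(p), n=len(x))


def species_table_summaries(df: pd.DataFrame, n_boot: int = 2000, seed: int = 0) -> dict:
    """Cohort statistics of the bundled 20-species BCAcc table.

    Returns mean/min/max BCAcc, counts of species clearing the 0.70 and
    0.80 accuracy bars, the Kruskal–Wallis test of BCAcc by tumour type,
    and both rank and product-moment correlations of BCAcc with the
    number of annotations.
    """
    kw = kruskal_wallis(df["bcacc"], df["tumour_type"], n_boot=n_boot, seed=seed)
    sp = correlate(df["annotations"], df["bcacc"], "spearman")
    pe = correlate(df["annotations"], df["bcacc"], "pearson")
    return {
        "n_species": int(len(df)),
        "mean_bcacc": float(df["bcacc"].mean()),
        "min_bcacc": float(df["bcacc"].min()),
        "max_bcacc": float(df["bcacc"].max()),
        "n_bcacc_ge_070": int((df["bcacc"] >= 0.70).sum()),
        "n_bcacc_ge_080": int((df["bcacc"] >= 0.80).sum()),
        "kruskal_H": kw.H,
        "kruskal_df": kw.df,
        "kruskal_p": kw.p,
        "eta_sq": kw.eta_sq,
        "eta_sq_ci": kw.eta_sq_ci,
        "spearman_rho": sp.rho,
        "spearman_p": sp.p,
        "pearson_r": pe.rho,
        "pearson_p": pe.p,
    }
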