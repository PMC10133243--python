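"""2-D morphospace embedding and the quantile-box overlap score ("port").

The morphospace is a 2-D t-SNE embedding of per-cell feature vectors.
Overlap between two cell groups A and B is measured dynamic-range-box
style: on each embedding dimension a ladder of central quantile intervals
``[Q_alpha, Q_{1-alpha}]`` is formed for both groups; the per-dimension
score is the mean (over the ladder) fraction of A's interval length covered
by B's interval, and the port score is the product of the two per-dimension
scores.  The score is asymmetric — "how much of A sits inside B" — and
lies in [0, 1].
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

#: default quantile ladder: alpha = 0.00, 0.01, ..., 0.49 (50 levels).
DEFAULT_ALPHAS: tuple[float, ...] = tuple(np.round(np.arange(0, 0.50, 0.01), 2))


@dataclass(frozen=True)
class EmbeddingConfig:
    """t-SNE settings; the defaults are exact-gradient t-SNE, perplexity 50."""

    perplexity: float = 50.0
    dims: int = 2
    seed: int = 0
    standardise: bool = True
    n_iter: int = 500

    def __post_init__(self) -> None:
        if self.dims != 2:
            raise ValueError("morphospace is 2-D by definition")
        if self.perplexity <= 0:
            raise ValueError("perplexity must be positive")


def embed(features: np.ndarray | pd.DataFrame, cfg: EmbeddingConfig = EmbeddingConfig()) -> np.ndarray:
    """Embed an (n, p) feature matrix into 2-D with exact (theta = 0) t-SNE.

    Features are z-scored per dimension first (unless ``cfg.standardise``
    is off), so that large-magnitude features such as area do not dominate
    the distance structure.  Deterministic for a fixed seed.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D array (cells x features)")
    n = X.shape[0]
    n_min = int(np.ceil(3 * cfg.perplexity + 2))
    if n < n_min:
        raise ValueError(
            f"need at least {n_min} cells for perplexity {cfg.perplexity} "
            f"(got {n}); perplexity must be < (n-1)/3"
        )
    if cfg.standardise:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    coords = TSNE(
        n_components=2,
        perplexity=cfg.perplexity,
        method="exact",  # theta = 0: exact gradient, no Barnes-Hut approximation
        random_state=cfg.seed,
        init="pca",
        max_iter=cfg.n_iter,
    ).fit_transform(X)
    return np.asarray(coords, dtype=float)


# --- quantile-box overlap -------------------------------------------------


def _interval(sample: np.ndarray, alpha: float) -> tuple[float, float]:
    return (
        float(np.quantile(sample, alpha)),
        float(np.quantile(sample, 1.0 - alpha)),
    )


def port(
    A: np.ndarray,
    B: np.ndarray,
    alphas: Sequence[float] = DEFAULT_ALPHAS,
) -> float:
    """Fraction of sample A's 2-D morphospace region inside sample B's.

    For each dimension d and ladder level alpha, the score contribution is
    ``|I_alpha(A,d) ∩ I_alpha(B,d)| / |I_alpha(A,d)|``; per-dimension
    scores average over the ladder and the two dimensions multiply.
    A zero-length A-interval (all values equal) scores 1 if that point
    falls inside B's interval and 0 otherwise, with a warning.
    """
    A = np.asarray(A, dtype=float).reshape(-1, 2)
    B = np.asarray(B, dtype=float).reshape(-1, 2)
    if len(A) < 10 or len(B) < 10:
        raise ValueError("port needs at least 10 points per group")
    if not all(0.0 <= a < 0.5 for a in alphas):
        raise ValueError("quantile ladder must lie in [0, 0.5)")
    dim_scores = []
    for d in (0, 1):
        level_scores = []
        for alpha in alphas:
            lo_a, hi_a = _interval(A[:, d], alpha)
            lo_b, hi_b = _interval(B[:, d], alpha)
            if hi_a == lo_a:
                warnings.warn(
                    f"degenerate interval in dimension {d} (all values equal)",
                    stacklevel=2,
                )
                level_scores.append(1.0 if lo_b <= lo_a <= hi_b else 0.0)
                continue
            inter = min(hi_a, hi_b) - max(lo_a, lo_b)
            level_scores.append(max(inter, 0.0) / (hi_a - lo_a))
        dim_scores.append(float(np.mean(level_scores)))
    return float(dim_scores[0] * dim_scores[1])


def port_symmetric(A: np.ndarray, B: np.ndarray, alphas: Sequence[float] = DEFAULT_ALPHAS) -> float:
    """Geometric mean of port(A, B) and port(B, A); a symmetrised variant."""
    return float(np.sqrt(port(A, B, alphas) * port(B, A, alphas)))


@dataclass
class OverlapMatrix:
    """Asymmetric group-by-group overlap; entry [A, B] = fraction of A in B."""

    values: pd.DataFrame
    flagged: list[str] = field(default_factory=list)  # degenerate/small groups

    def __getitem__(self, key: tuple[str, str]) -> float:
        return float(self.values.loc[key[0], key[1]])


MIN_GROUP_SIZE = 10


def overlap_matrix(
    groups: Mapping[str, np.ndarray],
    alphas: Sequence[float] = DEFAULT_ALPHAS,
) -> OverlapMatrix:
    """Full asymmetric port matrix over named 2-D coordinate groups.

    Groups with fewer than 10 members are flagged and their entries left
    NaN rather than fabricated.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    names = list(groups)
    small = [g for g in names if len(np.atleast_2d(groups[g])) < MIN_GROUP_SIZE]
    vals = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    for a, b in itertools.product(names, names):
        if a in small or b in small:
            continue
        vals.loc[a, b] = port(groups[a], groups[b], alphas)
    return OverlapMatrix(values=vals, flagged=small)


#: counterpart pairs entering the per-sample mean overlap: animal cancer
#: against human cancer and animal lymphocytes against human lymphocytes,
#: both directions.
COUNTERPART_PAIRS: tuple[tuple[str, str], ...] = (
    ("a-can", "h-can"),
    ("h-can", "a-can"),
    ("a-lymp", "h-lymp"),
    ("h-lymp", "a-lymp"),
)


def mean_sample_overlap(
    matrix: OverlapMatrix,
    pairs: Sequence[tuple[str, str]] = COUNTERPART_PAIRS,
) -> float:
    """Mean of the counterpart-pair overlaps for one sample.

    With the default pairing rule, this is the mean over the four
    directed animal/human counterpart overlaps (cancer and lymphocyte).
    """
    missing = sorted(
        {g for p in pairs for g in p} - set(matrix.values.index)
    )
    if missing:
        raise ValueError(f"overlap matrix lacks group(s): {missing}")
    vals = [matrix[p] for p in pairs]
    return float(np.mean(vals))
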