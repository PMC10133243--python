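"""End-to-end transfer experiment: morphospace overlap vs transfer accuracy.

For each synthetic species the per-sample morphospace is embedded jointly
over the human reference cells and that species' cells, counterpart
overlaps (animal-vs-human cancer and lymphocyte) are averaged into a mean
sample overlap, and a nearest-centroid classifier trained on the human
cells is scored on the species' cells to give a measured balanced
accuracy.  Across species with varying feature-space separation, mean
overlap and BCAcc should co-vary positively.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestCentroid

from .evaluation import confusion, metrics
from .morphospace import (
    EmbeddingConfig,
    mean_sample_overlap,
    overlap_matrix,
    embed,
)

_GROUP_OF = {
    ("human", "cancer"): "h-can",
    ("human", "lymphocyte"): "h-lymp",
    ("animal", "cancer"): "a-can",
    ("animal", "lymphocyte"): "a-lymp",
}


def score_species(sample: dict, cfg: EmbeddingConfig) -> dict:
    """Mean morphospace overlap and transfer BCAcc for one species sample."""
    X, cls, origin = sample["X"], sample["cls"], sample["origin"]
    coords = embed(X, cfg)
    groups: dict[str, np.ndarray] = {}
    for (orig, c), name in _GROUP_OF.items():
        sel = (origin == orig) & (cls == c)
        groups[name] = coords[sel]
    om = overlap_matrix(groups)
    overlap = mean_sample_overlap(om)

    human = origin == "human"
    clf = NearestCentroid().fit(X[human], cls[human])
    pred = clf.predict(X[~human])
    cm = confusion(pd.DataFrame({"true_cls": cls[~human], "pred_cls": pred}))
    rep = metrics(cm)
    return {
        "species": sample["species"],
        "shift": sample["shift"],
        "mean_overlap": overlap,
        "bcacc": rep.overall_bcacc,
    }


def score_transfer_cohort(cohort: list[dict], cfg: EmbeddingConfig | None = None) -> pd.DataFrame:
    """Score every species of a generated transfer cohort.

    Returns one row per species with its separation (``shift``), mean
    morphospace overlap and measured transfer BCAcc.
    """
    if cfg is None:
        cfg = EmbeddingConfig()
    return pd.DataFrame([score_species(s, cfg) for s in cohort])
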