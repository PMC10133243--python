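"""Per-nucleus morphometric and staining features from label masks.

Given a labelled nuclear mask and a paired grayscale intensity image, one
27-dimensional feature vector is extracted per nucleus: a 14-feature shape
block (region-property style measurements, lengths in µm, areas in µm²)
and a 13-feature intensity block (order statistics, spread, shape of the
within-nucleus intensity histogram on the 0–255 scale).

The feature list is held in a data-driven :class:`FeatureRegistry` whose
content hash is stamped on every output table, so an alternative feature
list can be swapped in without code changes and outputs remain traceable
to the registry that produced them.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st
from scipy.spatial import cKDTree
from skimage import measure

from .datamodel import SlideTable

# floor (in pixels) for the minor axis when forming the aspect ratio, so
# degenerate one-row regions stay finite (a 1-px-wide line has zero second
# moment across its width).
_MINOR_AXIS_FLOOR_PX = 1.0


def _shannon_entropy_256(values: np.ndarray) -> float:
    """Shannon entropy (bits) of the 256-bin intensity histogram."""
    hist, _ = np.histogram(values, bins=256, range=(0, 256))
    p = hist[hist > 0] / hist.sum()
    return float(-(p * np.log2(p)).sum())


def _mad(values: np.ndarray) -> float:
    return float(np.median(np.abs(values - np.median(values))))


# each entry: name -> fn(region, mpp) where mpp is µm per pixel
_SHAPE_FEATURES: dict[str, Callable] = {
    "area": lambda r, s: r.area * s**2,
    "convex_area": lambda r, s: r.area_convex * s**2,
    "filled_area": lambda r, s: r.area_filled * s**2,
    "perimeter": lambda r, s: r.perimeter * s,
    "equivalent_diameter": lambda r, s: r.equivalent_diameter_area * s,
    "major_axis_length": lambda r, s: r.axis_major_length * s,
    "minor_axis_length": lambda r, s: r.axis_minor_length * s,
    "eccentricity": lambda r, s: r.eccentricity,
    "orientation": lambda r, s: r.orientation,
    "solidity": lambda r, s: r.solidity,
    "extent": lambda r, s: r.extent,
    "euler_number": lambda r, s: float(r.euler_number),
    # circularity 4πA/P²; 1 for a disc, → 0 for ragged/elongated shapes
    "circularity": lambda r, s: (
        4.0 * np.pi * r.area / r.perimeter**2 if r.perimeter > 0 else 0.0
    ),
    "aspect_ratio": lambda r, s: r.axis_major_length
    / max(r.axis_minor_length, _MINOR_AXIS_FLOOR_PX),
}

_INTENSITY_FEATURES: dict[str, Callable] = {
    "intensity_mean": lambda v: float(np.mean(v)),
    "intensity_median": lambda v: float(np.median(v)),
    "intensity_min": lambda v: float(np.min(v)),
    "intensity_max": lambda v: float(np.max(v)),
    "intensity_std": lambda v: float(np.std(v)),
    "intensity_mad": _mad,
    "intensity_range": lambda v: float(np.max(v) - np.min(v)),
    "intensity_p25": lambda v: float(np.percentile(v, 25)),
    "intensity_p75": lambda v: float(np.percentile(v, 75)),
    "intensity_iqr": lambda v: float(np.percentile(v, 75) - np.percentile(v, 25)),
    "intensity_skewness": lambda v: (
        float(_st.skew(v)) if v.size > 2 and np.ptp(v) > 0 else 0.0
    ),
    "intensity_kurtosis": lambda v: (
        float(_st.kurtosis(v)) if v.size > 3 and np.ptp(v) > 0 else 0.0
    ),
    "intensity_entropy": _shannon_entropy_256,
}


@dataclass(frozen=True)
class FeatureRegistry:
    """Ordered, named feature set; hashable so outputs can be pinned to it."""

    shape_features: tuple[str, ...] = tuple(_SHAPE_FEATURES)
    intensity_features: tuple[str, ...] = tuple(_INTENSITY_FEATURES)

    def __post_init__(self) -> None:
        names = self.names
        if len(names) != len(set(names)):
            raise ValueError("feature names must be unique")

    @property
    def names(self) -> tuple[str, ...]:
        return self.shape_features + self.intensity_features

    def __len__(self) -> int:
        return len(self.names)

    @property
    def registry_hash(self) -> str:
        return hashlib.sha256("|".join(self.names).encode()).hexdigest()[:12]


DEFAULT_REGISTRY = FeatureRegistry()
assert len(DEFAULT_REGISTRY) == 27


def extract_features(
    mask: np.ndarray,
    intensity: np.ndarray,
    scale: float,
    registry: FeatureRegistry = DEFAULT_REGISTRY,
) -> pd.DataFrame:
    """One feature row per labelled nucleus.

    Parameters
    ----------
    mask : integer label image, 0 = background, k > 0 = nucleus k.
    intensity : grayscale image, same shape, values on the 0–255 scale.
    scale : µm per pixel; lengths scale by ``scale``, areas by ``scale**2``.
    registry : which features to compute, in which order.

    Returns
    -------
    DataFrame indexed by label with columns ``centroid_x``/``centroid_y``
    (µm), the 27 features and a ``registry_hash`` column.  Labels with
    fewer than 3 pixels are skipped with a warning (their moments are
    undefined).
    """
    if mask.shape != intensity.shape:
        raise ValueError("mask and intensity image must have the same shape")
    if not scale > 0:
        raise ValueError("scale must be > 0")
    rows = []
    skipped = []
    for region in measure.regionprops(mask.astype(np.int64), intensity_image=intensity):
        if region.area < 3:
            skipped.append(region.label)
            continue
        vals = region.image_intensity[region.image].astype(float)
        row: dict[str, float] = {
            "label": region.label,
            "centroid_x": region.centroid[1] * scale,
            "centroid_y": region.centroid[0] * scale,
        }
        for name in registry.shape_features:
            row[name] = float(_SHAPE_FEATURES[name](region, scale))
        for name in registry.intensity_features:
            row[name] = float(_INTENSITY_FEATURES[name](vals))
        rows.append(row)
    if skipped:
        warnings.warn(
            f"skipped {len(skipped)} label(s) with <3 pixels: {skipped[:10]}",
            stacklevel=2,
        )
    df = pd.DataFrame(rows).set_index("label") if rows else pd.DataFrame(
        columns=["centroid_x", "centroid_y", *registry.names]
    )
    df["registry_hash"] = registry.registry_hash
    return df


# --- annotation-to-centroid matching -------------------------------------

#: default matching radius: 4 px at the working resolution of 0.456 µm/px
#: (a 0.228 µm/px scan downsampled 2×), i.e. just under 2 µm.
DEFAULT_MATCH_DIST_UM = 4 * 0.456


@dataclass
class Pairing:
    """Result of one-to-one annotation ↔ detected-centroid matching."""

    matches: pd.DataFrame  # columns: annotation_id, cell_label, distance
    unmatched_annotations: list[str] = field(default_factory=list)
    unmatched_cells: list = field(default_factory=list)


def map_annotations_to_cells(
    annotations: SlideTable,
    centroids: pd.DataFrame,
    max_dist: float = DEFAULT_MATCH_DIST_UM,
) -> Pairing:
    """Greedily match annotations to detected centroids within ``max_dist`` µm.

    Candidate pairs within the radius are taken in ascending distance;
    each annotation and each centroid is used at most once.  ``centroids``
    must carry ``centroid_x``/``centroid_y`` columns in µm (the output of
    :func:`extract_features` works directly).

    Returns a :class:`Pairing`; unmatched annotations are listed so the
    evaluation stage can count them as detection misses.
    """
    if not max_dist > 0:
        raise ValueError("max_dist must be > 0")
    ann_ids = [c.cell_id for c in annotations.cells]
    apos = annotations.positions()
    cpos = centroids[["centroid_x", "centroid_y"]].to_numpy(dtype=float)
    clabels = list(centroids.index)
    pairs: list[tuple[float, int, int]] = []
    if len(apos) and len(cpos):
        tree = cKDTree(cpos)
        neighbours = tree.query_ball_point(apos, r=max_dist)
        pairs = sorted(
            (float(np.hypot(*(apos[a] - cpos[c]))), a, c)
            for a, cands in enumerate(neighbours)
            for c in cands
        )
    used_a: set[int] = set()
    used_c: set[int] = set()
    rows = []
    for dist, a, c in pairs:
        if a in used_a or c in used_c:
            continue
        used_a.add(a)
        used_c.add(c)
        rows.append({"annotation_id": ann_ids[a], "cell_label": clabels[c], "distance": dist})
    return Pairing(
        matches=pd.DataFrame(rows, columns=["annotation_id", "cell_label", "distance"]),
        unmatched_annotations=[ann_ids[i] for i in range(len(ann_ids)) if i not in used_a],
        unmatched_cells=[clabels[i] for i in range(len(clabels)) if i not in used_c],
    )
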