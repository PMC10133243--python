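"""Feature extraction closed forms and annotation-centroid matching."""

import itertools

import numpy as np
import pandas as pd
import pytest
from skimage.draw import ellipse

from panmorph import (
    CellRecord,
    DEFAULT_REGISTRY,
    SlideTable,
    extract_features,
    map_annotations_to_cells,
)


def flat_image(shape, value=100):
    return np.full(shape, value, dtype=np.uint8)


def test_registry_has_27_unique_features():
    assert len(DEFAULT_REGISTRY) == 27
    assert len(set(DEFAULT_REGISTRY.names)) == 27
    assert len(DEFAULT_REGISTRY.registry_hash) == 12


def test_rectangle_closed_forms():
    mask = np.zeros((20, 20), dtype=np.uint16)
    mask[3:8, 5:9] = 1  # 5 x 4 filled rectangle
    f = extract_features(mask, flat_image(mask.shape), scale=1.0)
    assert f.loc[1, "area"] == pytest.approx(20.0)
    assert f.loc[1, "extent"] == pytest.approx(1.0)
    assert f.loc[1, "euler_number"] == pytest.approx(1.0)
    assert f.loc[1, "solidity"] == pytest.approx(1.0)


def test_single_row_degenerate_ellipse():
    mask = np.zeros((10, 20), dtype=np.uint16)
    mask[5, 4:14] = 1  # 1 x 10 line
    f = extract_features(mask, flat_image(mask.shape), scale=1.0)
    assert f.loc[1, "aspect_ratio"] > 5
    assert f.loc[1, "eccentricity"] > 0.99
    assert np.isfinite(f.loc[1].drop("registry_hash").astype(float)).all()


def test_rasterised_ellipse_axes_within_5pct():
    mask = np.zeros((120, 120), dtype=np.uint16)
    rr, cc = ellipse(60, 60, 10, 20)
    mask[rr, cc] = 1
    f = extract_features(mask, flat_image(mask.shape), scale=1.0)
    assert f.loc[1, "major_axis_length"] == pytest.approx(40.0, rel=0.05)
    assert f.loc[1, "minor_axis_length"] == pytest.approx(20.0, rel=0.05)


def test_scale_equivariance():
    mask = np.zeros((80, 80), dtype=np.uint16)
    rr, cc = ellipse(40, 40, 12, 20)
    mask[rr, cc] = 1
    img = flat_image(mask.shape)
    f1 = extract_features(mask, img, scale=1.0).loc[1]
    f2 = extract_features(mask, img, scale=2.0).loc[1]
    for name in ("area", "convex_area", "filled_area"):
        assert f2[name] == pytest.approx(4.0 * f1[name])
    for name in ("perimeter", "equivalent_diameter", "major_axis_length"):
        assert f2[name] == pytest.approx(2.0 * f1[name])
    for name in ("eccentricity", "solidity", "extent", "circularity", "aspect_ratio"):
        assert f2[name] == pytest.approx(f1[name])


def test_rotation_robustness_90deg():
    mask = np.zeros((100, 100), dtype=np.uint16)
    rr, cc = ellipse(50, 50, 11, 23)
    mask[rr, cc] = 1
    img = flat_image(mask.shape)
    f1 = extract_features(mask, img, scale=1.0).loc[1]
    f2 = extract_features(np.rot90(mask).copy(), np.rot90(img).copy(), scale=1.0).loc[1]
    for name in ("eccentricity", "solidity", "area"):
        assert abs(f2[name] - f1[name]) / f1[name] < 0.03


def test_tiny_label_skipped_with_warning():
    mask = np.zeros((10, 10), dtype=np.uint16)
    mask[2:5, 2:5] = 1
    mask[8, 8] = 2  # 1-pixel label: moments undefined
    with pytest.warns(UserWarning, match="<3 pixels"):
        f = extract_features(mask, flat_image(mask.shape), scale=1.0)
    assert list(f.index) == [1]


def test_intensity_features_from_known_values():
    mask = np.zeros((4, 4), dtype=np.uint16)
    mask[0, :4] = 1
    mask[1, 0] = 1
    img = np.zeros((4, 4), dtype=np.uint8)
    img[0, :4] = [10, 20, 30, 40]
    img[1, 0] = 100
    f = extract_features(mask, img, scale=1.0)
    assert f.loc[1, "intensity_mean"] == pytest.approx(40.0)
    assert f.loc[1, "intensity_median"] == pytest.approx(30.0)
    assert f.loc[1, "intensity_range"] == pytest.approx(90.0)
    # five distinct values, uniform probabilities -> log2(5) bits
    assert f.loc[1, "intensity_entropy"] == pytest.approx(np.log2(5))


# --- matching -------------------------------------------------------------


def cents(points):
    return pd.DataFrame(
        {"centroid_x": [p[0] for p in points], "centroid_y": [p[1] for p in points]},
        index=range(1, len(points) + 1),
    )


def ann(points):
    return SlideTable(
        "t", "SYN", 1.0, [CellRecord(f"a{i}", x, y, "cancer") for i, (x, y) in enumerate(points)]
    )


def test_match_within_threshold():
    pairing = map_annotations_to_cells(ann([(0, 0)]), cents([(0, 1.0)]), max_dist=1.824)
    assert len(pairing.matches) == 1
    assert pairing.matches.iloc[0]["distance"] == pytest.approx(1.0)


def test_no_match_beyond_threshold():
    pairing = map_annotations_to_cells(ann([(0, 0)]), cents([(0, 2.5)]), max_dist=1.824)
    assert len(pairing.matches) == 0
    assert pairing.unmatched_annotations == ["a0"]


def test_one_centroid_between_two_annotations():
    # centroid at 1.0 from a0 and 0.5 from a1: nearer annotation wins
    pairing = map_annotations_to_cells(
        ann([(0, 0), (1.5, 0)]), cents([(1.0, 0)]), max_dist=1.824
    )
    assert list(pairing.matches["annotation_id"]) == ["a1"]
    assert pairing.unmatched_annotations == ["a0"]


def _brute_force_greedy(apos, cpos, max_dist):
    """Independent oracle: sort all pairs by distance, take one-to-one."""
    pairs = sorted(
        (np.hypot(ax - cx, ay - cy), i, j)
        for i, (ax, ay) in enumerate(apos)
        for j, (cx, cy) in enumerate(cpos)
    )
    used_a, used_c, out = set(), set(), {}
    for d, i, j in pairs:
        if d <= max_dist and i not in used_a and j not in used_c:
            used_a.add(i)
            used_c.add(j)
            out[i] = j
    return out


@pytest.mark.parametrize("seed", range(8))
def test_matching_equals_exhaustive_oracle_small(seed):
    r = np.random.default_rng(seed)
    apos = r.uniform(0, 6, size=(r.integers(1, 6), 2))
    cpos = r.uniform(0, 6, size=(r.integers(1, 6), 2))
    pairing = map_annotations_to_cells(
        ann([tuple(p) for p in apos]), cents([tuple(p) for p in cpos]), max_dist=3.0
    )
    got = {
        int(m.annotation_id[1:]): int(m.cell_label) - 1
        for m in pairing.matches.itertuples(index=False)
    }
    assert got == _brute_force_greedy(apos, cpos, 3.0)
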