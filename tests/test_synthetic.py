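"""Seed determinism and distributional fidelity of the generators."""

import numpy as np
import pytest
from scipy import stats as _st

from panmorph import (
    ColocSpec,
    ConfusionSpec,
    MorphologyProfile,
    SurvivalSpec,
    extract_features,
    gen_cell_image,
    gen_point_pattern,
    gen_predictions,
    gen_survival,
    gen_transfer_cohort,
    TransferCohortSpec,
)
from tests.conftest import make_truth


def test_cell_image_count_conservation():
    n = {"cancer": 50, "lymphocyte": 50, "stromal": 50}
    mask, img, truth = gen_cell_image(MorphologyProfile(), n, canvas_um=(450, 450), seed=1)
    assert mask.max() == 150
    assert len(truth) == 150
    assert sorted(np.unique(mask))[1:] == list(range(1, 151))
    assert {c.cls for c in truth.cells} == set(n)


def test_cell_image_seed_determinism():
    n = {"cancer": 20, "lymphocyte": 20}
    a = gen_cell_image(MorphologyProfile(), n, canvas_um=(300, 300), seed=42)
    b = gen_cell_image(MorphologyProfile(), n, canvas_um=(300, 300), seed=42)
    np.testing.assert_array_equal(a[0], b[0])
    np.testing.assert_array_equal(a[1], b[1])
    assert [c.cell_id for c in a[2].cells] == [c.cell_id for c in b[2].cells]


def test_cell_image_infeasible_packing_errors():
    with pytest.raises(RuntimeError, match="larger canvas"):
        gen_cell_image(MorphologyProfile(), {"cancer": 400}, canvas_um=(60, 60), seed=0)


def test_lymphocyte_area_distribution_matches_profile():
    profile = MorphologyProfile()
    mask, img, _ = gen_cell_image(
        profile, {"lymphocyte": 500}, canvas_um=(700, 700), scale=0.5, seed=7
    )
    areas = extract_features(mask, img, 0.5)["area"].to_numpy()
    m = profile.classes["lymphocyte"]
    assert np.median(areas) == pytest.approx(m.area_median, rel=0.05)
    ks = _st.kstest(areas, "lognorm", args=(m.area_dispersion, 0, m.area_median))
    assert ks.pvalue > 0.01


# --- predictions -----------------------------------------------------------


def test_predictions_identity_spec():
    truth = make_truth(200, seed=3)
    preds = gen_predictions(truth, ConfusionSpec.identity(), seed=0)
    assert len(preds) == len(truth)
    for t, p in zip(truth.cells, preds.cells):
        assert p.cls == t.cls
        assert (p.x, p.y) == (t.x, t.y)
        assert p.source == "prediction"


def test_predictions_forced_row():
    spec = ConfusionSpec(
        rows={"cancer": (0.0, 1.0, 0.0, 0.0),
              "lymphocyte": (0.0, 1.0, 0.0, 0.0),
              "stromal": (0.0, 0.0, 1.0, 0.0)},
        jitter_sd=0.0, miss_rate=0.0, spurious_rate=0.0,
    )
    preds = gen_predictions(make_truth(100, "cancer", seed=4), spec, seed=1)
    assert all(p.cls == "lymphocyte" for p in preds.cells)


def test_predictions_monte_carlo_row_frequencies():
    spec = ConfusionSpec(
        rows={"cancer": (0.9, 0.05, 0.05, 0.0),
              "lymphocyte": (0.0, 1.0, 0.0, 0.0),
              "stromal": (0.0, 0.0, 1.0, 0.0)},
        jitter_sd=0.0, miss_rate=0.0, spurious_rate=0.0,
    )
    preds = gen_predictions(make_truth(10000, "cancer", seed=5), spec, seed=2)
    freq = np.array(
        [np.mean([p.cls == c for p in preds.cells]) for c in ("cancer", "lymphocyte", "stromal")]
    )
    assert np.allclose(freq, [0.9, 0.05, 0.05], atol=0.01)


def test_predictions_miss_and_spurious_rates():
    spec = ConfusionSpec(jitter_sd=0.0, miss_rate=0.3, spurious_rate=0.0)
    truth = make_truth(5000, seed=6)
    preds = gen_predictions(truth, spec, seed=3)
    assert len(preds) / len(truth) == pytest.approx(0.7, abs=0.02)


def test_predictions_reject_prediction_input():
    truth = make_truth(10, seed=0)
    preds = gen_predictions(truth, ConfusionSpec.identity(), seed=0)
    with pytest.raises(ValueError, match="annotation records"):
        gen_predictions(preds, ConfusionSpec.identity(), seed=0)


def test_confusion_spec_row_validation():
    with pytest.raises(ValueError, match="sum to 1"):
        ConfusionSpec(rows={"cancer": (0.5, 0.4, 0.0, 0.0),
                            "lymphocyte": (0, 1, 0, 0),
                            "stromal": (0, 0, 1, 0)})


# --- point patterns --------------------------------------------------------


def test_point_pattern_counts_and_bounds():
    spec = ColocSpec(n_cancer=300, n_lymph=200)
    cancer, lymph = gen_point_pattern(spec, seed=8)
    assert cancer.shape == (300, 2)
    assert lymph.shape == (200, 2)
    for pts in (cancer, lymph):
        assert (pts >= 0).all()
        assert (pts[:, 0] <= spec.width).all()
        assert (pts[:, 1] <= spec.height).all()


def test_point_pattern_deterministic():
    a = gen_point_pattern(ColocSpec(), seed=11)
    b = gen_point_pattern(ColocSpec(), seed=11)
    np.testing.assert_array_equal(a[0], b[0])
    np.testing.assert_array_equal(a[1], b[1])


def test_theta_orders_single_seed_colocalisation():
    from panmorph import colocalization

    shared = colocalization(*gen_point_pattern(ColocSpec(theta=1.0, cluster_sd=40.0), seed=2))
    indep = colocalization(*gen_point_pattern(ColocSpec(theta=0.0, cluster_sd=40.0), seed=2))
    assert shared.mh > indep.mh


# --- survival --------------------------------------------------------------


def test_survival_no_effects_no_censoring_all_events():
    spec = SurvivalSpec(n=100, b_coloc=0.0, b_age=0.0, b_lymph=0.0, censor_rate=0.0)
    recs = gen_survival(spec, seed=1)
    assert all(r.event == 1 for r in recs)


def test_survival_censor_fraction():
    recs = gen_survival(SurvivalSpec(n=4000, censor_rate=0.25), seed=2)
    frac = np.mean([r.event == 0 for r in recs])
    assert frac == pytest.approx(0.25, abs=0.02)


def test_survival_parameter_recovery_large_n():
    from panmorph import fit_cox, survival_frame

    spec = SurvivalSpec(n=2000, b_coloc=-0.02, b_age=0.0, b_lymph=0.0)
    fit = fit_cox(survival_frame(gen_survival(spec, seed=3)))
    assert fit.coef("coloc100") == pytest.approx(-0.02, abs=0.005)


def test_survival_covariates_can_be_supplied():
    import pandas as pd

    cov = pd.DataFrame({"coloc100": [10.0, 90.0], "age": [8.0, 12.0], "lymphocyte_pct": [5.0, 30.0]})
    recs = gen_survival(SurvivalSpec(n=2, censor_rate=0.0), seed=0, covariates=cov)
    assert [r.coloc100 for r in recs] == [10.0, 90.0]


# --- transfer cohort -------------------------------------------------------


def test_transfer_cohort_shapes_and_shifts():
    spec = TransferCohortSpec(n_species=5)
    cohort = gen_transfer_cohort(spec, seed=0)
    assert len(cohort) == 5
    shifts = [s["shift"] for s in cohort]
    assert shifts == sorted(shifts)
    s0 = cohort[0]
    n_expected = 3 * (spec.n_human_per_class + spec.n_animal_per_class)
    assert s0["X"].shape == (n_expected, spec.n_feat)
    assert set(s0["cls"]) == {"cancer", "lymphocyte", "stromal"}
    assert set(s0["origin"]) == {"human", "animal"}
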