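"""Config-driven pipeline chaining the analysis stages.

A run is described by a small config (YAML file or dict): a seed, an
output directory and an ordered list of stages drawn from ``simulate``,
``featurize``, ``morphospace``, ``evaluate``, ``colocalize``, ``survive``
and ``cohort-stats``.  Every stage writes a machine-readable JSON report
that echoes the parameters and seed it consumed, so a run is fully
reproducible from its config alone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import evaluation, morphometry, morphospace, spatial, survival as surv
from .cohort import load_species_table
from .datamodel import survival_frame, write_cell_table
from .synthetic import (
    ColocSpec,
    ConfusionSpec,
    MorphologyProfile,
    SurvivalSpec,
    gen_cell_image,
    gen_point_pattern,
    gen_predictions,
    gen_survival,
)

log = logging.getLogger("panmorph")

KNOWN_STAGES = (
    "simulate",
    "featurize",
    "morphospace",
    "evaluate",
    "colocalize",
    "survive",
    "cohort-stats",
)


class ConfigError(ValueError):
    pass


def _dump(report: Mapping[str, Any], path: Path) -> None:
    path.write_text(json.dumps(report, indent=2, sort_keys=True, default=str))


def run_pipeline(config: str | Path | Mapping[str, Any]) -> dict[str, dict]:
    """Execute the configured stages in order; returns reports by stage.

    Raises :class:`ConfigError` for unknown stages before anything runs;
    a stage failure aborts the run with the stage named.
    """
    if isinstance(config, (str, Path)):
        cfg = yaml.safe_load(Path(config).read_text())
    else:
        cfg = dict(config)
    stages = cfg.get("stages")
    if not stages:
        raise ConfigError("config must list at least one stage")
    unknown = [s for s in stages if s not in KNOWN_STAGES]
    if unknown:
        raise ConfigError(
            f"unknown stage(s) {unknown}; known stages are {list(KNOWN_STAGES)}"
        )
    seed = int(cfg.get("seed", 0))
    out_dir = Path(cfg.get("out_dir", "panmorph_out"))
    out_dir.mkdir(parents=True, exist_ok=True)

    state: dict[str, Any] = {}
    reports: dict[str, dict] = {}
    for stage in stages:
        log.info("stage %s (seed=%d)", stage, seed)
        try:
            report = _STAGES[stage](cfg.get(stage.replace("-", "_"), {}) or {}, seed, out_dir, state)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        report["stage"] = stage
        report["seed"] = seed
        _dump(report, out_dir / f"{stage}.json")
        reports[stage] = report
    return reports


def _stage_simulate(params: Mapping, seed: int, out_dir: Path, state: dict) -> dict:
    """Generate a clustered truth slide and classifier predictions."""
    cspec = ColocSpec(**params.get("coloc", {}))
    spec = ConfusionSpec(**params.get("confusion", {}))
    cancer, lymph = gen_point_pattern(cspec, seed)
    rng = np.random.default_rng(seed + 1)
    n_str = int(params.get("n_stromal", cspec.n_lymph))
    stromal = rng.uniform([0, 0], [cspec.width, cspec.height], size=(n_str, 2))
    from .datamodel import CellRecord, SlideTable

    cells = (
        [CellRecord(f"c{i}", *p, "cancer") for i, p in enumerate(cancer)]
        + [CellRecord(f"l{i}", *p, "lymphocyte") for i, p in enumerate(lymph)]
        + [CellRecord(f"s{i}", *p, "stromal") for i, p in enumerate(stromal)]
    )
    truth = SlideTable("sim", "SYN", 1.0, cells)
    preds = gen_predictions(truth, spec, seed + 2)
    write_cell_table(truth, out_dir / "truth_cells.csv")
    write_cell_table(preds, out_dir / "predicted_cells.csv")
    state["truth"] = truth
    state["preds"] = preds
    state["pattern"] = (cancer, lymph)
    return {
        "n_truth": len(truth),
        "n_predictions": len(preds),
        "coloc_spec": cspec.__dict__,
        "confusion_spec": {"rows": {k: list(v) for k, v in spec.rows.items()},
                           "jitter_sd": spec.jitter_sd,
                           "miss_rate": spec.miss_rate,
                           "spurious_rate": spec.spurious_rate},
    }


def _stage_featurize(params: Mapping, seed: int, out_dir: Path, state: dict) -> dict:
    """Render synthetic nuclei and extract the 27-feature table."""
    profile = MorphologyProfile()
    n_per_class = dict(params.get("n_per_class", {"cancer": 60, "lymphocyte": 60, "stromal": 60}))
    canvas = tuple(params.get("canvas_um", (500.0, 500.0)))
    scale = float(params.get("scale", 0.5))
    mask, img, truth = gen_cell_image(profile, n_per_class, canvas, scale, seed)
    feats = morphometry.extract_features(mask, img, scale)
    labels = {i + 1: c.cls for i, c in enumerate(truth.cells)}
    feats["cls"] = [labels[i] for i in feats.index]
    feats.to_csv(out_dir / "features.csv")
    state["features"] = feats
    return {
        "n_cells": int(len(feats)),
        "n_per_class": n_per_class,
        "scale_um_per_px": scale,
        "registry_hash": feats["registry_hash"].iloc[0],
    }


def _stage_morphospace(params: Mapping, seed: int, out_dir: Path, state: dict) -> dict:
    """Embed the feature table and compute the class overlap matrix."""
    feats = state.get("features")
    if feats is None:
        raise RuntimeError("morphospace stage requires the featurize stage first")
    cfg = morphospace.EmbeddingConfig(
        perplexity=float(params.get("perplexity", 50.0)), seed=seed
    )
    cols = [c for c in feats.columns if c not in ("cls", "registry_hash", "centroid_x", "centroid_y")]
    coords = morphospace.embed(feats[cols].to_numpy(), cfg)
    groups = {
        cls: coords[(feats["cls"] == cls).to_numpy()] for cls in feats["cls"].unique()
    }
    om = morphospace.overlap_matrix(groups)
    om.values.to_csv(out_dir / "overlap_matrix.csv")
    np.savetxt(out_dir / "embedding.csv", coords, delimiter=",", header="dim1,dim2")
    return {
        "n_embedded": int(len(coords)),
        "perplexity": cfg.perplexity,
        "overlap_matrix": json.loads(om.values.to_json()),
        "flagged_groups": om.flagged,
    }


def _stage_evaluate(params: Mapping, seed: int, out_dir: Path, state: dict) -> dict:
    """Match predictions to truth, build the confusion matrix and metrics."""
    truth, preds = state.get("truth"), state.get("preds")
    if truth is None or preds is None:
        raise RuntimeError("evaluate stage requires the simulate stage first")
    max_dist = float(params.get("max_dist", 5.0))
    import pandas as pd

    centroids = pd.DataFrame(
        {
            "centroid_x": [c.x for c in preds.cells],
            "centroid_y": [c.y for c in preds.cells],
        },
        index=[c.cell_id for c in preds.cells],
    )
    pairing = morphometry.map_annotations_to_cells(truth, centroids, max_dist)
    cm = evaluation.confusion_from_matching(truth, preds, pairing)
    rep = evaluation.metrics(cm)
    return {
        "max_dist_um": max_dist,
        "n_matched": int(len(pairing.matches)),
        "n_missed": len(pairing.unmatched_annotations),
        "metrics": rep.to_dict(),
    }


def _stage_colocalize(params: Mapping, seed: int, out_dir: Path, state: dict) -> dict:
    """Quadrat Morisita–Horn colocalisation of the simulated pattern."""
    pattern = state.get("pattern")
    if pattern is None:
        raise RuntimeError("colocalize stage requires the simulate stage first")
    width = float(params.get("quadrat_width", spatial.DEFAULT_QUADRAT_WIDTH_UM))
    res = spatial.colocalization(*pattern, width)
    return {
        "quadrat_width_um": res.quadrat_width,
        "n_quadrats": res.n_quadrats,
        "morisita_horn": res.mh,
        "coloc100": res.coloc100,
    }


def _stage_survive(params: Mapping, seed: int, out_dir: Path, state: dict) -> dict:
    """Generate a survival cohort, screen VIF, fit Cox, dichotomise."""
    spec = SurvivalSpec(**params.get("survival", {}))
    records = gen_survival(spec, seed)
    df = survival_frame(records)
    vrep = surv.vif(df)
    fit = surv.fit_cox(df, vrep.retained)
    labels, cutoff = surv.dichotomize_lower_quartile(df["coloc100"])
    curves = surv.km(df, labels)
    return {
        "n": spec.n,
        "true_coefficients": {
            "coloc100": spec.b_coloc,
            "age": spec.b_age,
            "lymphocyte_pct": spec.b_lymph,
        },
        "vif": json.loads(vrep.table.to_json()),
        "cox": json.loads(fit.table.to_json()),
        "n_events": fit.n_events,
        "dichotomy_cutoff": cutoff,
        "km_groups": {g: c.n for g, c in curves.items()},
    }


def _stage_cohort_stats(params: Mapping, seed: int, out_dir: Path, state: dict) -> dict:
    """Statistics of the bundled 20-species accuracy table."""
    df = load_species_table()
    return evaluation.species_table_summaries(
        df, n_boot=int(params.get("n_boot", 2000)), seed=seed
    )


_STAGES = {
    "simulate": _stage_simulate,
    "featurize": _stage_featurize,
    "morphospace": _stage_morphospace,
    "evaluate": _stage_evaluate,
    "colocalize": _stage_colocalize,
    "survive": _stage_survive,
    "cohort-stats": _stage_cohort_stats,
}
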