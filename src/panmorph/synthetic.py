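"""Synthetic inputs with known ground truth for every pipeline stage.

Four generators replace the whole-slide images the real study used:

* :func:`gen_cell_image` — labelled nuclear masks plus an intensity image,
  nuclei drawn as radially perturbed ellipses with class-conditional size,
  elongation, irregularity and staining distributions;
* :func:`gen_predictions` — a classifier stand-in with a prescribed
  confusion matrix, positional jitter, misses and spurious detections;
* :func:`gen_point_pattern` — Thomas-type clustered cancer/lymphocyte
  point patterns whose colocalisation is tuned by a mixing parameter
  theta (the probability a lymphocyte attaches to a cancer cluster);
* :func:`gen_survival` — survival cohorts drawn forward from a
  proportional-hazards model with known log-hazard coefficients.

Every generator is deterministic given its seed and echoes its spec in
the returned metadata, so downstream estimates can be checked against the
generating truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from skimage import draw as _draw

from .datamodel import CellRecord, SlideTable, SurvivalRecord

CORE3 = ("cancer", "lymphocyte", "stromal")


# --- nuclear morphology ----------------------------------------------------


@dataclass(frozen=True)
class ClassMorphology:
    """Log-normal nuclear area (µm²) plus shape and staining parameters."""

    area_median: float  # µm²
    area_dispersion: float  # sd of log area
    aspect_mean: float  # >= 1
    aspect_sd: float
    irregularity: float  # [0, 1], low-frequency radial boundary perturbation
    intensity_mean: float  # [0, 255] mean stain intensity (dark nuclei = low)
    intensity_sd: float

    def __post_init__(self) -> None:
        if self.area_dispersion <= 0 or self.intensity_sd <= 0:
            raise ValueError("dispersions must be > 0")
        if self.aspect_mean < 1:
            raise ValueError("aspect ratio is >= 1 by convention")
        if not 0.0 <= self.irregularity <= 1.0:
            raise ValueError("irregularity must lie in [0, 1]")


@dataclass(frozen=True)
class MorphologyProfile:
    """Per-class morphology; defaults follow routine H&E nuclear morphometry.

    Lymphocyte nuclei are small, round and darkly stained (dense
    chromatin); cancer (epithelial) nuclei are large, moderately
    irregular and paler (vesicular chromatin); stromal (fibroblast/
    endothelial) nuclei are intermediate in size but elongated.
    """

    classes: Mapping[str, ClassMorphology] = field(
        default_factory=lambda: {
            "cancer": ClassMorphology(80.0, 0.30, 1.3, 0.15, 0.30, 130.0, 15.0),
            "lymphocyte": ClassMorphology(28.0, 0.20, 1.1, 0.08, 0.10, 80.0, 12.0),
            "stromal": ClassMorphology(45.0, 0.25, 2.5, 0.40, 0.20, 110.0, 15.0),
        }
    )

    def __post_init__(self) -> None:
        unknown = set(self.classes) - set(CORE3)
        if unknown:
            raise ValueError(f"unknown class(es) in profile: {sorted(unknown)}")


def _nucleus_polygon(
    area: float, aspect: float, irregularity: float, angle: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Boundary polygon (µm, centred) of a perturbed ellipse of given area."""
    b = math.sqrt(area / (math.pi * aspect))  # semi-minor
    a = aspect * b
    phi = np.linspace(0, 2 * np.pi, 64, endpoint=False)
    # low-frequency radial perturbation: 2nd-4th harmonics with random phase
    pert = np.zeros_like(phi)
    for k in (2, 3, 4):
        pert += rng.uniform(-1, 1) * np.cos(k * phi + rng.uniform(0, 2 * np.pi))
    r_mod = 1.0 + 0.15 * irregularity * pert / 3.0
    x = a * np.cos(phi) * r_mod
    y = b * np.sin(phi) * r_mod
    ca, sa = math.cos(angle), math.sin(angle)
    return x * ca - y * sa, x * sa + y * ca


def gen_cell_image(
    profile: MorphologyProfile,
    n_per_class: Mapping[str, int],
    canvas_um: tuple[float, float] = (400.0, 400.0),
    scale: float = 0.5,
    seed: int = 0,
    max_attempts_per_cell: int = 60,
) -> tuple[np.ndarray, np.ndarray, SlideTable]:
    """Rasterise non-overlapping synthetic nuclei onto a canvas.

    Returns ``(label_mask, intensity_image, truth_table)``: a 16-bit
    label mask (0 background, k > 0 = cell k), an 8-bit grayscale
    intensity image (background near white, nuclei at class-conditional
    stain levels plus pixel noise), and the ground-truth slide table of
    centroids in µm.  Raises if the requested cells cannot be packed
    (rejection rate above ~30%), suggesting a larger canvas.
    """
    rng = np.random.default_rng(seed)
    w_px = int(round(canvas_um[0] / scale))
    h_px = int(round(canvas_um[1] / scale))
    mask = np.zeros((h_px, w_px), dtype=np.uint16)
    intensity = np.full((h_px, w_px), 235.0) + rng.normal(0, 4, size=(h_px, w_px))
    cells: list[CellRecord] = []
    label = 0
    n_total = sum(n_per_class.values())
    attempts_budget = int(max_attempts_per_cell * n_total)
    attempts = 0
    for cls, n in n_per_class.items():
        if cls not in profile.classes:
            raise ValueError(f"profile has no morphology for class {cls!r}")
        m = profile.classes[cls]
        placed = 0
        while placed < n:
            if attempts >= attempts_budget:
                raise RuntimeError(
                    "infeasible packing: could not place all requested cells; "
                    "use a larger canvas or fewer cells"
                )
            attempts += 1
            area = m.area_median * math.exp(rng.normal(0, m.area_dispersion))
            aspect = max(1.0, rng.normal(m.aspect_mean, m.aspect_sd))
            angle = rng.uniform(0, np.pi)
            margin = math.sqrt(area * aspect / math.pi) + 2 * scale
            cx = rng.uniform(margin, canvas_um[0] - margin)
            cy = rng.uniform(margin, canvas_um[1] - margin)
            bx, by = _nucleus_polygon(area, aspect, m.irregularity, angle, rng)
            rr, cc = _draw.polygon((cy + by) / scale, (cx + bx) / scale, shape=mask.shape)
            if len(rr) < 3 or mask[rr, cc].any():
                continue
            label += 1
            mask[rr, cc] = label
            level = np.clip(rng.normal(m.intensity_mean, m.intensity_sd), 0, 255)
            intensity[rr, cc] = level + rng.normal(0, 6, size=len(rr))
            ccx = cc.mean() * scale
            ccy = rr.mean() * scale
            cells.append(CellRecord(f"{cls[:3]}-{label}", ccx, ccy, cls, "annotation"))
            placed += 1
    truth = SlideTable("synthetic", "SYN", scale, cells)
    return mask, np.clip(intensity, 0, 255).astype(np.uint8), truth


# --- classifier stand-in ---------------------------------------------------


@dataclass(frozen=True)
class ConfusionSpec:
    """Row-stochastic error model of a single-cell classifier.

    ``rows`` maps each true class to P(predicted class | true class) over
    (cancer, lymphocyte, stromal, other).  Kept cells are jittered by an
    isotropic Gaussian of ``jitter_sd`` µm; a fraction ``miss_rate`` is
    dropped, and ``spurious_rate`` × n extra detections are added at
    uniform positions with uniformly random class.
    """

    rows: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            "cancer": (0.90, 0.04, 0.04, 0.02),
            "lymphocyte": (0.05, 0.90, 0.03, 0.02),
            "stromal": (0.06, 0.04, 0.88, 0.02),
        }
    )
    jitter_sd: float = 0.5
    miss_rate: float = 0.05
    spurious_rate: float = 0.02

    def __post_init__(self) -> None:
        for cls, row in self.rows.items():
            if cls not in CORE3:
                raise ValueError(f"unknown true class {cls!r}")
            if any(p < 0 for p in row) or abs(sum(row) - 1.0) > 1e-9:
                raise ValueError(f"row for {cls!r} must be non-negative and sum to 1")
        if not 0.0 <= self.miss_rate < 1.0:
            raise ValueError("miss_rate must lie in [0, 1)")
        if self.spurious_rate < 0:
            raise ValueError("spurious_rate must be >= 0")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")

    @classmethod
    def identity(cls) -> "ConfusionSpec":
        rows = {c: tuple(1.0 if i == j else 0.0 for i in range(4)) for j, c in enumerate(CORE3)}
        return cls(rows=rows, jitter_sd=0.0, miss_rate=0.0, spurious_rate=0.0)


PRED4 = ("cancer", "lymphocyte", "stromal", "other")


def gen_predictions(truth: SlideTable, spec: ConfusionSpec, seed: int = 0) -> SlideTable:
    """Simulate classifier output for an annotation table.

    Each kept cell's predicted class is drawn from its confusion row, its
    position jittered by N(0, jitter_sd²) per axis (clipped at 0);
    ``miss_rate`` of cells are dropped and spurious detections appear at
    uniform positions inside the annotation bounding box.
    """
    if any(c.source != "annotation" for c in truth.cells):
        raise ValueError("truth table must contain only annotation records")
    rng = np.random.default_rng(seed)
    preds: list[CellRecord] = []
    k = 0
    for cell in truth.cells:
        if rng.random() < spec.miss_rate:
            continue
        row = spec.rows[cell.cls]
        pred_cls = PRED4[rng.choice(4, p=np.asarray(row, dtype=float))]
        x = max(0.0, cell.x + rng.normal(0, spec.jitter_sd)) if spec.jitter_sd else cell.x
        y = max(0.0, cell.y + rng.normal(0, spec.jitter_sd)) if spec.jitter_sd else cell.y
        k += 1
        preds.append(CellRecord(f"p{k}", x, y, pred_cls, "prediction"))
    n_spurious = rng.binomial(len(truth.cells), min(spec.spurious_rate, 1.0)) if spec.spurious_rate else 0
    if n_spurious and len(truth.cells):
        pos = truth.positions()
        lo, hi = pos.min(axis=0), pos.max(axis=0)
        for _ in range(n_spurious):
            k += 1
            preds.append(
                CellRecord(
                    f"p{k}",
                    rng.uniform(lo[0], hi[0]),
                    rng.uniform(lo[1], hi[1]),
                    CORE3[rng.integers(3)],  # uniform over the three classes
                    "prediction",
                )
            )
    return SlideTable(truth.slide_id, truth.species_code, truth.microns_per_pixel, preds)


# --- clustered point patterns ----------------------------------------------


@dataclass(frozen=True)
class ColocSpec:
    """Thomas-type cluster layout with a colocalisation dial.

    Cancer points form Gaussian clusters around uniform parent points.
    Each lymphocyte attaches to a cancer parent with probability
    ``theta`` and otherwise to an independent parent set, so theta = 1
    makes the two patterns share cluster structure (high Morisita–Horn)
    and theta = 0 makes them spatially independent.
    """

    width: float = 2000.0  # µm
    height: float = 2000.0
    n_cancer: int = 800
    n_lymph: int = 400
    cluster_sd: float = 60.0  # µm
    n_parents: int = 12
    theta: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0, 1]")
        if self.n_cancer <= 0 or self.n_lymph <= 0 or self.n_parents <= 0:
            raise ValueError("counts must be positive")


def _offspring(
    parents: np.ndarray, n: int, sd: float, lims: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Exactly n cluster offspring, resampled until inside the field."""
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        need = n - filled
        centres = parents[rng.integers(0, len(parents), size=need)]
        pts = centres + rng.normal(0, sd, size=(need, 2))
        ok = (
            (pts[:, 0] >= 0)
            & (pts[:, 0] <= lims[0])
            & (pts[:, 1] >= 0)
            & (pts[:, 1] <= lims[1])
        )
        pts = pts[ok]
        out[filled : filled + len(pts)] = pts
        filled += len(pts)
    return out


def gen_point_pattern(spec: ColocSpec, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Sample (cancer, lymphocyte) point sets with tunable colocalisation."""
    rng = np.random.default_rng(seed)
    lims = (spec.width, spec.height)
    cancer_parents = rng.uniform([0, 0], lims, size=(spec.n_parents, 2))
    indep_parents = rng.uniform([0, 0], lims, size=(spec.n_parents, 2))
    cancer = _offspring(cancer_parents, spec.n_cancer, spec.cluster_sd, lims, rng)
    attach = rng.random(spec.n_lymph) < spec.theta
    n_shared = int(attach.sum())
    lymph = np.empty((spec.n_lymph, 2))
    if n_shared:
        lymph[attach] = _offspring(cancer_parents, n_shared, spec.cluster_sd, lims, rng)
    if spec.n_lymph - n_shared:
        lymph[~attach] = _offspring(
            indep_parents, spec.n_lymph - n_shared, spec.cluster_sd, lims, rng
        )
    return cancer, lymph


# --- survival cohorts ------------------------------------------------------


@dataclass(frozen=True)
class SurvivalSpec:
    """Forward proportional-hazards generator.

    Event times are exponential with rate
    ``baseline_rate * exp(b_coloc*coloc100 + b_age*age + b_lymph*lymph%)``.
    The default coefficients mirror a protective colocalisation effect of
    HR 0.98 per point of coloc100 and a mild age effect; the baseline
    rate corresponds to a median survival of about a year for a subject
    with average covariates.  Censored subjects (an independent
    ``censor_rate`` fraction) are observed at a uniform fraction of their
    event time.
    """

    n: int = 200
    b_coloc: float = math.log(0.98)  # per point of coloc100
    b_age: float = math.log(1.05)  # per year
    b_lymph: float = 0.0  # abundance alone carries no effect by default
    baseline_rate: float = 0.0019  # events/day
    censor_rate: float = 0.2
    age_mean: float = 10.0  # years; companion-dog cohort scale
    age_sd: float = 2.5
    lymph_mean: float = 15.0  # %
    lymph_sd: float = 8.0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must lie in [0, 1)")


def gen_survival(
    spec: SurvivalSpec,
    seed: int = 0,
    covariates: pd.DataFrame | None = None,
) -> list[SurvivalRecord]:
    """Draw a survival cohort from the proportional-hazards model.

    ``covariates`` may supply measured ``coloc100``/``age``/
    ``lymphocyte_pct`` columns (e.g. scores computed from generated
    point patterns, closing the loop); otherwise covariates are drawn
    from the spec's marginal distributions with coloc100 uniform on
    [0, 100].
    """
    rng = np.random.default_rng(seed)
    n = spec.n
    if covariates is not None:
        if len(covariates) != n:
            raise ValueError("covariate table length must equal spec.n")
        coloc = covariates["coloc100"].to_numpy(dtype=float)
        age = covariates["age"].to_numpy(dtype=float)
        lymph = covariates["lymphocyte_pct"].to_numpy(dtype=float)
    else:
        coloc = rng.uniform(0, 100, size=n)
        age = np.clip(rng.normal(spec.age_mean, spec.age_sd, size=n), 0.5, None)
        lymph = np.clip(rng.normal(spec.lymph_mean, spec.lymph_sd, size=n), 0.0, 100.0)
    lin = spec.b_coloc * coloc + spec.b_age * age + spec.b_lymph * lymph
    rate = spec.baseline_rate * np.exp(lin)
    t_event = rng.exponential(1.0 / rate)
    censored = rng.random(n) < spec.censor_rate
    t_obs = np.where(censored, t_event * rng.uniform(0, 1, size=n), t_event)
    t_obs = np.maximum(t_obs, 1e-6)
    return [
        SurvivalRecord(
            subject_id=f"s{i}",
            time=float(t_obs[i]),
            event=int(not censored[i]),
            age=float(age[i]),
            lymphocyte_pct=float(lymph[i]),
            coloc100=float(coloc[i]),
        )
        for i in range(n)
    ]


# --- feature-space transfer cohort ----------------------------------------


@dataclass(frozen=True)
class TransferCohortSpec:
    """A multi-"species" feature-space experiment.

    For each synthetic species, human cancer / lymphocyte / stromal cells
    sit at fixed Gaussian class centres in feature space; the species'
    cells are the same clouds shifted away from the human centres by a
    species-specific separation (in within-class SD units).  Larger
    separation means less morphological conservation, hence lower
    expected morphospace overlap and lower transfer accuracy of a
    classifier trained on the human cells.
    """

    n_species: int = 20
    n_feat: int = 8
    n_human_per_class: int = 60
    n_animal_per_class: int = 50
    class_sep: float = 6.0  # distance between human class centres (SD units)
    max_shift: float = 5.0  # largest animal-vs-human separation


def gen_transfer_cohort(
    spec: TransferCohortSpec, seed: int = 0
) -> list[dict]:
    """One entry per species: features, class labels, origin labels, shift.

    Returns dicts with keys ``species``, ``shift``, ``X`` (n, n_feat),
    ``cls`` (cancer/lymphocyte/stromal) and ``origin`` (human/animal).
    Species shifts are evenly spaced on [0, max_shift].
    """
    rng = np.random.default_rng(seed)
    centres = {
        "cancer": np.zeros(spec.n_feat),
        "lymphocyte": np.r_[spec.class_sep, np.zeros(spec.n_feat - 1)],
        "stromal": np.r_[0.0, spec.class_sep, np.zeros(spec.n_feat - 2)],
    }
    shifts = np.linspace(0.0, spec.max_shift, spec.n_species)
    cohort = []
    for s, shift in enumerate(shifts):
        X, cls, origin = [], [], []
        # species-specific random shift direction, same for all classes
        u = rng.normal(size=spec.n_feat)
        u /= np.linalg.norm(u)
        for c, mu in centres.items():
            Xh = rng.normal(size=(spec.n_human_per_class, spec.n_feat)) + mu
            Xa = rng.normal(size=(spec.n_animal_per_class, spec.n_feat)) + mu + shift * u
            X.append(Xh)
            X.append(Xa)
            cls += [c] * (spec.n_human_per_class + spec.n_animal_per_class)
            origin += ["human"] * spec.n_human_per_class + ["animal"] * spec.n_animal_per_class
        cohort.append(
            {
                "species": f"SYN{s:02d}",
                "shift": float(shift),
                "X": np.vstack(X),
                "cls": np.array(cls),
                "origin": np.array(origin),
            }
        )
    return cohort
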