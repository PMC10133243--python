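"""Spatial immune scores: quadrat counts, Morisita–Horn colocalisation,
and lymphocyte relative abundance.

Two point patterns (cancer-cell and lymphocyte positions, µm) are
discretised onto one shared rectangular grid of quadrats anchored at the
joint bounding-box minimum.  The Morisita–Horn overlap index

    MH = 2 Σ x_i y_i / [ (Σx_i²/X² + Σy_i²/Y²) · X · Y ]

compares how similarly the two patterns distribute over quadrats; it is 1
for proportionally identical occupancy and 0 for disjoint occupancy.
Multiplied by 100 it gives the colocalisation score used as a prognostic
covariate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import CORE_CLASSES, SlideTable

#: default quadrat width in µm; reported with every score.
DEFAULT_QUADRAT_WIDTH_UM = 250.0


@dataclass
class QuadratCounts:
    origin: tuple[float, float]
    width: float
    nx: int
    ny: int
    x_counts: np.ndarray  # cancer counts per quadrat, flattened row-major
    y_counts: np.ndarray  # lymphocyte counts per quadrat

    @property
    def n_quadrats(self) -> int:
        return self.nx * self.ny


@dataclass
class ColocalizationResult:
    mh: float
    coloc100: float
    quadrat_width: float
    n_quadrats: int


def quadrats(
    cancer: np.ndarray,
    lymph: np.ndarray,
    width: float = DEFAULT_QUADRAT_WIDTH_UM,
) -> QuadratCounts:
    """Count both point sets on a shared grid of half-open quadrats.

    The grid is anchored at the joint bounding-box minimum; cells are
    half-open ``[a, a + width)``, so a point exactly on an interior
    boundary belongs to the higher-index quadrat.
    """
    cancer = np.asarray(cancer, dtype=float).reshape(-1, 2)
    lymph = np.asarray(lymph, dtype=float).reshape(-1, 2)
    if not width > 0:
        raise ValueError("quadrat width must be > 0")
    if len(cancer) == 0 or len(lymph) == 0:
        raise ValueError("both point sets must be non-empty")
    allpts = np.vstack([cancer, lymph])
    origin = allpts.min(axis=0)
    span = allpts.max(axis=0) - origin
    nx = int(span[0] // width) + 1
    ny = int(span[1] // width) + 1

    def _count(pts: np.ndarray) -> np.ndarray:
        ix = ((pts[:, 0] - origin[0]) // width).astype(int)
        iy = ((pts[:, 1] - origin[1]) // width).astype(int)
        flat = iy * nx + ix
        return np.bincount(flat, minlength=nx * ny).astype(float)

    return QuadratCounts(
        origin=(float(origin[0]), float(origin[1])),
        width=float(width),
        nx=nx,
        ny=ny,
        x_counts=_count(cancer),
        y_counts=_count(lymph),
    )


def morisita_horn(q: QuadratCounts) -> ColocalizationResult:
    """Morisita–Horn overlap of the two quadrat-count vectors."""
    x = np.asarray(q.x_counts, dtype=float)
    y = np.asarray(q.y_counts, dtype=float)
    X = x.sum()
    Y = y.sum()
    if X <= 0 or Y <= 0:
        raise ValueError("Morisita-Horn undefined when either total count is zero")
    mh = 2.0 * (x * y).sum() / (((x**2).sum() / X**2 + (y**2).sum() / Y**2) * X * Y)
    mh = float(min(max(mh, 0.0), 1.0))
    return ColocalizationResult(
        mh=mh, coloc100=100.0 * mh, quadrat_width=q.width, n_quadrats=q.n_quadrats
    )


def colocalization(
    cancer: np.ndarray,
    lymph: np.ndarray,
    width: float = DEFAULT_QUADRAT_WIDTH_UM,
) -> ColocalizationResult:
    """Convenience: quadrat counting followed by Morisita–Horn scoring."""
    return morisita_horn(quadrats(cancer, lymph, width))


def width_sweep(
    cancer: np.ndarray,
    lymph: np.ndarray,
    widths: np.ndarray,
) -> list[ColocalizationResult]:
    """Diagnostic sensitivity sweep of MH over quadrat widths."""
    return [colocalization(cancer, lymph, float(w)) for w in widths]


def immune_abundance(cells: SlideTable) -> float:
    """Lymphocyte percentage among classified cells.

    The denominator covers cancer + lymphocyte + stromal cells; ``other``
    cells are excluded.
    """
    counts = {c: 0 for c in CORE_CLASSES}
    for cell in cells.cells:
        if cell.cls in counts:
            counts[cell.cls] += 1
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError("no classified cells in the three scored classes")
    return 100.0 * counts["lymphocyte"] / denom
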