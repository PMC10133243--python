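"""Core data types and delimited-text I/O.

Coordinates are stored in micrometres (µm), origin at the image top-left,
y increasing downward (image convention).  Pixel-space inputs are converted
on read using a ``microns_per_pixel`` scale.  The cell-class vocabulary is
closed: ``cancer``, ``lymphocyte``, ``stromal`` and ``other``; any other
label is an error, never silently remapped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: the closed class vocabulary (cancer = malignant epithelial cells,
#: lymphocyte includes plasma cells, stromal = fibroblasts + endothelium,
#: other = everything non-identifiable).
CELL_CLASSES: tuple[str, ...] = ("cancer", "lymphocyte", "stromal", "other")

#: the three classes that carry ground-truth annotations and enter metrics.
CORE_CLASSES: tuple[str, ...] = ("cancer", "lymphocyte", "stromal")

SOURCES: tuple[str, ...] = ("annotation", "prediction")

TUMOUR_TYPES: tuple[str, ...] = (
    "round-cell",
    "epithelial",
    "mesenchymal",
    "neuroendocrine",
    "sex-cord stromal",
)


class FormatError(ValueError):
    """Raised when an input file violates the expected schema."""


@dataclass(frozen=True)
class CellRecord:
    """One detected or annotated cell.

    Parameters
    ----------
    cell_id : opaque identifier, unique within one source.
    x, y : position in µm (top-left origin, y downward).
    cls : one of :data:`CELL_CLASSES`.
    source : ``"annotation"`` (pathologist ground truth) or ``"prediction"``.
    """

    cell_id: str
    x: float
    y: float
    cls: str
    source: str = "annotation"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"cell {self.cell_id!r}: non-finite position")
        if self.x < 0 or self.y < 0:
            raise ValueError(f"cell {self.cell_id!r}: negative position")
        if self.cls not in CELL_CLASSES:
            raise ValueError(
                f"cell {self.cell_id!r}: unknown class {self.cls!r}; "
                f"allowed labels are {', '.join(CELL_CLASSES)}"
            )
        if self.source not in SOURCES:
            raise ValueError(f"cell {self.cell_id!r}: unknown source {self.source!r}")


@dataclass
class SlideTable:
    """All cells of one slide, with slide-level metadata."""

    slide_id: str
    species_code: str
    microns_per_pixel: float
    cells: list[CellRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.microns_per_pixel > 0:
            raise ValueError("microns_per_pixel must be > 0")
        for src in SOURCES:
            ids = [c.cell_id for c in self.cells if c.source == src]
            if len(ids) != len(set(ids)):
                raise ValueError(f"duplicate cell_ids within source {src!r}")

    def __len__(self) -> int:
        return len(self.cells)

    def filter(self, cls: str | None = None, source: str | None = None) -> "SlideTable":
        kept = [
            c
            for c in self.cells
            if (cls is None or c.cls == cls) and (source is None or c.source == source)
        ]
        return SlideTable(self.slide_id, self.species_code, self.microns_per_pixel, kept)

    def positions(self, cls: str | None = None, source: str | None = None) -> np.ndarray:
        """(n, 2) array of x, y positions in µm."""
        return np.array(
            [[c.x, c.y] for c in self.filter(cls, source).cells], dtype=float
        ).reshape(-1, 2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [c.cell_id for c in self.cells],
                "x": [c.x for c in self.cells],
                "y": [c.y for c in self.cells],
                "class": [c.cls for c in self.cells],
                "source": [c.source for c in self.cells],
            }
        )


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject of a survival cohort.

    ``time`` is overall survival in days; ``event`` is 1 for death, 0 for
    censoring.  ``coloc100`` is the Morisita–Horn tumour–immune
    colocalisation score on the 0–100 scale.
    """

    subject_id: str
    time: float
    event: int
    age: float
    lymphocyte_pct: float
    coloc100: float

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ValueError(f"subject {self.subject_id!r}: time must be > 0")
        if self.event not in (0, 1):
            raise ValueError(f"subject {self.subject_id!r}: event must be 0 or 1")
        if not 0.0 <= self.coloc100 <= 100.0:
            raise ValueError(f"subject {self.subject_id!r}: coloc100 outside [0, 100]")


CELL_TABLE_COLUMNS = ("id", "x", "y", "class", "source")
SURVIVAL_COLUMNS = ("subject_id", "time", "event", "age", "lymphocyte_pct", "coloc100")


def read_cell_table(
    path: str | Path,
    scale: float,
    slide_id: str | None = None,
    species_code: str = "",
) -> SlideTable:
    """Read a comma-delimited cell table; coordinates are pixels × ``scale`` µm/px.

    The file must carry a header with columns ``id,x,y,class,source``
    (``source`` defaults to ``annotation`` when absent).  Unknown class
    labels and non-numeric coordinates are rejected with the offending
    row named.
    """
    path = Path(path)
    if not scale > 0:
        raise ValueError("scale must be > 0")
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in ("id", "x", "y", "class") if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required column(s) {missing}")
    if "source" not in df.columns:
        df["source"] = "annotation"
    cells: list[CellRecord] = []
    for i, row in enumerate(df.to_dict("records")):
        try:
            x = float(row["x"]) * scale
            y = float(row["y"]) * scale
        except (TypeError, ValueError) as exc:
            raise FormatError(
                f"{path.name}, row {i + 2}: non-numeric coordinate "
                f"({row['x']!r}, {row['y']!r})"
            ) from exc
        cells.append(CellRecord(str(row["id"]), x, y, row["class"], row["source"]))
    return SlideTable(
        slide_id=slide_id if slide_id is not None else path.stem,
        species_code=species_code,
        microns_per_pixel=scale,
        cells=cells,
    )


def write_cell_table(table: SlideTable, path: str | Path) -> None:
    """Write a cell table back to delimited text, converting µm to pixels."""
    df = table.to_frame()
    df["x"] = df["x"] / table.microns_per_pixel
    df["y"] = df["y"] / table.microns_per_pixel
    df.to_csv(path, index=False)


def read_survival_table(path: str | Path) -> list[SurvivalRecord]:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in SURVIVAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required column(s) {missing}")
    return [
        SurvivalRecord(
            subject_id=str(r.subject_id),
            time=float(r.time),
            event=int(r.event),
            age=float(r.age),
            lymphocyte_pct=float(r.lymphocyte_pct),
            coloc100=float(r.coloc100),
        )
        for r in df.itertuples(index=False)
    ]


def write_survival_table(records: Iterable[SurvivalRecord], path: str | Path) -> None:
    pd.DataFrame([r.__dict__ for r in records]).to_csv(path, index=False)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a label mask (16-bit) or intensity image (8-bit) as TIFF/PNG."""
    import tifffile
    from PIL import Image

    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, mask)
    else:
        Image.fromarray(mask).save(path)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a single-channel label mask or intensity image."""
    import tifffile
    from PIL import Image

    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim != 2:
        raise FormatError(f"{path.name}: expected a single-channel image, got shape {arr.shape}")
    return arr


def survival_frame(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    """Survival records as a DataFrame (the fitting modules' input form)."""
    df = pd.DataFrame([r.__dict__ for r in records])
    return df.set_index("subject_id")
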