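"""The bundled 20-species balanced-accuracy reference table.

One H&E section per species was scored by a human-trained single-cell
classifier against veterinary-pathologist annotations; each row records the
species code, tumour type, number of single-cell annotations and the overall
balanced classification accuracy (BCAcc).  The table ships with the package
so the cohort-level statistics can be recomputed without any external data.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .datamodel import TUMOUR_TYPES

#: SHA-256 of the bundled CSV; pins the fixture to the published values.
SPECIES_BCACC_SHA256 = "ea9641a596526bf8c449dcb8564252322a832e74f154bb272434d3ad3907e484"

#: expected number of species per tumour type.
TUMOUR_TYPE_COUNTS = {
    "round-cell": 4,
    "epithelial": 9,
    "mesenchymal": 4,
    "neuroendocrine": 2,
    "sex-cord stromal": 1,
}


@dataclass(frozen=True)
class SpeciesRow:
    code: str
    common_name: str
    scientific_name: str
    diagnosis: str
    site: str
    tumour_type: str
    annotations: int
    bcacc: float

    def __post_init__(self) -> None:
        if self.tumour_type not in TUMOUR_TYPES:
            raise ValueError(f"unknown tumour type {self.tumour_type!r}")
        if not 0.0 <= self.bcacc <= 1.0:
            raise ValueError("bcacc must be a fraction in [0, 1]")
        if self.annotations <= 0:
            raise ValueError("annotations must be positive")


def _fixture_bytes() -> bytes:
    return (
        resources.files("panmorph").joinpath("data/species_bcacc.csv").read_bytes()
    )


def fixture_checksum() -> str:
    return hashlib.sha256(_fixture_bytes()).hexdigest()


def load_species_table(verify: bool = True) -> pd.DataFrame:
    """Load the 20-species BCAcc table as a DataFrame.

    With ``verify`` (default), the file checksum and the per-tumour-type
    row counts are asserted before returning.
    """
    if verify and fixture_checksum() != SPECIES_BCACC_SHA256:
        raise RuntimeError("species BCAcc fixture does not match pinned checksum")
    df = pd.read_csv(
        resources.files("panmorph").joinpath("data/species_bcacc.csv"),
        dtype={"annotations": int, "bcacc": float},
    )
    if verify:
        if len(df) != 20:
            raise RuntimeError(f"expected 20 species rows, found {len(df)}")
        counts = df["tumour_type"].value_counts().to_dict()
        if counts != TUMOUR_TYPE_COUNTS:
            raise RuntimeError(f"tumour-type counts {counts} != {TUMOUR_TYPE_COUNTS}")
    return df


def load_species_rows(verify: bool = True) -> list[SpeciesRow]:
    """The same table as a list of :class:`SpeciesRow`."""
    return [SpeciesRow(**rec) for rec in load_species_table(verify).to_dict("records")]
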