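"""Embedded per-residue amino-acid property tables (features C1--C21).

Twenty-one physicochemical and structural characteristics — hydrophobicity,
molecular weight, bulkiness, polarity, secondary-structure propensities and
so on — each mapping the 20 standard amino acids to a real number.  The
values are transcribed from the published scales of the ProtScale
collection and frozen in ``data/aa_scales.tsv`` (one row per scale with its
name and literature citation) so that the package builds without network
access and the tables stay diffable.  Where a characteristic exists in
several published numeric variants, the shipped variant is identified by
the ``citation`` field of the table.

Nonstandard residues (B, J, O, U, X, Z) have no values; sequences
containing them are rejected upstream.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from types import MappingProxyType
from typing import Mapping

from .peptides import STANDARD_AA

#: identifier of the hydrophobicity scale used by the mutation features
KYTE_DOOLITTLE = "C1"

SCALE_IDS = tuple(f"C{i}" for i in range(1, 22))


class UnknownScaleError(KeyError):
    """Raised when a scale identifier is not in the bundled set."""


@dataclass(frozen=True)
class AminoAcidScale:
    """One named per-residue property table.

    ``values`` maps each of the 20 standard one-letter codes to a real
    number; the table is complete by construction (load-time check).
    """

    id: str
    name: str
    citation: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = sorted(set(STANDARD_AA) - set(self.values))
        extra = sorted(set(self.values) - set(STANDARD_AA))
        if missing or extra:
            raise ValueError(
                f"scale {self.id}: values must cover exactly the 20 standard "
                f"amino acids (missing {missing}, unexpected {extra})"
            )
        object.__setattr__(self, "values", MappingProxyType(dict(self.values)))

    def __getitem__(self, aa: str) -> float:
        return self.values[aa]


@lru_cache(maxsize=1)
def load_scales() -> Mapping[str, AminoAcidScale]:
    """All bundled scales, keyed by identifier (C1..C21)."""
    path = resources.files("epiforest.data").joinpath("aa_scales.tsv")
    scales: dict[str, AminoAcidScale] = {}
    with path.open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            sid = row["scale_id"]
            if sid in scales:
                raise ValueError(f"duplicate scale id {sid} in bundled table")
            values = {aa: float(row[aa]) for aa in STANDARD_AA}
            scales[sid] = AminoAcidScale(
                id=sid, name=row["name"], citation=row["citation"], values=values
            )
    if set(scales) != set(SCALE_IDS):
        raise ValueError(
            f"bundled scale set mismatch: expected {SCALE_IDS}, got {sorted(scales)}"
        )
    return MappingProxyType(scales)


def get_scale(scale_id: str) -> AminoAcidScale:
    """Look up a bundled scale by identifier.

    >>> get_scale("C1")["I"]
    4.5
    """
    scales = load_scales()
    try:
        return scales[scale_id]
    except KeyError:
        raise UnknownScaleError(
            f"unknown scale id {scale_id!r}; valid identifiers are "
            f"{', '.join(SCALE_IDS)}"
        ) from None


def list_scales() -> list[AminoAcidScale]:
    """All bundled scales in C1..C21 order."""
    scales = load_scales()
    return [scales[sid] for sid in SCALE_IDS]
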