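"""Canonical essential-amino-acid keys and fixed-length quantity vectors.

Protein quality is scored over ten entities: the nine essential (indispensable)
amino acids, with phenylalanine and tyrosine combined into a single entity
(reference patterns give no separate recommendation for them, because
tyrosine's phenylalanine-sparing capacity cannot be quantified) and cysteine
tracked as its own entity so that methionine surplus can be credited to it.

The canonical ordering defined here is used everywhere: serialization,
tie-breaking of limiting amino acids, and array layouts.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping
from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = ["EAAKey", "AminoAcidVector", "CANONICAL_ORDER"]


class EAAKey(str, Enum):
    """The ten scored amino-acid entities, in canonical order."""

    HIS = "his"
    ILE = "ile"
    LEU = "leu"
    LYS = "lys"
    MET = "met"
    CYS = "cys"
    PHE_TYR = "phe_tyr"
    THR = "thr"
    TRP = "trp"
    VAL = "val"

    @property
    def display(self) -> str:
        """Full amino-acid name as reported in tables (e.g. 'methionine')."""
        return _DISPLAY[self]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_DISPLAY = {
    EAAKey.HIS: "histidine",
    EAAKey.ILE: "isoleucine",
    EAAKey.LEU: "leucine",
    EAAKey.LYS: "lysine",
    EAAKey.MET: "methionine",
    EAAKey.CYS: "cysteine",
    EAAKey.PHE_TYR: "phenylalanine+tyrosine",
    EAAKey.THR: "threonine",
    EAAKey.TRP: "tryptophan",
    EAAKey.VAL: "valine",
}

#: Fixed canonical ordering of the ten scored entities.
CANONICAL_ORDER: tuple[EAAKey, ...] = tuple(EAAKey)

_INDEX: dict[EAAKey, int] = {k: i for i, k in enumerate(CANONICAL_ORDER)}


@dataclass(frozen=True)
class AminoAcidVector:
    """Non-negative quantity per scored amino acid, in canonical order.

    Units are context-dependent: mg per g protein in food-composition tables,
    absolute mg in meal intakes and requirement sets. Entries are never
    missing — an absent amino acid is an explicit zero.
    """

    _values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self._values) != len(CANONICAL_ORDER):
            raise ValueError(
                f"expected {len(CANONICAL_ORDER)} entries, got {len(self._values)}"
            )
        for key, v in zip(CANONICAL_ORDER, self._values):
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{key.value}: entry must be finite and >= 0, got {v}")

    # -- constructors --------------------------------------------------
    @classmethod
    def from_mapping(cls, mapping: Mapping[EAAKey | str, float]) -> "AminoAcidVector":
        """Build from a {key: value} mapping; absent keys become 0."""
        values = [0.0] * len(CANONICAL_ORDER)
        for raw_key, v in mapping.items():
            key = EAAKey(raw_key) if not isinstance(raw_key, EAAKey) else raw_key
            values[_INDEX[key]] = float(v)
        return cls(tuple(values))

    @classmethod
    def from_values(cls, values: Iterable[float]) -> "AminoAcidVector":
        """Build from values already in canonical order."""
        return cls(tuple(float(v) for v in values))

    @classmethod
    def zero(cls) -> "AminoAcidVector":
        return cls((0.0,) * len(CANONICAL_ORDER))

    # -- access --------------------------------------------------------
    def __getitem__(self, key: EAAKey) -> float:
        return self._values[_INDEX[key]]

    def as_dict(self) -> dict[EAAKey, float]:
        return dict(zip(CANONICAL_ORDER, self._values))

    def to_array(self) -> np.ndarray:
        return np.asarray(self._values, dtype=float)

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other: "AminoAcidVector") -> "AminoAcidVector":
        return AminoAcidVector(
            tuple(a + b for a, b in zip(self._values, other._values))
        )

    def scale(self, factor: float) -> "AminoAcidVector":
        if factor < 0:
            raise ValueError("scale factor must be >= 0")
        return AminoAcidVector(tuple(v * factor for v in self._values))

    def replace(self, key: EAAKey, value: float) -> "AminoAcidVector":
        values = list(self._values)
        values[_INDEX[key]] = float(value)
        return AminoAcidVector(tuple(values))

    def total(self) -> float:
        return float(sum(self._values))

    def is_zero(self) -> bool:
        return all(v == 0.0 for v in self._values)
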