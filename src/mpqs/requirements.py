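"""Personalized essential-amino-acid requirements.

A meal should deliver, for each essential amino acid, at least

    body_weight_kg x protein_target_g_per_kg x pattern_mg_per_g_protein   [mg]

where the pattern is the FAO/WHO amino-acid scoring pattern for ages >3 y,
expressed in mg per g of high-quality protein, and the default per-meal
protein target is 0.3 g/kg body weight — an amount sufficient to stimulate
muscle protein synthesis, which over three main meals plus snacks lands in
the 1.0-1.2 g/kg/d range recommended for older adults.

The same product form yields per-day requirements from a daily protein
target (e.g. 0.8 or 1.2 g/kg/d), for scoring cumulative daily intake.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .aminoacids import CANONICAL_ORDER, AminoAcidVector, EAAKey

__all__ = [
    "ReferencePattern",
    "PersonProfile",
    "RequirementSet",
    "DEFAULT_PATTERN",
    "DEFAULT_MEAL_PROTEIN_G_PER_KG",
    "meal_requirements",
    "daily_requirements",
    "load_pattern",
]

#: Default per-meal protein-quantity target, g of high-quality protein per kg
#: body weight per meal moment.
DEFAULT_MEAL_PROTEIN_G_PER_KG = 0.3

#: Per-kg-bodyweight EAA requirements (mg/kg bw) at the 0.3 g/kg meal target.
#: These equal the FAO/WHO >3 y pattern (mg/g protein) multiplied by 0.3.
REQUIREMENT_MG_PER_KG_AT_MEAL_TARGET: dict[EAAKey, float] = {
    EAAKey.HIS: 4.5,
    EAAKey.ILE: 9.0,
    EAAKey.LEU: 17.7,
    EAAKey.LYS: 13.5,
    EAAKey.MET: 4.8,
    EAAKey.CYS: 1.8,
    EAAKey.PHE_TYR: 11.4,
    EAAKey.THR: 6.9,
    EAAKey.TRP: 1.8,
    EAAKey.VAL: 11.7,
}


@dataclass(frozen=True)
class ReferencePattern:
    """Amino-acid scoring pattern in mg per g of dietary protein.

    All entries must be strictly positive (a zero requirement would make
    coverage undefined). Users may substitute e.g. a leucine-enriched
    pattern for older adults via :func:`load_pattern`.
    """

    mg_per_g_protein: AminoAcidVector
    name: str = "custom"

    def __post_init__(self) -> None:
        for key, v in self.mg_per_g_protein.as_dict().items():
            if v <= 0:
                raise ValueError(f"pattern entry {key.value} must be > 0, got {v}")


#: FAO/WHO 2007 scoring pattern for >3 y, mg EAA per g protein.
DEFAULT_PATTERN = ReferencePattern(
    mg_per_g_protein=AminoAcidVector.from_mapping(
        {
            EAAKey.HIS: 15.0,
            EAAKey.ILE: 30.0,
            EAAKey.LEU: 59.0,
            EAAKey.LYS: 45.0,
            EAAKey.MET: 16.0,
            EAAKey.CYS: 6.0,
            EAAKey.PHE_TYR: 38.0,
            EAAKey.THR: 23.0,
            EAAKey.TRP: 6.0,
            EAAKey.VAL: 39.0,
        }
    ),
    name="FAO/WHO >3y",
)

# Startup self-test: the built-in pattern scaled by the 0.3 g/kg meal target
# must reproduce the published per-kg requirements to one decimal.
for _key in CANONICAL_ORDER:
    _derived = DEFAULT_PATTERN.mg_per_g_protein[_key] * DEFAULT_MEAL_PROTEIN_G_PER_KG
    _expected = REQUIREMENT_MG_PER_KG_AT_MEAL_TARGET[_key]
    if round(_derived, 1) != round(_expected, 1):  # pragma: no cover - guard
        raise AssertionError(
            f"default pattern inconsistent for {_key.value}: "
            f"{_derived:.2f} != {_expected:.2f} mg/kg"
        )
del _key, _derived, _expected


class PersonProfile(BaseModel):
    """A person for whom requirements are personalized by body weight."""

    model_config = ConfigDict(frozen=True)

    person_id: str
    body_weight_kg: float = Field(gt=0)


@dataclass(frozen=True)
class RequirementSet:
    """Personalized mg requirements per EAA, per meal or per day."""

    mg: AminoAcidVector
    scope: Literal["per_meal", "per_day"]
    protein_target_g: float

    def __post_init__(self) -> None:
        for key, v in self.mg.as_dict().items():
            if v <= 0:
                raise ValueError(f"requirement {key.value} must be > 0, got {v}")

    def __getitem__(self, key: EAAKey) -> float:
        return self.mg[key]


def meal_requirements(
    person: PersonProfile,
    pattern: ReferencePattern = DEFAULT_PATTERN,
    protein_target_g_per_kg: float = DEFAULT_MEAL_PROTEIN_G_PER_KG,
) -> RequirementSet:
    """Per-meal EAA requirements for a person.

    requirement(EAA) = body_weight_kg x protein_target_g_per_kg x pattern(EAA).
    For a 70 kg person at the default target this gives e.g. 336 mg
    methionine (70 x 4.8 mg/kg).
    """
    if protein_target_g_per_kg <= 0:
        raise ValueError("protein target must be > 0 g/kg")
    protein_target_g = person.body_weight_kg * protein_target_g_per_kg
    return RequirementSet(
        mg=pattern.mg_per_g_protein.scale(protein_target_g),
        scope="per_meal",
        protein_target_g=protein_target_g,
    )


def daily_requirements(
    person: PersonProfile,
    pattern: ReferencePattern = DEFAULT_PATTERN,
    protein_target_g_per_kg_per_day: float = 1.2,
) -> RequirementSet:
    """Per-day EAA requirements from a daily protein target (g/kg/d)."""
    if protein_target_g_per_kg_per_day <= 0:
        raise ValueError("daily protein target must be > 0 g/kg/d")
    if not 0.4 <= protein_target_g_per_kg_per_day <= 2.5:
        warnings.warn(
            f"daily protein target {protein_target_g_per_kg_per_day} g/kg/d is "
            "outside the usual 0.4-2.5 range",
            stacklevel=2,
        )
    protein_target_g = person.body_weight_kg * protein_target_g_per_kg_per_day
    return RequirementSet(
        mg=pattern.mg_per_g_protein.scale(protein_target_g),
        scope="per_day",
        protein_target_g=protein_target_g,
    )


def load_pattern(path: str | Path) -> ReferencePattern:
    """Load a reference-pattern override from YAML or JSON.

    Schema: ``{"name": str, "pattern_mg_per_g": {"his": 15, ...}}`` with all
    ten amino-acid keys present and positive.
    """
    path = Path(path)
    text = path.read_text()
    payload: Mapping = (
        json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    )
    raw = payload.get("pattern_mg_per_g")
    if not isinstance(raw, Mapping):
        raise ValueError(f"{path.name}: missing 'pattern_mg_per_g' mapping")
    missing = [k.value for k in CANONICAL_ORDER if k.value not in raw]
    if missing:
        raise ValueError(f"{path.name}: pattern missing keys: {missing}")
    vector = AminoAcidVector.from_mapping({k: float(v) for k, v in raw.items()})
    return ReferencePattern(
        mg_per_g_protein=vector, name=str(payload.get("name", path.stem))
    )
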