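"""The Meal Protein Quality Score (MPQS).

The score folds protein quantity, digestibility, amino-acid composition and
personalized requirements into one number:

    MPQS = 100 x min_i  sum_j( intake_ij x digestibility_j ) / requirement_i

where i ranges over the ten scored amino-acid entities and j over the foods
of the meal. A score of 0 means at least one essential amino acid is
entirely absent; 100 means every amino acid exactly reaches its requirement;
values above 100 mean every amino acid exceeds it. The amino acid attaining
the minimum is the limiting amino acid.

Methionine can be converted unidirectionally to cysteine in vivo, so before
coverage is computed, any methionine consumed above its own requirement is
credited ("topped up") to cysteine. Cysteine surplus never flows back to
methionine. Because the MPQS is a minimum and the donation happens only
above methionine's requirement, the top-up can rescue cysteine but never
change a methionine-limited score.

All summation is in full precision; rounding to integers happens only in
published-style display output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .aminoacids import CANONICAL_ORDER, AminoAcidVector, EAAKey
from .composition import (
    FoodRecordEntry,
    FoodTable,
    MealMoment,
    Portion,
    group_records,
)
from .requirements import RequirementSet

__all__ = [
    "MealIntake",
    "ScoreResult",
    "adjusted_eaa_intake",
    "met_cys_topup",
    "score_meal",
    "score_day",
    "meals_from_records",
    "round_half_up",
]


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero (display convention)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class MealIntake:
    """The portions one person ate at one meal moment on one day."""

    person_id: str
    day: int
    meal_moment: MealMoment
    portions: tuple[Portion, ...]

    @classmethod
    def from_portions(
        cls,
        portions: list[Portion],
        person_id: str = "",
        day: int = 1,
        meal_moment: MealMoment = MealMoment.LUNCH,
    ) -> "MealIntake":
        return cls(
            person_id=person_id,
            day=day,
            meal_moment=meal_moment,
            portions=tuple(portions),
        )


@dataclass(frozen=True)
class ScoreResult:
    """MPQS with per-amino-acid diagnostics for one meal (or one day).

    ``coverage_pct`` holds unrounded percentages; :meth:`rounded` gives the
    integer-rounded published style. ``limiting_eaa`` is ``None`` when every
    amino acid reaches its requirement (score >= 100).
    """

    mpqs: float
    limiting_eaa: EAAKey | None
    coverage_pct: AminoAcidVector
    adjusted_intake_mg: AminoAcidVector  # post top-up, post digestibility
    raw_intake_mg: AminoAcidVector  # pre digestibility, pre top-up
    requirement: RequirementSet
    total_protein_g: float
    plant_protein_g: float
    animal_protein_g: float
    energy_kcal: float
    pct_protein_without_aa_data: float
    tied_limiting: tuple[EAAKey, ...] = ()
    empty: bool = False

    @property
    def mpqs_truncated(self) -> float:
        """MPQS capped at 100 (scores above 100 indicate overconsumption)."""
        return min(self.mpqs, 100.0)

    @property
    def requirement_mg(self) -> AminoAcidVector:
        return self.requirement.mg

    def rounded(self) -> dict:
        """Published-style view: integer MPQS and coverage percentages."""
        return {
            "mpqs": round_half_up(self.mpqs),
            "mpqs_truncated": round_half_up(self.mpqs_truncated),
            "limiting_eaa": self.limiting_eaa.display if self.limiting_eaa else None,
            "coverage_pct": {
                k.value: round_half_up(v) for k, v in self.coverage_pct.as_dict().items()
            },
        }

    def to_dict(self) -> dict:
        """Full-precision machine-readable form (for JSON output)."""
        return {
            "mpqs": self.mpqs,
            "mpqs_rounded": round_half_up(self.mpqs),
            "mpqs_truncated": self.mpqs_truncated,
            "limiting_eaa": self.limiting_eaa.value if self.limiting_eaa else None,
            "limiting_eaa_name": (
                self.limiting_eaa.display if self.limiting_eaa else None
            ),
            "tied_limiting": [k.value for k in self.tied_limiting],
            "coverage_pct": {k.value: v for k, v in self.coverage_pct.as_dict().items()},
            "adjusted_intake_mg": {
                k.value: v for k, v in self.adjusted_intake_mg.as_dict().items()
            },
            "raw_intake_mg": {k.value: v for k, v in self.raw_intake_mg.as_dict().items()},
            "requirement_mg": {
                k.value: v for k, v in self.requirement.mg.as_dict().items()
            },
            "requirement_scope": self.requirement.scope,
            "protein_target_g": self.requirement.protein_target_g,
            "total_protein_g": self.total_protein_g,
            "plant_protein_g": self.plant_protein_g,
            "animal_protein_g": self.animal_protein_g,
            "energy_kcal": self.energy_kcal,
            "pct_protein_without_aa_data": self.pct_protein_without_aa_data,
            "empty": self.empty,
        }


def adjusted_eaa_intake(
    meal: MealIntake, table: FoodTable, apply_digestibility: bool = True
) -> AminoAcidVector:
    """Digestibility-adjusted amino-acid intake of a meal, in mg.

    For each amino acid: sum over foods of
    mass_g x protein_g_per_100g/100 x aa_mg_per_g_protein x digestibility,
    with the digestibility factor replaced by 1 when ``apply_digestibility``
    is off. Summation is in full precision — per-food contributions are
    never rounded.
    """
    total = AminoAcidVector.zero()
    for portion in meal.portions:
        food = table[portion.food_id]
        protein_g = portion.mass_g * food.protein_g_per_100g / 100.0
        factor = food.digestibility if apply_digestibility else 1.0
        total = total + food.aa_mg_per_g_protein.scale(protein_g * factor)
    return total


def met_cys_topup(intake: AminoAcidVector, req: RequirementSet) -> AminoAcidVector:
    """Credit methionine consumed above its requirement to cysteine.

    The transfer is unidirectional (Met -> Cys only) and leaves the reported
    methionine intake unchanged; only cysteine gains.
    """
    met_req = req[EAAKey.MET]
    if met_req <= 0:
        raise ValueError("methionine requirement must be > 0 for the top-up")
    surplus = max(0.0, intake[EAAKey.MET] - met_req)
    if surplus == 0.0:
        return intake
    return intake.replace(EAAKey.CYS, intake[EAAKey.CYS] + surplus)


def _score(
    meal_like: MealIntake,
    table: FoodTable,
    req: RequirementSet,
    apply_digestibility: bool,
) -> ScoreResult:
    raw = adjusted_eaa_intake(meal_like, table, apply_digestibility=False)
    adjusted = adjusted_eaa_intake(meal_like, table, apply_digestibility=apply_digestibility)
    topped = met_cys_topup(adjusted, req)

    coverage = AminoAcidVector.from_values(
        100.0 * topped[k] / req[k] for k in CANONICAL_ORDER
    )
    empty = len(meal_like.portions) == 0

    mpqs = min(coverage.as_dict().values())
    tied = tuple(
        k for k in CANONICAL_ORDER if math.isclose(coverage[k], mpqs, rel_tol=0.0, abs_tol=1e-9)
    )
    limiting = tied[0] if mpqs < 100.0 else None
    if empty:
        limiting = CANONICAL_ORDER[0]
        tied = CANONICAL_ORDER

    total_protein = plant_protein = animal_protein = energy = no_aa_protein = 0.0
    for portion in meal_like.portions:
        food = table[portion.food_id]
        protein_g = portion.mass_g * food.protein_g_per_100g / 100.0
        total_protein += protein_g
        energy += portion.mass_g * food.energy_kcal_per_100g / 100.0
        if food.origin == "plant":
            plant_protein += protein_g
        else:
            animal_protein += protein_g
        if not food.has_aa_data:
            no_aa_protein += protein_g

    return ScoreResult(
        mpqs=mpqs,
        limiting_eaa=limiting,
        coverage_pct=coverage,
        adjusted_intake_mg=topped,
        raw_intake_mg=raw,
        requirement=req,
        total_protein_g=total_protein,
        plant_protein_g=plant_protein,
        animal_protein_g=animal_protein,
        energy_kcal=energy,
        pct_protein_without_aa_data=(
            100.0 * no_aa_protein / total_protein if total_protein > 0 else 0.0
        ),
        tied_limiting=tied,
        empty=empty,
    )


def score_meal(
    meal: MealIntake,
    table: FoodTable,
    req: RequirementSet,
    apply_digestibility: bool = True,
) -> ScoreResult:
    """Score one meal against a per-meal requirement set.

    An empty meal scores 0 with the first canonical amino acid reported as
    limiting and the ``empty`` flag set.
    """
    if req.scope != "per_meal":
        raise ValueError("score_meal requires a per_meal requirement set; use score_day")
    return _score(meal, table, req, apply_digestibility)


def score_day(
    meals: list[MealIntake],
    table: FoodTable,
    req: RequirementSet,
    apply_digestibility: bool = True,
) -> ScoreResult:
    """Score the cumulative intake of one person-day against a per-day requirement.

    All meals (snacks included) are pooled and scored with the identical
    minimum-coverage computation.
    """
    if req.scope != "per_day":
        raise ValueError("score_day requires a per_day requirement set; use score_meal")
    persons = {m.person_id for m in meals}
    days = {m.day for m in meals}
    if len(persons) > 1 or len(days) > 1:
        raise ValueError(
            f"score_day expects one person-day, got persons={sorted(persons)} "
            f"days={sorted(days)}"
        )
    pooled = MealIntake(
        person_id=next(iter(persons)) if persons else "",
        day=next(iter(days)) if days else 1,
        meal_moment=MealMoment.DINNER,
        portions=tuple(p for m in meals for p in m.portions),
    )
    return _score(pooled, table, req, apply_digestibility)


def meals_from_records(entries: list[FoodRecordEntry]) -> list[MealIntake]:
    """Turn record entries into MealIntake groups, deterministically ordered."""
    return [
        MealIntake(person_id=pid, day=day, meal_moment=moment, portions=tuple(portions))
        for (pid, day, moment), portions in group_records(entries).items()
    ]
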