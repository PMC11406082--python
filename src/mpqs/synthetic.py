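"""Seeded generators for food tables, cohorts, and the worked example.

The generator emulates the contrastive structure that protein-quality
analyses of Western diets rest on:

- cereals (bread, rice, pasta) are lysine-poor relative to the reference
  pattern but adequate in methionine;
- legumes (pea, lentil, soy) show the opposite trend: lysine-rich but poor
  in the sulfur amino acids methionine and cysteine;
- animal foods carry every essential amino acid at or above the reference
  pattern and are highly (>=95%) digestible;
- collagen/gelatin contains no tryptophan at all, so a collagen-only meal
  scores 0;
- tubers (potato) sit in between, with modest protein density.

Cohort records are built so breakfasts are cereal-heavy and low in protein
while dinners are animal-rich, reproducing the qualitative pattern that
fully plant-based meals are mostly breakfasts and score lowest. Everything
is deterministic under the configured seed.

Template profiles are loosely modeled on typical literature values for
wheat, pea, milk/meat, gelatin, and potato protein; only the qualitative
bounds above are enforced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .aminoacids import AminoAcidVector, EAAKey
from .composition import FoodItem, FoodRecordEntry, FoodTable, MealMoment, Portion
from .requirements import DEFAULT_PATTERN, PersonProfile
from .scoring import MealIntake

__all__ = [
    "Archetype",
    "ARCHETYPES",
    "GeneratorConfig",
    "make_food_table",
    "make_cohort",
    "table2_fixture",
]

_REF = DEFAULT_PATTERN.mg_per_g_protein


@dataclass(frozen=True)
class Archetype:
    """A food class with a template amino-acid profile and qualitative bounds."""

    name: str
    origin: str  # plant | animal
    protein_g_per_100g: float
    energy_kcal_per_100g: float
    profile: AminoAcidVector  # mg per g protein
    digestibility_range: tuple[float, float]

    def validate_profile(self, profile: AminoAcidVector) -> None:
        """Enforce the archetype's qualitative bounds; raise on violation."""
        if self.name == "cereal":
            if profile[EAAKey.LYS] > _REF[EAAKey.LYS] * 0.7:
                raise ValueError("cereal profile must be lysine-poor (<= 0.7x reference)")
            if profile[EAAKey.MET] < _REF[EAAKey.MET]:
                raise ValueError("cereal profile must be at/above reference methionine")
        elif self.name == "legume":
            if profile[EAAKey.MET] + profile[EAAKey.CYS] >= (
                _REF[EAAKey.MET] + _REF[EAAKey.CYS]
            ):
                raise ValueError("legume profile must be Met+Cys poor")
            if profile[EAAKey.LYS] <= _REF[EAAKey.LYS]:
                raise ValueError("legume profile must be lysine-rich")
        elif self.name == "animal":
            for key, ref in _REF.as_dict().items():
                if profile[key] < ref:
                    raise ValueError(f"animal profile must be >= reference for {key.value}")
        elif self.name == "collagen":
            if profile[EAAKey.TRP] != 0.0:
                raise ValueError("collagen profile must contain zero tryptophan")

    def validate(self) -> None:
        self.validate_profile(self.profile)
        lo, hi = self.digestibility_range
        if not 0 < lo <= hi <= 1:
            raise ValueError(f"{self.name}: bad digestibility range ({lo}, {hi})")
        if self.name == "animal" and lo < 0.95:
            raise ValueError("animal foods must be >= 95% digestible")


def _profile(**mg_per_g: float) -> AminoAcidVector:
    return AminoAcidVector.from_mapping({EAAKey(k): v for k, v in mg_per_g.items()})


ARCHETYPES: dict[str, Archetype] = {
    a.name: a
    for a in [
        # wheat-like: lysine well below the reference pattern
        Archetype(
            name="cereal",
            origin="plant",
            protein_g_per_100g=11.0,
            energy_kcal_per_100g=250.0,
            profile=_profile(
                his=22, ile=38, leu=72, lys=27, met=18, cys=22,
                phe_tyr=78, thr=30, trp=11, val=45,
            ),
            digestibility_range=(0.85, 0.92),
        ),
        # pea-like: lysine-rich, sulfur-amino-acid poor
        Archetype(
            name="legume",
            origin="plant",
            protein_g_per_100g=8.0,
            energy_kcal_per_100g=120.0,
            profile=_profile(
                his=25, ile=42, leu=72, lys=70, met=10, cys=11,
                phe_tyr=85, thr=38, trp=9, val=47,
            ),
            digestibility_range=(0.70, 0.85),
        ),
        # milk/meat-like: complete and highly digestible
        Archetype(
            name="animal",
            origin="animal",
            protein_g_per_100g=20.0,
            energy_kcal_per_100g=180.0,
            profile=_profile(
                his=28, ile=48, leu=85, lys=80, met=26, cys=12,
                phe_tyr=80, thr=44, trp=12, val=55,
            ),
            digestibility_range=(0.95, 0.99),
        ),
        # gelatin: no tryptophan whatsoever
        Archetype(
            name="collagen",
            origin="animal",
            protein_g_per_100g=85.0,
            energy_kcal_per_100g=340.0,
            profile=_profile(
                his=7, ile=14, leu=28, lys=33, met=6, cys=0,
                phe_tyr=23, thr=18, trp=0, val=23,
            ),
            digestibility_range=(0.95, 0.99),
        ),
        # potato-like: modest protein, reasonably balanced
        Archetype(
            name="tuber",
            origin="plant",
            protein_g_per_100g=2.0,
            energy_kcal_per_100g=80.0,
            profile=_profile(
                his=19, ile=38, leu=60, lys=54, met=15, cys=12,
                phe_tyr=80, thr=37, trp=10, val=52,
            ),
            digestibility_range=(0.75, 0.88),
        ),
    ]
}

for _a in ARCHETYPES.values():
    _a.validate()
del _a


class MomentMix(BaseModel):
    """Archetype usage rules for one meal moment."""

    model_config = ConfigDict(frozen=True)

    vegan_probability: float = Field(default=0.0, ge=0, le=1)


class GeneratorConfig(BaseModel):
    """Knobs of the synthetic cohort; identical config + seed => identical output."""

    model_config = ConfigDict(frozen=True)

    seed: int = 0
    n_persons: int = Field(default=12, ge=1)
    n_days: int = Field(default=7, ge=1)
    n_foods_per_archetype: int = Field(default=3, ge=2)
    weight_mean_kg: float = 75.0
    weight_sd_kg: float = 13.0
    profile_jitter: float = Field(default=0.08, ge=0, le=0.3)
    breakfast_vegan_probability: float = Field(default=0.35, ge=0, le=1)
    snack_probability: float = Field(default=0.8, ge=0, le=1)
    large_snack_probability: float = Field(default=0.15, ge=0, le=1)


def _rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def make_food_table(config: GeneratorConfig) -> FoodTable:
    """Generate a food table with >= 2 jittered foods per archetype."""
    rng = _rng(config, 0)
    table = FoodTable(source="synthetic", version=f"seed={config.seed}")
    for arch in ARCHETYPES.values():
        for i in range(config.n_foods_per_archetype):
            jitter = rng.uniform(
                1.0 - config.profile_jitter, 1.0 + config.profile_jitter, size=10
            )
            values = arch.profile.to_array() * jitter
            profile = AminoAcidVector.from_values(np.round(values, 3))
            profile = _clamp_to_bounds(arch, profile)
            arch.validate_profile(profile)
            lo, hi = arch.digestibility_range
            digestibility = round(float(rng.uniform(lo, hi)), 3)
            protein = round(
                arch.protein_g_per_100g * float(rng.uniform(0.9, 1.1)), 2
            )
            energy = round(
                arch.energy_kcal_per_100g * float(rng.uniform(0.9, 1.1)), 1
            )
            table.add(
                FoodItem(
                    id=f"{arch.name}_{i + 1}",
                    name=f"synthetic {arch.name} #{i + 1}",
                    protein_g_per_100g=protein,
                    energy_kcal_per_100g=energy,
                    origin=arch.origin,  # type: ignore[arg-type]
                    digestibility=digestibility,
                    aa_mg_per_g_protein=profile,
                    has_aa_data=True,
                )
            )
    return table


def _clamp_to_bounds(arch: Archetype, profile: AminoAcidVector) -> AminoAcidVector:
    """Push a jittered profile back inside its archetype's qualitative bounds."""
    if arch.name == "cereal":
        profile = profile.replace(
            EAAKey.LYS, min(profile[EAAKey.LYS], _REF[EAAKey.LYS] * 0.7)
        )
        profile = profile.replace(
            EAAKey.MET, max(profile[EAAKey.MET], _REF[EAAKey.MET])
        )
    elif arch.name == "legume":
        profile = profile.replace(
            EAAKey.LYS, max(profile[EAAKey.LYS], _REF[EAAKey.LYS] + 1.0)
        )
        budget = (_REF[EAAKey.MET] + _REF[EAAKey.CYS]) - 1.0
        sulfur = profile[EAAKey.MET] + profile[EAAKey.CYS]
        if sulfur >= budget:
            shrink = budget / sulfur
            profile = profile.replace(EAAKey.MET, profile[EAAKey.MET] * shrink)
            profile = profile.replace(EAAKey.CYS, profile[EAAKey.CYS] * shrink)
    elif arch.name == "animal":
        for key, ref in _REF.as_dict().items():
            if profile[key] < ref:
                profile = profile.replace(key, ref)
    elif arch.name == "collagen":
        profile = profile.replace(EAAKey.TRP, 0.0)
    return profile


def _pick(rng: np.random.Generator, table: FoodTable, archetype: str) -> str:
    ids = [fid for fid in table.ids() if fid.startswith(f"{archetype}_")]
    return ids[int(rng.integers(len(ids)))]


def make_cohort(
    config: GeneratorConfig, table: FoodTable
) -> tuple[list[PersonProfile], list[FoodRecordEntry]]:
    """Generate person profiles and multi-day food records.

    Breakfasts are cereal-based and low in protein, with a configurable
    share of fully plant-based (cereal-only) breakfasts; lunches mix cereal,
    legume and sometimes animal foods; dinners are animal-rich. Snack
    entries are included so protein outside the main meals can be inspected.
    """
    rng = _rng(config, 1)
    persons = []
    for p in range(config.n_persons):
        weight = float(
            np.clip(rng.normal(config.weight_mean_kg, config.weight_sd_kg), 45.0, 120.0)
        )
        persons.append(
            PersonProfile(person_id=f"p{p + 1:03d}", body_weight_kg=round(weight, 1))
        )

    entries: list[FoodRecordEntry] = []

    def add(pid: str, day: int, moment: MealMoment, food_id: str, mass_g: float) -> None:
        entries.append(
            FoodRecordEntry(
                person_id=pid,
                day=day,
                meal_moment=moment,
                portion=Portion(food_id=food_id, mass_g=round(float(mass_g), 1)),
            )
        )

    for person in persons:
        pid = person.person_id
        for day in range(1, config.n_days + 1):
            # breakfast: cereal-heavy, low protein; sometimes fully plant-based
            add(pid, day, MealMoment.BREAKFAST, _pick(rng, table, "cereal"),
                rng.uniform(50, 90))
            if rng.random() >= config.breakfast_vegan_probability:
                add(pid, day, MealMoment.BREAKFAST, _pick(rng, table, "animal"),
                    rng.uniform(50, 150))
            # lunch: mixed plant sources, animal food in ~60% of lunches
            add(pid, day, MealMoment.LUNCH, _pick(rng, table, "cereal"),
                rng.uniform(60, 100))
            add(pid, day, MealMoment.LUNCH, _pick(rng, table, "legume"),
                rng.uniform(80, 150))
            if rng.random() < 0.6:
                add(pid, day, MealMoment.LUNCH, _pick(rng, table, "animal"),
                    rng.uniform(50, 120))
            # dinner: animal-rich with sides
            add(pid, day, MealMoment.DINNER, _pick(rng, table, "animal"),
                rng.uniform(100, 180))
            add(pid, day, MealMoment.DINNER, _pick(rng, table, "tuber"),
                rng.uniform(150, 250))
            if rng.random() < 0.5:
                add(pid, day, MealMoment.DINNER, _pick(rng, table, "legume"),
                    rng.uniform(50, 120))
            # snacks: usually small; occasionally a protein-rich one
            if rng.random() < config.snack_probability:
                if rng.random() < config.large_snack_probability:
                    add(pid, day, MealMoment.SNACK, _pick(rng, table, "animal"),
                        rng.uniform(150, 300))
                else:
                    snack_arch = ["cereal", "animal", "tuber"][int(rng.integers(3))]
                    add(pid, day, MealMoment.SNACK, _pick(rng, table, snack_arch),
                        rng.uniform(20, 60))
    return persons, sorted(
        entries,
        key=lambda e: (
            e.person_id,
            e.day,
            list(MealMoment).index(e.meal_moment),
            e.portion.food_id,
        ),
    )


# ----------------------------------------------------------------------
# Worked example
# ----------------------------------------------------------------------

# Digestibility-adjusted per-ingredient EAA contributions (mg) of the
# three-ingredient example meal, in canonical order. Ingredient C absorbs the
# display-rounding slack so columns sum exactly to the published totals
# (263, 488, 803, 706, 148, 128, 825, 430, 146 mg; valine is not part of the
# published example and is assigned a comfortable, non-limiting total).
_EXAMPLE_ADJUSTED_MG = {
    "example_a": (204.0, 368.0, 628.0, 517.0, 102.0, 107.0, 653.0, 312.0, 103.0, 400.0),
    "example_b": (30.0, 62.0, 91.0, 97.0, 23.0, 14.0, 99.0, 56.0, 26.0, 100.0),
    "example_c": (29.0, 58.0, 84.0, 92.0, 23.0, 7.0, 73.0, 62.0, 17.0, 100.0),
}
_EXAMPLE_DIGESTIBILITY = {"example_a": 0.94, "example_b": 0.75, "example_c": 0.64}
_EXAMPLE_PROTEIN_G_PER_100G = {"example_a": 20.0, "example_b": 5.0, "example_c": 8.0}


def table2_fixture() -> tuple[FoodTable, MealIntake, PersonProfile]:
    """The three-ingredient worked example: MPQS 44, methionine limiting.

    Ingredient profiles are reconstructed by dividing the published
    digestibility-adjusted contributions back through their digestibility
    factors (94%, 75%, 64%) at 100 g portions, so scoring the meal
    reproduces the published adjusted-intake totals exactly for a 70 kg
    person. Valine, absent from the published example, is set well above the
    methionine coverage so neither the score (44) nor the limiting amino
    acid changes.
    """
    table = FoodTable(source="synthetic worked example")
    portions = []
    for food_id, adjusted in _EXAMPLE_ADJUSTED_MG.items():
        digestibility = _EXAMPLE_DIGESTIBILITY[food_id]
        protein = _EXAMPLE_PROTEIN_G_PER_100G[food_id]
        protein_g_in_portion = protein  # 100 g portion
        profile = AminoAcidVector.from_values(
            mg / (digestibility * protein_g_in_portion) for mg in adjusted
        )
        table.add(
            FoodItem(
                id=food_id,
                name=f"synthetic ingredient {food_id[-1].upper()}",
                protein_g_per_100g=protein,
                energy_kcal_per_100g=150.0,
                origin="plant" if food_id != "example_a" else "animal",
                digestibility=digestibility,
                aa_mg_per_g_protein=profile,
                has_aa_data=True,
            )
        )
        portions.append(Portion(food_id=food_id, mass_g=100.0))
    meal = MealIntake(
        person_id="example",
        day=1,
        meal_moment=MealMoment.LUNCH,
        portions=tuple(portions),
    )
    person = PersonProfile(person_id="example", body_weight_kg=70.0)
    return table, meal, person
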