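import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from mpqs import (
    AminoAcidVector,
    EAAKey,
    FoodItem,
    FoodTable,
    GeneratorConfig,
    MealIntake,
    PersonProfile,
    Portion,
    make_cohort,
    make_food_table,
    meal_requirements,
    table2_fixture,
)


@pytest.fixture(scope="session")
def example():
    """The three-ingredient worked example: (table, meal, 70 kg person)."""
    return table2_fixture()


@pytest.fixture(scope="session")
def example_requirements(example):
    _, _, person = example
    return meal_requirements(person)


@pytest.fixture(scope="session")
def synthetic_table():
    return make_food_table(GeneratorConfig(seed=17))


@pytest.fixture(scope="session")
def synthetic_cohort(synthetic_table):
    config = GeneratorConfig(seed=17, n_persons=8, n_days=7)
    persons, records = make_cohort(config, synthetic_table)
    return persons, records


def make_food(
    food_id="f1",
    protein=10.0,
    digestibility=1.0,
    origin="animal",
    profile=None,
    energy=100.0,
):
    """Hand-built food with a flat 30 mg/g profile unless overridden."""
    if profile is None:
        profile = AminoAcidVector.from_values([30.0] * 10)
    return FoodItem(
        id=food_id,
        name=f"test food {food_id}",
        protein_g_per_100g=protein,
        energy_kcal_per_100g=energy,
        origin=origin,
        digestibility=digestibility,
        aa_mg_per_g_protein=profile,
        has_aa_data=not profile.is_zero(),
    )


def random_meal(rng: np.random.Generator, table: FoodTable, max_portions=5):
    ids = table.ids()
    n = int(rng.integers(1, max_portions + 1))
    portions = [
        Portion(food_id=ids[int(rng.integers(len(ids)))], mass_g=float(rng.uniform(5, 300)))
        for _ in range(n)
    ]
    return MealIntake.from_portions(portions)


def reference_score(meal, table, req, apply_digestibility=True):
    """Independent oracle: plain per-EAA dict loop, no shared scoring code.

    Recomputes digestibility-adjusted intake, the Met->Cys top-up, and the
    minimum coverage directly from food fields.
    """
    intake = {k: 0.0 for k in EAAKey}
    for portion in meal.portions:
        food = table[portion.food_id]
        grams_protein = portion.mass_g * food.protein_g_per_100g / 100.0
        factor = food.digestibility if apply_digestibility else 1.0
        for k in EAAKey:
            intake[k] += grams_protein * food.aa_mg_per_g_protein[k] * factor
    surplus = intake[EAAKey.MET] - req.mg[EAAKey.MET]
    if surplus > 0:
        intake[EAAKey.CYS] += surplus
    coverage = {k: 100.0 * intake[k] / req.mg[k] for k in EAAKey}
    mpqs = min(coverage.values())
    limiting = None
    if mpqs < 100.0:
        limiting = [k for k in EAAKey if coverage[k] == mpqs][0]
    return mpqs, limiting, coverage


@pytest.fixture
def person_70kg():
    return PersonProfile(person_id="p", body_weight_kg=70.0)
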