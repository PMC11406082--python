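"""Meal scoring: worked-example values, top-up rule, and score invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mpqs import (
    CANONICAL_ORDER,
    AminoAcidVector,
    EAAKey,
    FoodTable,
    MealIntake,
    PersonProfile,
    Portion,
    adjusted_eaa_intake,
    daily_requirements,
    meal_requirements,
    met_cys_topup,
    score_day,
    score_meal,
)
from mpqs.composition import MealMoment

from conftest import make_food, random_meal, reference_score

# Published digestibility-adjusted totals of the worked example, mg.
EXAMPLE_TOTALS = {
    EAAKey.HIS: 263,
    EAAKey.ILE: 488,
    EAAKey.LEU: 803,
    EAAKey.LYS: 706,
    EAAKey.MET: 148,
    EAAKey.CYS: 128,
    EAAKey.PHE_TYR: 825,
    EAAKey.THR: 430,
    EAAKey.TRP: 146,
}
EXAMPLE_COVERAGE = {
    EAAKey.HIS: 83,
    EAAKey.ILE: 77,
    EAAKey.LEU: 65,
    EAAKey.LYS: 75,
    EAAKey.MET: 44,
    EAAKey.CYS: 102,
    EAAKey.PHE_TYR: 103,
    EAAKey.THR: 89,
    EAAKey.TRP: 116,
}


class TestAdjustedIntake:
    def test_worked_example_totals(self, example):
        table, meal, _ = example
        intake = adjusted_eaa_intake(meal, table)
        for key, expected in EXAMPLE_TOTALS.items():
            assert intake[key] == pytest.approx(expected, abs=1e-9), key

    def test_empty_meal_is_all_zero(self, example):
        table, _, _ = example
        empty = MealIntake.from_portions([])
        assert adjusted_eaa_intake(empty, table).is_zero()

    def test_digestibility_off_divides_out_the_factor(self):
        food = make_food(digestibility=0.8, protein=10.0)
        table = FoodTable([food])
        meal = MealIntake.from_portions([Portion(food_id="f1", mass_g=100)])
        with_dig = adjusted_eaa_intake(meal, table, apply_digestibility=True)
        without = adjusted_eaa_intake(meal, table, apply_digestibility=False)
        for key in CANONICAL_ORDER:
            assert with_dig[key] == pytest.approx(0.8 * without[key])
        # 100 g x 10 g/100g protein x 30 mg/g = 300 mg unadjusted
        assert without[EAAKey.LYS] == pytest.approx(300.0)


class TestMetCysTopup:
    def test_no_surplus_leaves_cysteine_unchanged(self, example, example_requirements):
        table, meal, _ = example
        intake = adjusted_eaa_intake(meal, table)
        assert intake[EAAKey.MET] < example_requirements[EAAKey.MET]
        topped = met_cys_topup(intake, example_requirements)
        assert topped[EAAKey.CYS] == intake[EAAKey.CYS]
        assert topped[EAAKey.MET] == intake[EAAKey.MET]

    def test_surplus_moves_to_cysteine_only(self, example_requirements):
        intake = AminoAcidVector.from_mapping({EAAKey.MET: 500.0})
        topped = met_cys_topup(intake, example_requirements)
        assert topped[EAAKey.CYS] == pytest.approx(500 - 336)  # = 164
        assert topped[EAAKey.MET] == 500.0
        for key in CANONICAL_ORDER:
            if key not in (EAAKey.MET, EAAKey.CYS):
                assert topped[key] == intake[key]

    def test_met_exactly_at_requirement_is_no_op(self, example_requirements):
        intake = AminoAcidVector.from_mapping(
            {EAAKey.MET: example_requirements[EAAKey.MET], EAAKey.CYS: 10.0}
        )
        assert met_cys_topup(intake, example_requirements)[EAAKey.CYS] == 10.0

    def test_cysteine_surplus_never_flows_to_methionine(self, example_requirements):
        intake = AminoAcidVector.from_mapping({EAAKey.CYS: 10_000.0, EAAKey.MET: 1.0})
        topped = met_cys_topup(intake, example_requirements)
        assert topped[EAAKey.MET] == 1.0
        assert topped[EAAKey.CYS] == 10_000.0


class TestScoreMeal:
    def test_worked_example_scores_44_limited_by_methionine(
        self, example, example_requirements
    ):
        table, meal, _ = example
        result = score_meal(meal, table, example_requirements)
        rounded = result.rounded()
        assert rounded["mpqs"] == 44
        assert result.limiting_eaa == EAAKey.MET
        for key, expected in EXAMPLE_COVERAGE.items():
            assert rounded["coverage_pct"][key.value] == expected, key

    def test_worked_example_without_digestibility_scores_higher(
        self, example, example_requirements
    ):
        table, meal, _ = example
        adjusted = score_meal(meal, table, example_requirements)
        unadjusted = score_meal(
            meal, table, example_requirements, apply_digestibility=False
        )
        assert unadjusted.mpqs > adjusted.mpqs
        for key in CANONICAL_ORDER:
            assert unadjusted.coverage_pct[key] >= adjusted.coverage_pct[key]

    def test_collagen_only_meal_scores_zero(self, example_requirements):
        collagen = make_food(
            food_id="gelatin",
            protein=85.0,
            digestibility=0.98,
            profile=AminoAcidVector.from_mapping(
                {
                    EAAKey.HIS: 7, EAAKey.ILE: 14, EAAKey.LEU: 28, EAAKey.LYS: 33,
                    EAAKey.MET: 6, EAAKey.CYS: 0, EAAKey.PHE_TYR: 23,
                    EAAKey.THR: 18, EAAKey.TRP: 0, EAAKey.VAL: 23,
                }
            ),
        )
        table = FoodTable([collagen])
        meal = MealIntake.from_portions([Portion(food_id="gelatin", mass_g=100)])
        result = score_meal(meal, table, example_requirements)
        assert result.mpqs == 0.0
        assert result.limiting_eaa in (EAAKey.CYS, EAAKey.TRP)

    def test_empty_meal_scores_zero_with_flag(self, example, example_requirements):
        table, _, _ = example
        result = score_meal(MealIntake.from_portions([]), table, example_requirements)
        assert result.mpqs == 0.0
        assert result.empty
        assert result.limiting_eaa == CANONICAL_ORDER[0]

    def test_per_day_requirement_rejected(self, example, person_70kg):
        table, meal, _ = example
        req = daily_requirements(person_70kg)
        with pytest.raises(ValueError, match="per_meal"):
            score_meal(meal, table, req)

    def test_score_above_100_has_no_limiting_eaa(self, person_70kg):
        food = make_food(protein=50.0, digestibility=1.0)  # flat, generous profile
        table = FoodTable([food])
        meal = MealIntake.from_portions([Portion(food_id="f1", mass_g=1000)])
        result = score_meal(meal, table, meal_requirements(person_70kg))
        assert result.mpqs > 100
        assert result.limiting_eaa is None
        assert result.mpqs_truncated == 100.0

    def test_protein_origin_bookkeeping(self, person_70kg):
        plant = make_food("soy", protein=10, origin="plant")
        animal = make_food("egg", protein=12, origin="animal")
        table = FoodTable([plant, animal])
        meal = MealIntake.from_portions(
            [Portion(food_id="soy", mass_g=100), Portion(food_id="egg", mass_g=50)]
        )
        result = score_meal(meal, table, meal_requirements(person_70kg))
        assert result.plant_protein_g == pytest.approx(10.0)
        assert result.animal_protein_g == pytest.approx(6.0)
        assert result.total_protein_g == pytest.approx(16.0)

    def test_foods_without_aa_data_counted_in_protein_not_score(self, person_70kg):
        plain = make_food("milk", protein=10)
        unknown = make_food(
            "mystery", protein=10, profile=AminoAcidVector.zero()
        )
        table = FoodTable([plain, unknown])
        req = meal_requirements(person_70kg)
        base = score_meal(
            MealIntake.from_portions([Portion(food_id="milk", mass_g=100)]), table, req
        )
        mixed = score_meal(
            MealIntake.from_portions(
                [Portion(food_id="milk", mass_g=100), Portion(food_id="mystery", mass_g=100)]
            ),
            table,
            req,
        )
        assert mixed.mpqs == pytest.approx(base.mpqs)
        assert mixed.pct_protein_without_aa_data == pytest.approx(50.0)


class TestScoreDay:
    def test_day_of_identical_meals_matches_single_meal_score(
        self, example, person_70kg
    ):
        table, meal, _ = example
        meal_req = meal_requirements(person_70kg)
        day_req = daily_requirements(person_70kg, protein_target_g_per_kg_per_day=1.2)
        meals = [
            MealIntake(person_id="p", day=1, meal_moment=m, portions=meal.portions)
            for m in (
                MealMoment.BREAKFAST,
                MealMoment.LUNCH,
                MealMoment.DINNER,
                MealMoment.SNACK,
            )
        ]
        # 4 identical meals against a 4x requirement; no top-up is active
        assert score_day(meals, table, day_req).mpqs == pytest.approx(
            score_meal(meal, table, meal_req).mpqs
        )

    def test_zero_meals_score_zero(self, example, person_70kg):
        table, _, _ = example
        req = daily_requirements(person_70kg)
        assert score_day([], table, req).mpqs == 0.0

    def test_day_equals_single_pass_on_concatenated_portions(
        self, synthetic_table, person_70kg
    ):
        rng = np.random.default_rng(5)
        req = daily_requirements(person_70kg)
        meals = [
            MealIntake(
                person_id="p",
                day=1,
                meal_moment=m,
                portions=random_meal(rng, synthetic_table).portions,
            )
            for m in (MealMoment.BREAKFAST, MealMoment.LUNCH, MealMoment.DINNER)
        ]
        pooled = MealIntake.from_portions(
            [p for m in meals for p in m.portions], person_id="p"
        )
        expected_mpqs, expected_lim, _ = reference_score(pooled, synthetic_table, req)
        result = score_day(meals, synthetic_table, req)
        assert result.mpqs == pytest.approx(expected_mpqs, rel=1e-12)
        assert result.limiting_eaa == expected_lim

    def test_mixed_persons_rejected(self, example, person_70kg):
        table, meal, _ = example
        req = daily_requirements(person_70kg)
        meals = [
            MealIntake(person_id="a", day=1, meal_moment=MealMoment.LUNCH, portions=meal.portions),
            MealIntake(person_id="b", day=1, meal_moment=MealMoment.DINNER, portions=meal.portions),
        ]
        with pytest.raises(ValueError, match="one person-day"):
            score_day(meals, table, req)


class TestScoreInvariants:
    def test_oracle_equivalence_on_random_meals(self, synthetic_table):
        """Implementation matches an independent per-EAA loop to 1e-9 relative."""
        rng = np.random.default_rng(123)
        for _ in range(300):
            weight = float(rng.uniform(40, 120))
            req = meal_requirements(PersonProfile(person_id="r", body_weight_kg=weight))
            meal = random_meal(rng, synthetic_table)
            apply_dig = bool(rng.integers(2))
            expected_mpqs, expected_lim, expected_cov = reference_score(
                meal, synthetic_table, req, apply_dig
            )
            result = score_meal(meal, synthetic_table, req, apply_digestibility=apply_dig)
            assert result.mpqs == pytest.approx(expected_mpqs, rel=1e-9)
            assert result.limiting_eaa == expected_lim
            for key in CANONICAL_ORDER:
                assert result.coverage_pct[key] == pytest.approx(
                    expected_cov[key], rel=1e-9
                )

    @settings(max_examples=40, deadline=None)
    @given(k=st.integers(2, 7), seed=st.integers(0, 10_000))
    def test_partition_invariance(self, synthetic_table, k, seed):
        """Splitting any portion into k equal sub-portions changes nothing."""
        rng = np.random.default_rng(seed)
        req = meal_requirements(PersonProfile(person_id="r", body_weight_kg=70))
        meal = random_meal(rng, synthetic_table)
        split = MealIntake.from_portions(
            [
                Portion(food_id=p.food_id, mass_g=p.mass_g / k)
                for p in meal.portions
                for _ in range(k)
            ]
        )
        whole = score_meal(meal, synthetic_table, req)
        parts = score_meal(split, synthetic_table, req)
        assert parts.mpqs == pytest.approx(whole.mpqs, rel=1e-9)
        assert parts.limiting_eaa == whole.limiting_eaa

    def test_digestibility_monotonicity(self, person_70kg):
        """Coverage is non-decreasing in every food's digestibility factor."""
        req = meal_requirements(person_70kg)
        rng = np.random.default_rng(7)
        profile = AminoAcidVector.from_values(rng.uniform(5, 90, size=10))
        meal = MealIntake.from_portions([Portion(food_id="f1", mass_g=150)])
        previous = None
        for dig in (0.2, 0.5, 0.8, 1.0):
            table = FoodTable([make_food(digestibility=dig, profile=profile)])
            result = score_meal(meal, table, req)
            if previous is not None:
                for key in CANONICAL_ORDER:
                    assert result.coverage_pct[key] >= previous.coverage_pct[key]
            previous = result

    @settings(max_examples=40, deadline=None)
    @given(scale=st.floats(0.1, 3.0, allow_nan=False), seed=st.integers(0, 10_000))
    def test_conditional_homogeneity_in_portion_mass(self, synthetic_table, scale, seed):
        """With no Met top-up active, scaling all masses by k scales MPQS by k."""
        rng = np.random.default_rng(seed)
        req = meal_requirements(PersonProfile(person_id="r", body_weight_kg=70))
        meal = random_meal(rng, synthetic_table)
        scaled = MealIntake.from_portions(
            [Portion(food_id=p.food_id, mass_g=p.mass_g * scale) for p in meal.portions]
        )
        base_intake = adjusted_eaa_intake(meal, synthetic_table)
        if max(base_intake[EAAKey.MET], base_intake[EAAKey.MET] * scale) > req[EAAKey.MET]:
            return  # top-up active: linearity not expected
        base = score_meal(meal, synthetic_table, req)
        result = score_meal(scaled, synthetic_table, req)
        assert result.mpqs == pytest.approx(scale * base.mpqs, rel=1e-9)

    @settings(max_examples=40, deadline=None)
    @given(weight=st.floats(40, 140, allow_nan=False), seed=st.integers(0, 10_000))
    def test_inverse_body_weight_scaling(self, synthetic_table, weight, seed):
        """With no top-up active, MPQS at weight w = MPQS at 70 kg x 70/w."""
        rng = np.random.default_rng(seed)
        meal = random_meal(rng, synthetic_table)
        req70 = meal_requirements(PersonProfile(person_id="r", body_weight_kg=70))
        reqw = meal_requirements(PersonProfile(person_id="r", body_weight_kg=weight))
        intake = adjusted_eaa_intake(meal, synthetic_table)
        if intake[EAAKey.MET] > min(req70[EAAKey.MET], reqw[EAAKey.MET]):
            return
        at70 = score_meal(meal, synthetic_table, req70).mpqs
        atw = score_meal(meal, synthetic_table, reqw).mpqs
        assert atw == pytest.approx(at70 * 70.0 / weight, rel=1e-9)

    def test_zero_score_iff_some_eaa_absent(self, person_70kg):
        req = meal_requirements(person_70kg)
        no_trp = make_food(
            "collagen",
            protein=80,
            profile=AminoAcidVector.from_mapping(
                {k: 20.0 for k in CANONICAL_ORDER if k != EAAKey.TRP}
            ),
        )
        complete = make_food("whey", protein=80)
        table = FoodTable([no_trp, complete])
        zero = score_meal(
            MealIntake.from_portions([Portion(food_id="collagen", mass_g=100)]), table, req
        )
        assert zero.mpqs == 0.0
        rescued = score_meal(
            MealIntake.from_portions(
                [
                    Portion(food_id="collagen", mass_g=100),
                    Portion(food_id="whey", mass_g=10),
                ]
            ),
            table,
            req,
        )
        assert rescued.mpqs > 0.0

    def test_limiting_tie_break_uses_canonical_order(self, person_70kg):
        req = meal_requirements(person_70kg)
        # profile proportional to the requirement pattern -> all coverages tie
        pattern = req.mg
        profile = AminoAcidVector.from_values(
            pattern.to_array() / pattern.to_array().sum() * 1000
        )
        table = FoodTable([make_food(profile=profile, protein=10)])
        result = score_meal(
            MealIntake.from_portions([Portion(food_id="f1", mass_g=10)]), table, req
        )
        assert result.limiting_eaa == CANONICAL_ORDER[0]
        assert set(result.tied_limiting) == set(CANONICAL_ORDER)
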