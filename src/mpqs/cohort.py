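"""Batch scoring of food records and descriptive cohort analyses.

Given multi-day food records, each (person, day, main-meal) group is scored
twice — with and without digestibility adjustment — and summarized:

- per meal-moment statistics (mean, SEM, SD, median, IQR) of the MPQS and of
  the paired per-meal impact of the digestibility adjustment;
- plant-protein-proportion categories 0-27%, 27-65%, 65-<100%, exactly 100%
  (fully plant-based meals form their own category);
- frequency of the limiting amino acid by meal moment and by category;
- per-person summaries: median MPQS, share of meals reaching 100, daily
  protein/energy intake, and protein consumed outside the three main meals
  ("missed" protein), with a split report comparing persons whose median
  MPQS reaches 100 with those below.

No inferential statistics are computed here; the emitted tidy tables can be
fed to any statistics tool.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Literal

import numpy as np
import pandas as pd

from .aminoacids import CANONICAL_ORDER, EAAKey
from .composition import (
    MAIN_MEALS,
    FoodRecordEntry,
    FoodTable,
    MealMoment,
    validate_records,
)
from .requirements import (
    DEFAULT_MEAL_PROTEIN_G_PER_KG,
    DEFAULT_PATTERN,
    PersonProfile,
    ReferencePattern,
    meal_requirements,
)
from .scoring import MealIntake, ScoreResult, meals_from_records, score_meal

__all__ = [
    "PlantCategory",
    "MealSummary",
    "PersonSummary",
    "score_records",
    "moment_summary",
    "limiting_frequency",
    "person_summary",
    "MISSED_PROTEIN_THRESHOLD_G",
]

logger = logging.getLogger(__name__)

#: Daily protein outside main meals above which a day is flagged in the
#: missed-protein report.
MISSED_PROTEIN_THRESHOLD_G = 20.0


class PlantCategory(str, Enum):
    """Plant-protein proportion of a meal, percent of total protein.

    The edges are half-open on the right; the top category requires exactly
    100% (fully plant-based), so 65-<100% and vegan meals are distinguished.
    """

    P0_27 = "0-27%"
    P27_65 = "27-65%"
    P65_100 = "65-99%"
    P100 = "100%"

    @classmethod
    def of(cls, plant_pct: float) -> "PlantCategory":
        if not 0.0 <= plant_pct <= 100.0:
            raise ValueError(f"plant percentage out of range: {plant_pct}")
        if plant_pct == 100.0:
            return cls.P100
        if plant_pct < 27.0:
            return cls.P0_27
        if plant_pct < 65.0:
            return cls.P27_65
        return cls.P65_100


@dataclass(frozen=True)
class MealSummary:
    """One scored meal with both digestibility variants and plant diagnostics."""

    result: ScoreResult  # digestibility-adjusted
    result_nodig: ScoreResult  # factors forced to 1
    person_id: str
    day: int
    meal_moment: MealMoment
    plant_pct_protein: float
    plant_pct_aa: float
    category: PlantCategory

    @property
    def mpqs(self) -> float:
        return self.result.mpqs

    @property
    def mpqs_nodig(self) -> float:
        return self.result_nodig.mpqs

    @property
    def digestibility_impact_pct(self) -> float:
        """Relative MPQS loss due to the digestibility adjustment, percent."""
        if self.mpqs_nodig > 0:
            return 100.0 * (self.mpqs_nodig - self.mpqs) / self.mpqs_nodig
        return 0.0


@dataclass(frozen=True)
class PersonSummary:
    person_id: str
    n_meals: int
    median_mpqs: float
    iqr: tuple[float, float]
    pct_meals_ge_100: float
    protein_g_per_day: float
    protein_g_per_kg_per_day: float
    plant_protein_pct: float
    energy_kcal_per_day: float
    missed_protein_g_per_day: float
    n_days_missed_gt_threshold: int
    n_days: int


def _share_pct(part: float, total: float) -> float:
    """100 x part/total with exact 0/100 endpoints despite float slop."""
    if part <= 0.0:
        return 0.0
    if part >= total:
        return 100.0
    return min(100.0, 100.0 * part / total)


def _plant_aa_pct(meal: MealIntake, table: FoodTable) -> float:
    """Percent of the meal's total amino-acid mass from plant foods (unadjusted)."""
    plant = total = 0.0
    for portion in meal.portions:
        food = table[portion.food_id]
        aa_mg = (
            portion.mass_g
            * food.protein_g_per_100g
            / 100.0
            * food.aa_mg_per_g_protein.total()
        )
        total += aa_mg
        if food.origin == "plant":
            plant += aa_mg
    return _share_pct(plant, total) if total > 0 else float("nan")


def score_records(
    entries: list[FoodRecordEntry],
    persons: list[PersonProfile],
    table: FoodTable,
    include_snacks: bool = False,
    merge_before_breakfast: bool = False,
    pattern: ReferencePattern = DEFAULT_PATTERN,
    protein_target_g_per_kg: float = DEFAULT_MEAL_PROTEIN_G_PER_KG,
    plant_basis: Literal["protein", "aa"] = "protein",
) -> list[MealSummary]:
    """Score every (person, day, meal-moment) group of a food record.

    Main meals (breakfast, lunch, dinner) are scored; snacks only when
    ``include_snacks`` is set. ``merge_before_breakfast`` folds the rare
    'before breakfast' entries into breakfast. Meals with zero total protein
    cannot be categorized by plant proportion and are excluded with a logged
    count. ``plant_basis`` selects whether the plant category is driven by
    protein mass or by total amino-acid mass.
    """
    validate_records(entries, table)
    profiles = {p.person_id: p for p in persons}
    referenced = sorted({e.person_id for e in entries})
    missing = [pid for pid in referenced if pid not in profiles]
    if missing:
        raise ValueError(f"missing body weight for persons: {missing}")

    if merge_before_breakfast:
        entries = [
            e.model_copy(update={"meal_moment": MealMoment.BREAKFAST})
            if e.meal_moment == MealMoment.BEFORE_BREAKFAST
            else e
            for e in entries
        ]

    scored_moments = set(MAIN_MEALS) | ({MealMoment.SNACK} if include_snacks else set())
    requirements = {
        pid: meal_requirements(profiles[pid], pattern, protein_target_g_per_kg)
        for pid in referenced
    }

    summaries: list[MealSummary] = []
    n_zero_protein = 0
    for meal in meals_from_records(entries):
        if meal.meal_moment not in scored_moments:
            continue
        req = requirements[meal.person_id]
        result = score_meal(meal, table, req, apply_digestibility=True)
        if result.total_protein_g <= 0:
            n_zero_protein += 1
            continue
        result_nodig = score_meal(meal, table, req, apply_digestibility=False)
        plant_pct_protein = _share_pct(result.plant_protein_g, result.total_protein_g)
        plant_pct_aa = _plant_aa_pct(meal, table)
        basis_pct = plant_pct_protein if plant_basis == "protein" else plant_pct_aa
        summaries.append(
            MealSummary(
                result=result,
                result_nodig=result_nodig,
                person_id=meal.person_id,
                day=meal.day,
                meal_moment=meal.meal_moment,
                plant_pct_protein=plant_pct_protein,
                plant_pct_aa=plant_pct_aa,
                category=PlantCategory.of(basis_pct),
            )
        )
    if n_zero_protein:
        logger.info("excluded %d zero-protein meals from scoring", n_zero_protein)
    return summaries


def _moment_stats(values: np.ndarray) -> dict[str, float]:
    n = len(values)
    q25, med, q75 = (
        np.percentile(values, [25, 50, 75]) if n else (math.nan,) * 3
    )
    return {
        "n": n,
        "mean": float(np.mean(values)) if n else math.nan,
        "sd": float(np.std(values, ddof=1)) if n > 1 else math.nan,
        "sem": float(np.std(values, ddof=1) / math.sqrt(n)) if n > 1 else math.nan,
        "median": float(med),
        "q25": float(q25),
        "q75": float(q75),
    }


def moment_summary(summaries: list[MealSummary]) -> pd.DataFrame:
    """MPQS statistics per meal moment, with and without digestibility.

    Rows are ordered breakfast, lunch, dinner (then snack if present), one
    row per (moment, adjustment) pair, plus a paired-difference row per
    moment summarizing the per-meal drop caused by the digestibility
    adjustment (absolute and as a percentage of the unadjusted score).
    """
    if not summaries:
        raise ValueError("moment_summary requires at least one scored meal")
    rows = []
    for moment in (*MAIN_MEALS, MealMoment.SNACK):
        group = [s for s in summaries if s.meal_moment == moment]
        if not group:
            continue
        with_dig = np.array([s.mpqs for s in group])
        without = np.array([s.mpqs_nodig for s in group])
        rows.append(
            {"moment": moment.value, "adjustment": "digestibility", **_moment_stats(with_dig)}
        )
        rows.append(
            {"moment": moment.value, "adjustment": "none", **_moment_stats(without)}
        )
        diff = without - with_dig
        impact = np.array([s.digestibility_impact_pct for s in group])
        rows.append(
            {
                "moment": moment.value,
                "adjustment": "paired_difference",
                **_moment_stats(diff),
                "median_impact_pct": float(np.median(impact)),
            }
        )
    return pd.DataFrame(rows)


def limiting_frequency(
    summaries: list[MealSummary], by: Literal["moment", "category"] = "moment"
) -> pd.DataFrame:
    """Frequency (percent of meals) of each limiting amino acid.

    Only meals below 100 (i.e. with a limiting amino acid) enter the
    percentages, so each row sums to 100 up to rounding; the count of meals
    with no limiting amino acid is reported in its own column.
    """
    if not summaries:
        raise ValueError("limiting_frequency requires at least one scored meal")
    if by == "moment":
        groups = [*MAIN_MEALS, MealMoment.SNACK]
        key = lambda s: s.meal_moment  # noqa: E731
    else:
        groups = list(PlantCategory)
        key = lambda s: s.category  # noqa: E731

    rows = []
    for group in groups:
        members = [s for s in summaries if key(s) == group]
        if not members:
            continue
        limited = [s for s in members if s.result.limiting_eaa is not None]
        row: dict[str, object] = {
            by: group.value,
            "n_meals": len(members),
            "n_limited": len(limited),
            "n_not_limited": len(members) - len(limited),
        }
        for eaa in CANONICAL_ORDER:
            count = sum(1 for s in limited if s.result.limiting_eaa == eaa)
            row[eaa.value] = 100.0 * count / len(limited) if limited else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def person_summary(
    summaries: list[MealSummary],
    entries: list[FoodRecordEntry],
    persons: list[PersonProfile],
    table: FoodTable,
    include_snacks_in_median: bool = False,
) -> tuple[list[PersonSummary], pd.DataFrame]:
    """Per-person summaries plus a split report at median MPQS >= 100.

    Medians use unrounded MPQS over main meals (snacks only when the flag is
    set). Daily protein and energy include every record entry; protein
    consumed outside the three main meals is reported as "missed" protein
    with a count of days where it exceeds 20 g.
    """
    profiles = {p.person_id: p for p in persons}
    by_person: dict[str, list[MealSummary]] = {}
    for s in summaries:
        if s.meal_moment in MAIN_MEALS or include_snacks_in_median:
            by_person.setdefault(s.person_id, []).append(s)

    results: list[PersonSummary] = []
    for pid in sorted(by_person):
        group = by_person[pid]
        person_entries = [e for e in entries if e.person_id == pid]
        days = sorted({e.day for e in person_entries}) or sorted({s.day for s in group})
        n_days = len(days)
        scores = np.array([s.mpqs for s in group])
        q25, med, q75 = np.percentile(scores, [25, 50, 75])

        daily_protein = {d: 0.0 for d in days}
        daily_plant = {d: 0.0 for d in days}
        daily_energy = {d: 0.0 for d in days}
        daily_missed = {d: 0.0 for d in days}
        for e in person_entries:
            food = table[e.portion.food_id]
            protein_g = e.portion.mass_g * food.protein_g_per_100g / 100.0
            daily_protein[e.day] += protein_g
            daily_energy[e.day] += e.portion.mass_g * food.energy_kcal_per_100g / 100.0
            if food.origin == "plant":
                daily_plant[e.day] += protein_g
            if e.meal_moment not in MAIN_MEALS:
                daily_missed[e.day] += protein_g

        protein_per_day = float(np.mean(list(daily_protein.values()))) if n_days else 0.0
        total_protein = sum(daily_protein.values())
        plant_pct = (
            100.0 * sum(daily_plant.values()) / total_protein if total_protein > 0 else 0.0
        )
        weight = profiles[pid].body_weight_kg if pid in profiles else math.nan
        results.append(
            PersonSummary(
                person_id=pid,
                n_meals=len(group),
                median_mpqs=float(med),
                iqr=(float(q25), float(q75)),
                pct_meals_ge_100=100.0 * float(np.mean(scores >= 100.0)),
                protein_g_per_day=protein_per_day,
                protein_g_per_kg_per_day=protein_per_day / weight,
                plant_protein_pct=plant_pct,
                energy_kcal_per_day=(
                    float(np.mean(list(daily_energy.values()))) if n_days else 0.0
                ),
                missed_protein_g_per_day=(
                    float(np.mean(list(daily_missed.values()))) if n_days else 0.0
                ),
                n_days_missed_gt_threshold=sum(
                    1 for v in daily_missed.values() if v > MISSED_PROTEIN_THRESHOLD_G
                ),
                n_days=n_days,
            )
        )

    split = _group_split(results)
    return results, split


def _group_split(results: list[PersonSummary]) -> pd.DataFrame:
    """Group means +/- SD (and median [IQR] for MPQS) split at median MPQS >= 100."""
    frame = pd.DataFrame(
        {
            "person_id": [r.person_id for r in results],
            "median_mpqs": [r.median_mpqs for r in results],
            "pct_meals_ge_100": [r.pct_meals_ge_100 for r in results],
            "protein_g_per_day": [r.protein_g_per_day for r in results],
            "protein_g_per_kg_per_day": [r.protein_g_per_kg_per_day for r in results],
            "plant_protein_pct": [r.plant_protein_pct for r in results],
            "energy_kcal_per_day": [r.energy_kcal_per_day for r in results],
            "missed_protein_g_per_day": [r.missed_protein_g_per_day for r in results],
        }
    )
    rows = []
    groups = {
        "all": frame,
        "median_mpqs_lt_100": frame[frame["median_mpqs"] < 100.0],
        "median_mpqs_ge_100": frame[frame["median_mpqs"] >= 100.0],
    }
    for label, g in groups.items():
        row: dict[str, object] = {"group": label, "n_persons": len(g)}
        for col in frame.columns.drop("person_id"):
            values = g[col].to_numpy(dtype=float)
            row[f"{col}_mean"] = float(np.mean(values)) if len(values) else math.nan
            row[f"{col}_sd"] = float(np.std(values, ddof=1)) if len(values) > 1 else math.nan
        if len(g):
            q25, med, q75 = np.percentile(g["median_mpqs"], [25, 50, 75])
            row["median_mpqs_median"] = float(med)
            row["median_mpqs_q25"] = float(q25)
            row["median_mpqs_q75"] = float(q75)
        rows.append(row)
    return pd.DataFrame(rows)


def meal_summaries_frame(summaries: list[MealSummary]) -> pd.DataFrame:
    """Tidy one-row-per-meal table of scores and diagnostics."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "person_id": s.person_id,
                "day": s.day,
                "moment": s.meal_moment.value,
                "mpqs": s.mpqs,
                "mpqs_truncated": s.result.mpqs_truncated,
                "mpqs_no_digestibility": s.mpqs_nodig,
                "digestibility_impact_pct": s.digestibility_impact_pct,
                "limiting_eaa": (
                    s.result.limiting_eaa.value if s.result.limiting_eaa else ""
                ),
                "total_protein_g": s.result.total_protein_g,
                "plant_protein_g": s.result.plant_protein_g,
                "animal_protein_g": s.result.animal_protein_g,
                "energy_kcal": s.result.energy_kcal,
                "plant_pct_protein": s.plant_pct_protein,
                "plant_pct_aa": s.plant_pct_aa,
                "category": s.category.value,
                "pct_protein_without_aa_data": s.result.pct_protein_without_aa_data,
            }
        )
    return pd.DataFrame(rows)


def person_summaries_frame(results: list[PersonSummary]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "person_id": r.person_id,
                "n_meals": r.n_meals,
                "n_days": r.n_days,
                "median_mpqs": r.median_mpqs,
                "iqr_q25": r.iqr[0],
                "iqr_q75": r.iqr[1],
                "pct_meals_ge_100": r.pct_meals_ge_100,
                "protein_g_per_day": r.protein_g_per_day,
                "protein_g_per_kg_per_day": r.protein_g_per_kg_per_day,
                "plant_protein_pct": r.plant_protein_pct,
                "energy_kcal_per_day": r.energy_kcal_per_day,
                "missed_protein_g_per_day": r.missed_protein_g_per_day,
                "n_days_missed_gt_threshold": r.n_days_missed_gt_threshold,
            }
        )
    return pd.DataFrame(rows)
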