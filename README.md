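# mpqs — Meal Protein Quality Score

`mpqs` scores the protein **quantity and quality of whole meals**. Existing
protein-quality scores (PDCAAS, DIAAS) rate individual protein sources, but
people eat meals in which sources complement each other — cereals are
lysine-poor and legumes methionine-poor, yet together they can cover every
essential amino acid (EAA). At the same time, a tiny portion of a perfect
protein is physiologically meaningless, so quantity must enter the score.
This matters most for groups at risk of sarcopenia or malnutrition (older
adults, patients) as diets and institutional menus shift toward plant
proteins.

## The score

For a person of body weight *w* (kg) and a per-meal protein target *t*
(default 0.3 g/kg, an amount sufficient to stimulate muscle protein
synthesis), the personalized requirement for EAA *i* is

```
req_i = w · t · pattern_i          [mg]
```

with `pattern_i` the FAO/WHO amino-acid reference pattern (mg per g
protein, ages >3 y). The meal's digestibility-adjusted intake of EAA *i* is

```
intake_i = Σ_j  mass_j · protein_j/100 · aa_ij · d_j     [mg]
```

summing over foods *j* with digestibility factor `d_j`. Methionine consumed
above its own requirement is credited to cysteine (the conversion is
metabolically unidirectional; the reverse never happens). The score is the
worst coverage across the ten scored entities (nine EAAs, with Phe+Tyr
combined):

```
MPQS = 100 · min_i ( intake_i / req_i )
```

0 means an EAA is entirely absent; 100 means every EAA exactly meets its
requirement; above 100 every EAA exceeds it. The arg-min is the **limiting
amino acid**. `MPQS_TRUNQ = min(MPQS, 100)` is also reported, as is a
per-day variant that pools a whole day's intake against a daily protein
target (e.g. 1.2 g/kg/d).

## Worked example

Generate the bundled fixtures (including a three-ingredient example meal)
and score the meal for a 70 kg reference person:

```sh
mpqs make-fixtures --seed 17 --out demo
mpqs score-meal --table demo/example_foods.csv \
                --recipe demo/example_recipe.csv --reference-70kg
```

prints (abridged):

```json
{
 "mpqs": 44.04761904761905,
 "rounded": {
  "mpqs": 44,
  "limiting_eaa": "methionine",
  "coverage_pct": {"his": 83, "ile": 77, "leu": 65, "lys": 75, "met": 44,
                   "cys": 102, "phe_tyr": 103, "thr": 89, "trp": 116, "val": 73}
 },
 "total_protein_g": 33.0
}
```

The meal delivers 33 g of protein, ample in bulk, but its
digestibility-adjusted methionine (148 mg) covers only 44% of the 336 mg
this person needs per meal (70 kg × 4.8 mg/kg), so the MPQS is 44 with
methionine limiting. Cysteine and Phe+Tyr exceed their requirements (102%,
103%) — quality, not quantity, is this meal's problem.

Cohort-style analysis of multi-day food records writes six tidy TSV
reports (per-meal scores, meal-moment statistics with/without the
digestibility adjustment, limiting-EAA frequencies by moment and by
plant-protein category, per-person summaries, and a split of persons at
median MPQS ≥ 100):

```sh
mpqs cohort --table demo/foods.csv --records demo/records.csv \
            --persons demo/persons.csv --out demo/report
```

On the seed-17 synthetic cohort, mean MPQS rises over the day (breakfast
112 < lunch 120 < dinner 197, from `demo/report/moment_summary.tsv`):
cereal-heavy breakfasts are mostly lysine-limited while animal-rich dinners
clear every requirement.

The same machinery is available as a library (`mpqs.score_meal`,
`mpqs.score_day`, `mpqs.score_records`, …); see `docs/methods.md` for the
model's assumptions and design choices.

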