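# Methods

## Model

The Meal Protein Quality Score treats each essential amino acid (EAA) as an
individual nutrient at the meal level. Ten entities are scored: His, Ile,
Leu, Lys, Met, Cys, Phe+Tyr (combined, because reference patterns give no
separate tyrosine value), Thr, Trp, Val. For each entity the
digestibility-adjusted intake summed over the meal's foods is divided by a
personalized requirement, and the score is the minimum of these coverage
ratios, ×100. The minimum — rather than a sum or mean — encodes Liebig's
barrel: protein synthesis is constrained by the scarcest amino acid, so
surpluses elsewhere cannot compensate.

Three assumptions underlie the requirement side:

1. **0.3 g/kg body weight of high-quality protein per meal** is the
   quantity target (default `protein_target_g_per_kg=0.3`). Over three main
   meals plus snacks this lands at 1.0–1.2 g/kg/d, the range recommended
   for older adults.
2. **Complementation must happen within one meal.** Free amino acids have
   no dedicated storage pool; the per-day variant (`score_day`,
   `daily_requirements`) is provided for users who prefer the
   whole-day window, with a configurable daily target (warned outside
   0.4–2.5 g/kg/d).
3. **The FAO/WHO >3 y amino-acid pattern suits the scored population.** The
   pattern ships as a named constant (mg per g protein: His 15, Ile 30,
   Leu 59, Lys 45, Met 16, Cys 6, Phe+Tyr 38, Thr 23, Trp 6, Val 39) and is
   self-checked at import time against its per-kg form at the 0.3 g/kg
   target (His 4.5 … Val 11.7 mg/kg). Alternative patterns (e.g.
   leucine-enriched for older adults) can be loaded from YAML/JSON.

**Methionine→cysteine top-up.** Methionine converts to cysteine in vivo but
not the reverse, so instead of pooling the sulfur amino acids, only
methionine consumed *above its own requirement* is credited to cysteine.
Reported methionine coverage stays uncapped; since the score is a minimum
and donation happens only above methionine's requirement, the top-up can
rescue cysteine but never alter a methionine-limited score.

**Digestibility** is a single per-food fraction applied to every amino acid
of that food (ileal values preferred where a table has them; per-EAA
digestibility is a known refinement this package does not model). Scoring
with the adjustment disabled is supported everywhere so its impact can be
quantified; the per-meal impact is reported as
`100·(MPQS_unadjusted − MPQS_adjusted)/MPQS_unadjusted` (defined as 0 when
the unadjusted score is 0).

## Units and data model

Amino-acid profiles are stored as **mg per g protein**, making them
portion-independent; absolute intake is
`mass_g × protein_g_per_100g/100 × aa_mg_per_g_protein × digestibility`.
Digestibility is serialized as a percentage (the convention of composition
tables) and converted to a fraction exactly once at parse time, through
decimal arithmetic so save→load round-trips bit-for-bit. Foods lacking
amino-acid data (composition tables typically profile only foods >1%
protein) carry an all-zero profile and a `has_aa_data=False` flag: they
count toward protein and energy totals but contribute nothing to EAA
intake, and the scorer reports the fraction of meal protein lacking data
rather than imputing quality.

## Numerical choices

- All summation is in double precision; per-food contributions are never
  rounded. Published-style output rounds coverage and MPQS to integers
  (half away from zero); comparisons and medians use unrounded values.
- Limiting-amino-acid ties (coverage equal within 1e-9 absolute) are broken
  by canonical order (His, Ile, Leu, Lys, Met, Cys, Phe+Tyr, Thr, Trp,
  Val); all tied keys are kept in a diagnostic field.
- An empty meal scores 0 with the first canonical key reported as limiting
  and an `empty` flag set — a defined contract for degenerate input.
- Plant-protein percentages use exact 0/100 endpoints (a meal whose foods
  are all plant is exactly 100%) so float slop cannot leak a vegan meal out
  of its category.

## Cohort analyses

Each (person, day, main-meal) group in a food record is scored with and
without the digestibility adjustment. Plant-protein categories are 0–27%,
27–65%, 65–<100%, and exactly 100% (half-open right edges; fully
plant-based meals form their own category). Two plant bases are computed —
percent of protein mass and percent of total amino-acid mass — with a flag
selecting which drives categorization (default protein mass, the base used
for dietary records; the amino-acid base suits recipe reports).
Limiting-EAA frequencies count only meals below 100; meals with no limiting
amino acid are tallied separately, so each frequency row sums to 100 up to
rounding. Per-person summaries report the median MPQS over main meals
(snacks excluded by default, includable by flag), the share of meals
reaching 100, daily protein/energy, and protein eaten outside the main
meals ("missed" protein), flagging days where it exceeds 20 g. Meal-moment
statistics emit both mean±SEM and mean±SD, plus medians with IQR, since
conventions differ between reports. Inferential statistics are deliberately
out of scope; the TSV outputs are tidy inputs for any statistics package.

## Synthetic data

The generator emulates the contrastive structure the analyses assume, not
any real cohort's distributions:

- **cereal** (wheat-like): lysine ≤ 0.7× the reference pattern, methionine
  at/above it; digestibility 0.85–0.92;
- **legume** (pea-like): Met+Cys below the reference sum, lysine above;
  digestibility 0.70–0.85;
- **animal** (milk/meat-like): every EAA at/above the pattern,
  digestibility ≥ 0.95;
- **collagen** (gelatin): zero tryptophan — a collagen-only meal scores 0;
- **tuber** (potato-like): balanced but only ~2 g protein/100 g.

Profiles are jittered ±8% per food within these bounds and validated at
build time. Cohorts default to 12 persons × 7 days (body weight
N(75, 13) kg, clipped to 45–120), with cereal-heavy breakfasts (35% fully
plant-based), mixed lunches, animal-rich dinners, and snack entries
(occasionally protein-rich, so the missed-protein report has signal). The
worked-example fixture reconstructs a three-ingredient meal from its
published digestibility-adjusted totals (factors 0.94/0.75/0.64, 100 g
portions); the third ingredient absorbs display-rounding slack so
full-precision sums reproduce the printed totals exactly, and valine —
absent from the published example — is set to a comfortable non-limiting
level (600 mg adjusted, 73% coverage at 70 kg) so neither the score (44)
nor the limiting amino acid (methionine) changes. All generation is
deterministic under the configured seed (independent substreams for table
and cohort via seed sequences).

Passing tests on this synthetic material demonstrate the *mechanics* —
score algebra, top-up behavior, categorization, report shapes, and the
qualitative patterns (plant-only meals scoring <100 with lysine/methionine
limiting; scores rising from breakfast to dinner). They do not validate the
score against real dietary records, preparation effects on digestibility,
or muscle-physiology outcomes.

## Verification

Unit tests pin the worked example (adjusted intakes, requirement row,
coverage row, score 44, methionine limiting) and the per-kg requirement
values exactly. Property tests check: equivalence with an independently
coded per-EAA reference loop to 1e-9 relative on randomized meals (1,000 in
the acceptance suite); invariance to splitting portions; monotonicity in
digestibility and zero impact when all factors are 1; linearity in portion
mass and inverse proportionality to body weight wherever the Met→Cys
top-up is inactive; and frequency rows summing to 100±1. Problem sizes
(8–12 persons × 7 days; hundreds of randomized meals) keep the whole suite
in the low seconds while exercising every code path.

## Known limitations

- One digestibility factor per food; no per-EAA ileal digestibility.
- No modeling of preparation/cooking effects on protein quality.
- Reference patterns for children (<3 y), pregnancy, or disease states are
  not bundled (custom patterns can be loaded).
- Composite/recipe foods must be resolved to ingredient rows upstream; the
  loader treats every row as a single resolved food.
- The synthetic cohort reproduces qualitative contrasts only; its absolute
  score distributions are not calibrated to any real population.
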