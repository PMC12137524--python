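# Methods

## Dosage arithmetic and catalogues

All dosages are integer milligrams; grams appear only in rendered reports
(2 decimals). A pack's total dosage is `unit_dose_mg x units_per_pack`; a
regimen's recommended total is `unit_dose_mg x doses_per_day x duration_days`.
Regimens stated as ranges ("2 or 3 times daily for 5 to 7 days") are encoded
with min/max frequency and duration and expanded to the envelope interval
`[dose x f_min x t_min, dose x f_max x t_max]`; the entire closed interval is
treated as conform, both endpoints included. Combination substances
(amoxicillin/clavulanic acid 625 = 500 + 125, 1000 = 875 + 125;
sulfamethoxazole/trimethoprim 960 = 800 + 160) are keyed by the summed dose;
the component split is metadata only.

The built-in guideline catalogue holds 23 substance/indication regimens over
11 substances and 5 indications; the pack catalogue holds 44 products whose
totals reproduce the published per-substance pack lists. Two kinds of
judgement calls live in the fixtures:

* One regimen's published recommended total (amoxicillin/clavulanic acid,
  second-line UTI: 4.5 g) conflicts with its own regimen arithmetic
  (625 mg x 3/day x 3 days = 5.625 g). The published total drives
  classification, via an explicit override field; `regimen_total()` keeps the
  arithmetic and `catalogue_discrepancies()` reports the conflict, which the
  `validate` CLI command surfaces.
* Pack totals that are not integral multiples of the guideline unit dose
  (doxycycline 1.12/2.24 g, azithromycin 0.3/0.9 g) carry explicit unit
  counts (112 mg tablets, 300 mg sachets) in the fixture; a stored redundant
  pack total is verified against `unit_dose x units` at load time.

Catalogues round-trip losslessly through one YAML file.

## Classification

`classify_against` is a pure trichotomy on exact numbers: conform inside the
closed interval (reference = the total itself, surplus 0), under below
(reference = lower bound), over above (reference = upper bound). Surplus is
`(total - reference) / unit_dose` as an exact `Fraction`, so the conservation
identity `surplus x unit_dose + reference == total` holds identically, also
for partial-pack totals such as half of 6.25 g. Prescription pack counts are
decimal-valued floats (0.5, 1, 1.5, 2, ...) converted through their decimal
string representation, which keeps totals exact.

`cross_guideline_call` declares a total conform when any of the substance's
recommendation intervals contains it; otherwise the reference is the interval
endpoint minimizing absolute distance, enumerated over the lower *and* upper
limits of every recommendation. Equidistant ties resolve to the larger
endpoint, turning the call into an underprescription — the conservative
direction when the quantity of interest is overprescribed tablets. The
tie-break is applied globally across the substance's indications. A property
test checks the chosen reference against exhaustive endpoint enumeration.

Per-combination summaries classify each prescription's *pack* total (main
analysis, single packs only) or the full prescribed total (sub-analysis with
partial/multiple packs, after the twice-rule below). Percentages use the
substance's whole classified pool as denominator, so a substance recommended
for several indications reports every indication's cell from the same
denominator — identical pack lists then produce identical cells across
indications, reproducing the published table's convention.

## Study population filters

Inclusion: GP prescriber, age ≥ 18 at dispensing (as supplied; no birthday
arithmetic), dispensing year equal to the analysis year, enteral solid
preparation, and no male patients on the three substances recommended
exclusively for UTI in women (fosfomycin, nitrofurantoin, norfloxacin).
Removals are attributed to the first failing rule in the fixed order
prescriber → age → year → galenic → sex, so counts are reproducible;
malformed input rows are counted as unparseable, never silently dropped, and
the report satisfies input = retained + removed + unparseable on every run.

Partial packs are non-whole pack counts (integrality judged after rounding to
a configurable 1e-6 tolerance); multiple packs are whole counts ≥ 2.
Sub-analyses admit partial/multiple-pack prescriptions only when the
prescribed total does not exceed twice the substance's largest recommended
upper bound (boundary inclusive) — a guard against chronic-treatment
prescriptions. "Twice the amount recommended by any guideline" is read as
2 x the maximum across the substance's recommendations, the permissive
reading consistent with the guard's purpose.

## Extrapolation

Stratum weights are `census_count / insured_count` over canton (26) x sex
(2) x age class (16) x year — 832 cells per year; year stays in the key even
for single-year analyses. Cells with zero insured have an undefined weight
and are reported, with a configurable policy (error, or exclude-with-count)
for prescriptions that land in them. The 16 age-class boundaries are not
part of any published table and are configuration: the default is {18},
19–25, then 5-year bands to an open 91+ class. Weighted counts sum weights;
weighted mean age and proportions are weight-weighted; patient-level counts
weight each distinct patient once by their stratum. No variance estimation
is attached to extrapolated totals, and no calibration beyond the single
ratio is attempted.

## Synthetic data generator

The generator emulates, at configurable scale, a stratified insured
population inside a national census and a GP prescription stream:

* census: deterministic counts over the full stratum grid from fixed canton
  shares (roughly proportional to Swiss resident populations) and a humped
  adult age distribution; default 400,000 adults, about 1/17 of the real
  adult population, chosen to keep desk-scale runs fast while leaving no
  empty cells;
* insured population: per-stratum binomial thinning with probability 0.15 by
  default (a large insurer's market share), so true weights concentrate near
  1/p;
* prescriptions: stratum drawn proportional to insured counts, product from
  a configurable mixture (default anchored at amoxicillin/clavulanic acid ≈
  36% with the remainder spread over the other ten substances, uniform
  within a substance's packs), multiplicity from (single, partial, multiple)
  probabilities — partial counts only from {0.5, 1.5}, multiple from
  {2, 3, 4} — defaults (0.90, 0.03, 0.07); optional rates for non-GP
  prescribers, non-solid preparations and male patients on women-only
  substances exist purely to exercise the filters. When a male share is
  forced, the stratum is re-drawn conditional on the target sex so records
  stay stratum-consistent. Patients are pooled at about two-thirds of each
  stratum's record count so some patients carry several prescriptions, with
  one age drawn per patient.

Draws come from one seeded `numpy` generator in a fixed field-block order
(stratum, product, sex adjustment, multiplicity, pack count, patient slot,
age, prescriber, galenic); appending a configuration field appends a block
and cannot perturb earlier fields. Identical configurations produce
byte-identical outputs.

Ground truth is computed in closed form from the mixture and the catalogues
— per-combination conform/under/over probabilities, expected cross-guideline
surplus units per prescription, and the expected weighted total
`n x census_total / insured_total` given the realized insured table — never
by simulation, so recovery tests compare the simulation against an
independent expectation.

What the generator does *not* emulate: the real joint distribution of age,
canton, substance and pack choice; seasonal and regional prescribing
variation; refill chains and treatment episodes; diagnosis-dependent product
choice. Passing recovery tests therefore demonstrate that the pipeline's
arithmetic and weighting are correct, not that real-world conformity shares
equal the synthetic ones — with the exception of cells the catalogues force
(a substance all of whose packs sit on one side of a recommendation
classifies 100% into that cell on any nonempty stream, synthetic or real).

## Pipeline and numerical choices

The pipeline is deterministic end to end: identical inputs and configuration
reproduce every output file byte for byte (the run log echoes versions and
configuration but no timestamps). A stage failure aborts with a
stage-attributed message and leaves an `_INCOMPLETE` marker in the output
directory. Equality of totals is exact (integer mg / exact fractions); no
floating-point tolerance enters classification. Percentages are rendered to
2 decimals. Reported weighted counts are rounded to 2 decimals at the report
boundary only.

Test and acceptance runs use deliberately small problem sizes — streams of a
few hundred to a few thousand prescriptions and a 100,000–400,000-person
census — since every check is either exact (classification is deterministic)
or statistical with explicit 3-standard-error bands over repeated seeds.

## Known limitations

* Indications cannot be inferred from claims; per-indication cells therefore
  count each substance's whole pool against each of its recommendations, and
  the cross-guideline analysis is the only indication-free summary.
* The twice-rule reading and the filter attribution order are documented
  conventions, not published facts; changing them changes sub-analysis
  membership and the removal breakdown (not the main single-pack results).
* Prescriptions spanning year boundaries are attributed by the supplied
  dispensing-year column.
* No costs, no clinical-appropriateness judgement, and no graphics: the
  per-prescription call export carries the data a density plot would need,
  but plotting is out of scope.
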