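# packconform

Antibiotics are dispensed in fixed pack sizes, and a pack rarely contains
exactly the number of tablets a guideline-recommended course needs. The
mismatch produces leftover tablets — fuel for self-medication, waste and
antimicrobial resistance. `packconform` is a drug-utilization pipeline that
measures this mismatch on outpatient prescription claims: it classifies every
prescribed pack against national treatment recommendations, estimates surplus
tablets, and extrapolates insurer claims to population scale. A seeded
synthetic claims generator with closed-form ground truth replaces the
proprietary insurer data, so the whole pipeline is testable end to end.

## The model

For a marketed product with unit dose $d$ (mg) and $u$ units per pack, the
**total dosage per pack** is $T_{pack} = d \cdot u$. For a guideline regimen
with unit dose $d$, frequency $f$ doses/day and duration $t$ days, the
**recommended total** is $T_{rec} = d \cdot f \cdot t$; regimens given as
ranges yield a closed interval $[T_{rec}^{lo}, T_{rec}^{hi}]$, all of which
counts as *potentially conform*. A pack is a **potential over-** or
**underprescription** when its total falls above or below the interval, with
the surplus expressed in tablets: $(T_{pack} - T_{ref}) / d$.

Because claims carry no diagnosis, an exploratory **cross-guideline** variant
calls a pack non-conform only if it matches *none* of its substance's
recommendations, and then measures the surplus against the *closest*
recommended total (interval endpoints included; equidistant ties go to the
larger reference, the conservative choice for overprescription estimates).

Counts are extrapolated by post-stratification over canton × sex ×
age class × year (26 × 2 × 16 = 832 strata per year), each prescription
weighted by `census_count / insured_count` of its cell.

The built-in catalogues encode the Swiss first- and second-line
recommendations for the five most frequent outpatient indications
(uncomplicated UTI in women, acute bacterial rhinosinusitis,
community-acquired pneumonia, acute otitis media, streptococcal pharyngitis)
— 23 substance/indication combinations over 11 substances — and the marketed
pack sizes of those substances. All dosage arithmetic is exact integer
milligrams.

## Worked example

```python
from packconform import (
    GeneratorConfig, RunConfig, generate, run_pipeline,
)

dataset = generate(GeneratorConfig(seed=42, n_prescriptions=5000))
paths = dataset.write("demo/data")
result = run_pipeline(RunConfig(
    claims_path=paths["claims"], census_path=paths["census"],
    insured_path=paths["insured"], out_dir="demo/out",
))

print("retained:", result.filter_report.retained, "of",
      result.filter_report.input_count)
print("zero-conform combinations:", result.zero_conform)
nit = next(s for s in result.summaries
           if s.substance_atc == "J01XE01" and s.indication == "UTI")
print(f"nitrofurantoin/UTI: n={nit.n_total:.0f} weighted, "
      f"{nit.pct_over:.2f}% over, {nit.pct_conform:.2f}% conform")
```

prints

```
retained: 4145 of 5000
zero-conform combinations: (10, 13)
nitrofurantoin/UTI: n=1428 weighted, 100.00% over, 0.00% conform
```

Of 5,000 synthetic prescriptions, 855 are removed by the inclusion filters
(non-GP prescriber, non-solid preparation, men on women-only substances).
10 of the 23 substance/indication combinations have *no* marketed pack
inside their recommended interval — nitrofurantoin for UTI among them: its
smallest pack (20 × 100 mg) doubles the recommended 1 g course, so every
single-pack prescription is a potential overprescription of 10 tablets.
The weighted `n` (1,428 from 212 retained nitrofurantoin records) is the
population-scale estimate after stratum weighting. `demo/out/` additionally
contains the full 23-row conformity matrix, the cross-guideline
non-conformity shares, per-substance over/underprescribed tablet totals,
the filter report and a machine-readable run log.

The same pipeline is available from the shell:

```bash
packconform generate --seed 42 --n 5000 --out demo/data
packconform validate --claims demo/data/claims.csv
packconform run --claims demo/data/claims.csv --census demo/data/census.csv \
    --insured demo/data/insured.csv --out demo/out
```

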