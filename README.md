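# tracerbudget

Dual stable-isotope (¹³C/¹⁵N) tracer analysis for closed-chamber feeding
experiments on benthic suspension feeders — built around the classic
coral–sponge design in which algae and bacteria are labeled in complementary
ways (¹³C-algae + ¹⁵N-bacteria vs ¹⁵N-algae + ¹³C-bacteria) so that each
element traces exactly one food source per treatment.

The package is for ecophysiologists who have per-specimen delta values
(tissue, whole sample, DIC) and want defensible, reproducible fluxes. It
implements the full chain:

1. **Enrichment arithmetic** — δX (‰) = (R/R_ref − 1)×1000 with
   R_ref = 0.0111797 (C, VPDB) and 0.0036765 (N, air); atomic fraction
   F = R/(R+1); excess above an unfed-control background E = F_sample − F_control.
2. **Rates** — tracer uptake = E × pool / food enrichment, normalized to
   biomass and time (μmol tracer mmol⁻¹ d⁻¹); respiration from DIC
   enrichment in the closed incubation; coral calcification as whole-sample
   minus organic-fraction uptake (nmol mmol⁻¹ d⁻¹ in reports).
3. **Synthesis** — net growth efficiency
   NGE = tissue / (tissue + respiration); uptake C:N stoichiometry against
   food and tissue ratios; a whole-experiment carbon budget whose closure
   term is *unaccounted = added − (tissue + respiration + calcification)*.
4. **Statistics** — fixed-effects factorial ANOVAs on log₁₀-transformed
   rates, with a Monte-Carlo calibration of type-I error and power.
5. **Synthetic experiments** — a generator that forward-simulates the whole
   design from known true rates, so every stage is validated by parameter
   recovery.

## Worked example

```python
import tracerbudget as tb

# simulate the default design: 2 treatments x 3 compositions x 3 replicates
exp = tb.generate_experiment(tb.TruthConfig(seed=42))
res = tb.analyze(exp.measurements, exp.chambers, exp.foods)

print(res.nge["nge"].describe().loc[["mean", "min", "max"]])
print(res.anova.query("model == 'incorporation_C_species_x_food'")
      [["term", "F", "df_num", "df_den", "p"]].to_string(index=False))
```

```
mean    0.062131
min     0.034920
max     0.081856
Name: nge, dtype: float64
   term            F  df_num  df_den            p
species 11708.941763       1       9 2.495608e-15
   food   418.360516       1       9 7.448553e-09
```

The simulated net growth efficiency sits near 6% — tissue incorporation is
a small fraction of total carbon processing, most of which is respired —
and the species contrast (sponge rates an order of magnitude above coral)
dominates the factorial test, with F₁,₉ in the hundreds-to-thousands range
at these noise levels.

The same analysis runs on measured CSVs (`measurements.csv`,
`chambers.csv`, `foods.csv`; schemas in `tracerbudget.io`) via the CLI:

```bash
tracerbudget simulate --seed 42 --out data/
tracerbudget analyze --measurements data/measurements.csv \
    --chambers data/chambers.csv --foods data/foods.csv --out results/
tracerbudget reproduce-budget
```

`reproduce-budget` recomputes the published whole-experiment carbon budget
from the bundled mean terms: per chamber, 8,125 μmol bacterial C and
2,708 μmol algal C were added over 10 days, of which the coral processed
273 and 111 μmol and the sponge 345 and 219 μmol, leaving closure terms of
7,852 / 2,597 (coral) and 2,489 (sponge × algae) μmol unaccounted.

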