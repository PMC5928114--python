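# fishmerc

Accounting of ocean-to-land mercury transport by marine fisheries, and of the
dietary methylmercury exposure that harvest supports.

Fisheries remove mercury from the ocean with every landed catch: total
mercury (THg) bioaccumulates, and its methylated form (MeHg) biomagnifies, so
the flux depends on *which* species are caught, not just how much. `fishmerc`
is for researchers who want to pair catch statistics (FAO FishStatJ-style
tables: year × Major Fishing Area × ISSCAAP group) with literature mercury
concentrations and national food-supply balances to quantify

1. the THg and MeHg mass exported from the ocean each year, resolved by
   fishing area, taxonomic group, trophic-level bin, coastal/high-seas zone
   and fishing country;
2. changes in the trend of those series (one-breakpoint segmented
   regressions with a Davies test); and
3. potential per-capita weekly MeHg intake by country against the
   provisional tolerable weekly intake (PTWI) of 1.6 µg kg⁻¹ week⁻¹.

A synthetic-data module generates all three input streams with known ground
truth, so the entire pipeline is testable offline.

## The model

Per ISSCAAP group, study means x̄ᵢ with sample sizes nᵢ are pooled as

    Hg_w = Σ nᵢ x̄ᵢ / Σ nᵢ,    SD_w = √( Σ nᵢ (sdᵢ² + (x̄ᵢ − Hg_w)²) / Σ nᵢ ),

after converting fish muscle concentrations to whole-body equivalents with
the allometric relation log₁₀ C_wb = (log₁₀ C_muscle − 0.2545)/1.0623, and
whale tissues with the mass-fraction combination C_wb = Σ Cᵢ·wᵢ (wᵢ
renormalized over measured tissues). Export follows by unit algebra
(1 µg g⁻¹ = 1 g t⁻¹):

    THg [g] = catch [t] × Hg_w [µg g⁻¹],   MeHg = THg × f_class,

with whole-body MeHg fractions f = 0.58 (fish), 0.46 (invertebrates), 0.39
(turtles), 0.19 (marine mammals); masses convert to kilomoles with
M(Hg) = 200.59 g mol⁻¹. Weekly intake for country j with supply rates IR_ij
(kg capita⁻¹ yr⁻¹) and edible MeHg concentrations Cᵢ is

    WI_j = Σᵢ IR_ij × Cᵢ / BM_k / 52,

with continental mean body masses BM. Trend breaks are estimated by fitting
y = β₀ + β₁t + β₂(t − ψ)₊ via grid-seeded iterative linearization
(`SegmentedModel(...).fit()`), with SE(ψ) = SE(γ̂)/|β̂₂| and a Davies-bound
p-value for β₂ = 0.

## Worked example

```sh
fishmerc run-all --out-dir run --synthetic --seed 7
```

runs the full pipeline on the default synthetic scenario and prints

```
pipeline outputs written to run
```

with tidy CSVs in `run/`. Inspecting the fitted trends:

```python
>>> import pandas as pd
>>> pd.read_csv("run/segmented_fits.csv").round(2)
   series_id  breakpoint  breakpoint_se  slope_before  slope_after  davies_p  converged
0     global     1990.96           0.47          0.69         0.22       0.0       True
1    coastal     1988.96           0.17          0.49        -0.09       0.0       True
2  high_seas     1974.62           0.58          0.15         0.31       0.0       True
```

The global export series rises by ~0.69 kmol THg yr⁻¹ until a breakpoint
near 1991 and then flattens; the coastal series peaks in the late 1980s and
declines while the high-seas series accelerates after the mid-1970s —
exactly the structure the generator builds in (configured breakpoints 1991,
1989 and 1975). `run/exceedance_summary.json` reports that 5 of the 10
synthetic countries (50%) exceed the PTWI in 2001–2011, 2 of them (40%)
being Small Island Developing States or Least Developed Countries.

The same stages are importable directly: `fishmerc.pool_table`,
`fishmerc.aggregate`, `fishmerc.SegmentedModel`, `fishmerc.weekly_intake`.

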