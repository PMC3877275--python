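# growthscape

Growth models for juvenile walleye pollock (*Theragra chalcogramma*) on
the eastern Bering Sea shelf. The package asks where and why juvenile
pollock grow well in late summer — the "growth hot spot" question that
links climate-driven shifts in zooplankton prey to overwinter survival
and recruitment — and answers it with two models run over station
surveys:

1. a **Wisconsin-type bioenergetics model** of maximum growth
   potential,

       G = (C − F − U − SDA)/ρ − R·O2cal/(1000·v̄),   C = η·Cmax,
       Cmax = α_C·W^β_C·f_C(T)

   with allometric consumption (α_C = 0.119, β_C = −0.46), dome-shaped
   thermal responses for consumption (optimum 10 °C, zero at 15 °C)
   and respiration, waste proportions, an oxycalorific conversion of
   respiration, and ρ = v̄/ε̄ the predator:prey energy-density ratio;

2. a **depth-stratified individual-based model** (IBM): 100 fish per
   station stepped hourly through a 1-m binned water column with
   light-dependent visual prey encounter, size-dependent capture,
   gut dynamics capped by the bioenergetics Cmax, metabolic costs at
   the local temperature, a vertical-migration surcharge, and
   behaviour trading surface feeding against depth refuge; zooplankton
   switch between day and night vertical profiles at
   1 µmol·m⁻²·s⁻¹ surface irradiance.

Around the models sit the survey computations (trawl CPUE, CPUE-weighted
diets and main-prey selection, the copepod energy-density vs %-lipid
regression, biomass-weighted station prey energy, vertical-profile
construction, temperature preparation), ±1 SD and Monte Carlo
sensitivity analyses, the bioenergetics-vs-IBM comparison, and a
synthetic generator of warm (2005-like) and cold (2010-like) survey
scenarios so the whole pipeline runs and is testable without the
unreleased field data. See `docs/methods.md` for the full model
account.

## Worked example

```python
import numpy as np
from growthscape import (ScenarioConfig, make_scenario, simulate_bundle,
                         compare_models, sensitivity)
from growthscape.survey import prep_temperature

for regime in ("warm", "cold"):
    b = make_scenario(ScenarioConfig(regime=regime, n_stations=30, seed=1))
    t, _ = prep_temperature(b.temperature_profiles, b.stations)
    inputs = sensitivity.station_inputs(b)          # W=2.5 g, station T and prey ED
    g = sensitivity.base_growth_table(inputs)       # bioenergetics, eta = 1
    ibm = simulate_bundle(b, seed=1)                # 100 fish x 72 h per station
    res = compare_models(g.loc[ibm.station_id],
                         ibm.set_index("station_id")["growth"],
                         inputs=[i for i in inputs
                                 if i.station_id in set(ibm.station_id)])
    print(regime, round(t.upper30_mean_C.mean(), 2),
          round(float(np.mean([i.prey_ed for i in inputs])), 2),
          round(res.mean_bioen, 4), round(res.mean_ibm, 4),
          round(res.percent_reduction), round(res.eta_half, 2))
```

prints

```
warm 8.8 3.7 0.0124 0.0104 16 0.74
cold 7.6 4.47 0.0162 0.0114 30 0.59
```

Reading the rows: the warm scenario has warmer upper-30-m water
(8.8 °C vs 7.6 °C) but poorer prey (mean biomass-weighted prey energy
density 3.70 vs 4.47 kJ·g⁻¹), so maximum growth potential is lower
(0.0124 vs 0.0162 g·g⁻¹·d⁻¹) — the cold regime is the better growing
environment. The IBM, whose foraging is limited by light, prey size and
gut capacity, predicts growth below the bioenergetics ceiling in both
regimes (16% and 30% mean reductions here), and the relative foraging
rate needed for positive growth at half of all stations is higher in
the warm scenario (η = 0.74 vs 0.59): warm-year fish must forage closer
to their physiological maximum to break even.

The same pipeline is available from the shell:

```sh
growthscape all --regime cold --n-stations 30 --seed 1 --out runs/cold
growthscape synth --regime warm --n-stations 30 --seed 1 --out runs/warm-bundle
growthscape sens --in runs/warm-bundle --param preyED --out runs/sens_preyED.csv
```

Every stage writes a `manifest.json` with the seed and config hash;
equal manifests give byte-identical outputs.

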