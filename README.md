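# thermotrack

A reusable pipeline for bio-logger studies of how large ungulates cope
with drought. It was built around a two-species Kalahari study design —
arid-adapted gemsbok (*Oryx gazella*) versus water-dependent blue
wildebeest (*Connochaetes taurinus*) carrying body-temperature implants,
accelerometers, GPS collars and collar-mounted black-globe ("miniglobe")
thermometers through two successive hot-dry seasons (September–November),
one following a failed wet season ("drought") and one following normal
rains ("non-drought").

The package covers the full chain:

1. **Daily metrics** from raw sensor streams:
   - minimum, maximum and amplitude (max − min) of the 24 h body
     temperature rhythm from 10-min implant records;
   - *cool-microclimate hours* — daylight hours in which the collar
     miniglobe reads more than 0.5 °C below a full-sun reference
     miniglobe — and *cumulative cool-microclimate use*, the daily sum of
     that cooling depth (°C·h), an intensity-weighted shade-use index;
   - *travel hours* — hours in which consecutive hourly GPS fixes are
     more than 1.6 km apart (haversine distance);
   - total 24 h activity (5-min counts normalized to each logger's
     study-wide maximum) and the proportion of activity in the
     10:00–16:00 heat window.
2. **Mixed models**: for each daily response a GLMM
   `g(E[y_ij]) = β₀ + β_season + β_species + β_interaction + a_i + d_j`
   with crossed random intercepts for animal `a_i` and date `d_j`
   (reference levels drought / gemsbok), Gaussian, binomial (weighted
   logit) or Poisson (log) families, an optional per species-season
   residual-variance structure and AR(1) residuals for Gaussian fits.
   Candidates {global, season-only, species-only} are compared with
   AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1), Akaike weights
   wᵢ = exp(−Δᵢ/2)/Σⱼ exp(−Δⱼ/2), the ΔAICc < 2 plausibility rule, and
   Nakagawa–Schielzeth conditional R²; estimated marginal means and
   within-species seasonal contrasts are reported on the response scale.
3. **Synthetic studies**: a generator that plants the published
   coefficient tables as ground truth and renders complete raw streams
   (cosinor body-temperature days, crepuscular activity profiles,
   shade bouts carved from the reference globe, correlated random walks
   with planted excursion hours, plus weather/rainfall/NDVI context
   tables), so the entire pipeline is testable offline with known
   answers. See `docs/methods.md` for the generative model.

## Worked example

Simulate the default study (5 gemsbok + 6 wildebeest, two 91-day
seasons, published effect sizes planted), derive daily metrics and fit
the body-temperature-amplitude models:

```python
from thermotrack import default_config, simulate_study
from thermotrack.models import fit_candidates, build_selection_table, marginal_means

dataset, truth = simulate_study(default_config())
daily = dataset.daily_metrics()          # 2002 animal-days
fits = fit_candidates("t_amplitude", daily)
print(build_selection_table(fits))
print(fits["global"].coefficients)
print(marginal_means(fits["global"]))
```

which prints (abridged):

```
  model  k     aicc  delta_aicc  weight  plausible  conditional_r2
 global 10 3070.931       0.000     1.0       True           0.659
 season  8 3543.560     472.629     0.0      False           0.551
species  8 3736.869     665.938     0.0      False           0.533

       term  estimate  ci_low  ci_high
  intercept     2.169   1.711    2.627
     season    -0.044  -0.122    0.034
    species     1.134   0.515    1.753
interaction    -1.037  -1.125   -0.950

   species      season  mean  ci_low  ci_high
   gemsbok     drought  2.17    1.77     2.57
   gemsbok non-drought  2.13    1.73     2.52
wildebeest     drought  3.30    2.94     3.67
wildebeest non-drought  2.22    1.86     2.58
```

The global model (season × species interaction) wins decisively, and
the fit recovers the planted truth (intercept 2.2 °C, season −0.08,
species +1.0, interaction −1.03): gemsbok hold a narrow ~2.2 °C daily
body-temperature rhythm in both seasons, while wildebeest widen from
~2.2 to ~3.3 °C under drought — the "relaxed homeothermy" signal the
amplitude metric is designed to expose.

The same can be run from a shell:

```bash
thermotrack simulate --seed 1 --out raw/
thermotrack metrics --in raw/ --out daily.csv
thermotrack fit --metrics daily.csv --response t_amplitude --out fits/
thermotrack run --seed 1 --out results/      # everything, all 8 responses
```

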