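# ch4hyst

Seasonal hysteresis analysis for the emergent temperature dependence of
wetland CH₄ emissions.

Daily eddy-covariance records from wetland and rice-paddy flux towers show
that CH₄ emission (F_CH4, mg C m⁻² d⁻¹) plotted against air temperature does
not collapse onto one curve: the warming (earlier) and cooling (later) halves
of the frost-free season trace different branches, forming a loop. This
package quantifies that loop per site-year, compares pooled
temperature-dependence models of increasing spatial/temporal resolution, and
trains a hybrid tree-ensemble/quadratic flux predictor — all exercisable end
to end on synthetic multi-site data with known ground truth, or on a real
FLUXNET-CH4-style daily download. It is written for flux-synthesis and
CH₄-modelling work: anyone asking whether a single static F_CH4(T) curve is an
adequate parameterization.

## The model

For each site-year, the frost-free season (days with air temperature > 0 °C;
GPP-based thresholds available) is split at the day of maximum seasonal
temperature T_max. Each branch gets a one-parameter constrained quadratic

```
F_CH4(T) = a_hys · T² + (F_CH4,Tmax / T_max − a_hys · T_max) · T
```

forced through the origin (zero flux at 0 °C) and through the flux measured
at T_max, so the two branch curves always close into a loop. The loop is
summarised by

- **H_A** — the signed area between the later and earlier curves on
  [0, T_max], normalized by T_max times the largest |F| either fitted curve
  reaches (dimensionless). The numerator is closed-form:
  (a_early − a_late) · T_max³ / 6.
- **H_μ** — mean measured daily flux, later branch minus earlier branch
  (mg C m⁻² d⁻¹).

Positive values mean more CH₄ later in the season at the same temperature (a
counterclockwise loop). Apparent activation energies come from the
Boltzmann–Arrhenius form ln F = Ē_a·(−1/kT) + ε with k = 8.62 × 10⁻⁵ eV K⁻¹.

On top of the per-site-year fits sit:

- **Tier models** (`ch4hyst.tiers`): six pooled regressions that resolve
  temperature only (`T`), ecosystem-type variability (`T+type`), inter-site
  and inter-annual variability (`T+site`, `T+site+IAV`), and the
  intra-seasonal branch split (`+ISV`), each group fit with a free
  quadratic-through-origin curve; scored by absolute bias
  100·Σ|pred−obs|/Σobs per ecosystem type, and by branch-wise signed bias.
- **Hybrid model** (`ch4hyst.hybrid`): a seeded random forest regressing
  a_hys on ten predictors (seasonal branch, branch-cumulative GPP and
  precipitation, T_max, branch-mean temperature, ecosystem type, latitude,
  site, site-year, flux at T_max), whose prediction is plugged back into the
  constrained quadratic.
- **Synthetic generators** (`ch4hyst.synthetic`): a parametric generator
  that inverts the constrained quadratic with injected branch parameters
  (exact round-trip recovery), and a mechanistic lagged-substrate-pool
  generator (GPP feeds a carbon store that decays into emission with a Q10
  response) that produces predominantly positive loops.

## Worked example

The `analysis/` scripts run the whole study on a synthetic 48-site network
(8 ecosystem types, 2–6 years per site, 20 % multiplicative flux noise, 75 %
of site-years positive-hysteresis by construction):

```bash
python analysis/01_simulate_network.py --seed 1
python analysis/02_fit_hysteresis.py
python analysis/03_tier_comparison.py
python analysis/04_hybrid_model.py
```

which prints (seed 1):

```
analyzed 189 site-years (0 skipped)
positive-H_A fraction: 0.751
H_A median: 0.273; H_mu median: 13.2 mg C m-2 d-1
recovery vs ground truth: slope 1.004, sign agreement 100.0%

absolute bias (% of total flux), all types:
T                 74.0
T+type            56.3
T+type+ISV        49.3
T+site            50.1
T+site+IAV        48.3
T+site+IAV+ISV    16.5

hybrid absolute bias: 23.8% vs universal tier 74.0%
```

Reading this: the pipeline detects the injected 75 % positive-hysteresis
fraction almost exactly (0.751) and recovers the branch parameters with unit
slope; pooling all sites into one temperature curve misallocates ~74 % of the
total flux, resolving ecosystem types helps only moderately, and resolving
site, year, and season branch — or predicting a_hys with the forest —
recovers most of the variance, the same qualitative tiering reported for the
real flux-tower network. `analysis/05_replicate_fluxnet.py --data-dir <dir>`
runs the identical computation on a user-supplied daily download;
`analysis/06_figures.py` draws loop and distribution figures.

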