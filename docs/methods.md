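# Methods

## The constrained branch model

The emergent flux–temperature relationship of one season branch is the
quadratic `F(T) = a_hys·T² + (F_Tmax/T_max − a_hys·T_max)·T`, the unique
quadratic family through `(0, 0)` and `(T_max, F_Tmax)` with one free
coefficient. Both anchors are measured site-year quantities: `T_max` is the
maximum driver value over the season (ties broken to the earliest day) and
`F_Tmax` the flux measured on that day. Forcing both branches through the
same two points guarantees a closed loop, which is what makes the loop area
a comparable statistic across site-years and climate zones. The zero
intercept encodes the physical assumption of negligible emission at 0 °C; a
sensitivity variant replaces it with the mean flux measured between −0.5 and
0.5 °C (falling back to zero when no such day exists).

The least-squares solution is closed-form: with `x' = T² − T_max·T` and `y'`
the flux minus the anchored chord, `a_hys = Σx'y' / Σx'²`. The general
constrained polynomial fit (used for the degree-1/2/3/5 functional-form
robustness check) eliminates the constraints via the null space of the
constraint Vandermonde and solves the reduced least-squares problem; an
independent Lagrange-multiplier (KKT) solve is kept in the package as an
internal oracle, and the test suite requires the two to agree to 1e−9.
Because degree-5 Vandermonde systems are poorly conditioned, both paths run
three steps of iterative refinement; without it, agreement plateaus near
1e−8. Branch anchors are honoured to 1e−9 relative by construction and
asserted as a property test.

Degenerate inputs: `T_max ≤ 0` is a domain error (no frost-free season in
any meaningful sense); a branch whose temperatures all sit on the anchors
leaves `a_hys` unidentifiable and raises; conflicting fixed points raise a
constraint error.

## Hysteresis statistics

`H_A` integrates the later-minus-earlier curve difference over `[0, T_max]`.
Since both curves share anchors, the integral is `(a_early − a_late)·T_max³/6`
exactly; the sign convention is therefore positive when the later branch
lies above the earlier branch on the open interval (note `T² − T_max·T < 0`
there, so positive loops have `a_early > a_late`). The normalization divides
by `T_max` times the maximum `|F|` over both *fitted* curves, evaluated
analytically from the candidate set {0, T_max, interior vertex}. A toggle
normalizes by a measured maximum flux instead, since the two readings of the
statistic differ in how they treat curves that overshoot the measured range;
the fitted-curve form is primary. `H_μ` deliberately uses measured daily
values, not fitted curves, so the two statistics are not redundant: `H_A`
captures the shape difference at equal temperature, `H_μ` the raw seasonal
asymmetry including sampling imbalance. Sign classification treats
|H_A| ≤ 1e−12 as zero.

Scale equivariance (flux × c leaves H_A unchanged, scales H_μ by c) is
asserted as a property; temperature *shifts* are deliberately not an
invariance, because the 0 °C anchor is physical — a dedicated test documents
this non-invariance.

## Season detection

The frost-free season is the longest run of days with driver > 0 °C inside
the site-year window. Interior cold snaps of up to 3 days do not break the
run but are excluded from fitting (`gap_tolerance=0` restores strict
contiguity); noisy daily air temperature would otherwise fragment seasons
that plainly have one start and one end. Southern-hemisphere sites use a
1 July–30 June window so one austral season is contiguous, labelled by its
starting year; northern sites use the calendar year. The temperature-maximum
day belongs to the earlier branch — both curves are anchored at that day
anyway, so the choice only marginally moves H_μ, and fixing it keeps results
reproducible. If flux is missing on the maximum day, the anchor falls back
to the mean flux over the nearest (≤2 per side) season days whose driver is
within 1 °C of the maximum; with no such day the site-year is skipped.
Defaults: seasons shorter than 30 days are rejected; branches with fewer
than 10 analyzable days are skipped with a logged reason (one-parameter fits
on a couple of points would otherwise dominate the distributions). Monthly
aggregation (means over months with ≥15 valid days, roughly half-month
coverage) feeds the same machinery for the temporal-resolution robustness
check.

## Quality control

Gap-filled flux days are excluded by default (`use_gapfilled=True` retains
them); a day missing any required field drops out of analysis. QC only masks
the flux column of a copy, which makes it idempotent and leaves the original
series untouched. The exact QC recipe behind any given published data count
is not reconstructible from a daily product alone, so the policy is an
explicit parameter object rather than hard-coded rules.

## Tier models

The six pooled tiers partition the day-level data by the cross-product of
their active factors (none → 1 global group; type → 8; site; site-year;
×2 branches) and fit each group with `F = b₁T + b₂T²` through the origin —
free linear and quadratic coefficients, *not* the one-parameter branch model,
because the `(T_max, F_Tmax)` anchors are site-year quantities that do not
exist for pooled groups. Intra-seasonal variability enters through per-branch
groups. Groups under 3 days inherit the parent tier's curve (factors dropped
in the order ISV, IAV, site, type down to the global fit), and prediction for
unseen groups falls back the same way, so every tier scores exactly the same
days. An Arrhenius group form is available for the type-level curves.

Bias uses ratio-of-sums (100·Σ|pred−obs|/Σobs, and signed
100·(Σpred−Σobs)/Σobs per site-year branch) rather than mean-of-ratios:
near-zero flux days otherwise blow up individual ratios. Site-year branches
with non-positive total observed flux are excluded and counted. Scoring is
in-sample, matching the descriptive model comparison the pipeline mirrors;
grouped holdout exists in the hybrid module for honest skill estimates.

## Hybrid model

A random forest (scikit-learn, 500 trees, seed 20210415 by default — the
source analysis states no hyperparameters, so these are package defaults
logged in every report) regresses per-branch `a_hys` on ten predictors; four
(branch, ecosystem type, site, site-year) are categorical and one-hot
encoded with category order fixed by first appearance, which together with
the seed makes predictions bit-reproducible. Observation year and branch
means of WTD, wind speed and pressure are computed and stored but excluded
from the default predictor set (limited predictive power). Permutation
importance shuffles each raw predictor — all dummy columns of a categorical
together — over 10 seeded repeats and reports the mean MSE increase.
Out-of-bag R² is the built-in held-out error; because site-year is itself a
predictor, in-sample fit is near-perfect by construction, so the module also
provides leave-site-out R² and the reports print both. The hybrid flux
prediction plugs the forest's `a_hys` into the constrained quadratic with the
site-year's anchors, so anchor constraints hold exactly regardless of the
regression.

## Synthetic generators

The parametric generator draws temperature as a sinusoid (peak near day 182,
phase-flipped south of the equator) plus stationary AR(1) noise
(innovation sd 1.5 °C, coefficient 0.6), finds the frost-free season on the
generated series, and emits branch fluxes from the constrained quadratic
with injected `a_early`/`a_late` anchored at `(T_max, f_peak)`. Noise is
multiplicative lognormal (unit mean) because flux magnitudes span orders of
magnitude across sites and additive noise would drown the low-flux ones;
sub-zero days emit a truncated-normal floor (~0.5 mg C m⁻² d⁻¹) so winter
stays non-informative without zeros breaking log plots. Noise-free
generation round-trips through the analysis to ≤1e−9, which is the basis of
the recovery experiments.

The network generator assigns the 8 ecosystem types round-robin across
sites, draws latitude per type and climate (mean and amplitude of the
temperature cycle) from latitude, and scales peak flux by loosely realistic
type baselines (bog 40 … marsh 200 mg C m⁻² d⁻¹) with lognormal site and
year multipliers — this type-plus-site structure is what gives the tier
comparison something to resolve. The hysteresis-sign mix is constructed
deterministically: exactly `round(0.75·n_site_years)` site-years get
`a_early > a_late` (gap magnitude uniform in 0.1–0.6, scaled to site flux),
the rest the reverse, so the injected fraction is exact rather than a
binomial draw and detection error is the only noise source in the
fraction-recovery experiment. Default study conditions are 48 sites, 2–6
years each, 20 % flux noise.

The mechanistic generator integrates a substrate pool
`S' = α·GPP(t − lag) − k(T)·S` with `k(T) = k₀·Q10^((T−T_ref)/10)` (emission
rate capped at the pool, pool kept non-negative, divergence detected) and
emits the decay term. It exists for qualitative realism only: substrate
accumulated before the temperature peak sustains emission after it, which
yields predominantly positive loops across a Latin-hypercube of plausible
parameters — the sign, not any magnitude, is the assertion. It is not
calibrated to any real site.

What the synthetic data do *not* emulate: instrument gaps and gap-filling
artifacts beyond a per-day flag, water-table or salinity control of the flux
(WTD is generated but does not feed back on emission), management events in
rice paddies, or cold-season emission processes. Passing tests therefore
demonstrate that the estimators recover what they are defined to estimate
under the stated noise model — not that real flux towers satisfy that model.

## Problem sizes

The test suite and acceptance script run the recovery experiment at 200
site-years, the fraction-recovery network at the full 48 sites, the
tier-ordering and hybrid replicates on 10–12-site networks over ≥20 seeds,
and the importance-stability check over 20 seeded forest runs — sizes chosen
as the smallest at which the respective statistics are stable, and stated
here so they can be scaled up deliberately.

## Known limitations

- H_A carries no uncertainty interval; the statistic is a point summary.
- The tier definitions are one consistent reading of "selectively
  representing variability by grouping"; other group/functional-form
  combinations are expressible through `TierSpec` and the `form` argument
  but are not the defaults.
- The branch-wise bias standard deviations are heavy-tailed on synthetic
  networks containing near-zero-flux site-years; the ratio-of-sums
  aggregation bounds but does not eliminate this.
- Arrhenius fits exclude non-positive flux days by necessity (log), so
  uptake-dominated sites are summarised by the quadratic branch fits only.
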