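# Methods

This note documents the models implemented in `rasctl`, the provenance of
their constants, the synthetic-data generators used for validation, and the
numerical and design choices that were genuinely open.

## Growth surface and cycle value

The specific growth rate (SGR, %/day) of juvenile crucian carp is a
quadratic polynomial in water temperature and dissolved oxygen, fitted (by
its original authors) to a 3×3 full-factorial trial over
{10, 20, 30} °C × {2.5, 5, 7.5} mg/L. The six coefficients ship as
`GrowthSurfaceParams` defaults and are taken as given; refitting from raw
fish data is out of scope. Predictions outside the factorial hull are
returned with an `extrapolated` flag rather than an error, because the
scenario sweep intentionally visits intermediate temperatures the design
only brackets. The surface is concave in each variable and its factorial
argmax sits at (20 °C, 7.5 mg/L); note that the *fitted* surface evaluates
to ≈1.37 %/day there while the empirical treatment mean was 1.36 %/day — an
ordinary fitted-vs-observed gap, not a defect.

The cycle value increment is modelled as affine in SGR,
`Fn = α·SGR − β`. The affine form is not itself a published equation; it is
forced by the published scenario tables, in which gross value
(profit + control cost) is exactly a common affine image of `SGR(T, 5)`
across all three ambient conditions (cross-table identity and constant
second differences ≈ −2.31 RMB are asserted in the test suite).
`calibrate_value_model` solves α, β exactly from two rows (least squares
for more); the shipped defaults (α ≈ 370.098 RMB per SGR-percent,
β ≈ 299.998 RMB) are recomputed at call time from the packaged anchor rows
(ambient 8 °C, targets 10 and 20 °C) and validated against all 59 rows.
The decomposition α = biomass × price × days / 100 is underdetermined by
the published material (e.g. 300 kg × ~24.7 RMB/kg × 5 days); it is exposed
as optional, consistency-checked fields rather than defaults.

## Thermal plant and energy costs

Heat exchange follows Newton's law of cooling with a lumped coefficient
k = U_air·S_air + U_wall·S_wall = 17·12 + 40·22.72 = 1112.8 W/K. The
published costing convention charges losses at the **full set-point lift**
for the entire run — net heating power `Pz − k·(T₂−T₁)` is a constant — so
run time and cost have closed forms. The physically exact
instantaneous-temperature ODE is implemented separately in the digital twin
(`loss_convention="instantaneous"`); the twin also supports the fixed-lift
convention so the two routes can be cross-checked (they agree within the
Euler tolerance).

Neither the water specific heat nor the electricity tariff is published.
The cost formula identifies only their product, so `calibrate_energy_price`
fixes c = 4200 J/(kg·K) (the standard value for water) and solves the
tariff by one-parameter least squares from published cost rows, giving
C₁ = 0.5000 RMB/kWh with all 59 rows reproduced within ±0.05 RMB. Both
ship as config-overridable defaults tagged `derived`.

Cooling mirrors heating with effective capacity 0.9 × 27 kW (the published
"0.9·Pzz − Pzs" is read as (0.9 × Pzz) − Pzs, since the printed zero-lift
capacity 24 300 W equals 0.9 × 27 000). Cooling runs are billed at the
chiller's electrical draw. There are no published cooling-cost rows; the
closed form is validated against brute-force numeric integration.

Aerator oxygen transfer uses the fitted decay
`rate(T) = 0.36·10^(−T/8.17) + 0.18` mg/(L·min) (fitted range 13–23 °C),
and `aeration_time` inverts it at a constant rate over the DO interval —
the same averaging used in the trials it was fitted from. Dissolved-oxygen
saturation uses the Benson–Krause freshwater formula at 1 atm, zero
salinity, which matches the quoted anchor 10.08 mg/L at 15 °C.

Rated powers of pumps, cameras and sensors are not published; the device
cost model defaults to the laser curtain only (5×10⁻⁴ kW at 40% duty) and
accepts arbitrary `(name, kW, duty)` triples. Scenario sweeps exclude
DO-maintenance energy by default — temperature control alone reproduces the
published cost columns exactly — and accept an optional aerator rating for
DO-aware sweeps.

## Scenario optimization

`sweep` enumerates integer-grid (T, DO) set-points, skipping DO above
saturation and unreachable temperatures, and prices each with the models
above. The selection criterion defaults to **profit** because the published
optima are profit maxima; the output–input ratio Dn = Fn/En is computed per
row and available as an alternative criterion (undefined, and flagged, at
zero cost). Ties break to the smallest temperature move, then the lowest
DO. `profit_advantage` divides 2-decimal-rounded profits — the published
table-cell convention; with full precision the 2 °C figure would read 8.94
rather than 8.93. The published "1.43×" advantage at 8 °C ambient is
inconsistent with its own table (110.55/96.64 ≈ 1.14); the implementation
reports the computed 1.14.

All RMB amounts are computed at full precision and rounded half-up to
2 decimals only at reporting boundaries.

## Control state machine

Priorities: envelope restoration > stress response > economic tracking,
one actuator and one unit step per tick. Open points resolved here:

- *Band boundaries* 10–14 / 15–25 / 26–30 °C are integer-closed; fractional
  temperatures dispatch by `floor`.
- *"Heat until the upper limit"* in the low band is read band-locally:
  heating stops at 14 °C (configurable `low_band_top`), after which
  behavior-1 events aerate.
- *Behavior 1 in the 26–30 °C band* is unspecified; both behaviors are
  treated identically there (aerate first, cool at saturation).
- *Simultaneous behaviors in 15–25 °C* aerate (the band has a single rule).
- *Dwell*: the re-assessment interval between steps is configurable
  (default 10 min) and gated on fresh observations.
- DO commands above saturation are clamped and logged as no-ops, never
  emitted; temperature commands are clamped to the envelope.

Night mode records the dusk entry temperature; the floor is
max(10, entry − 4) °C and hourly commanded changes are capped at 4 °C
(the conservative end of the published 4–5 °C/h guidance, matching the
−4 °C floor). Exhaustive small-state enumeration in the test suite checks
safety (commands never leave the envelope), liveness (quiescence once
stressors clear) and decision-table totality.

## Closed-loop digital twin

Explicit Euler at dt ≤ 60 s default (tests use up to 300 s); the linear
thermal time constant is m·c/k ≈ 8.4 h, so these steps are comfortably
stable. Energy is metered as the time integral of commanded electrical
power at the tariff. Fish oxygen consumption has no published model; the
twin uses a Q10-scaled rate — 250 mg O₂/(kg·h) at 20 °C, Q10 = 2, spread
over 8000 L — and an assumed 0.75 kW aerator, all tagged `assumed` in the
config. Stress behaviors arrive by Poisson thinning of a hazard
(base 0.05/h + 2/h per mg/L DO deficit below 5 + 1/h per °C beyond a 2 °C
comfort margin, 5 min refractory); these rates are synthetic, so all
twin-level claims are property-based (determinism under seed, hazard
monotonicity, rate consistency within 3 SE, paired-policy cost ordering),
never numeric reproductions.

Trial sizes: unit tests run 0.2–2 day trials at dt = 120 s; the paired
policy comparison runs 20 seeds × 25 days at dt = 300 s — sizes chosen to
exercise multi-day day/night cycling while keeping the suite quick.

## Composite stress score (PCA)

PCA is computed on the **correlation** matrix (the published eigenvalues
sum to 5, which forces this), components with eigenvalue > 1 are retained
(Kaiser rule, k = 2 for the published panel), score coefficients are
loadings divided by √eigenvalue, and the composite combines retained
components with variance-fraction weights (0.632/0.368 for the published
model). Eigenvector sign is arbitrary: fitted components are sign-fixed so
the dominant loading is positive, and the composite vector is oriented so
the MDA (lipid-peroxidation) coefficient is ≤ 0 — the published
orientation, making higher scores healthier. The published score
coefficient −0.445 for LZM on the second component is inconsistent with
its own loading/eigenvalue chain (−0.513/√1.425 ≈ −0.430); the model uses
the chain and surfaces the discrepancy in its metadata, with the published
composite equation kept as `PRINTED_COMPOSITE` for display. The published
per-group scores (0.223, −0.036, −0.348) require unpublished group means
and are shipped as reference display values only.

The synthetic serum generator draws multivariate-normal panels around
group mean shifts. The canonical three-group damage study
(`damage_study_conditions`) uses adjacent-group effects of
(−0.7, −0.7, −1.2, +0.8, +1.2) within-group SD for (LZM, SOD, CAT,
cortisol, MDA) — magnitudes consistent with the reported per-indicator
significance levels at n ≈ 9–10, where p < 0.0001 for CAT and MDA implies
severe-group separations above 2 SD — and a within-group correlation that
couples the antioxidant/peroxidation block (SOD–CAT +0.5, each vs MDA
−0.4) and the immune/hormone pair (LZM–cortisol −0.3), mirroring the
published two-component structure. What passing the ordering-recovery
study shows is that the composite-score pipeline ranks graded damage
correctly under realistic effect sizes and correlation; it does not
validate the hazard model, assay noise distributions, or any particular
fish cohort.

## Detection metrics

Per-class precision, recall and F1 from confusion counts; AP values are
inputs (ranked detections are out of scope). The overall report averages
mAP/P/R arithmetically and averages **per-class F1 values** for the overall
F1. On the published rows both candidate conventions evaluate to 96.73 at
2 decimals (the printed 96.72 appears truncated); on asymmetric classes
the two genuinely diverge, and the mean-of-per-class-F1 convention is the
one documented in the report metadata. Zero-denominator metrics are NaN
and flag the report as undefined, never silently 0.

## Known limitations

- The growth surface is species- and stage-specific (juvenile crucian
  carp, ~50 g); no density, feeding or survival effects.
- The thermal model is lumped single-node: no stratification, humidity or
  evaporative loss, and no chiller COP dependence on lift.
- The behavior hazard and oxygen-consumption parameters are assumptions;
  simulator outputs are for policy comparison, not absolute prediction.
- Single-cycle economics at a static tariff; no time-of-use scheduling or
  multi-day dynamic programming over ambient forecasts.
- PCA scoring assumes approximately linear, normally distributed
  standardized indicators; no factor rotation or inferential testing.
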