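# Methods

## Model

The counterfactual ("deweathering") estimator rests on one assumption: within
a period whose emission regime is stable, the conditional expectation of
PM2.5 given meteorology and location,

    E[PM2.5 | u_wind, v_wind, msl, d2m, t2m, lat, lon, hour],

characterises that regime.  A regression model fitted on a reference period
therefore predicts, for any weather, the concentration expected *under the
reference emissions*.  Feeding it the target period's weather and subtracting
the prediction from the observation removes the meteorological contribution
and leaves the emission difference plus model error.

The regressor is an hour-stratified random forest: one forest per analysis
hour (02/08/14/20 BJT), each over the seven features above.  Stratifying by
hour absorbs the diurnal cycle without forcing the meteorological response to
be shared across day and night; latitude/longitude absorb stationary spatial
heterogeneity (terrain, persistent source patterns).  Defaults follow the
regression-forest conventions: 200 trees, 2 candidate split features per node
(`mtry`), minimum leaf size 5, bootstrap resamples of size n, split by
within-child variance minimisation, prediction = tree mean clamped at 0
(concentrations are non-negative).  The generic CART forest underneath is
scikit-learn's `RandomForestRegressor`; the tests verify it node-for-node
against an exhaustive-split brute-force builder on small datasets, so the
split rule implemented is the one documented here.  Tie-breaks among
equal-cost splits follow scikit-learn's internal ordering; ties only occur
between splits inducing the same partition on the training data, so fitted
values are unaffected.

All features are standardized (`x* = (x − x̄)/σ`, population σ).  Parameters
are fitted per training scenario and stored in the model; counterfactual
inputs are always transformed with the *training* parameters, so no
information from the target period leaks into the model.

## Pre-processing

* **Station screening.** A station is dropped iff its missing fraction over
  the union of the configured study periods (at the four analysis hours) is
  strictly greater than the threshold (default 0.20, i.e. "over 20 %").
* **Gap filling** is temporal-first, spatial-second, and no filled value is
  ever reused as an interpolation source: a gap is replaced by the midpoint
  of the two adjacent candidate hours when both are observed (adjacency never
  crosses a period boundary — slots months apart are not neighbours);
  remaining gaps use inverse-distance-squared weighting over co-temporal
  observed stations with haversine distances, a coincident donor (d = 0)
  taking all weight.  Records with no co-temporal donors stay missing and are
  flagged.
* **Interpolation CV** masks k random folds of *individually observed values*
  (not whole stations) and reconstructs them by the same rule; the report
  averages the per-fold MAEs.
* **Grid matching.** Meteorology is resampled to a regular analysis grid
  (default 0.05° ≈ 5 km) by nearest source cell, deliberately without
  smoothing.  Each station maps to its nearest cell (index rounding, which on
  a regular lat/lon grid coincides with haversine-nearest); each cell with
  stations emits one sample per timestamp with the arithmetic mean of its
  stations' PM2.5.  Region and land-use labels are joined from user-supplied
  per-cell tables; neither is inferred from coordinates.

## Difference statistics

Hourly regional cells are arithmetic means of per-sample observed-minus-
counterfactual differences.  A region's "All" summary is the **unweighted
mean of its four hourly cells** (this convention exactly reproduces the
published regional summaries this layout mirrors); the cross-region bottom
row is sample-weighted and labelled as such, since equal weighting of regions
with very different station counts would be misleading there.  A cell is
flagged significant when its magnitude exceeds the corresponding model's
region- and hour-specific cross-validated MAE.  The firework effect per
region is `All(vs NC) − All(vs NSF)`: the shutdown contribution common to
both comparisons cancels, leaving the firework difference between the two
reference regimes.

The turning point of a daily regional series is the earliest date that lies
below both counterfactuals by more than `margin` and for which at least a
fraction `q` of all dates from there to the period end do as well (defaults
q = 0.75, margin = 0; both configurable, and a variant using the model MAE as
the margin is available).  Delay counts calendar days from the period start
(start = day 0).  Note the rule finds the onset of a *persistent exceedance
of the margin*: for a gradual decline it triggers as soon as the decline
clears the margin plus the series' own day-to-day error, which can be well
before the decline is complete (see Limitations).

## Synthetic world

The generator emulates the structure of the real inputs while staying fully
specified:

* **Meteorology** per variable = climatological mean + a static spatial field
  (sum of seeded Gaussian bumps, length-scale 0.3°) + a domain-shared AR(1)
  daily anomaly (ρ = 0.7, innovation scales of synoptic magnitude) + a fixed
  diurnal harmonic over the four hours.
* **Response.** PM2.5(cell, t) = max(0, base(landuse) + hourprofile(hour) +
  g(met, lat, lon) + emission(scenario, day, hour, landuse, region) + ε),
  ε ~ N(0, σ²) with σ = 5 µg/m³.  The true response g is fixed and documented
  in code (stagnation-like: low wind and high pressure raise PM2.5, a
  dew-point/temperature interaction, a smooth spatial term), never redrawn,
  so failures reproduce exactly; only fields, noise and missingness vary with
  the seed.
* **Scenarios** mirror a three-period design of 31 days each: a shutdown
  period (SD), a normal-commute reference (NC), and a normal-festival
  reference (NSF).  The shutdown subtracts a per-region reduction Δ
  (defaults 8/23/27 µg/m³ for the three region labels) with a linear
  cumulative-emission ramp reaching Δ at day D (default 17) — emulating the
  build-up and decay of previously accumulated pollution.  SD and NSF add a
  firework pulse (default 100 µg/m³) on festival days 4–6 of their periods,
  so the default period-mean firework contribution is 100·3/31 ≈ 9.7 µg/m³.
  The generator refuses configurations whose Δ exceeds the minimum emission
  term (they would force systematic clamping at 0).
* **Stations** (default 430) are placed one per cell while cells last, with
  sub-cell jitter, extras at random; they copy their cell's value.
  Missingness is MCAR at 3.5 % plus 30 designated stations forced above the
  20 % screening threshold.

What a green end-to-end test does establish: the full chain — file formats,
screening, gap filling, matching, per-hour training, counterfactual routing,
aggregation — recovers injected emission effects up to the forest's transfer
error.  What it does not establish: performance under features real data
have and the generator lacks — seasonality across periods, spatially varying
synoptic systems, instrument error structure, station siting bias, emission
trends inside a scenario.

## Numerical choices

* Population (÷n) standard deviation everywhere in standardization; constant
  variables are a hard error naming the variable.
* Haversine on the WGS84 mean radius for all distances.
* Forest RNG: one independent stream per (scenario, hour) model derived from
  the run seed via `SeedSequence` (stable CRC-based label), so adding a model
  never perturbs the others; CV fold models are seeded `seed + fold`.
* R² is the squared Pearson correlation reported as a fraction in [0, 1]
  (the ×100 form is carried alongside); it is an error for constant
  sequences, so CV folds whose held-out region slice is degenerate are
  skipped and logged rather than fabricated.
* Rounding/IO: all tabular outputs are plain CSV written deterministically;
  rerunning with the same config and seed is byte-identical.

## Known limitations

* With 31-day periods and a domain-shared daily anomaly, each hour model sees
  only ~31 distinct meteorological states; the counterfactual transfer error
  therefore has a day-correlated regional component of sd ≈ 3 µg/m³ at the
  default world size.  Regional effects of that order (e.g. the 8 µg/m³
  default for the least-affected region) are inside the noise — consistent
  with such effects being flagged *not significant* by the MAE gate — and
  small relative errors on them cannot be certified by the end-to-end
  recovery experiment.  The experiment reports pass fractions rather than
  hiding this.
* The turning-point rule detects the onset of persistent exceedance, not the
  completion day of a gradual ramp; under the default margin of 0 it triggers
  within a few days of the intervention start whenever any reduction exceeds
  the daily error.  Recovering a ramp-completion day would need a different
  statistic (e.g. change-point fitting on the difference series), which is
  out of scope here.
* The firework estimate is a difference of two model means, so its error
  combines both models' transfer errors; on short periods it is best treated
  as qualitative (sign and rough magnitude).
* No uncertainty intervals are attached to the difference cells beyond the
  MAE gate; resampling-based intervals are a possible extension.
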