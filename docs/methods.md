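# Methods

## Persistence regression

The model is ordinary least squares of `log10(persistence duration, years)`
on mean annual temperature (MAT, °C).  Base-10 logs are used for coefficient
readability; the base does not affect R² or p-values.  Two burial-history
classes are fitted:

* `never_buried` uses only bones confidently exposed for their whole
  post-mortem history;
* `potentially_never_buried` uses the **union** of both classes — a bone that
  certainly stayed on the surface is a fortiori one that may have.  A
  disjoint-sets fit can be obtained by filtering records before calling
  `fit_persistence`.

Input tables are consolidated to the **oldest bone per region** before
fitting (each region contributes one realised persistence duration); ties on
age break by smaller 2σ dating error, then lexicographic record id, so
output is deterministic.  Dating error is ignored in the fit itself — the
2σ ranges are small relative to the persistence durations — but a
variance-weighted fit (`weighted=True`, 1/σ² weights delta-method-propagated
to the log scale) is available.

Predictions at a new temperature report the back-transformed mean
`10^(a + b·MAT)` and an upper bound.  Two interval kinds are implemented:

* `mean_confidence` (default): the t-based confidence interval of the
  regression line, `SE² = s²(1/n + (x−x̄)²/Sxx)`;
* `new_observation`: the prediction interval for a single new bone,
  `SE² = s²(1 + 1/n + (x−x̄)²/Sxx)`.

The default follows the convention of quoting the regression line's 95%
confidence envelope.  Which kind matches a given published number can only
be checked against the underlying data table; the reproduction tests use the
default, and switching is one keyword argument.  Predictions outside the
fitted MAT range are allowed but carry `extrapolated=True`.

## Extinction estimator

The estimator is the Gaussian-resampled inverse-weighted sighting-rate
method (GRIWM).  With ages sorted oldest → youngest (descending yr BP) and
all distinct, sighting *i* implies the rate λᵢ = kᵢ/(tᵢ − t_last), where kᵢ
counts the sightings from *i* through the youngest minus one.  The
persistence probability *t* years past the last sighting is (1 − λᵢ)ᵗ;
solving for the threshold α gives the offset ln(α)/ln(1 − λᵢ), taken as 0
when λᵢ ≥ 1 (the probability is already below α at the last sighting).
Single-reference estimates `t_last − offset` are combined with weights
1/(tᵢ − t_last).

`estimate_extinction` redraws every age from Normal(age, 2σ/2) — 2σ is the
convention in which dating errors arrive — for `n_resamples` iterations
(default 10,000), recomputes the weighted estimate each time, and summarises
the resample distribution (median, mean, 2.5th/97.5th percentiles).  The
whole noise matrix is drawn from one seeded generator in a single call, so
output is bit-identical for identical inputs and seed.  Exact age ties
within a resample (possible only with zero dating error) are broken by a
10⁻⁶-yr jitter ordered by record id.  Resampled ages and estimates may go
negative: the BP axis is unbounded below, and a younger interval bound past
the present day is meaningful, so nothing is clamped.

**Known limitation — interval under-coverage.**  The resampling interval
propagates *dating* uncertainty only.  Two error sources it does not carry:
the gap between the last preserved sighting and the true extinction
(exponential with mean 1/rate under a constant-rate record), and the fixed
offset construction itself (≈ ln(1/α)·1/rate beyond the last sighting, i.e.
about 3/rate at α = 0.05, roughly 2/rate past the expected truth).  In
simulation with realistic settings (record from 50 to 11 kyr BP, ~12 dated
finds per kyr, 2σ dating errors of 200 yr) the nominal 95% interval covers
the true extinction time in only ~55–65% of replicates, and no point of a
wide sweep over sighting rate (0.5–8 per kyr) and dating error (200–1600 yr)
exceeds ~71%.  The acceptance-level coverage check therefore fails, and is
left failing: the interval should be read as the dating-noise envelope of
the point estimate, not as a calibrated frequentist interval.  The point
estimate itself is verified exactly against the closed form.

## Mixing windows and classification

For each region the expected-mixing window runs from the median of the
fossil-based extinction estimate (`window_old`) toward the present by the
predicted persistence duration at the region's site MAT.  Three nested
windows are built: mean persistence (never-buried model), upper 95% bound
(never-buried), upper 95% bound (potentially-never-buried).  Each eDNA age
is assigned the tightest window containing it, with **inclusive** bounds —
ages are point estimates, and boundary cases should not flip on rounding.
Ages older than `window_old` precede the extinction estimate, need no
explanation, and are labelled `within_mean`.  Classification uses point ages
only; eDNA host-sediment dating uncertainty is not propagated (its 2σ is
retained in the records for callers who want to resample).

The persistence regression is global — fitted once from the bone table —
and applied per region; regions are otherwise fully independent.  Per-region
estimator seeds are derived from the root seed and a CRC of the
region/source name, so pipeline output is deterministic and independent of
input row order.

## Synthetic data

`gen_bone_table` draws MAT uniformly on `mat_range` and sets
`log10(age) = intercept + slope·MAT + N(0, sigma_resid)` (defaults −0.06
log10-yr/°C, 2.6 log10-yr, σ = 0.15), which spans decades of persistence at
warm-temperate MATs to several kyr at deep-Arctic MATs.  Bones with
ambiguous burial histories additionally get a positive log-age offset
(default +0.25) and extra scatter (default σ = 0.10), emulating exhumed
material reading older and noisier — this is what makes the
potentially-never-buried envelope sit above the never-buried one, as in real
surface collections.  Each record gets its own region, so consolidation is
the identity on generated tables.

`gen_occurrence_series` draws fossil ages as a Poisson process (default 12
finds per kyr, matching a few hundred finds over a ~40-kyr record) on
`[true_extinction, record_start]` (defaults 11 and 50 kyr BP); eDNA ages are
the same process plus `n_edna_postmortem` dead-tissue inputs (default 10)
uniform on the `persistence_true`-long window after extinction (default 4
kyr).  Observed ages add Normal(0, 2σ/2) dating noise (default 2σ = 200 yr)
and are floored at 0 BP, which the defaults make vanishingly rare.  A
Poisson realisation with fewer than three fossils is regenerated with an
incremented seed and a logged warning; `fixed_n_fossils` gives a fixed-size
uniform record instead.

What the generator does **not** emulate: time-varying sighting rates,
radiocarbon-calibration multimodality (dating noise is Gaussian), spatial
structure, exhumation pulses feeding old eDNA into young layers, and any
dependence between fossil and eDNA preservation.  Passing synthetic checks
therefore demonstrate correctness of the estimators under their own
generative assumptions, not robustness to those real-data complications.

## Problem sizes and numerics

The test suite uses 500 replicates for extinction-interval coverage (1,000
resamples each) and 1,000 replicates for regression-coefficient CI coverage,
sizes at which the binomial noise on a 95% rate is ±0.7–1%.  The acceptance
script uses 200 coverage replicates at 500 resamples and reports every
quantity it computes to JSON.  Percentiles are numpy's default linear
interpolation; OLS is delegated to statsmodels and verified against the
closed-form sums in tests to 10⁻¹⁰ relative tolerance.
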