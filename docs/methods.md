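# Methods

## Model structure

The population of undocumented immigrants in year *y* is modelled as

P_y = N₀·q_{0,y} + Σ_c λ_c·q_{c,y}

where N₀ is the initial (1990) stock, λ_c the expected number of entries
of cohort *c* (entry year × entry channel), and q_{c,y} the probability a
member of cohort *c* is still present and undocumented in year *y*.
Cohorts never mix; all heterogeneity is by entry year, entry channel and
duration of stay.

### Inflows

**Illegal border crossers** are inferred from apprehension statistics by
the repeated-trials (capture–recapture) model. Per attempt an individual
is apprehended with probability p; an apprehended individual abandons
further attempts with probability d (deterrence), otherwise retries. All
attempts resolve within the calendar year of the first attempt. Writing
q = p(1−d), the expected number of apprehension events per individual is
p/(1−q), of which p·q/(1−q) are re-apprehensions, so the recidivist share
of apprehension events is exactly R/A = p(1−d) and

p̂ = (R/A)/(1−d),  Ŝ = A(1−p̂)/p̂.

"Recidivist apprehensions" here counts *events* involving an individual
already apprehended earlier in the year (total events minus distinct
individuals apprehended); the agent-based oracle in
`undocpop.synthetic_data` tallies the same quantity and is the arbiter of
these closed forms in the tests. Years 1990–2004 use an assumed early
apprehension rate (conservative value 0.39, the average of the published
2005–10 estimates); 2005–2015 use the published estimates directly, which
are preferred over recidivism-based estimates when both are available;
2016, which has recidivism inputs but no published rate, is estimated from
recidivism (equivalently, the 2015 published rate carried forward — the
bundled series makes these coincide). Only southern-border statistics are
used; crossings elsewhere are ignored, which lowers the estimate.

**Visa overstayers** in year *t* number V_t·ρ·k: visas issued times the
2016 overstay rate times a multiplier k (1 in the conservative run,
uniform on [0.5, 1.5] in simulation). ρ is interpreted as the rate of
overstays persisting *beyond one year*; the first-year emigration rate of
counted overstayers is then applied by the cohort dynamics like any other
cohort, with no additional within-module attrition (applying both an
under-one-year exclusion and a separate first-year exit inside the inflow
module would double-count early exits).

### Outflows

Within each year a cohort's retention is multiplied by
(1−e)(1−m)(1−a), in that fixed order (the product is order-invariant; the
order only standardises intermediate reporting):

* **e** — voluntary emigration, duration-banded: first year (channel- and
  cohort-specific), years 2–10, beyond 10. Conservative values 0.40 /
  0.04 / 0.01 per year.
* **m** — mortality, age-adjusted national rate; conservative 0.007/yr.
* **a** — administrative outflow: observed deportations plus status
  adjustments (incl. DACA) for the year divided by the total
  post-emigration, post-mortality stock. The source data give no cohort
  attribution, so a single pooled rate (proportional allocation) is the
  minimal-assumption choice; it makes absolute outflows proportional to
  cohort size. If the counts ever exceed the stock the rate clamps at 1
  with a warning.

**Timing conventions.** Entrants arrive at the start of their entry year
and face their first-year emigration rate within it. The initial 1990
stock is treated as having been present one year already: it enters the
2–10-year band in 1990 (reaching the >10 band in 1999), so the very high
first-year rate is never applied to an observed survivor population —
which maximises its subsequent modelled emigration and keeps the estimate
conservative.

## Conservative preset

p_early = 0.39, k = 1, e₁ = 0.40, e_mid = 0.04, e_late = 0.01, m = 0.007,
N₀ = 3.5 M. Every value understates inflows or overstates outflows
relative to the literature, so the deterministic run is a defensible lower
bound *within the model's assumptions*.

## Simulation methodology

Each trial draws one value per parameter, uniform over:

| parameter | range |
|---|---|
| early apprehension rate (1990–2004) | [0.25, 0.40] |
| overstay multiplier k | [0.5, 1.5] |
| first-year emigration, overstayers | [0.25, 0.50] |
| first-year emigration, crossers (per entry cohort) | [ℓ_c, 0.50] |
| emigration years 2–10 | [0.01, 0.05] |
| emigration beyond 10 | [0.005, 0.02] |
| mortality | [0.005, 0.010] |

ℓ_c rises linearly from 0.10 for 1990 cohorts to 0.25 for 2010 and later.
This cohort table is a documented stand-in: cohort-level studies support
low first-year exit among 1990s crossers rising with enforcement, but no
published per-cohort series is bundled, and the table is a constructor
argument (`ParameterRanges.e1_crosser_lower`) precisely so users can
substitute their own.

**Correlation.** Tighter border enforcement suppresses circular migration,
so the early apprehension rate and the cohort first-year crosser
emigration rates are drawn with linear correlation −0.5 on the uniform
margins via a Gaussian copula (Gaussian coefficient r = 2·sin(πρ/6) =
−0.5176 gives uniform-margin correlation exactly −0.5; linear rescaling to
the ranges preserves it). One first-year rate is drawn per entry cohort
per trial, shared across that cohort's single first year. Empirically the
coupling leaves per-year means within ~1.5% (a small fraction of the
distribution spread) and reduces per-year variance by roughly a third to a
half; the tests assert both.

**Population noise.** Conditional on a trial's parameters, cohort sizes
are independent Poisson and survival is independent thinning, so each
cohort's surviving count — and hence the yearly total — is Poisson. The
engine therefore draws one Poisson variate per year at the summed expected
mean (equal in law to summing per-cohort draws; unit-tested equivalence of
mean/variance). Draws are independent across years within a trial, as the
independence structure implies. The initial stock's Poisson(3.5 M)
variability is subsumed by the same mechanism.

**Implementation.** Trials are vectorized (numpy) in fixed chunks of
50,000 from a single seeded `default_rng`, making any run bit-reproducible
from its master seed. The scalar `CohortLedger` path and the vectorized
engine implement the same dynamics twice by design; the test suite pins
their agreement to round-off and checks trial means against the
deterministic run. 100,000-trial runs take seconds; the CLI default is
1,000,000 trials.

## Scenario and calibration

The 1990–98 scenario fixes *net* inflows at 0.5 M/yr: the stock follows
3.5 M + 0.5 M·(y−1989) through 1998 (8.0 M at end-1998) without gross-flow
bookkeeping, then the model resumes in 1999 with the pooled 8.0 M treated
as a single survivor cohort in the 2–10-year band (mirroring the
initial-stock convention; it reaches the >10 band in 2008). In simulation
mode the calibrated-path years get Poisson noise around the fixed path —
the pooled mean itself is held at 8.0 M across trials, since it is a
calibration target rather than an uncertain estimate.

Overstay calibration inverts the conservative run: find k such that the
overstayer component in a target year equals a target stock. The component
is monotone and nearly linear in k (administrative pooling introduces a
weak feedback through the total stock), so a bracketing Brent solve to
relative tolerance 1e-6 suffices; unreachable targets (k beyond 1/ρ) raise
rather than extrapolate.

## Synthetic data

`generate_inputs` emulates the *shape* of the source series: apprehensions
~10⁵–10⁶/yr flat-then-declining, visas ~10⁷/yr rising, deportations
~10⁵/yr rising, published apprehension-rate estimates 2005–2015 rising
0.35→0.55, deterrence estimates from 2005, lognormal count jitter, and —
crucially — recidivist counts constructed from the repeated-trials
identity at an embedded true rate, so estimator recovery is testable
against known truth. It does not emulate policy breaks (e.g. the 2001–03
visa dip), category composition, or any correlation between series beyond
the embedded identity, so passing tests demonstrate internal consistency
of the method, not agreement with real measurements.

The bundled `us_1990_2016_synthetic.csv` is likewise synthetic: a one-time
reconstruction at the publicly documented magnitudes of the real series,
with the accompanying overstay rate (0.060) reconstructed from the public
FY2016 overstay count over visas issued. Absolute outputs on this series
(e.g. the 12.6 M conservative 2016 estimate) therefore characterise the
bundled reconstruction, not the original source spreadsheet; analyses of
the real data should replace it via `--inputs`/`--config`. Two known
biases of the reconstruction: its `deportations` column uses total
removals although the model conceptually wants interior removals distinct
from border apprehensions (overstating the administrative outflow), and
its overstay rate is on the low side of plausible visas-issued-based
measures.

## Numerical choices and degenerate inputs

* Rates are validated into [0,1] at construction; counts non-negative;
  recidivist ≤ total apprehensions; years contiguous. Missing values are
  explicit NaN and never imputed.
* p̂ > 1 (recidivist share exceeding 1−d) raises rather than clamps: it
  signals inconsistent inputs.
* A year with zero apprehensions and no rate information yields zero
  crossers (the rate is unidentified but irrelevant).
* The agent oracle caps attempt sequences at 1,000 per individual and
  raises if reached (guards p ≈ 0 configurations).
* Percentile ranks use strictly-below counting with midpoint ties.

## Limitations

* No age/sex/origin stratification; a single aggregate mortality rate.
* Deportation counts are not de-duplicated against border apprehensions.
* The cohort table ℓ_c and the bundled input series are stand-ins; results
  on them are methodologically faithful but numerically tied to the
  reconstruction.
* No variance reduction in the Monte-Carlo; plain independent trials.
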