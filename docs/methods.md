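# Methods

## The model

`migsim` implements a stochastic evolution model for international
migration. Within each country it tracks a *native* population `P_i`
(people living in their country of birth) and *migrant stocks*
`D[i, k]` — people born in `k` residing in `i` (country-of-birth
definition). One yearly step draws all flows from the state at time `t`
and applies them simultaneously:

```
P_i(t+1) = (P_i − Σ_l M_il) · (1 + c_i) + Σ_l R_li + Σ_l B_il
D_ik(t+1) = D_ik · (1 − c†_k) − R_ik + M_ki
```

where `M[origin, destination]` are emigration flows, `R[residence,
origin]` return flows, `B[residence, origin]` births from migrant stocks
into the residence country's native population (children of migrants are
natives of the country they are born in), `c_i` the origin's natural
change rate and `c†_k` the origin country's death rate (migrant change
rates are assumed equal to those of the origin country). The death rate is
stored as a nonnegative number and applied as a survival factor
`(1 − c†)`: a positive death rate must shrink a stock. Migration inflows
are not rescaled by births or deaths within the step. Transit migration
(migrant population to migrant population in a third country) is not
modelled. With all natural rates zero the step conserves total persons
exactly; any negative value produced by extreme draws is clamped to zero
and counted.

Arrival times of migrants are aggregated out: because return and birth
flows are proportional to the current stock with arrival-time-independent
rates, storing `D` as a two-index matrix is mathematically equivalent to
tracking arrival cohorts, and initializing all stocks at the start year
loses nothing.

## Flow sampling

The complexity of the migration process is confined to three stochastic
rate functions, each calibrated within a partition of a covariate:

* **Emigration rate** per origin-year, drawn from a Jones–Faddy skew-t
  fitted per origin population bin — P1=[0, 1e6], P2=(1e6, 1e7],
  P3=(1e7, 1e8], P4=(1e8, ∞) (right-closed). Bilateral flows are
  `M_ij = P_i · rate · share_j`.
* **Destination share** per ordered pair, drawn from a Weibull-maximum
  fitted per (GDPc-ratio bin, diaspora bin) cell. GDPc-ratio bins
  g1..g4 have edges 0.1, 1, 10 (left-closed) on `g_ij = g_i/g_j`;
  diaspora bins d1..d5 have edges 1e-7, 1e-5, 1e-3, 0.1 (left-closed).
  The diaspora covariate is implemented bilaterally,
  `d_ij = D[j, i] / P_i` — the stock of i-born people already in the
  candidate destination relative to the origin population — because an
  origin-level covariate could not differentiate destinations
  (`diaspora_mode: origin_total` is available as a switch). Raw share
  draws rarely sum to one, so every share vector is uniformly
  renormalized; an all-zero raw vector falls back to uniform shares with
  a logged diagnostic.
* **Return rate** per (residence, origin) pair, drawn from a single
  unpartitioned Student-t (return rates are tightly concentrated);
  `R = D · r`. Independence across pairs and years is the documented
  choice; the alternative (one global draw per year) is not used.

Births are deterministic in both modes: `B[i, l] = D[i, l] · c*_l` with
the origin country's birth rate.

All rate and share draws are truncated to [0, 1] by rejection sampling
with a 1000-round cap followed by clamping, preserving the fitted shape
on the valid support. Sampling granularity is one emigration-rate draw
per origin-year, one share draw per ordered pair-year, one return draw
per occupied pair-year, all independent. **Deterministic mode** replaces
every draw by the median of the truncated distribution (computed through
the quantile function); it needs no seed. Ensembles spawn one child seed
per sample from the master seed (`numpy.random.SeedSequence`), making
results reproducible and order-independent, and summarize each output
series by the yearly median and central 50%/95% prediction intervals.

## Calibration

Calibration consumes bilateral flow tables aggregated to 5-year periods,
stock snapshots at period starts, and a country panel:

* 5-year rates are converted to yearly rates with
  `m1 = 1 − (1 − m5)^(1/5)` (homogeneity within the quinquennium); its
  inverse is used for round-trip checks. Five-year return rates above
  100% — an artifact of the source estimates — are discarded and counted.
  Emigration rates divide a period's total outflow by the origin's native
  population at the period start.
* Each labeled sample is fitted by maximum likelihood. The skew-t
  likelihood has a shape/scale ridge that defeats single-start
  optimization, so fits run from a small grid of shape starts with
  location/scale initialized at the sample median and standard deviation;
  the best likelihood wins. Fits are deterministic given the data.
* The goodness score used for ranking candidate families is the sum of
  squared errors between the fitted density and the sample histogram
  (100 equal-width bins over the observed range, density-normalized, at
  bin centers). MLE estimates the parameters; SSE only ranks families
  (ties: fewer parameters, then name). `exploratory=True` keeps the
  top-ranked family instead of the canonical one.
* Cells with fewer than `min_fit` observations (default 30) are EMPTY and
  fall back to the distribution pooled over GDP-ratio bins at the same
  diaspora bin — the diaspora covariate dominates destination choice, the
  GDP ratio is a minor modifier — then to the global pool. Empty
  population bins are a hard error: the model cannot sample emigration
  without them.

Fitted families remain unbounded; truncation happens at sampling time, so
heavy calibrated tails survive.

## The synthetic world

The generator stands in for the external inputs (bilateral flow
estimates, population prospects, stock matrices, GDP panels) so every
stage is testable offline, and closes the loop: worlds are generated from
a known distribution set, histories exported in the exact CSV dialects
the calibration reads, and recalibration is compared against the
generating truth.

Default study conditions: 40 countries over 1990–2020, populations
stratified log-uniformly across the four population bins (kept a factor
2.5 away from interior bin edges so countries do not migrate between bins
over the horizon), GDPc log-uniform over 500–100,000, birth rates
1.0–2.8% and death rates 0.6–1.4% per year (natural change is their
difference). The truth set uses skew-t emigration rates with medians
falling 0.006 → 0.001 from P1 to P4 and scales narrowing in proportion
(relative scale 0.45), Weibull-max share distributions whose medians rise
over orders of magnitude across diaspora bins (1e-6 … 0.4, roughly
proportional to the bin's covariate so corridors grow at comparable
relative speed) with weak GDP-ratio modulation, and a tight Student-t
return rate (location 0.004, scale 0.0012).

The default emigration truth uses the *symmetric* member of the skew-t
family. Exported flow histories are 5-year sums, so each recovered rate
sample is effectively an average of five yearly draws; for a skewed
distribution that shifts the sample median toward the mean by roughly
`(mean − median)(1 − 5^{-1/2})`, which would contaminate closed-loop
median-recovery checks with a bias that has nothing to do with the code
under test. Skew-dependent behaviour (the deterministic-vs-stochastic
stock gap) is exercised with a dedicated strongly right-skewed truth
(shapes (10, 2), relative scale 0.6).

Initial stocks are built origin by origin: a few *major corridors*
toward destinations chosen with probability proportional to destination
population (diaspora covariate log-uniform in 2e-4–0.02), their count
growing with origin size so raw share sums stay near one across origin
scales; plus sparse minor corridors whose presence probability scales
with destination size. Stocks are bounded by the destination — at most
5% of the destination's population per corridor and 20% in total — and
sub-person remnants are zeroed, as integer-valued stock data would record
them. Before the recorded window the stock matrix is burned in for 100
years under the truth dynamics (native populations rescaled back
afterwards), so corridors enter the window with the long accumulation
history real stock data embodies; without it, corridors ramping from a
cold start inflate recovered return rates by 10–15% because a period's
returns are divided by the period-*start* stock.

What the generator does **not** emulate: geography and distance, policy
shocks and historical events (wars, unions dissolving, visa regimes),
between-country persistent heterogeneity within a partition cell
(real emigration-rate spreads within a bin are wider and heavier-tailed
than the default truth), age/sex structure, and measurement error in the
source estimates. Passing closed-loop tests therefore demonstrates the
correctness of the calibration-simulation machinery under the model's own
assumptions, not the model's adequacy for any real-world series.

## Numerical choices

* Partition lookups: population bins right-closed, ratio/diaspora bins
  left-closed, exactly as defined; boundary membership is tested
  explicitly. A 50-million-person country falls in P3.
* Four GDP-ratio bins are implemented (the published partition names five
  but defines four); edges are configurable.
* The standard three-parameter Weibull-maximum family is used for shares.
* Truncated medians solve `F⁻¹((F(0) + F(1))/2)` and are cached per
  distribution; degenerate cases (no mass on [0, 1]) clamp to the nearer
  endpoint.
* Zero-variance samples are a calibration error, not a fit; empty share
  vectors renormalize to uniform with a warning; zero origin populations
  are skipped with a warning; negative populations after a step are
  clamped and counted.
* Ensemble quantiles of aggregated series are computed per sample and
  then summarized — quantiles are not additive across countries.
* Panel preprocessing: population gaps are linearly interpolated strictly
  within a country's observed span; per-capita GDP follows the
  PPP → MER → USD precedence, then closest-year fill (ties to the earlier
  year); every filled cell carries a provenance flag.

## Scales and limitations

Desk-scale defaults keep the full pipeline and test suite in the
single-digit-minute range: ensembles of hundreds to a few thousand
samples over 12–40 countries and 15–30 years, versus production
hindcasts with ensembles of 10⁵ samples over ~200 countries. Sample
sizes are configurable throughout; results in the test suite state the
scale they were computed at.

Known limitations:

* Recovered return-rate medians stay biased high by a few percent even in
  a stationary world, because within-period stock growth enters the
  numerator of `R5/D0` but not its denominator — the familiar
  1-year/5-year aggregation problem; the same mechanism inflates
  emigration-rate medians by 1–2% via within-period population growth.
* In a generate → calibrate → simulate loop at the default 40-country,
  6-period scale, the recalibrated ensemble's median tracks the
  generating run within ~2%, but its 95% Monte-Carlo band (±~1% of total
  stock under the mild-skew truth) is of the same order as the
  calibration's finite-sample error, so the band cannot be relied on to
  contain the generating run year by year; the band-coverage guarantee is
  exact only when sampling from the calibrated distributions themselves,
  which is what the self-coverage check verifies. The ratio of the two
  error sources is insensitive to the number of countries (both shrink as
  its inverse square root).
* Small destinations are inherently unstable under diaspora-driven
  destination choice with uniform renormalization: once a corridor into a
  small country crosses diaspora-bin edges its share grows by orders of
  magnitude. The generator's corridor structure keeps this feedback in a
  realistic regime; the dynamics themselves contain no destination-side
  capacity term.
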