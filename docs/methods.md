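# Methods

This note documents the models, conventions and numerical choices behind
`pentaphen`, and what the synthetic validation does and does not establish.

## Pentad calendar

All pooling uses 73 five-day bins with fixed calendar boundaries
(pentad *p* covers days 5(p−1)+1 … 5p of a non-leap year). Multi-year
pooling requires the boundaries to be date-aligned across years, so in leap
years 29 February is folded into the pentad of 25 February–1 March, which
then spans six days; every later pentad keeps its usual dates. All reported
percentile dates are day-of-year in the non-leap reference calendar
(1 January = 1). The fold-in rule is a package convention: any fixed
convention would do, but it must be applied consistently on both the
observation and the ringing side.

## Window determination

Field practice identifies a season's migration window by eye: counts rise
from a constant background and form an outstanding peak lasting more than
three pentads. The automated surrogate makes this reproducible:

| parameter | default | meaning |
|---|---|---|
| `baseline_quantile` | 0.10 | quantile of in-range counts taken as background |
| `rise_fraction` | 0.05 | above-background margin, as a fraction of the peak |
| `min_run` | 4 | minimum above-threshold run holding the peak (">3 pentads") |
| spring search range | pentads 1–37 | mid-January to early July |
| autumn search range | pentads 34–73 | mid-June to year's end |

The window is the maximal above-threshold run containing the seasonal
maximum; equal maxima resolve to the earliest with a warning; an all-zero or
flat season raises "no detectable migration" (the pipeline logs and skips
such series rather than aborting — a resident with no passage pulse is an
expected outcome, not an error). The season ranges overlap around mid-July
because late-summer wader return passage begins while spring stragglers may
still be moving; both ranges are configurable per run. Manual windows from a
config table always override detection.

## Adjustments

A1 rewrites pentads between an anchor `k_o` (forced to 0) and a reference
`k_r` (kept at its observed count) linearly, over 3–5 pentads; it exactly
satisfies `A_{k_o} = 0` and `A_{k_r} = n_r`, and the affected range is
restricted to the closed interval [k_o, k_r]. A2–A4 transplant a *relative*
profile (neighbour zone, lag-shifted; or an external reference series) onto
the affected segment and rescale it so the segment total is conserved. The
rescaling rule is a design choice: the pipeline's outputs are relative
distributions, so the transplanted content is shape, not magnitude, and
total-conservation leaves percentages outside the segment untouched. A3/A4
are restricted to zones 1–2 unless explicitly overridden, since the southern
reference stations' timing is not representative further north. Which series
need adjusting remains an expert decision supplied via config; the package
does not auto-detect candidates.

## Smoothing and percentile dates

The running mean divides by the full width even at window edges (missing
neighbours contribute zero), and values outside the window are re-zeroed so
smoothing never extends the migration period. rm3 is the default; the
pipeline escalates to rm5 when the rm3-smoothed profile still has more than
two local maxima, and a manual override always wins.

Percentile dates are computed at day resolution by spreading each pentad's
count uniformly over its five days and returning the *first* day whose
cumulative share of the in-window total reaches q/100 (ties earliest,
integer days, no interpolation). The uniform-within-pentad rule is the
simplest assumption producing day-resolution output from pentad bins; a
brute-force oracle that expands the counts into an explicit per-day multiset
and takes order statistics agrees with it exactly (property-tested on 1,000
random series). Consequences of the earliest-day tie-break: percentiles are
non-decreasing in q, translating a series by one pentad moves every
percentile by exactly 5 days, and symmetric pulses can show a one-day
asymmetry between mirrored percentile pairs.

The 5–95% truncation used on ringing series keeps the closed day interval
[d5, d95]; for mass spread uniformly over 100 days this retains 91 days
rather than exactly 90, within one count-equivalent of the nominal 90% —
the inclusive boundary is the same convention the percentile rule uses.

## Progression model

`d50 ~ zone + mean_median + zone:mean_median + (1 | species)` with Gaussian
errors, fitted separately per season. Zone enters as a numeric 1–4 covariate
(a single days-per-zone slope); `mean_median` is the species' seasonal mean
median across zones, so its interaction with zone tests whether early and
late migrants progress at different speeds. The response and `mean_median`
are centred before fitting (the lone "centring of both" interpretation:
centring the response and the continuous covariate), which changes only the
intercept. Species present in fewer than two zones are dropped; fewer than
ten species triggers a variance-stability warning; a single-zone design is
rejected as singular.

The default fitter is REML (deterministic; statsmodels `MixedLM`). An
optional species covariance matrix — e.g. phylogenetically derived —
structures the random effects; that path uses a profiled-REML fit via the
eigendecomposition of Z C Zᵀ, and agrees with the standard fit when C = I
(tested). An optional MCMC fitter samples the marginal likelihood with an
ensemble sampler; its iteration/burn-in/thinning counts are interpreted as
totals across walkers, and intervals are 95% credible intervals. Tree
handling/downloading is out of scope; C defaults to the identity.

## Ringing comparison

Captures before the species' autumn season start (default 15 July,
per-species later starts configurable) are discarded as local breeders;
the remainder is pooled into pentads over all years, rm3-smoothed, truncated
to 5–95%, and summarised by its median day. Species enter the comparison
only with more than 50 raw captures (counted before smoothing). Δd = NCL
median − ringing median; bins |0–2|, |3–4|, |5–10|, |11–28|; |Δd| ≤ 4 is
"equivalent" given natural interannual timing variation. The sample-size
check correlates capture totals with |Δd| (the magnitude, since the question
is whether small samples inflate the error). Long-vs-short archive
sensitivity is a date filter on the input records, not a separate code path.

## Synthetic data generator

The generator defines the study conditions under which the pipeline is
validated:

- **Passage pulses**: skew-normal day densities per species × zone × season,
  discretized to days; one clear peak per season (an optional second autumn
  wave reproduces the adult-then-juvenile wader pattern). Default community:
  12 species (9 obligate migrants, 3 partial/resident-leaning) with
  typical boreal timings (spring peaks day 90–142, autumn 205–285).
- **Latitudinal lags**: +4 days/zone in spring, −3 days/zone in autumn
  (north later in spring, earlier in autumn) — within the few-days-per-250-km
  progression the zone system is designed to resolve.
- **Interannual jitter**: per species × year × season, uniform over ±7 days,
  so true annual medians spread by at most 14 days across the decade.
- **Baselines**: partial migrants/residents get constant breeding-season and
  winter presence (birds/day) outside a ±3σ passage span.
- **Observation noise**: daily counts are gamma-Poisson (negative binomial,
  shape 5) around effort-modulated intensities; observer effort is a
  weekend-boosted weekly pattern times lognormal day noise, constant in
  expectation across the year; expected passage 20,000 birds per zone ×
  season × year, split over two reporting areas per zone.
- **Biases** (observation layer only; truth untouched): survey spikes over
  1–3 consecutive pentads, winter feeder boosts (rejected for obligates),
  pre-migratory flocking boosts.
- **Ringing**: Poisson thinning of the zone-1 autumn density with the same
  jitter table (twin data); a capture-bias shift reproduces large-Δd cases.

Truth bookkeeping records the generating densities' exact percentile days
(same first-day-≥-q rule at day resolution), per-year medians, the jitter
table and realized count totals. Identical seeds give byte-identical CSVs.

What passing tests show — and don't. The generator matches the analysis'
assumptions by construction: unimodal pulses, effort constant in
expectation, independent daily noise. Validation therefore demonstrates
internal correctness (windows, adjustments, percentiles and models recover
known truth) but cannot certify robustness to real-data pathologies the
generator omits: spatially clustered observers, day-correlated weather
effects on both birds and observers, double counting at hotspots, species
misidentification, or secular trends across years.

## Problem sizes and determinism

The default validation study is 12 species × 4 zones × 10 years
(~10⁵ records, ~2×10⁷ birds), which the full pipeline processes in a few
seconds; the acceptance script's complete run (pipeline, spike-repair
scenario, two model fits, ringing comparison) completes in well under a
minute. All randomness flows from a single integer seed through
`numpy.random.default_rng`; REML runs are fully deterministic, and the MCMC
fitter is reproducible given a seed.

## Known limitations

- Window detection assumes one dominant seasonal peak; irruptive or
  second-winter movements are out of scope and can confuse the surrogate.
- The automated window rule is a stand-in for expert judgement; its
  defaults were chosen on synthetic pulses and real deployments should
  review detected windows (manual windows override).
- Percentile dates are integer days with an earliest-day tie-break, so
  single-day asymmetries around symmetric pulses are inherent.
- The progression model treats zone as numeric; non-monotone latitudinal
  patterns (common in autumn) are visible only through diagnostics, not the
  slope.
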