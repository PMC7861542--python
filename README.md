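# pentaphen

Bird migration phenology from unstructured count data pooled in pentads.

Online bird portals accumulate millions of dated, located count reports that
are not structured as checklists. `pentaphen` turns such non-checklist (NCL)
streams into species- and zone-specific descriptors of migration phenology:
the days of year by which 5%, 50% and 95% of a season's migrants have passed
(d5 = onset, d50 = migration median, d95 = end), separately for spring and
autumn and for latitudinal zones. It is aimed at ornithologists and movement
ecologists who want climatological passage timings from portal archives, and
ships a fully instrumented synthetic-data generator so the whole pipeline can
be exercised and validated without access to a real portal database.

## Method

Counts are pooled into **pentads** — 73 fixed five-day bins covering the year
(29 February folds into the pentad of 28 February) — summed over all study
years and over the reporting areas of each of four latitudinal zones. Per
species × zone × season the pipeline then:

1. determines the **migration window** (the contiguous pentad run holding an
   outstanding peak of more than three pentads) and zeroes all counts outside
   it (non-migratory presence);
2. applies optional **bias adjustments**: A1 semi-linear extrapolation to
   zero, `A_k = n_r·|k_o − k| / |k_o − k_r|`, which levels out survey spikes
   and breeding-count peaks at the season's edges; A2 transplant of a
   neighbouring zone's relative profile (lag-shifted by the interzonal
   migration speed); A3/A4 replacement by an external reference phenology
   (observatory or waterbird counts, southern zones only);
3. smooths with a **running mean** over three pentads (rm3), or five (rm5)
   for highly irregular series, without expanding the window;
4. converts to relative values (%) and reads off **d5/d50/d95** at day
   resolution, spreading each pentad's count uniformly over its days and
   taking the first day whose cumulative share reaches the level.

Latitudinal progression is tested with a Gaussian mixed model
`d50 ~ zone × mean_median + (1 | species)` (REML by default, an MCMC fitter
optionally), where `mean_median` is the species' seasonal mean median across
zones. Autumn medians are validated against standardized ringing captures:
pooled from 15 July, rm3-smoothed, truncated to the central 5–95% of the
season, and compared per species as Δd = NCL median − ringing median
(|Δd| ≤ 4 days counts as equivalent; negative Δd means the ringing median is
later).

## Worked example

```python
import pentaphen as pp
from pentaphen.progression import build_progression_data, fit_progression

gen = pp.GeneratorConfig(seed=1)              # 12 species, 4 zones, 10 years
records, truth = pp.generate_observations(gen)
summaries, report = pp.run_phenology(records, gen.zonemap())
print(pp.summaries_to_frame(summaries).head(4).to_string(index=False))
```

```
species  zone  spr_5  spr_50  spr_95  aut_5  aut_50  aut_95 proc_spr proc_aut    n_spr    n_aut
 ALAARV     1     83      95     106    257     271     283      rm3      rm3 191399.0 202502.0
 ALAARV     2     88      99     111    256     269     281      rm3      rm3 196345.0 193319.0
 ALAARV     3     93     103     115    252     265     277      rm3      rm3 196195.0 204430.0
 ALAARV     4     97     107     119    248     262     275      rm3      rm3 189988.0 203161.0
```

The skylark-like early migrant ALAARV peaks in spring around day 95 (early
April) in the southernmost zone and ~4 days later per zone northward, while
its autumn median moves ~3 days earlier per zone — exactly the latitudinal
lags the generator built in. The mixed model recovers them with tight
intervals:

```python
fit = fit_progression(build_progression_data(summaries, "spring"))
print(fit.summary_frame().round(3))
```

```
                  estimate  lower  upper      p
intercept            0.000 -0.086  0.086  1.000
zone                 4.000  3.924  4.076  0.000
mean_median          1.000  0.995  1.005  0.000
zone:mean_median     0.001 -0.004  0.005  0.755
```

(The response is centred, so the intercept is the grand-mean deviation; the
zone slope of +4.0 days/zone is the built-in spring lag.) Comparing autumn
medians with a thinned "ringing station" sampling of the same passage gives
per-species differences of at most 2 days:

```
species  ncl_median_day  ringing_median_day  delta_d bin  equivalent    n_ncl  n_ringing
 ALAARV             271                 271        0 0-2        True 202502.0    10102.0
 ANTPRA             254                 254        0 0-2        True 207031.0     9914.0
 CALALP             211                 213       -2 0-2        True 195080.0     9093.0
```

The same workflow is available from the shell:

```sh
pentaphen simulate --seed 1 --out run/
pentaphen phenology --config run.yaml
pentaphen progression --config run.yaml --season spring --phenology-table run/phenology.csv
pentaphen compare-ringing --config run.yaml --phenology-table run/phenology.csv
```

with a YAML config holding the CSV paths (observations: `species,date,count,
area,behaviour`; zone map: `area,zone`; ringing: `species,date,captures`;
optional manual windows and adjustment specs).

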