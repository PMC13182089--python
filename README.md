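# thermoguild

Does a hot day pull subordinate predators into the path of their
dominant competitor?  `thermoguild` is a tested, reusable pipeline for
answering that question from multi-species GPS tracking data.  It links
daily maximum temperature — on the same day (lag 0) and the previous
day (lag 1) — to four behavioural responses of a predator guild (one
dominant species, two subordinates):

1. **Close encounters** — days on which a dyad's concurrently sampled
   fixes (within 2.5 min) come within 400 m of one another;
2. **Spatial overlap** — the proportion of an animal's hourly fixes
   inside its competitor's rolling 30-day Brownian-bridge home range;
3. **Habitat selection** — integrated step selection analysis (iSSA)
   with habitat × temperature interactions;
4. **Diel activity overlap** — the coefficient of overlapping Δ between
   species' activity densities on the sun-time circle.

Responses 1, 2 and 4 are modelled with penalized-spline binomial GAMMs
(smooths of standardized temperature at lags 0/1, a day-of-year smooth,
a dyad/individual random intercept, and an AR(1) working correlation);
response 3 uses conditional logistic regression of each used movement
step against 150 sampled available steps,
`w(x) = exp(βx)`, with cluster-robust (GEE sandwich) standard errors by
individual.  A seeded synthetic world — seasonal autocorrelated
temperature, a patchy 4-class habitat raster at 10 m, and
correlated-random-walk animals whose attraction to a zone shared with
the dominant predator is a logistic function of the previous day's
temperature z-score — provides ground truth for every stage, so the
whole chain is testable without any field data.

Intended users: movement ecologists who want the full
temperature-to-encounter analysis chain as composable, tested Python
functions, plus a CLI for running it end to end.

## Worked example

Run the bundled `lag1-effect` scenario, in which subordinate species A
("cheetah") is given a programmed lag-1 temperature attraction toward
the zone occupied by the dominant species ("lion"), while subordinate B
("wild_dog") has none:

```bash
thermoguild all --scenario lag1-effect --seed 1 --outdir out
```

or in Python:

```python
from thermoguild.pipeline import PipelineConfig, run_pipeline
report = run_pipeline(PipelineConfig(scenario="lag1-effect", seed=1, outdir="out"))
```

At seed 1 the encounter GAMM for the cheetah–lion pair (dry season, 736
dyad-days, 206 encounter days) estimates an 80th-vs-median lag-1
fold change of **2.49** (lag-1 smooth p ≈ 3.5 × 10⁻⁶): following a
warm day, a close encounter is about 2.5 times as likely as after a
median-temperature day.  The spatial-overlap model shows the same
signature (lag-1 fold change **2.32**, p < 0.001), while the lag-0
smooths and the entire wild dog–lion pair stay flat — exactly the
programmed ground truth.  The diel overlap between the diurnal cheetah
and nocturnal lion is Δ ≈ 0.83 at both cool and warm temperatures
(no programmed activity shift, no significant change).  Rerunning with
`--scenario null` (no programmed effect anywhere) yields fold changes
near 1 and no significant smooths.

Outputs under `out/`: `report.json` (models, diagnostics, fold
changes, threshold-sensitivity grid), `dyad_days.csv`,
`proportions.csv`, `fold_changes.csv`, `rss.csv`, plus the simulated
world (`fixes.csv`, `habitat.asc`, `temperature.csv`, `sun.csv`,
`ledger.json` with the true effect sizes).

## Package layout

| module | contents |
| --- | --- |
| `thermoguild.synthetic` | seeded world + trajectory generator, ground-truth ledger |
| `thermoguild.tracking` | hourly regularisation, 20 m activity rule, temperature scaling, pseudoreplication filter |
| `thermoguild.dyads` | 2.5 min concurrency matching, daily minimum distances, encounter flags, dyad exclusion |
| `thermoguild.homerange` | BBMM motion variance, utilization distributions, isopleths, rolling proportion-in-range |
| `thermoguild.gamm` | penalized-spline GAMM engine, diagnostics (concurvity/VIF), fold-change predictions |
| `thermoguild.issa` | step construction, gamma/von Mises fits, available-step sampling, conditional logistic + RSS |
| `thermoguild.activity` | sun-time transform, activity densities, coefficient of overlapping + CIs |
| `thermoguild.pipeline` / `cli` | config-driven orchestration (`thermoguild simulate|preprocess|encounters|homerange|issa|activity|report|all`) |

See `docs/methods.md` for the statistical details, default parameters,
and known limitations.
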