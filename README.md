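# ddphen

Degree-day phenology toolkit for multivoltine insect pests monitored with
pheromone traps. It covers the full analysis chain:

- **thermal** — daily and accumulated degree days (DD) from daily min/max
  temperatures using the single sine method with a lower threshold of 7.2 °C,
  an upper threshold of 32.2 °C and a horizontal cutoff; accumulation restarts
  every 1 January.
- **model** — a fixed-offset multivoltine forecast: first catch predicted at
  126 DD after 1 January, successive generation windows of 535 DD (egg to
  egg), optionally widened by 60 DD per generation for development on apple
  (595 DD total).
- **traps** — weekly per-trap catch aggregation (mean ± SE per area-year) and
  re-keying of the weekly series onto the accumulated-DD axis.
- **segmentation** — splitting a season's capture curve into flights at the
  minima between peaks, cross-year imputation of unresolved boundaries and
  flight durations in DD (the operational adult-to-adult generation time).
- **stats** — backward-stepwise factorial ANOVA (sequential sums of squares
  with rank-aware df, honest under nested factor layouts), Shapiro–Wilk and
  Bartlett assumption checks, Tukey HSD per province with a compact letter
  display, and the jackknife SE of the mean.
- **synthetic** — ground-truthed weather and trap-catch simulators
  (`girona_like`, `lleida_like` presets) so every stage is testable at desk
  scale without field data.
- **evaluation** — coverage of catches by predicted windows, per-generation
  boundary offsets, and calendar/DD-axis season plots.

## Test

```sh
python -m pytest tests/
```

The suite includes property tests (hypothesis), independent numerical oracles
(quadrature of the clipped sine, brute-force ANOVA sums of squares) and
`tests/test_acceptance.py`, which checks the model constants, the
oracle-equivalence bound (1e−6 DD), analytic statistical identities,
50-seed parameter recovery on both synthetic scenarios, the accumulating
boundary-offset property and end-to-end determinism.

## CLI

Each stage is a subcommand; `run` wires them together:

```sh
# simulate a ground-truthed season
ddphen simulate --scenario lleida_like --seed 7 \
    --out-weather w.csv --out-catches c.csv --out-truth t.json

# degree days from a weather CSV (date,tmin_C,tmax_C)
ddphen dd --weather w.csv --lower 7.2 --upper 32.2 --out dd.csv

# predicted generation windows (peach: 535 DD; apple: 595 DD)
ddphen predict --host apple --n-gen 5 --out windows.csv

# trap catches on the DD axis, flight segmentation, statistics
ddphen traps --catches c.csv --weather w.csv --out ddcatch.csv
ddphen segment --ddcatch ddcatch.csv --smooth 3 --prominence 0.15 --out flights.csv
ddphen stats --flights flights.csv --out-anova anova.txt --out-tukey tukey.csv

# everything at once, with a manifest for reproducibility
ddphen run --weather w.csv --catches c.csv --outdir out/
```

Exit codes: 0 success, 2 validation error, 3 data error.

## Input formats

- Weather CSV: `date,tmin_C,tmax_C` (ISO dates, one station per file).
- Trap CSV, per-trap: `area,year,check_date,trap_id,catch_count`; or
  pre-aggregated: `area,year,check_date,mean_catch,se,n_traps`.
- Model config (YAML/JSON): `biofix_dd`, `generation_dd`, `host_delay_dd`,
  `n_generations`.
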