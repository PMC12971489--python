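# syndyn

Two-state stochastic modelling of developmental synapse turnover from
interval-censored live-imaging schedules.

Synapses are born along dendrites by a homogeneous Poisson process (rate
`b_n`, synapses per µm per hour) into a short-lived *new* state, from
which they either stabilize (hazard `c_ns`, per hour) or decay (hazard
`d_n`); stable synapses decay at a much slower hazard `d_s`. Imaging
visits the dendrite at a fixed schedule (e.g. t = 0, 6, 12, 24, 48, 72 h),
so each synapse is observed only as a *lifetime category* — the pair of
first and last detection times — with deaths interval-censored and
survivors right-censored at the final visit.

The package provides:

- **`syndyn.core_model`** — closed-form survival functions, stationary
  densities, expected lifetime-category densities and expected turnover
  rates for the two-state model and its one-state (pure
  immigration–death) null.
- **`syndyn.simulator`** — exact, seeded event-level simulation of
  synapse tracks on dendrites (competing exponential clocks, no time
  discretization), with order-invariant per-dendrite substreams.
- **`syndyn.observation`** — conversion of tracks (or real tracking
  tables) to presence matrices, stable/new cohorts, lifetime-category
  counts, two-time-point turnover summaries, Kaplan–Meier curves and
  log-rank tests.
- **`syndyn.inference`** — exact Poisson category-count likelihood,
  multi-start maximum-likelihood fitting, AIC comparison of the two-state
  model against the one-state null, bootstrap standard errors
  (resampling fish or dendrites), percent-change comparisons and a
  Mann–Whitney rank-sum test.
- **`syndyn.synthetic_data`** — calibrated parameter fixtures
  (`theta_ctrl`, `theta_mut`) reproducing the study's printed summary
  statistics, study-design presets, and deterministic dataset generation.
- **`syndyn.cli`** — a `syndyn` command-line tool tying it together.

## CLI

```sh
# generate a synthetic dataset (tracks, presence table, params, manifest)
syndyn simulate --fixture theta_ctrl --preset fate72 --seed 7 -o out/

# fit the two-state model to lifetime-category counts, with bootstrap SEs
syndyn fit out/presence.tsv --dendrites out/dendrites.tsv \
    --model two_state --bootstrap 200 --unit fish -o fit_ctrl.json

# compare two fits: percent change per parameter (+ rank-sum p with draws)
syndyn compare fit_ctrl.json fit_mut.json -o report.json

# turnover summaries and Kaplan-Meier curves
syndyn summarize out/presence.tsv --dendrites out/dendrites.tsv --window 0 24
syndyn summarize out/presence.tsv --dendrites out/dendrites.tsv --km stable
```

All logging goes to stderr; data go to files or stdout. Exit codes:
0 success, 1 runtime failure, 2 usage error.

## Data formats

Plain-text TSV throughout: track tables (one row per synapse with birth /
stabilization / death times, empty when the event did not occur),
long-format presence tables plus a per-dendrite length table, and
lifetime-category count tables. Parameters are flat YAML/JSON mappings;
fits and bootstrap results are JSON.
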