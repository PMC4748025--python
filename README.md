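# proxsoc

Analysis toolkit for intersexual association patterns in multilevel
(one-male-unit based) animal societies, built around proximity scan
sampling and focal observation data, plus a calibrated simulator that
generates such data with known ground truth.

## What it does

- **records** — data model and CSV I/O for the four study tables
  (`roster.csv`, `scans.csv`, `events.csv`, `states.csv`): individuals,
  instantaneous proximity scans with disjoint 2-m / (2,5]-m rings, timed
  behaviour events (approach, retreat, supplant, groom, greet, aggression,
  copulation, infant handling; surreptitious flag), and daily reproductive
  states (L, P, C0–C3).
- **network** — weighted female–male proximity networks (2-m ring, or
  cumulative 5-m relation), density / degree / strength, Newman weighted
  modularity, walktrap community detection (random-walk distances, Ward
  merges, modularity-maximising cut, deterministic refinement), a
  Potts-model simulated-annealing partitioner, and pairing-success scoring
  (fraction of females co-assigned with their primary male). Exports to
  edge-list CSV and GraphML.
- **status** — fortnightly classification of males as *primary* (most often
  within 2 m of a female), *secondary* (within 2 m at least once) or
  *unaffiliated* (never within 2 m of any female); Friedman/Nemenyi
  preferred-associate tests per female; model-ready long-format yes/no
  behaviour-occurrence tables (no mixed-model fitting — that is an
  explicit hand-off).
- **dyadstats** — Hinde index `HI = A_f − R_f` with the ≥10-interaction
  inclusion rule and supplant exclusion; tie-corrected Friedman
  average-rank test with exact small-sample permutation p-values; Nemenyi
  post hoc critical differences; approach-initiation shares by male status.
- **tenure** — transfer detection from the ad libitum stream (a change of
  primary male requires a non-surreptitious affiliative interaction with a
  different male, confirmed by sustained affiliation) and tenure intervals
  with truncation flags and median length.
- **simulate** — a society generator (parties → one-male units → primary /
  secondary males, females, bachelors), semi-Markov reproductive-state
  series, focal follows with 4 scans per 30-min sample, state-dependent
  greeting logits, status-dependent behaviour rates, high copulation
  fidelity, and fortnightly female transfers. Deterministic per seed with
  named substreams per stage.

## Command line

```sh
# generate a synthetic study (all defaults; any key can be set in YAML)
proxsoc simulate --out data/ --seed 7
# optionally: proxsoc simulate --config my_config.yaml --out data/

# run the full analysis bundle
proxsoc analyze --data data/ --out results/

# human-readable summary
proxsoc report --results results/
```

`analyze` writes networks (edge lists + GraphML), per-window statuses,
Friedman/Nemenyi results, occurrence tables, Hinde indices, transfers,
tenures, affiliation timelines, and `summary.json`. Exit codes: 0 ok,
1 user error, 2 internal error. The YAML config keys mirror
`proxsoc.simulate.SocietyConfig` field-for-field.

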