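# pvsignal

Disproportionality-based safety-signal detection for spontaneous
adverse-event report data in the quarterly dollar-delimited ASCII dialect
(DEMO / DRUG / REAC / OUTC / THER / INDI tables), built around a two-drug
comparison workflow (cenobamate vs lacosamide by default).

The pipeline:

1. **faers_io** — read/write the quarterly ASCII dialect and assemble one
   record per report (demographics, drugs with roles and daily doses, event
   PTs, outcomes, indications). Also loads the bundled published-signal
   fixture (`pvsignal/data/table5_signals.csv`).
2. **dedup** — one report per case: keep the version with the highest FDA
   date, ties broken by the largest primary id.
3. **mapping** — normalize verbatim drug names against a synonym dictionary
   (generic + brand names, dose/form noise ignored), select reports by drug
   role (suspect-only by default), remove each report's own indication PTs
   from its events, and map PTs to system organ classes via a flat
   `pt<TAB>soc` vocabulary (a small demo vocabulary is bundled; supply your
   own licensed vocabulary for real analyses).
4. **contingency** — report-level 2×2 tables for every (drug, PT) and
   (drug, SOC) pair against the whole ingested report universe.
5. **dispro** — ROR with 95% Woolf interval, PRR with Pearson χ² (Yates
   optional), BCPNN information component posterior moments (E(IC), V(IC),
   IC−2SD), and the composite signal rule
   (a ≥ 6; ROR ≥ 2 with lower 95% bound > 1; PRR > 2 with χ² > 4;
   IC−2SD > 0; "strong" when IC−2SD ≥ 1.0).
6. **compare** — baseline characteristics with half-up percentages, top-k
   events, daily-dose strata, yearly counts, and the cross-drug comparison
   exports (signal table, forest-plot data for shared signals, Sankey edge
   list).
7. **synthetic** — a deterministic generator that writes the same ASCII
   dialect with planted (drug, event) reporting-rate ratios, duplicate case
   versions and configurable missingness, for end-to-end testing without
   any external data.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance checks: published-table
reproductions plus property-based substitutes (statistic oracle
equivalence, dedup invariants, null calibration < 2% flag rate on 5×50k
null reports, ≥ 95% planted-signal recovery over 20 seeds, IC convergence).
The full suite runs in well under a minute.

## CLI

```sh
# generate a synthetic quarter with a planted signal
pvsignal simulate --out scratch/q1 --n 20000 --seed 7 --rr cenobamate:Diplopia:10

# run the full pipeline (CSV outputs + summary.json + run.log)
pvsignal run --input scratch/q1 --out scratch/q1-results

# summarise the bundled published-signal fixture
pvsignal fixture-check
```

`run` accepts `--config run.yaml` (same keys as the flags), threshold
overrides such as `--min-a`, `--roles PS,SS,C`, and custom `--drug-dict` /
`--vocab` paths. Exit codes: 0 ok, 1 config error, 2 stage failure (no
partial outputs are left behind).

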