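# File formats

## Orthogonal array CSV (`data/l36.csv`)

Header `W1,...,W23`; 36 rows of 1-based level indices (1/2 for W1–W11,
1/2/3 for W12–W23). `OrthogonalArray.to_csv`/`from_csv` round-trip this
bit-exactly; loading re-validates all balance invariants.

## Prevalence table CSV

Long format, one row per (disease, panel, stratum, year):

| column           | values                                                        |
|------------------|---------------------------------------------------------------|
| `disease`        | one of the 17 disease names                                   |
| `panel`          | `region` \| `age` \| `gender`                                 |
| `stratum`        | `all`, a region name, an age band, or `male`/`female`         |
| `year`           | `2013` \| `2019` \| `pooled`                                  |
| `prevalence_pct` | percent in [0, 100]                                           |

`annl36 simulate` emits the same schema plus an `n` denominator column.

## Microdata CSV (`annl36 simulate`)

Columns `year, region, age_group, gender` followed by the 17 disease
columns (0/1), one row per respondent. Same seed ⇒ byte-identical file.

## Weights CSV (`weights_<year>.csv`)

`factor,value` with factors `W1..W23`; `value` is `repr(float)`, so the
round trip is bit-exact.

## Trace CSV (`trace.csv`)

`year, iteration, winner, winner_objective, best_objective` — one row per
search iteration; `winner` is the array row id `ANN1..ANN36`.

## Report CSV (`report.csv`)

`model, phase, year, mmre_pct, pearson, spearman_rho, r2_cubic`; one row
per model × phase × year. `report_rounded.csv` is the same table with
percentages rounded half-up to one decimal (table style);
`summary.csv` (from `annl36 report`) aggregates training rows per model,
ranked by MMRE.

## Coders YAML (`coders_<year>.yaml`)

The fitted `CodingConfig` of inputs and targets (kind, support, peaks,
band, moments) — everything needed to re-apply the coding bit-identically.

## Manifest (`manifest.yaml`)

Command name, package version, all parameters (including the seed), and
SHA-256 prefixes of the shipped fixtures.
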