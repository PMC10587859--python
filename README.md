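# araskit

Entropy-weighted additive ratio assessment (ARAS) for ranking decision
alternatives under multiple, possibly conflicting criteria — with a worked
case study on selecting a provisional restoration for single-tooth implant
treatment.

The pipeline:

1. **Conversion** — qualitative assessment grids (labels such as
   *excellent*, *lengthy*, *none*) are mapped to integer scores via five
   built-in ordinal vocabularies; each criterion is annotated as a benefit
   (maximise) or cost (minimise) with scale bounds taken from its rule.
2. **Entropy weighting** — cost columns are reflected onto the benefit
   orientation (`scale_max + scale_min − x`), columns are normalised to
   shares, and each criterion's weight is its normalised dispersion
   `|1 − e_j|` under the Shannon entropy `e_j` (natural log, `1/ln m`
   normaliser). The reflection can be disabled (`--no-reverse-score`) for
   ablation.
3. **ARAS ranking** — an ideal row (column max/min) is prepended, benefit
   columns are share-normalised directly and cost columns via reciprocals,
   weighted row sums give the optimality value `S_i`, and each alternative
   is scored by its utility degree `K_i = S_i / S_opt ∈ (0, 1]`.
4. **Sensitivity analysis** — equal weighting plus per-criterion dominance
   scenarios (dominant criterion `k`-fold the rest; `k = 3` → "S1",
   `k = 2` → "S2"), ranking comparison (Kendall tau, first divergence) and
   a best-option summary report.
5. **Synthetic problems** — a seeded generator for random bounded-ordinal
   decision problems, used heavily by the property-test suite.

## CLI

```sh
# criterion weights (entropy e/d/w table) for the bundled case study
araskit weights

# ARAS ranking under entropy and equal weighting
araskit rank --weighting entropy --weighting equal

# dominance-scenario grid (k = 3 and k = 2 per criterion) + best options
araskit scenarios --out results/

# your own problem: CSV of alternatives x criteria plus a criteria config
araskit rank --input problem.csv --criteria criteria.yaml --qualitative

# random synthetic problem (CSV + criteria YAML)
araskit simulate --n-alternatives 7 --n-criteria 8 --seed 1 --out sim/
```

A criteria config is a YAML/JSON list:

```yaml
- {name: Esthetic potential, direction: max, rule: 1}
- {name: Treatment time,     direction: min, rule: 2}
- {name: Score,              direction: max, rule: numeric, scale: [1, 10]}
```

Exit codes: 0 success, 2 usage, 3 configuration, 4 label conversion,
5 malformed input, 6 degenerate (all-constant) matrix, 7 numeric-domain
violation.

## Layout

```
src/araskit/
  conversion.py   rules, criterion specs, raw tables, decision matrices, I/O
  case_study.py   the bundled 7x8 case study
  entropy.py      reverse-scoring, shares, entropy, dispersion, weights
  scenarios.py    equal and dominance weight vectors
  aras.py         ideal row, normalisation, weighting, S/K, ranking
  sensitivity.py  scenario grid, ranking comparison, best-option report
  synthetic.py    seeded random decision problems
  cli.py          `araskit` command-line entry point
```
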