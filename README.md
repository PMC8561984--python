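# equicat

Socioeconomic health-equity analysis for individual-level household
utilization surveys:

- **Concentration indices** for binary healthcare-use outcomes against the
  weighted fractional rank of equivalized consumption, with **Wagstaff**
  (`CI/(1-mu)`) and **Erreygers** (`4*mu/(b-a)*CI`) normalizations, robust
  standard errors via the weighted convenient regression, and quintile
  summary tables.
- **Decomposition** of a use variable's concentration index into need,
  non-need and living-standards contributions using a weighted probit with
  partial effects at means (weighted LPM fallback); contributions plus a
  generalized-CI residual add up to the total index exactly.
- **Horizontal inequity** via indirect need-standardization (need factors at
  actual values, non-need factors at weighted means), preserving the mean
  exactly and matching the CI-minus-need-contributions route to machine
  precision.
- **Benefit incidence analysis**: unit costs from a spending/units ledger,
  gross and net (zero-floored, out-of-pocket-adjusted) subsidy benefits with
  recall-period annualization, quintile benefit shares and benefit CIs.
- A **synthetic survey generator** with known ground truth (stratified
  governorates, overdispersed household sizes, log-normal equivalized
  consumption, need-gradient chronic disease, per-service probit
  utilization, rank-dependent out-of-pocket payments) so the whole pipeline
  is testable end to end, plus a Monte-Carlo oracle for the generator's true
  concentration index.

## Command line

```bash
equicat simulate --seed 1 --out data/                    # individuals.csv, households.csv, costs.yaml, population.yaml
equicat equity    --in data/ --outcomes all --out table4.csv
equicat decompose --in data/ --outcome total_outpatient --out table3.csv
equicat inequity  --in data/ --outcomes all --out hi.csv
equicat bia       --in data/ --costs data/costs.yaml --out table5.csv
equicat run       --seed 1 --out results_dir/            # full pipeline, tables 1-5 + results.json
```

`equicat run` accepts a YAML config (`--config run.yaml`) with keys
`input_dir`, `simulate` (synthetic-config overrides), `theta`, `alpha`,
`use_weights`, `method` (`probit`/`lpm`), `seed`, `output_dir`.

## Library sketch

```python
from equicat import (
    read_survey, build_weights, rank_dataset, concentration_index,
    design_matrix, decompose_ci, horizontal_inequity,
    unit_costs, individual_benefits, benefit_shares,
)

ds = read_survey("individuals.csv", "households.csv")
ds = build_weights(ds, {"greater_cairo": 40000, "alexandria": 15000, ...})
ranked = rank_dataset(ds, theta=0.56)            # equivalize, rank, quintiles
est = concentration_index(ranked.data["use_out_public"], ranked.rank, ranked.weights)
X, groups = design_matrix(ranked)
dec = decompose_ci(y, X, ranked.weights, ranked.rank, groups=groups)
hi = horizontal_inequity(y, X, ranked.weights, ranked.rank, groups=groups)
```

File schemas (`individuals.csv`, `households.csv`, `costs.yaml`,
`population.yaml`) are documented in `equicat.survey_io`; monetary amounts
are analyzed in USD (EGP inputs are converted at load, default 17.6 EGP/USD).

## Notes

- Fractional ranks pool tied consumption values at their block midpoint
  (weighted mean rank is exactly 0.5); quintiles split ties in stable order
  so shares stay at 20% per quintile.
- The standardized-use variable is not clipped to [0, 1]; clipping would
  break mean preservation and the decomposition identity.
- `required_sample_size` rounds to the nearest integer by default
  (`rounding="ceil"` available).
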