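# commflux

Community metabolic modelling for low-complexity anaerobic consortia:
abundance-weighted multi-species genome-scale models coupled through a
shared lumen, cooperative trade-off flux balance analysis (ctFBA) with
parsimonious environmental exchange and minimal-medium computation,
transcriptomics-constrained reaction bounds calibrated against measured
community growth, and cross-feeding network extraction. A synthetic-data
module generates every input the pipeline consumes with known ground truth.

## Modules

| module           | contents |
|------------------|----------|
| `gem_core`       | `MetabolicModel` / `Reaction` / `Metabolite` dataclasses, JSON + SBML (L3 core + fbc) readers/writers, validation, gene-product rule parsing and evaluation (AND = min, OR = sum) |
| `expression`     | count matrices, median-of-ratios size factors, nFPK, log transform, per-member count splitting, semi-log growth rates from OD, absolute abundance |
| `community`      | abundance-weighted community assembly (`memberId__` namespacing, shared lumen, environmental exchanges), medium application |
| `ctfba`          | stage 1 community growth LP, stage 2 minimum-norm member-growth allocation at trade-off fraction *f* (Wolfe's min-norm-point algorithm over LP oracles), stage 3 parsimonious environmental exchange, minimal medium, flux ranges |
| `integration`    | GPR-based reaction expression scores, bound scaling `w = β·min(1, (E/E_ref)^α)`, grid calibration of (f, α) by Pearson correlation against measured growth |
| `crossfeeding`   | per-member exchange tables (export-positive), producer→consumer edge extraction with proportional allocation, condition comparison, GraphML export |
| `pathways`       | Wood–Ljungdahl / reductive-glycine completeness scoring, marker-gene FPK activity, net ATP yield of acetate oxidation variants by FBA on a built-in stoichiometric network |
| `synthetic_data` | toy member archetypes, feeding scenarios with fixed carbon-mole totals, negative-binomial count and OD simulators, the seeded calibration benchmark |

## CLI

```bash
commflux benchmark --seed 1 --out-dir bench/     # synthetic dataset + manifest
commflux validate bench/methanogen.json          # model validation report
commflux solve bench/config.yaml --out-dir out/  # ctFBA + cross-feeding outputs
commflux rg-yield canonical                      # net ATP per acetate
```

`solve` reads a YAML config with `members` (model path + abundance),
`medium` (metabolite → max uptake), optional `bound_overrides`
(reaction → [lb, ub]) and the trade-off fraction `f`; it writes fluxes,
a growth summary, the minimal medium, exchange tables, and the
cross-feeding network (TSV + GraphML).

## Conventions

- Exchange fluxes: negative = uptake, positive = release, everywhere.
- Member fluxes are per gDW of that member; lumen balances weight member
  exchanges by relative abundance, so `Σᵢ aᵢ·(member exchange) +
  environmental exchange = 0` row-wise.
- Reported fluxes below τ = 1e-6 are rounded to zero; the solver never is.
- Glycine-reductase directionality depends on thioredoxin reduction that
  is not modelled; the ATP-yield network treats thioredoxin as a free sink.
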