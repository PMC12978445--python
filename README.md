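# ideorice

In-silico rice ideotype design: a surrogate process-based growth simulator
exposing 11 cultivar coefficients, Morris elementary-effects screening with a
relative sensitivity index (RSI), a genetic-algorithm optimizer maximizing a
harvest-index + normalized water-use-efficiency fitness, and a multi-metric
similarity layer that ranks field cultivars against the optimized ideotypes.
Synthetic weather/soil/panel generators make every stage runnable with no
external data.

## Layout

| Module | Role |
| --- | --- |
| `ideorice.crop_model` | Daily-loop growth surrogate: GDD phenology with photoperiod modulation, phyllochron-driven canopy, tillering, bucket water balance, heat/cold sterility, source-limited grain filling. |
| `ideorice.sensitivity` | Morris trajectories, elementary effects, pooled-max RSI, replicated screening with t-based 95% CIs, target selection. |
| `ideorice.optimizer` | GA (roulette selection, arithmetic crossover, adaptive single-gene mutation, elitism) over the 8 selected coefficients; HI+WUEnorm fitness. |
| `ideorice.similarity` | Min-max scaled Euclidean/Manhattan/cosine distances, normalized-average similarity index, top-k frequency consensus, PCA validation. |
| `ideorice.synthetic_data` | Climate/soil archetypes, weather generator, Saxton-Rawls pedotransfer, cultivar panels, the four-environment set, Tetens VPD. |
| `ideorice.pipeline` / `ideorice.cli` | End-to-end orchestration with serialized artifacts, manifest, and a `click` CLI. |
| `ideorice.io` | DSSAT-style `.WTH` dialect, weather CSV, soil CSV/JSON. |

## CLI

```bash
ideorice generate-data --outdir synthetic --seed 1     # weather/.WTH, soils, panel
ideorice simulate --weather synthetic/south.wth --soil synthetic/soil_env1.csv
ideorice sensitivity --weather synthetic/south.wth --soil synthetic/soil_env1.csv --out rsi.csv
ideorice optimize --weather synthetic/south.wth --soil synthetic/soil_env1.csv --seed 1
ideorice similarity --ideotypes ideotypes.csv --panel synthetic/panel.csv
ideorice run-all --seed 7 --outdir bundle              # full three-layer pipeline
```

Exit codes: 0 success, 1 input error, 2 stage failure. `run-all` accepts a
flat YAML config (`ideorice run-all --config config.yaml`); see
`ideorice.pipeline.PipelineConfig` for the keys.

Cultivar panels are CSV with header
`name,group,P1,P5,P2R,PHINT,P2O,G1,G2,G3`.

## Notes

- All surrogate constants (base temperature, radiation-use efficiency,
  phase spans, stress ramps, partition fractions) live in
  `ideorice.crop_model.SimulatorConfig` with documented defaults.
- Every stochastic component takes an explicit seed; identical seeds give
  bit-identical results (simulations, screenings, GA runs, generators,
  pipeline bundles).
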