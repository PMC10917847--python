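# adexmf

Simulation and analysis toolkit for a multi-area brain model built from
coupled AdEx mean-field regions. Each of the (typically 68) regions follows
the second-order mean-field description of an excitatory/inhibitory
adaptive-exponential-integrate-and-fire network — seven state variables per
region: two population rates, three rate covariances and two adaptation
currents. Regions interact through delayed excitatory coupling weighted by a
structural connectome and are driven by per-region Ornstein–Uhlenbeck noise;
the joint system is integrated with a stochastic Heun scheme.

The package covers the full exploration pipeline:

- **`adexmf.connectome`** — synthetic structural connectomes (log-normal
  weights, geometric tract lengths) plus plain-text bundle I/O
  (`weights.txt` / `tract_lengths.txt` / `centres.txt`, directory or zip).
- **`adexmf.meanfield`** — membrane-moment formulas, erfc-form population
  transfer functions (coefficients shipped as data, overridable), the
  seven-equation drift, and fixed-point location/classification (Down, Up
  and the pathological ~190 Hz point).
- **`adexmf.network`** — delayed coupling, OU drive, stochastic Heun
  integration, rate/covariance guards, reproducible seeding.
- **`adexmf.features`** — paroxysm detection (175 Hz rule), rate statistics,
  Up-state durations, node-averaged spectral peak, functional connectivity
  and its correlation with the structural matrix.
- **`adexmf.sweep`** — the constrained five-parameter grid (16 values per
  parameter, strict `E_L_i < E_L_e + 4 mV` admissibility; 675,840
  combinations at defaults), checkpointed parallel execution, and the
  paroxysm census over (S, E_L_i, E_L_e).
- **`adexmf.traces`** — adaptation-indexed feature traces (42,240 per
  feature on the default grid) and their K-means classification.

## CLI

```bash
adexmf make-connectome 68 --seed 7 --out conn/
adexmf simulate --synthetic 68 --duration 5000 --transient 2000 \
    --be 0 --ele -64 --eli -64 --t-scale 19 --s 0.3 --seed 1 --out run.h5
adexmf features --in run.h5 --synthetic 68 --out features.csv
adexmf sweep --config sweep.yaml --workers 4 --checkpoint ckpt/ --out results.csv
adexmf classify --results results.csv --feature corrFCSC --k 6 --seed 0 --out classes.json
```

A minimal `sweep.yaml`:

```yaml
n_values: 4
synthetic_regions: 16
master_seed: 0
simulation:
  duration: 1500
  transient: 500
```

## Conventions worth knowing

- Rates are Hz, times ms, potentials mV, currents pA at every public
  interface (SI internally).
- `simulate` discards the first `transient` ms; a 5 s run at dt = 0.1 ms
  executes 5×10⁴ steps and returns 30,000 post-transient samples.
- A run whose excitatory rate exceeds 175 Hz anywhere is flagged paroxysmal
  — that is data, not an error.
- The default initial condition is the self-consistent quasi-stationary
  state of the coupled system (with a small per-node spread); pass
  `initial_state=` for explicit control.
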