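# bicnn

A bi-hemispheric cerebellar neuronal network controller, exercised in closed
loop against a simulated two-wheel inverted-pendulum robot.

Each hemisphere is a spatially wired rate-coded microcircuit (4694 node
models: mossy-fiber glomeruli, granule, Golgi, basket/stellate and Purkinje
cells; ~110,300 synapses) built inside a 100 um cube of tissue with a
nearest-neighbour rule under fixed per-class convergence ratios, and encoded
in a four-vector address-event representation (ID, N_P, P, W).  A
directional climbing-fiber pair carries the signed wheel tracking error on
top of a spontaneous rate (0.05); it gates LTD/LTP at the parallel-fiber to
Purkinje synapses, while a second plastic site adapts the Purkinje to
vestibular-nucleus weights.  The vestibular nucleus subtracts the
bi-hemispheric output from a Ziegler-Nichols-tuned PD controller to form the
motor command.  Scenarios add a 50% body-mass load (centered or off-center
front/back), or tilt the platform by +/-10 degrees, at cycle 50 of a
100-cycle sinusoidal tracking task; performance is reported as per-cycle
root-mean-square error split into forward and backward motion.

## Layout

| module | contents |
| --- | --- |
| `bicnn.microcircuit` | placement, nearest-neighbour wiring, weight init, AER codec, validation, persistence |
| `bicnn.dynamics` | mossy encoding, climbing-fiber pair, hemisphere rate update, both plasticity rules |
| `bicnn.control` | PD pathway, vestibular-nucleus combination, Ziegler-Nichols tuning |
| `bicnn.plant` | wheeled inverted-pendulum rigid-body simulator with perturbations |
| `bicnn.runner` | closed-loop scenario orchestration, trial logs, repeats |
| `bicnn.metrics` | directional RSE, repeat summaries, cycle overlays |
| `bicnn.config` / `bicnn.cli` | YAML configuration and the `bicnn` command |

## CLI

```sh
# closed-loop experiment: 6 repeats, logs + per-cycle directional RSE CSVs
bicnn run --scenario load_center --cycles 100 --repeats 6 --seed 1 --out out/

# figure from a finished run directory
bicnn report --in out/

# build one hemisphere and export the AER container + JSON sidecar
bicnn build-net --seed 1 --export net.npz
```

Scenarios: `baseline`, `load_center`, `load_front`, `load_back`, `incline`,
`decline`, `cf_no_spont`, `cf_one_sided`, `cf_asymmetric`.  Controllers:
`bicnn`, `uni_cnn` (single-hemisphere ablation), `pd_only`.  A YAML file
passed via `--config` overrides any default; see `bicnn.config` for the
schema.

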