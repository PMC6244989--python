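# loopsearch

Simulator for the centred-loop "systematic search" movement pattern: a point
moves in fixed-length integration steps whose direction, measured against the
home vector (the vector to the origin), turns by a constant increment each
step. A backward factor straightens and speeds the inbound legs so every loop
curves back through the origin; block-wise Gaussian perturbations with a sine
envelope add the variability seen in real searches. The package also ships
the trajectory analytics used to characterise such searches: distance-to-
origin series, 5-step smoothing, and loop segmentation at origin-return
events.

## Library

```python
import loopsearch as ls

params, _ = ls.load_preset("run5", seed=42)        # published parameter sets
traj = ls.simulate_perturbed(params)               # stochastic run
summary = ls.segment_loops(ls.distance_series(traj))
print(summary.n_loops, summary.loop_maxima[:5])

# deterministic dynamics + independent polar-frame oracle
quiet = ls.simulate_noiseless(params.replace(f=0.0))
oracle = ls.simulate_noiseless_polar(params.replace(f=0.0))

# widening search: ramp the turn increment and backward factor
traj7 = ls.simulate_scheduled(
    ls.ModelParams(b=0.08, f=0.0),
    [ls.ParamSchedule("beta", 3.0, 1.8), ls.ParamSchedule("b", 0.08, -0.03)],
)
```

Model parameters (`ModelParams`): initial angle `alpha`, per-step turn
increment `beta` (degrees), step length `s`, backward factor `b < 1`,
perturbation factor `f`, block length `n`, initial position `(x0, y0)`
(never the origin), `n_steps`, `seed`, and `perturbation_mode`
(`transient`, default, evaluates the step geometry at the perturbed
position while keeping the accumulated state noiseless; `persistent` folds
the offset into the state).

Presets: `run2` … `run10` (the nine published simulation parameter sets),
`fig1-top|mid|bottom` (backward-factor sweep b = 0.2/0.02/0),
`fig2-top|mid|bottom` (perturbation sweep f = 0.1/0.04/0.02),
`fig3-top|mid|bottom` (step-length sweep s = 0.12/0.07/0.04), each with a
`-noiseless` variant, and the scheduled `fig7-left` / `fig7-right`.

## CLI

```bash
loopsearch simulate --preset run2 --seed 42 --out traj.csv
loopsearch simulate --alpha 10 --beta 3 --s 0.12 --b 0.2 --f 0.1 --out traj.csv
loopsearch simulate --config run.yaml --out traj.csv
loopsearch sweep --param s --values 0.12,0.07,0.04 --seed 7 --out-dir sweeps/
loopsearch analyze traj.csv --threshold 0.2 --out loops.csv
loopsearch plot traj.csv --out figure.png
```

Trajectory CSVs have columns
`step,x,y,x_pert,y_pert,gamma_deg,r,r_pert` at full precision (write→read is
bit-exact); the `_pert` columns equal the raw ones when `f = 0`. YAML configs
use the flat keys `alpha, beta, s, b, f, n, x0, y0, n_steps, seed,
perturbation_mode` plus an optional `schedules:` list of
`{param, start, end}` ramps.

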