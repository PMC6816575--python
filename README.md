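# dyadsync

Coupled-oscillator modelling of dyadic sensorimotor synchronization.

When two people tap a rhythm together they settle into distinct
*synchronization strategies* — mutual adaptation, leading–following, or
leading–leading — which are invisible to plain synchronization measures but
show up in the lagged cross-correlations of their intertap intervals (ITIs).
`dyadsync` implements a four-oscillator Kuramoto model of this interaction:
each person ("unit") is a pair of phase oscillators standing for perception
and action, coupled within the unit with weight *i* (intrapersonal
action–perception coupling) and across units with weight *e* (hearing the
partner's taps). The package provides

- a stochastic simulator for the model (and a reduced one-oscillator-per-unit
  control variant),
- tap-event extraction, ITI statistics, lag-correlation patterns and a
  phase-locking index,
- complete-linkage clustering of lag patterns with a similarity-profile
  (SIMPROF) permutation test for the number of genuinely distinct patterns,
- a two-step simulation-based grid search that fits coupling weights to a
  target lag pattern, scored with Bhattacharyya distribution overlap,
- synthetic targets and tap logs emulating empirical tapping data, and a CLI.

## Model

The phase θ<sub>n</sub> of oscillator *n* follows

dθ<sub>n</sub>/dt = ω<sub>n</sub> + Σ<sub>p</sub> K<sub>np</sub> sin(θ<sub>p</sub> − θ<sub>n</sub>) + ξ(t)

with intrinsic frequencies ω<sub>n</sub> ~ N(2 Hz, 0.2 Hz) (in rad/s), Gaussian
phase noise ξ calibrated to empirical ITI variability (0.2513 rad or
0.4335 rad per 500 ms tap interval), and the coupling matrix

```
          sender ->   P1   A1   A2   P2
receiver  P1        [  0   i1   e1   0 ]
          A1        [ i1    0    0   0 ]
          A2        [  0    0    0  i2 ]
          P2        [  0   e2   i2   0 ]
```

(P = perception, A = action; weights in 1/s). Taps are emitted where an
action oscillator's unwrapped phase crosses multiples of 2π; the strategy
of a simulated dyad is read off the Pearson correlations of the two units'
ITI series at lags −1, 0, +1.

## Worked example

```python
import numpy as np
from dyadsync import ModelSpec, SimulationConfig, run_condition

# asymmetric units (unit 1: weak within-unit coupling; unit 2: balanced):
# a forced leading-following dyad
spec = ModelSpec("four_osc", i1=1.7, e1=5.5, i2=4.1, e2=5.5)
config = SimulationConfig(dt=0.01, sample_interval=0.01, noise_sd=0.4335, seed=1)
cond = run_condition(spec, config, n_trials=200)
print(np.round(cond.mean_pattern.as_array(), 3), round(cond.mean_sync, 3))
```

prints

```
[0.026 0.094 0.241] 0.935
```

The mean lag pattern has a dominant positive lag +1 correlation
(unit 2's intervals echo unit 1's previous interval) with a much weaker
lag −1 — the leading-following signature — and the two action oscillators
are strongly but not perfectly phase-locked (synchronization index 0.94).

The same pipeline is available from the shell:

```bash
dyadsync simulate --config examples/simulate.yaml --seed 1 --outdir out/
dyadsync cluster  --config examples/cluster.yaml  --seed 1 --outdir out/
dyadsync fit      --config examples/fit.yaml      --seed 1 --outdir out/
```

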