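# imustate

Unsupervised behavioral-state classification for seabird biologging data.
`imustate` turns raw tri-axial accelerometer + magnetometer (IMU) records
into time series of three major movement modes — **flapping flight**,
**soaring flight** and **on-water** behavior — using a hidden Markov model
with Weibull state-dependent distributions. It is aimed at movement
ecologists working with high-resolution tag deployments on albatrosses and
similar dynamic-soaring seabirds, where the three modes differ sharply in
wingbeat signature, postural loading and heading dynamics.

## What it does

1. **Preprocessing** — decimation to 25 Hz, tag-mount roll-offset
   correction from resting-on-water segments, magnetometer trimming and
   median filtering, data-driven hard/soft-iron ellipsoid calibration with
   attitude-aided refinement, and tilt-compensated heading.
2. **Features** — eight candidate summaries per fixed 30-s window,
   including the highest dominant heave frequency `hf` (FFT), the
   top-fifth-percentile static heave `p5`, mean ODBA `mo`, and the
   circular standard deviation of heading `sh`; plus a correlation-based
   feature screen.
3. **Model** — an N-state HMM observing one feature vector per window.
   Given state *i*, each feature *f* is Weibull:

   ```
   x_tf | s_t = i  ~  Weibull(k_if, lambda_if)
   ```

   Transitions follow a multinomial logit with the diagonal as reference,
   `gamma_ij(c) = exp(eta_ij(c)) / sum_j exp(eta_ij(c))`, where a
   categorical covariate *c* (e.g. species) shifts the off-diagonal
   logits. Fitting maximizes the scaled forward likelihood from 25 random
   restarts (exact forward-backward gradients, L-BFGS-B); decoding is
   Viterbi; model comparison is AIC; diagnostics are forecast
   pseudo-residuals.
4. **Evaluation** — validation-window sampling, confusion matrices with
   exact (Clopper-Pearson) binomial confidence intervals, per-group
   accuracy, bout extraction and time-activity budgets.
5. **Synthetic deployments** — a seeded generator renders ground-truth
   labeled raw IMU streams for all three regimes (wingbeat oscillations
   near 2.6 Hz, banked dynamic-soaring arcs, on-water swell), including
   magnetometer distortion and mount tilt, so the entire pipeline is
   testable without any field data.

See `docs/methods.md` for the model details and numerical choices.

## Worked example

Simulate four birds (200 windows each), run the full chain and score the
decoding against the generator's truth:

```python
import numpy as np
from imustate import GeneratorConfig, RunConfig, confusion
from imustate.cli import run_benchmark

out = run_benchmark(
    11,
    GeneratorConfig(seed=11, n_individuals=4, windows_per_individual=200),
    RunConfig(trim_start_s=0.0, seed=11, n_restarts=8),
)
merged = out["decoded"].merge(out["truth"], on=["individual_id", "window_index"])
print(confusion(merged["true_state"], merged["behavior_label"]).report())

fit = out["fit"]
inv = {v: k for k, v in out["mapping"].items()}
order = [inv["flap"], inv["soar"], inv["water"]]
print(fit.params.transition.gamma("A")[np.ix_(order, order)].round(3))
```

which prints

```
n = 800
overall accuracy: 100.0% (99.5, 100.0)
column % (rows = assigned, cols = true):
        flap   soar  water
flap   100.0    0.0    0.0
soar     0.0  100.0    0.0
water    0.0    0.0  100.0
[[0.806 0.159 0.035]
 [0.1   0.873 0.027]
 [0.03  0.019 0.951]]
```

All 800 windows are decoded correctly (the exact binomial interval on
100% accuracy at n = 800 still spans down to 99.5%), and the fitted
transition matrix — rows: state at *t*, columns: state at *t+1*, relabeled
to flap/soar/water — recovers the persistent on-water state (0.951
self-transition) and the flap-to-soar switching structure the generator
used. At this small size the matrix carries visible sampling noise; the
parameter-recovery test at 10,000 windows pins every entry within 0.02.

The same chain is available from the shell:

```bash
imustate run-all --seed 1 --out results/demo --n-individuals 4 --windows 200 \
    --config myconfig.yaml
```

with `simulate | features | fit | decode | evaluate | budget` as individual
subcommands over delimited text artifacts.

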