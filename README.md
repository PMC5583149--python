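# dnfip — dynamic neural fields with intrinsic plasticity

Dynamic neural fields (DNFs) model the activity of a recurrently
connected neural population as a continuous activation function `u(x, t)`
over a feature dimension, with winner-take-all lateral coupling and a
sigmoid output. They are a standard building block for perceptual
decision making in cognitive and robotic architectures — but their
resting level and sigmoid slope must normally be hand-tuned to the input
distribution, and retuned whenever that distribution drifts.

`dnfip` removes that tuning step: it couples a 1-D DNF,

    tau u̇(x,t) = −u(x,t) + S(x,t) + Σ_x' ω(x−x') g_{a,b}(u(x',t)),
    g_{a,b}(u) = 1 / (1 + e^{−(a·u + b)}),

to an **intrinsic-plasticity (IP)** homeostat that adapts the global
gain `a` and bias `b` online so that the field's scalar output measure
`y(t) = max_x g(u)` matches an exponential target distribution with
mean `μ` (sparse detections: silent most of the time, confident peaks
occasionally). The learning rules are the KL-divergence gradient for
the logistic transfer,

    Δb = η (1 − (2 + 1/μ) y + y²/μ),      Δa = η/a + z·Δb,

with `z(t)` the field activation at the output maximum, applied once per
input sample — optionally preconditioned by an online-estimated,
Tikhonov-regularized Fisher metric (**natural gradient**), which makes
re-adaptation after sudden input changes roughly an order of magnitude
faster at the same learning rate.

The package ships the field simulator, both IP variants, a synthetic
population-coded tactile input stream (0–2 contacts per frame at
opposing orientations, circularity-scaled Gaussian bumps over a periodic
0–360° dimension), the evaluation statistics (sliding-window output
histograms, windowed input–output correlation, convergence monitoring),
experiment protocols for distribution shifts (`÷6`, `×6`, `−12`), a thin
CLI, and narrative examples.

## Worked example

```python
from dnfip import ExperimentConfig, run_experiment

record = run_experiment(
    ExperimentConfig(variant="mean_sweep", mu=0.2, seed=1, duration=1800.0)
)
s = record.summary
print(s["final_a"], s["final_b"], s["mean_y_final_window"])
```

Running `python examples/03_ip_adaptation.py` (the same computation with
commentary) prints:

```
adaptation trajectory (5-minute blocks):
  min  0- 5:  a = 1.068   b = -3.909   mean y = 0.162
  min  5-10:  a = 0.898   b = -3.212   mean y = 0.184
  ...
  min 25-30:  a = 0.871   b = -3.120   mean y = 0.188

converged: a = 0.872, b = -3.121 (resting level h = b/a = -3.58)
sliding mean of y over the final 5 min: 0.187 (configured target mean: 0.2)
input-output correlation (final 5 min): 0.93
KLD of the final y distribution vs the exponential target: 0.180 nats
```

Starting from `(a, b) = (1, −5)` the homeostat settles within a few
simulated minutes; the sliding mean of the output measure lands at the
configured target mean (0.187 vs 0.2), the bias has found the detection
threshold appropriate for the [0, 6] input range, and the output tracks
the input (correlation 0.93) while its distribution approximates the
exponential target.

The other examples show the underlying field dynamics and hysteresis
(`01`), the synthetic input stream (`02`), re-adaptation after the input
is scaled down sixfold (`04`), and the natural-vs-plain-gradient
comparison under a −12 mean shift (`05`).

## Command line

```bash
dnfip generate-input --duration 300 --seed 1 --out stream.csv
dnfip run --variant low_amplitude --seed 1 --outdir out/
dnfip compare-gradients --seed 1 --outdir out/ng_vs_plain/
dnfip plot --series out/series.csv --out overview.png
```

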