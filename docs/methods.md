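# Methods

## Model

`dnfip` simulates a one-dimensional dynamic neural field (DNF): a
mean-field description of a homogeneous, recurrently connected neural
population whose activation `u(x, t)` is spanned over a periodic feature
dimension — here the orientation of a tactile contact, 0–360°, sampled
at `n_sites` points. The dynamics are

    tau * du/dt = -u(x, t) + S(x, t) + sum_x' omega(x - x') * g_{a,b}(u(x', t))

with an explicit-Euler integrator (`dt` ≤ `tau`). The interaction kernel

    omega(d) = c_exc * exp(-d^2 / (2 sigma_exc^2)) - c_inh * exp(-d^2 / (2 sigma_inh^2))

is excitatory at short range and inhibitory at long range
(`sigma_inh > sigma_exc`), the winner-take-all coupling that lets a
localized input ignite a self-stabilized activity peak (detection
instability) and keeps it alive below the detection amplitude
(hysteresis; reverse detection instability).

The transfer function is a parametric logistic,

    g_{a,b}(u) = 1 / (1 + exp(-(a*u + b))),

with global gain `a > 0` and bias `b`. The bias encodes a gain-dependent
resting level `h = b/a`; there is no separate resting-level term in the
dynamics. With `b < 0` the field is effectively silent below the
detection threshold `u = -b/a`. Distances and kernel widths are measured
in grid-index units; the feature dimension is periodic (a zero-padded
non-periodic mode exists for non-circular features). The convolution is
a plain discrete sum over sites. Argmax ties break to the lowest site
index; the logistic is evaluated in the overflow-safe branch form;
activations are checked finite at every step.

### Scalar measures

The whole-field summary read by the adaptation is

    y(t) = max_x g_{a,b}(u(x, t))        (output measure, in (0, 1))
    z(t) = u(argmax_x g_{a,b}(u), t)     (input measure, activation units)

`y` is the field's "confidence of a detection somewhere"; `z` is the
drive (stimulus plus recurrent feedback) at that location. Because the
logistic is strictly increasing, `z = max(u)`.

## Intrinsic plasticity

The homeostatic goal is that the distribution of `y` over time matches
an exponential target with mean `mu` (mostly-silent output with
occasional detections; the maximum-entropy distribution for a fixed
positive mean). Gradient descent on the Kullback–Leibler divergence
between the output distribution and the target gives, for the logistic
transfer, the per-sample rules

    delta_b = eta * (1 - (2 + 1/mu) * y + y^2 / mu)
    delta_a = eta / a + z * delta_b

The bias quadratic has roots at y ≈ 0.16 and 1.24 for `mu = 0.2`: the
bias rises while output is low, falls while output is high, which drives
the field toward — and repeatedly through — the detection instability.
The gain is clamped below at 1e-6 so the `eta/a` term stays finite and
the transfer remains orientation-preserving.

**Update cadence.** One unit update is applied per input frame (one
per sample, the canonical cadence of per-sample intrinsic plasticity; at
3.33 fps this is 3.33 updates per simulated second). A per-step cadence
that spreads the same update over the frame's Euler steps is available;
it changes the micro-structure of the trajectory, not the effective
learning speed.

**Natural gradient.** The preconditioned variant keeps an online
estimate of the Fisher metric as an exponential moving average of
per-sample gradient outer products,

    F <- (1 - lam) * F + lam * grad grad^T,     grad = -(delta_a, delta_b),

and updates `theta = (a, b)` by `-eta * (F + eps I)^{-1} grad` with the
2×2 tensor inverted exactly (`eps = 1e-4` Tikhonov regularization,
`lam = 0.01`, i.e. a memory of ~100 samples). Note that `grad` carries
the learning-rate factor: when the Fisher estimate is small the natural
step approaches `(eta^2 / eps) * gradient`, a tenfold amplification of
the plain step at the defaults. This is the property that makes the
natural-gradient learner restore the output regime several times faster
than the plain learner after a mean shift of the input, while the moving
average damps the large, consistent gradients that would otherwise crash
the gain ("input variance overestimation"). Plain and natural updates
share fixed points: a vanishing Euclidean gradient moves neither.

### Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `tau` | 0.1 s | field time constant |
| `dt` | 0.01 s | Euler step |
| `n_sites` | 100 | grid resolution over 360° |
| `c_exc, sigma_exc` | 14, 2 sites | excitatory lobe (strength, width) |
| `c_inh, sigma_inh` | 7, 6 sites | inhibitory lobe (positive magnitude) |
| `lateral_scale` | 1/(c_exc−c_inh) = 1/7 | kernel normalization in the preset (below) |
| `a0, b0` | 1, −5 | initial gain/bias (resting level −5) |
| `eta` | 0.001 | learning rate per update |
| `mu` | 0.2 | target mean of the output measure |
| `lam` | 0.01 | Fisher low-pass coefficient |
| `eps` | 1e-4 | Tikhonov regularization |

### Kernel normalization in the preset

The simulator exposes a `lateral_scale` factor on the interaction
kernel (default 1.0: the raw discrete sum). The tactile preset sets it
to `1/(c_exc - c_inh)`, i.e. it normalizes the kernel to unit peak so
that the printed strengths set the kernel *shape* while the recurrent
drive stays on the scale of one output unit. The reason is quantitative:
with the raw amplitudes the recurrent drive inside a formed peak is
≈ 21.6 activation units against a detection threshold of 5, so *every*
peak is permanently self-sustaining, the output measure saturates at 1,
and the homeostat can only chase a runaway bias — no input tracking, no
convergence, no recovery experiments. With the unit-peak kernel the
formed peak's self-excitation (≈ 3.1) sits just below the initial
threshold: peaks are stabilized against input fluctuations but die when
their stimulus leaves, which is the operating regime in which gain/bias
homeostasis is meaningful. In this regime the converged parameters on
the synthetic stream land at `a ≈ 0.87, b ≈ -3.1` for `mu = 0.2` and
`b ≈ -3.9` for `mu = 0.1`, with detection thresholds inside the upper
part of the [0, 6] input range.

## Synthetic input stream

The generator emulates a two-fingered tactile exploration feeding a
population code over contact orientation:

- per (re)draw, 0/1/2 simultaneous contacts with probabilities
  (0.3, 0.4, 0.3); a second contact sits exactly 180° from the first
  (opposing fingers);
- each contact has a circularity in (0, 1) drawn from a Beta(2, 5)
  (right-skewed: highly circular contacts — flat surfaces — are a
  minority); the encoded bump has peak amplitude
  `amplitude_scale * circularity` (default scale 6 ⇒ amplitudes in
  [0, 6]) and Gaussian width `blur_sigma = 10.8°` (3 sites);
- overlapping bumps combine by element-wise maximum (respecting the
  encoding ceiling; `sum` is available);
- contact configurations persist for a geometric number of frames
  (mean 2) at 3.33 fps, giving the slowly varying stripe structure of a
  real exploration;
- a base block of 315 s is generated once from the seed and looped, like
  a looped recording; frames are presented with zero-order hold for
  `floor(frame_dt/dt)` = 30 Euler steps each.

Distribution shifts are applied as `S -> scale * S + offset` to all
frames from a switch time onward (`÷6`, `×6`, `−12` presets).

What the generator does **not** emulate: sensor physics, realistic
contact trajectories (orientations are drawn uniformly), or the
temporal/amplitude correlations of any particular recorded data set.
Consequently the input–output correlations in the converged regime
(~0.85–0.93) are higher than the ~0.67–0.69 a noisy recording produces,
and converged gains sit somewhat above the values reported for such
recordings, while converged biases match closely. Passing tests show
that the adaptation mechanism works and re-adapts as designed, not that
any particular hardware stream would yield identical statistics.

## Experiments and summaries

`run_experiment` covers five protocols: `mean_sweep` (stationary, 30
simulated minutes), `low_amplitude` (`÷6` at minute 20, to minute 50),
`high_amplitude` (`×6`), `offset_ng` (`−12`, natural gradient) and
`offset_plain` (`−12`, plain gradient, to minute 100). All summaries use
trailing 5-minute windows (one loop of the input block): sliding
histograms, windowed Pearson input–output correlation (undefined windows
are emitted as missing values, never as 0), trailing means of `a`, `b`,
`y`.

*Recovery time* after a switch is artifact-defined: the first time the
5-minute sliding mean of `y`, having left a ±25% band around its value
at the switch, re-enters that band (0 if it never leaves). *Convergence*
of `(a, b)` is declared at the earliest time after which both traces
stay within ±2% of their trailing-window means for a further full
window. The directional claim "a variance change is compensated mainly
by the gain" is checked as: the gain's relative change after `÷6`
exceeds twice the bias's relative change (measured ratio ≈ 4.4); a mean
shift is checked through the detection threshold `-b/a`, which follows
the −12 offset while the gain returns toward its pre-switch value.

Measured at the reference scale (seed 1): stationary sliding mean of `y`
0.187 for `mu = 0.2` and 0.094 for `mu = 0.1`; `÷6` recovery ≈ 6
simulated minutes; offset recovery 16 minutes with the natural gradient
versus 56 with the plain gradient.

## Numerical and design notes

- Euler stepping is exact enough at `dt = tau/10`; the relaxation error
  to a constant input contracts by exactly `1 - dt/tau` per step and is
  tested in closed form.
- The periodic convolution runs via FFT; an O(n²) double loop serves as
  the test oracle on small grids.
- The Fisher estimate is symmetric PSD by construction; the regularized
  tensor is inverted in closed form (2×2).
- The KLD diagnostic renormalizes the exponential target on (0, 1)
  (the logistic output cannot leave it) and is histogram-based; it is a
  monitor, not part of the learning rules.
- Snapshots (`.npz`: `u`, `t`, `a`, `b`, Fisher, frame index) resume a
  run bit-for-bit at frame boundaries.
- Runs are deterministic given (config, seed); all randomness lives in
  the input generator.

## Known limitations

- A single 1-D field; no multi-field architectures, no 2-D/3-D fields.
- The global gain couples stimulus and recurrence: compensating a
  variance change shifts the balance between input drive and lateral
  stabilization (visible as correlation changes after `÷6`/`×6`) — a
  property of the method, not an implementation artifact.
- Under near-zero input the homeostat has no fixed point: `(a, b)` rise
  until recurrence self-ignites, the output saturates, the parameters
  fall back, and the cycle repeats (on–off oscillation). This is
  demonstrated in the tests and is a documented boundary of the method.
- The `×6` up-scaling transiently drives the gain to its lower clamp
  before it settles near the rescaled optimum.
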