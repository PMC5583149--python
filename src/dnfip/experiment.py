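"""End-to-end experiment protocols.

Each variant presents a synthetic tactile stream to the reference field,
lets the IP adaptation converge, optionally perturbs the input
distribution at a switch time, and summarizes the run: converged
parameters, pre/post output statistics, and the recovery time of the
sliding output mean after the perturbation.

Variants
--------
mean_sweep      stationary stream, amplitudes [0, 6] (vary ``mu`` between runs)
low_amplitude   input scaled by 1/6 at the switch  ->  range [0, 1]
high_amplitude  input scaled by 6 at the switch    ->  range [0, 36]
offset_ng       input shifted by -12 at the switch ->  range [-12, -6], natural gradient
offset_plain    same shift, plain gradient, run twice as long
custom          whatever the config says

Times are simulated seconds throughout; "minutes" in summaries are
simulated minutes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import yaml

from .inputs import InputScenario, generate_series
from .metrics import convergence_monitor, sliding_mean
from .presets import get_preset
from .simulate import SimulationResult, simulate

__all__ = ["ExperimentConfig", "RunRecord", "run_experiment", "compare_gradients", "VARIANTS"]

#: variant name -> (scale_factor, offset, default duration s, default switch s)
VARIANTS: dict[str, tuple[float, float, float, float | None]] = {
    "mean_sweep": (1.0, 0.0, 1800.0, None),
    "low_amplitude": (1.0 / 6.0, 0.0, 3000.0, 1200.0),
    "high_amplitude": (6.0, 0.0, 3000.0, 1200.0),
    "offset_ng": (1.0, -12.0, 3000.0, 1200.0),
    "offset_plain": (1.0, -12.0, 6000.0, 1200.0),
    "custom": (1.0, 0.0, 1800.0, None),
}


@dataclass(frozen=True)
class ExperimentConfig:
    """Full description of one experiment run."""

    variant: str = "mean_sweep"
    preset: str = "tactile"
    mu: float = 0.2
    eta: float = 0.001
    use_natural_gradient: bool = True
    ip_enabled: bool = True
    seed: int = 0
    duration: float | None = None  # seconds; None -> variant default
    switch_time: float | None = None  # None -> variant default
    scale_factor: float | None = None
    offset: float | None = None
    amplitude_scale: float = 6.0
    window: float = 300.0  # sliding-window length for all summaries

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {sorted(VARIANTS)}")

    def resolve(self) -> "ExperimentConfig":
        """Fill in variant defaults for duration / switch / manipulation."""
        scale, offset, duration, switch = VARIANTS[self.variant]
        updates: dict = {}
        if self.duration is None:
            updates["duration"] = duration
        if self.switch_time is None and switch is not None:
            updates["switch_time"] = switch
        if self.scale_factor is None:
            updates["scale_factor"] = scale
        if self.offset is None:
            updates["offset"] = offset
        if self.variant == "offset_plain":
            updates["use_natural_gradient"] = False
        return replace(self, **updates) if updates else self

    def scenario(self) -> InputScenario:
        cfg = self.resolve()
        manipulated = cfg.switch_time is not None and (
            cfg.scale_factor != 1.0 or cfg.offset != 0.0
        )
        return InputScenario(
            duration=cfg.duration,
            amplitude_scale=cfg.amplitude_scale,
            scale_factor=cfg.scale_factor if manipulated else 1.0,
            offset=cfg.offset if manipulated else 0.0,
            switch_time=cfg.switch_time if manipulated else None,
            seed=cfg.seed,
        )

    # -- (de)serialization -------------------------------------------------

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


@dataclass
class RunRecord:
    """Everything one run produced."""

    config: ExperimentConfig
    result: SimulationResult
    summary: dict

    def series_frame(self):
        """Per-step trace with IP rates appended."""
        preset = get_preset(self.config.preset, mu=self.config.mu)
        return self.result.with_rates(replace(preset.ip, eta=self.config.eta))

    def write(self, outdir, stride: int = 10) -> None:
        """Write the trace (CSV, subsampled by ``stride``) and summary
        (JSON) under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        df = self.series_frame().iloc[::stride]
        df.to_csv(outdir / "series.csv", index=False)
        (outdir / "summary.json").write_text(json.dumps(self.summary, indent=2))
        self.config.to_yaml(outdir / "config.yaml")


def _recovery_time(
    times: np.ndarray, y: np.ndarray, switch_time: float, window: float, band: float = 0.25
) -> tuple[float | None, float]:
    """Recovery time of the trailing-window mean of y after a switch.

    The reference is the sliding mean at the switch itself (the converged
    pre-switch statistic).  Recovery is the first time, after the mean
    has left the ``+-band`` envelope around the reference, at which it
    re-enters it; 0 if it never leaves.  Returns (recovery_seconds or
    None, reference value).
    """
    m = sliding_mean(y, times, window)
    i_switch = int(np.searchsorted(times, switch_time, side="right")) - 1
    ref = float(m[i_switch])
    post = slice(i_switch + 1, None)
    inside = np.abs(m[post] - ref) <= band * abs(ref)
    if inside.all():
        return 0.0, ref
    first_out = int(np.argmin(inside))  # first False
    back_in = np.nonzero(inside[first_out:])[0]
    if back_in.size == 0:
        return None, ref
    idx = i_switch + 1 + first_out + int(back_in[0])
    return float(times[idx] - switch_time), ref


def run_experiment(config: ExperimentConfig) -> RunRecord:
    """Simulate one variant end to end and summarize it."""
    config = config.resolve()
    preset = get_preset(config.preset, mu=config.mu, use_natural_gradient=config.use_natural_gradient)
    ip_cfg = replace(preset.ip, eta=config.eta) if config.ip_enabled else None
    scenario = config.scenario()
    series = generate_series(scenario, preset.grid)
    result = simulate(
        series,
        preset.grid,
        preset.kernel,
        preset.initial_transfer(),
        preset.dynamics,
        ip_cfg,
        lateral_scale=preset.lateral_scale,
    )
    df = result.series
    times = df["t"].to_numpy()
    y = df["y"].to_numpy()
    a = df["a"].to_numpy()
    b = df["b"].to_numpy()
    w = config.window

    tail = times > times[-1] - w
    summary: dict = {
        "variant": config.variant,
        "mu": config.mu,
        "seed": config.seed,
        "duration_s": float(times[-1]),
        "final_a": float(sliding_mean(a, times, w)[-1]),
        "final_b": float(sliding_mean(b, times, w)[-1]),
        "mean_y_final_window": float(y[tail].mean()),
    }
    z_tail = df["z"].to_numpy()[tail]
    if np.std(z_tail) > 1e-9 and np.std(y[tail]) > 1e-9:
        summary["io_correlation_final_window"] = float(np.corrcoef(z_tail, y[tail])[0, 1])
    else:
        summary["io_correlation_final_window"] = None
    span = times[-1] - times[0]
    if span >= 2 * w:
        converged, t_conv = convergence_monitor(
            np.column_stack([a, b]), times, tolerance=0.02, horizon=w
        )
        summary["converged"] = bool(converged)
        summary["convergence_time_s"] = t_conv

    if config.switch_time is not None:
        t_sw = config.switch_time
        pre = (times > t_sw - w) & (times <= t_sw)
        post = times > t_sw
        recovery, ref = _recovery_time(times, y, t_sw, w)
        summary.update(
            {
                "switch_time_s": t_sw,
                "mean_y_pre_switch": float(y[pre].mean()),
                "sliding_mean_y_at_switch": ref,
                "recovery_time_s": recovery,
                "recovery_time_min": None if recovery is None else recovery / 60.0,
                "pre_switch_a": float(sliding_mean(a, times, w)[pre.nonzero()[0][-1]]),
                "pre_switch_b": float(sliding_mean(b, times, w)[pre.nonzero()[0][-1]]),
                "pre_switch_b_band": [float(b[pre].min()), float(b[pre].max())],
                "pre_switch_a_band": [float(a[pre].min()), float(a[pre].max())],
                "post_switch_min_a": float(a[post].min()),
                "post_switch_final_a": float(sliding_mean(a, times, w)[-1]),
            }
        )
    return RunRecord(config=config, result=result, summary=summary)


def compare_gradients(config: ExperimentConfig) -> dict:
    """Run the mean-shift experiment twice - natural gradient vs plain
    gradient - with identical seed and learning rate, and compare
    recovery speed and the transient gain collapse."""
    base = config.resolve()
    if base.offset == 0.0 and base.scale_factor == 1.0:
        raise ValueError("compare_gradients expects a manipulated (offset) variant")
    ng_cfg = replace(base, variant="offset_ng", use_natural_gradient=True, duration=base.duration)
    plain_cfg = replace(
        base,
        variant="offset_plain",
        use_natural_gradient=False,
        duration=VARIANTS["offset_plain"][2] if config.duration is None else base.duration * 2,
    ).resolve()
    ng = run_experiment(ng_cfg)
    plain = run_experiment(plain_cfg)
    comparison = {
        "ng_recovery_time_s": ng.summary["recovery_time_s"],
        "plain_recovery_time_s": plain.summary["recovery_time_s"],
        "ng_post_switch_min_a": ng.summary["post_switch_min_a"],
        "plain_post_switch_min_a": plain.summary["post_switch_min_a"],
        "ng_final_a": ng.summary["post_switch_final_a"],
        "plain_final_a": plain.summary["post_switch_final_a"],
        "ng_pre_switch_a": ng.summary["pre_switch_a"],
        "plain_pre_switch_a": plain.summary["pre_switch_a"],
    }
    return {"ng": ng, "plain": plain, "comparison": comparison}
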