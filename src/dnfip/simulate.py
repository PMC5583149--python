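"""Coupled integration of the field dynamics and the IP adaptation.

The input series is presented with zero-order hold: each frame is held
for ``floor(frame_dt / dt)`` Euler steps.  The scalar measures y and z
are read off the state after every Euler step; the IP adaptation applies
one unit update per input frame (the per-sample cadence of intrinsic
plasticity), or, with ``ip_cadence="step"``, spreads that same update
evenly over the frame's Euler steps.  The whole loop is deterministic
given the input series and initial state; randomness lives entirely in
the input generator.

``lateral_scale`` rescales the interaction kernel used by the loop; the
shipped preset normalizes the kernel to unit peak (see
:mod:`dnfip.presets`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .field import (
    DynamicsConfig,
    FieldDivergenceError,
    FieldGrid,
    FieldState,
    KernelParams,
    TransferParams,
    make_kernel,
    transfer,
)
from .inputs import InputSeries
from .ip import FisherState, IPConfig, bias_rate, euclidean_gradient, gain_rate, ip_step

__all__ = ["SimulationResult", "Simulator", "simulate"]


@dataclass
class SimulationResult:
    """Per-step traces and final state of one run."""

    series: pd.DataFrame  # columns: t, a, b, y, z
    state: FieldState
    tp: TransferParams
    fisher: FisherState

    def with_rates(self, ip_cfg: IPConfig) -> pd.DataFrame:
        """Series augmented with the instantaneous IP rates db_dt, da_dt."""
        df = self.series.copy()
        mu, eta = ip_cfg.mu, ip_cfg.eta
        y, z, a = df["y"].to_numpy(), df["z"].to_numpy(), df["a"].to_numpy()
        db = eta * (1.0 - (2.0 + 1.0 / mu) * y + y * y / mu)
        df["db_dt"] = db
        df["da_dt"] = eta / a + z * db
        return df


class Simulator:
    """Stepping engine holding the full mutable state of a run.

    Exists mainly so a run can be snapshotted and resumed bit-for-bit;
    :func:`simulate` is the one-shot convenience wrapper.
    """

    def __init__(
        self,
        grid: FieldGrid,
        kernel_params: KernelParams,
        tp: TransferParams,
        dynamics: DynamicsConfig = DynamicsConfig(),
        ip_cfg: IPConfig | None = None,
        ip_cadence: str = "frame",
        state: FieldState | None = None,
        fisher: FisherState | None = None,
        frame_index: int = 0,
        lateral_scale: float = 1.0,
    ) -> None:
        if ip_cadence not in ("step", "frame"):
            raise ValueError("ip_cadence must be 'step' or 'frame'")
        self.grid = grid
        self.kernel_params = kernel_params
        self.lateral_scale = lateral_scale
        self.kernel = lateral_scale * make_kernel(kernel_params, grid)
        self.tp = TransferParams(tp.a, tp.b)
        self.dynamics = dynamics
        self.ip_cfg = ip_cfg
        self.ip_cadence = ip_cadence
        self.state = state.copy() if state is not None else FieldState(np.zeros(grid.n_sites))
        self.fisher = fisher.copy() if fisher is not None else FisherState()
        self.frame_index = frame_index

    def run(self, series: InputSeries) -> SimulationResult:
        """Integrate over the remaining frames of ``series`` and record
        (t, a, b, y, z) at every Euler step."""
        dyn = self.dynamics
        dt, tau = dyn.dt, dyn.tau
        steps_per_frame = int(series.frame_dt / dt)
        if steps_per_frame < 1:
            raise ValueError("frame_dt must cover at least one Euler step")
        n = self.grid.n_sites
        periodic = self.grid.periodic
        if periodic:
            kernel_fft = np.fft.fft(self.kernel)
        else:
            from .field import lateral_input as _lateral

        frames = series.frames
        start_frame = self.frame_index
        n_frames = frames.shape[0] - start_frame
        total_steps = n_frames * steps_per_frame
        rec = np.empty((total_steps, 5))

        u = self.state.u.copy()
        t = self.state.t
        a, b = self.tp.a, self.tp.b
        fisher = self.fisher.f.copy()
        cfg = self.ip_cfg
        use_ip = cfg is not None
        per_frame = self.ip_cadence == "frame"
        if use_ip:
            eta, mu, lam, eps = cfg.eta, cfg.mu, cfg.lam, cfg.eps
            use_ng = cfg.use_natural_gradient
            # one unit update per input sample (frame); the per-step
            # cadence spreads the same update over the frame's Euler steps
            ip_dt = 1.0 if per_frame else 1.0 / steps_per_frame
        alpha = dt / tau

        i = 0
        for f in range(start_frame, frames.shape[0]):
            S = frames[f]
            for s in range(steps_per_frame):
                g = expit(a * u + b)
                if periodic:
                    drive = np.real(np.fft.ifft(kernel_fft * np.fft.fft(g)))
                else:
                    drive = _lateral(g, self.kernel, self.grid)
                u = u + alpha * (-u + S + drive)
                t += dt
                if not np.all(np.isfinite(u)):
                    raise FieldDivergenceError(
                        f"non-finite activation at step {i} (t={t:.4f} s, frame {f})"
                    )
                k = int(np.argmax(u))  # transfer is monotone: argmax g = argmax u
                z = float(u[k])
                y = float(expit(a * z + b))
                rec[i] = (t, a, b, y, z)
                i += 1
                if use_ip and (not per_frame or s == steps_per_frame - 1):
                    rb = 1.0 - (2.0 + 1.0 / mu) * y + y * y / mu
                    if use_ng:
                        # eta-scaled per-sample gradient (the negated plain
                        # update vector) feeds the Fisher estimate
                        g0 = -eta * (1.0 / a + z * rb)
                        g1 = -eta * rb
                        one_m = 1.0 - lam
                        fisher[0, 0] = one_m * fisher[0, 0] + lam * g0 * g0
                        fisher[0, 1] = one_m * fisher[0, 1] + lam * g0 * g1
                        fisher[1, 0] = fisher[0, 1]
                        fisher[1, 1] = one_m * fisher[1, 1] + lam * g1 * g1
                        m00 = fisher[0, 0] + eps
                        m11 = fisher[1, 1] + eps
                        m01 = fisher[0, 1]
                        det = m00 * m11 - m01 * m01
                        a = a - eta * ip_dt * (m11 * g0 - m01 * g1) / det
                        b = b - eta * ip_dt * (-m01 * g0 + m00 * g1) / det
                    else:
                        db = eta * rb
                        a = a + ip_dt * (eta / a + z * db)
                        b = b + ip_dt * db
                    if a < 1e-6:
                        a = 1e-6
        self.frame_index = frames.shape[0]
        self.state = FieldState(u, t)
        self.tp = TransferParams(a, b)
        self.fisher = FisherState(fisher)
        df = pd.DataFrame(rec[:i], columns=["t", "a", "b", "y", "z"])
        return SimulationResult(df, self.state, self.tp, self.fisher)

    # -- snapshot / resume ------------------------------------------------

    def save_snapshot(self, path) -> None:
        """Self-describing binary snapshot (NumPy .npz) of the full run
        state: field activation, clock, transfer params, Fisher tensor and
        input-frame position."""
        np.savez(
            path,
            u=self.state.u,
            t=np.array(self.state.t),
            a=np.array(self.tp.a),
            b=np.array(self.tp.b),
            fisher=self.fisher.f,
            frame_index=np.array(self.frame_index),
        )

    @classmethod
    def from_snapshot(
        cls,
        path,
        grid: FieldGrid,
        kernel_params: KernelParams,
        dynamics: DynamicsConfig = DynamicsConfig(),
        ip_cfg: IPConfig | None = None,
        ip_cadence: str = "frame",
        lateral_scale: float = 1.0,
    ) -> "Simulator":
        with np.load(path) as snap:
            return cls(
                grid,
                kernel_params,
                TransferParams(float(snap["a"]), float(snap["b"])),
                dynamics,
                ip_cfg,
                ip_cadence,
                state=FieldState(snap["u"].copy(), float(snap["t"])),
                fisher=FisherState(snap["fisher"].copy()),
                frame_index=int(snap["frame_index"]),
                lateral_scale=lateral_scale,
            )


def simulate(
    series: InputSeries,
    grid: FieldGrid,
    kernel_params: KernelParams,
    tp: TransferParams,
    dynamics: DynamicsConfig = DynamicsConfig(),
    ip_cfg: IPConfig | None = None,
    ip_cadence: str = "frame",
    initial_state: FieldState | None = None,
    lateral_scale: float = 1.0,
) -> SimulationResult:
    """One-shot run over a full input series (IP disabled if ``ip_cfg`` is
    None).  See :class:`Simulator` for resumable runs."""
    sim = Simulator(
        grid,
        kernel_params,
        tp,
        dynamics,
        ip_cfg,
        ip_cadence,
        state=initial_state,
        lateral_scale=lateral_scale,
    )
    return sim.run(series)
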