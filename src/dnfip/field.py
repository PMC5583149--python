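"""Discretized one-dimensional dynamic neural field (DNF).

A DNF is a mean-field model of a homogeneous, recurrently connected neural
population.  Activation ``u(x, t)`` is spanned over a periodic feature
dimension (here: contact orientation, 0-360 degrees) and evolves under

    tau * du/dt = -u + S(x, t) + (omega * g(u))(x)

where ``S`` is external input, ``omega`` a Mexican-hat interaction kernel
(short-range excitation, long-range inhibition) and ``g`` a parametric
logistic transfer function ``g_{a,b}(u) = 1 / (1 + exp(-(a*u + b)))``.
The static resting level of the classical formulation is absorbed into the
bias via ``b = a * h``, so no explicit ``h`` term appears in the dynamics;
thresholding happens entirely inside the transfer function.

Scalar summary measures of the whole field are the output measure
``y(t) = max_x g(u(x, t))`` and the input measure ``z(t)``, the activation
at the site of maximal output.  These are the quantities the homeostatic
adaptation in :mod:`dnfip.ip` observes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import toeplitz
from scipy.special import expit

__all__ = [
    "FieldGrid",
    "KernelParams",
    "TransferParams",
    "DynamicsConfig",
    "FieldState",
    "FieldDivergenceError",
    "make_kernel",
    "transfer",
    "lateral_input",
    "field_step",
    "output_measure",
    "input_measure",
]


class FieldDivergenceError(RuntimeError):
    """Raised when field activation becomes non-finite during integration."""


@dataclass(frozen=True)
class FieldGrid:
    """Discretization of the periodic feature dimension.

    Parameters
    ----------
    n_sites:
        Number of sample points (>= 3).
    domain_extent:
        Length of the feature dimension in degrees (default 360).
    periodic:
        Whether the dimension wraps (orientation does).  A non-periodic
        mode (zero padding beyond the boundary) is available for
        non-circular features.
    """

    n_sites: int
    domain_extent: float = 360.0
    periodic: bool = True

    def __post_init__(self) -> None:
        if self.n_sites < 3:
            raise ValueError(f"n_sites must be >= 3, got {self.n_sites}")
        if self.domain_extent <= 0:
            raise ValueError("domain_extent must be positive")

    @property
    def spacing(self) -> float:
        """Site spacing in degrees."""
        return self.domain_extent / self.n_sites

    @property
    def sites(self) -> np.ndarray:
        """Site positions in degrees, ``0, dx, 2*dx, ...``."""
        return np.arange(self.n_sites) * self.spacing

    def circular_offsets(self) -> np.ndarray:
        """Signed circular index offsets from site 0 to every site.

        For site i the offset is the smaller of ``i`` and ``i - n`` in
        magnitude, i.e. values in roughly ``[-n/2, n/2)``.
        """
        idx = np.arange(self.n_sites)
        return np.where(idx <= self.n_sites // 2, idx, idx - self.n_sites)


@dataclass(frozen=True)
class KernelParams:
    """Mexican-hat interaction kernel parameters.

    Strengths are dimensionless amplitudes; widths are in grid-index units
    (sites).  ``c_inh`` is stored as a positive magnitude and always
    subtracted, so the kernel is excitatory at short range and inhibitory
    at long range whenever ``c_inh > 0``.
    """

    c_exc: float
    sigma_exc: float
    c_inh: float
    sigma_inh: float

    def __post_init__(self) -> None:
        if self.sigma_exc <= 0 or self.sigma_inh <= 0:
            raise ValueError("kernel widths must be positive")
        if self.sigma_inh <= self.sigma_exc:
            raise ValueError("sigma_inh must exceed sigma_exc (long-range inhibition)")
        if self.c_exc <= 0:
            raise ValueError("c_exc must be positive")
        if self.c_inh < 0:
            raise ValueError("c_inh is a magnitude and must be >= 0")

    def evaluate(self, d: float) -> float:
        """Kernel value at a scalar distance ``d`` (grid-index units)."""
        return self.c_exc * np.exp(-(d**2) / (2 * self.sigma_exc**2)) - self.c_inh * np.exp(
            -(d**2) / (2 * self.sigma_inh**2)
        )


@dataclass
class TransferParams:
    """Gain ``a`` and bias ``b`` of the logistic transfer function.

    The pair is the state adapted by intrinsic plasticity.  The bias
    encodes a gain-dependent resting level ``h = b / a``; with negative
    ``b`` the field stays silent below the detection threshold
    ``u = -b / a``.
    """

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError(f"gain a must be positive, got {self.a}")

    @property
    def resting_level(self) -> float:
        return self.b / self.a

    @property
    def threshold(self) -> float:
        """Activation at which the transfer output crosses 1/2."""
        return -self.b / self.a


@dataclass(frozen=True)
class DynamicsConfig:
    """Time constant and Euler step of the field integration (seconds)."""

    tau: float = 0.1
    dt: float = 0.01

    def __post_init__(self) -> None:
        if not (0 < self.dt <= self.tau):
            raise ValueError("require 0 < dt <= tau")


@dataclass
class FieldState:
    """Field activation over the grid plus the simulation clock."""

    u: np.ndarray
    t: float = 0.0

    def copy(self) -> "FieldState":
        return FieldState(self.u.copy(), self.t)


def make_kernel(params: KernelParams, grid: FieldGrid) -> np.ndarray:
    """Evaluate the interaction kernel at the circular distance from site 0
    to every site, in grid-index units.

    The returned array is what circular convolution expects: entry ``i``
    is ``omega(d_i)`` with ``d_i`` the (signed) circular offset of site
    ``i`` from site 0; symmetry of the kernel makes the sign irrelevant.
    For a non-periodic grid the entries are instead the plain distances
    ``0 .. n-1`` (no wraparound).
    """
    if grid.periodic:
        d = grid.circular_offsets().astype(float)
    else:
        d = np.arange(grid.n_sites, dtype=float)
    return params.c_exc * np.exp(-(d**2) / (2 * params.sigma_exc**2)) - params.c_inh * np.exp(
        -(d**2) / (2 * params.sigma_inh**2)
    )


def transfer(u_values: np.ndarray | float, params: TransferParams) -> np.ndarray | float:
    """Parametric logistic transfer ``g_{a,b}(u) = expit(a*u + b)``.

    Strictly increasing in ``u`` (``a > 0``), output in the open interval
    (0, 1), half-activation exactly at ``u = -b/a``.  ``expit`` evaluates
    the overflow-safe branch form.
    """
    return expit(params.a * np.asarray(u_values, dtype=float) + params.b)


def lateral_input(
    output_values: np.ndarray, kernel_values: np.ndarray, grid: FieldGrid
) -> np.ndarray:
    """Recurrent drive: discrete convolution of transferred output with the
    interaction kernel.

    The convolution integral is approximated by a plain sum over sites
    (no spacing factor): the kernel amplitudes of the shipped preset are
    calibrated against a 100-site field under this convention.  Periodic
    grids use circular convolution; non-periodic grids zero-pad.
    """
    output_values = np.asarray(output_values, dtype=float)
    if output_values.shape[0] != grid.n_sites or kernel_values.shape[0] != grid.n_sites:
        raise ValueError(
            f"length mismatch: output {output_values.shape[0]}, "
            f"kernel {kernel_values.shape[0]}, grid {grid.n_sites}"
        )
    if grid.periodic:
        return np.real(
            np.fft.ifft(np.fft.fft(kernel_values) * np.fft.fft(output_values))
        )
    # Non-periodic: kernel_values hold omega at plain distances 0..n-1;
    # sites beyond the boundary contribute nothing.
    return toeplitz(kernel_values) @ output_values


def field_step(
    state: FieldState,
    input_frame: np.ndarray,
    kernel_values: np.ndarray,
    tp: TransferParams,
    cfg: DynamicsConfig,
    grid: FieldGrid | None = None,
) -> FieldState:
    """One explicit Euler step of the field dynamics.

    ``u <- u + (dt/tau) * (-u + S + omega * g(u))`` and the clock advances
    by ``dt``.  There is no explicit resting-level term: it lives in the
    transfer bias.
    """
    u = state.u
    if grid is None:
        grid = FieldGrid(u.shape[0])
    g = transfer(u, tp)
    drive = lateral_input(g, kernel_values, grid)
    u_new = u + (cfg.dt / cfg.tau) * (-u + np.asarray(input_frame, dtype=float) + drive)
    if not np.all(np.isfinite(u_new)):
        raise FieldDivergenceError(
            f"non-finite activation after step at t={state.t + cfg.dt:.4f} s"
        )
    return FieldState(u_new, state.t + cfg.dt)


def output_measure(state: FieldState, tp: TransferParams) -> float:
    """Output measure ``y(t)``: maximum of the transferred field, in (0, 1)."""
    return float(np.max(transfer(state.u, tp)))


def input_measure(state: FieldState, tp: TransferParams) -> float:
    """Input measure ``z(t)``: activation at the site of maximal output.

    The transfer is strictly increasing, so this is ``max(u)``; ties are
    broken toward the lowest site index (the convention ``argmax`` uses).
    """
    return float(state.u[int(np.argmax(transfer(state.u, tp)))])
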