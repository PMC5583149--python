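"""Intrinsic plasticity (IP) for the field's global gain and bias.

IP is a homeostatic rule: it adapts the transfer-function parameters
``(a, b)`` so that the distribution of the scalar output measure ``y``
approaches an exponential target with mean ``mu`` (sparse output: mostly
silent, occasional detections).  The rules descend the Kullback-Leibler
divergence between the output distribution and the target; for the
logistic transfer they reduce to

    db/dt = eta * (1 - (2 + 1/mu) * y + y**2 / mu)
    da/dt = eta / a + z * db/dt

with ``z`` the input measure.  The natural-gradient variant multiplies
the (per-sample, Euclidean) gradient by the inverse of a regularized
online Fisher-information estimate, which equalizes parameter steps in
output space and in particular suppresses the transient gain collapse
seen under mean-shifted input.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dc_field

import numpy as np

from .field import TransferParams

__all__ = [
    "GAIN_FLOOR",
    "IPConfig",
    "FisherState",
    "bias_rate",
    "gain_rate",
    "euclidean_gradient",
    "update_fisher",
    "natural_update",
    "ip_step",
    "empirical_kld",
]

#: Lower clamp on the gain: keeps the transfer orientation-preserving and
#: the eta/a term finite without affecting the operating regime.
GAIN_FLOOR = 1e-6


@dataclass(frozen=True)
class IPConfig:
    """Learning configuration.

    eta:
        Learning rate per second (default 0.001).
    mu:
        Mean of the exponential target distribution of the output measure
        (default 0.2; dimensionless because y is in (0, 1)).
    use_natural_gradient:
        Whether to precondition the gradient with the inverse regularized
        Fisher estimate (default True).
    lam:
        Low-pass coefficient of the online Fisher estimate (default 0.01;
        the Fisher memory then spans ~100 input samples, short enough for
        the estimate to track a sudden change in the input statistics).
    eps:
        Tikhonov regularization added to the Fisher tensor before
        inversion (default 1e-4).
    """

    eta: float = 0.001
    mu: float = 0.2
    use_natural_gradient: bool = True
    lam: float = 0.01
    eps: float = 1e-4

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if not (0 < self.mu < 1):
            raise ValueError("mu must lie in (0, 1)")
        if not (0 < self.lam <= 1):
            raise ValueError("lam must lie in (0, 1]")
        if self.eps <= 0:
            raise ValueError("eps must be positive")


@dataclass
class FisherState:
    """Running 2x2 Fisher-information estimate (symmetric, PSD)."""

    f: np.ndarray = _dc_field(default_factory=lambda: np.zeros((2, 2)))

    def copy(self) -> "FisherState":
        return FisherState(self.f.copy())


def bias_rate(y: float, mu: float, eta: float) -> float:
    """Rate of change of the bias, ``eta * (1 - (2 + 1/mu) y + y^2 / mu)``.

    Positive for output below the smaller root of the quadratic (output
    too low -> raise the resting level), negative between the roots
    (output too high -> lower it).
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    return eta * (1.0 - (2.0 + 1.0 / mu) * y + y * y / mu)


def gain_rate(z: float, db_dt: float, a: float, eta: float) -> float:
    """Rate of change of the gain, ``eta / a + z * db/dt``.

    The eta/a term alone always drifts the gain upward; the coupling to
    the bias rate pulls it down when a high output coincides with a high
    input measure.
    """
    if a <= 0:
        raise ValueError("gain must be positive")
    return eta / a + z * db_dt


def euclidean_gradient(y: float, z: float, a: float, mu: float) -> np.ndarray:
    """Per-sample loss gradient ``(dL/da, dL/db)`` of the KLD objective.

    Equals ``-(gain_rate, bias_rate)`` with the learning rate factored
    out, so a plain gradient-descent step ``-eta * grad`` reproduces the
    rate-based updates exactly.
    """
    rb = bias_rate(y, mu, 1.0)
    ra = gain_rate(z, rb, a, 1.0)
    return np.array([-ra, -rb])


def update_fisher(fs: FisherState, grad: np.ndarray, lam: float) -> FisherState:
    """Exponential moving average of the gradient outer product.

    ``F <- (1 - lam) F + lam g g^T``; symmetry and positive
    semidefiniteness are preserved by construction.
    """
    g = np.asarray(grad, dtype=float)
    return FisherState((1.0 - lam) * fs.f + lam * np.outer(g, g))


def natural_update(
    tp: TransferParams,
    grad: np.ndarray,
    fs: FisherState,
    eta: float,
    eps: float,
) -> TransferParams:
    """Natural-gradient step ``theta <- theta - eta (F + eps I)^{-1} grad``.

    The 2x2 regularized tensor is inverted exactly; the gain clamp is
    applied afterwards.
    """
    m00 = fs.f[0, 0] + eps
    m11 = fs.f[1, 1] + eps
    m01 = fs.f[0, 1]
    det = m00 * m11 - m01 * m01
    if det <= 0 or not np.isfinite(det):
        raise np.linalg.LinAlgError(
            f"regularized Fisher tensor numerically singular (det={det})"
        )
    g0, g1 = float(grad[0]), float(grad[1])
    step0 = (m11 * g0 - m01 * g1) / det
    step1 = (-m01 * g0 + m00 * g1) / det
    a = max(tp.a - eta * step0, GAIN_FLOOR)
    b = tp.b - eta * step1
    return TransferParams(a, b)


def ip_step(
    tp: TransferParams,
    fs: FisherState,
    y: float,
    z: float,
    cfg: IPConfig,
    dt: float = 1.0,
) -> tuple[TransferParams, FisherState]:
    """One IP update given the current measures, with step size ``dt``.

    The canonical cadence is one unit update (``dt = 1``) per input
    sample, as in single-neuron IP; fractional ``dt`` integrates the same
    rates on a finer clock.

    Without the natural gradient the plain rate equations are applied:
    ``(a, b) += dt * (gain_rate, bias_rate)``.  With it, the per-sample
    gradient *including the learning-rate factor* (i.e. the update vector
    of the plain rule, negated) feeds the Fisher estimate, and the
    preconditioned step ``-eta (F + eps I)^{-1} grad`` is applied.  The
    double appearance of eta is deliberate: it makes the natural-gradient
    step approach ``(eta^2 / eps) * gradient`` when the Fisher estimate is
    small, the amplification that gives the method its fast, metrically
    uniform convergence.
    """
    if cfg.use_natural_gradient:
        grad = cfg.eta * euclidean_gradient(y, z, tp.a, cfg.mu)
        fs = update_fisher(fs, grad, cfg.lam)
        tp = natural_update(tp, grad, fs, cfg.eta * dt, cfg.eps)
        return tp, fs
    db = bias_rate(y, cfg.mu, cfg.eta)
    da = gain_rate(z, db, tp.a, cfg.eta)
    a = max(tp.a + dt * da, GAIN_FLOOR)
    return TransferParams(a, tp.b + dt * db), fs


def empirical_kld(y_samples: np.ndarray, mu: float, n_bins: int = 50) -> float:
    """Histogram estimate of the KLD between the sample distribution of y
    and the exponential target with mean ``mu``, renormalized on (0, 1).

    Diagnostic only: the learning rules use the analytic gradient, not
    this estimate.  The target is truncated to (0, 1) because the
    logistic output cannot leave that interval.  Non-negative by Gibbs'
    inequality (both histograms are normalized over the same bins).
    """
    y = np.asarray(y_samples, dtype=float)
    if y.size == 0:
        raise ValueError("empirical_kld requires at least one sample")
    if mu <= 0:
        raise ValueError("mu must be positive")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(np.clip(y, 0.0, 1.0), bins=edges)
    p = counts / counts.sum()
    cdf = 1.0 - np.exp(-edges / mu)
    q = np.diff(cdf) / cdf[-1]
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))
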