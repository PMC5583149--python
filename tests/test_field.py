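"""Field dynamics: kernel, transfer, convolution, Euler stepping, measures."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from dnfip import (
    DynamicsConfig,
    FieldDivergenceError,
    FieldGrid,
    FieldState,
    KernelParams,
    TransferParams,
    field_step,
    input_measure,
    lateral_input,
    make_kernel,
    output_measure,
    transfer,
)


class TestKernel:
    def test_value_at_zero_distance(self, kernel_params, grid100):
        # exp(0) = 1 on both lobes: omega(0) = c_exc - c_inh
        kernel = make_kernel(kernel_params, grid100)
        assert kernel[0] == pytest.approx(14.0 - 7.0)

    def test_symmetry_under_reflection(self, kernel_params, grid100):
        kernel = make_kernel(kernel_params, grid100)
        # circularly opposite offsets d and -d carry equal values
        assert np.allclose(kernel[1:], kernel[1:][::-1])

    def test_scalar_formula_oracle(self, kernel_params, grid100):
        # independent per-point evaluation outside the vectorized path
        kernel = make_kernel(kernel_params, grid100)
        d = 3.0
        expected = 14.0 * math.exp(-(d**2) / (2 * 2.0**2)) - 7.0 * math.exp(
            -(d**2) / (2 * 6.0**2)
        )
        assert kernel[3] == pytest.approx(expected, abs=1e-14)
        assert kernel[97] == pytest.approx(expected, abs=1e-14)  # circular distance 3

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            KernelParams(c_exc=14, sigma_exc=0.0, c_inh=7, sigma_inh=6)
        with pytest.raises(ValueError):
            KernelParams(c_exc=14, sigma_exc=6, c_inh=7, sigma_inh=2)  # widths swapped
        with pytest.raises(ValueError):
            KernelParams(c_exc=14, sigma_exc=2, c_inh=-7, sigma_inh=6)  # magnitude


class TestTransfer:
    def test_half_activation_at_threshold(self):
        assert transfer(0.0, TransferParams(1.0, 0.0)) == pytest.approx(0.5)
        assert transfer(0.5, TransferParams(2.0, -1.0)) == pytest.approx(0.5)

    def test_half_activation_root_oracle(self):
        # converged parameters of the mu=0.2 run: threshold found by an
        # independent root-finder must equal -b/a = 3.0/0.59
        tp = TransferParams(0.59, -3.0)
        root = brentq(lambda u: transfer(u, tp) - 0.5, -100, 100, xtol=1e-12)
        assert root == pytest.approx(3.0 / 0.59, abs=1e-9)

    @given(u=st.floats(-1e6, 1e6), a=st.floats(1e-3, 50), b=st.floats(-50, 50))
    @settings(max_examples=200, deadline=None)
    def test_output_in_open_unit_interval(self, u, a, b):
        y = float(transfer(u, TransferParams(a, b)))
        assert 0.0 <= y <= 1.0
        assert np.isfinite(y)

    def test_strictly_increasing(self):
        tp = TransferParams(0.7, -2.0)
        u = np.linspace(-20, 20, 401)
        assert np.all(np.diff(transfer(u, tp)) > 0)


class TestLateralInput:
    def test_zero_output_gives_zero_drive(self, kernel_params, grid100):
        kernel = make_kernel(kernel_params, grid100)
        drive = lateral_input(np.zeros(100), kernel, grid100)
        assert np.allclose(drive, 0.0)

    def test_impulse_reproduces_centered_kernel(self, kernel_params, grid100):
        kernel = make_kernel(kernel_params, grid100)
        out = np.zeros(100)
        out[17] = 1.0
        drive = lateral_input(out, kernel, grid100)
        assert np.allclose(drive, np.roll(kernel, 17), atol=1e-12)

    @pytest.mark.parametrize("n_sites", range(3, 33))
    def test_matches_double_loop_oracle(self, kernel_params, n_sites):
        grid = FieldGrid(n_sites=n_sites)
        kernel = make_kernel(kernel_params, grid)
        rng = np.random.default_rng(n_sites)
        out = rng.uniform(0, 1, n_sites)
        drive = lateral_input(out, kernel, grid)
        brute = np.zeros(n_sites)
        for i in range(n_sites):
            for j in range(n_sites):
                brute[i] += kernel[(i - j) % n_sites] * out[j]
        assert np.allclose(drive, brute, atol=1e-10)

    def test_nonperiodic_matches_truncated_sum(self, kernel_params):
        grid = FieldGrid(n_sites=20, periodic=False)
        kernel = make_kernel(kernel_params, grid)
        rng = np.random.default_rng(7)
        out = rng.uniform(0, 1, 20)
        drive = lateral_input(out, kernel, grid)
        brute = np.zeros(20)
        for i in range(20):
            for j in range(20):
                brute[i] += kernel_params.evaluate(abs(i - j)) * out[j]
        assert np.allclose(drive, brute, atol=1e-10)

    def test_length_mismatch_rejected(self, kernel_params, grid100):
        kernel = make_kernel(kernel_params, grid100)
        with pytest.raises(ValueError):
            lateral_input(np.zeros(50), kernel, grid100)


class TestFieldStep:
    dyn = DynamicsConfig(tau=0.1, dt=0.01)

    def test_full_relaxation_step(self, grid100):
        # dt = tau relaxes u -> S in a single Euler step; zero kernel, S=0
        state = FieldState(np.ones(100))
        new = field_step(state, np.zeros(100), np.zeros(100), TransferParams(1, -5),
                         DynamicsConfig(tau=0.1, dt=0.1), grid100)
        assert np.allclose(new.u, 0.0)
        assert new.t == pytest.approx(0.1)

    def test_fixed_point_is_constant_input(self, grid100):
        S = np.full(100, 3.7)
        state = FieldState(np.zeros(100))
        tp = TransferParams(1, -5)
        for _ in range(2000):
            prev = state.u
            state = field_step(state, S, np.zeros(100), tp, self.dyn, grid100)
            if np.max(np.abs(state.u - prev)) < 1e-10:
                break
        assert np.allclose(state.u, 3.7, atol=1e-7)

    def test_geometric_relaxation_rate(self, grid100):
        # with zero kernel the error to a constant input contracts by
        # exactly (1 - dt/tau) per step
        S = np.full(100, 2.0)
        state = FieldState(np.zeros(100))
        tp = TransferParams(1, -5)
        k = 25
        for _ in range(k):
            state = field_step(state, S, np.zeros(100), tp, self.dyn, grid100)
        expected_err = 2.0 * (1 - self.dyn.dt / self.dyn.tau) ** k
        assert np.allclose(np.abs(state.u - 2.0), expected_err, rtol=1e-9)

    def test_trajectory_matches_scalar_loop_oracle(self, kernel_params, grid100):
        # 50 steps under a step input, against an unvectorized
        # reimplementation of the same update
        kernel = make_kernel(kernel_params, grid100)
        tp = TransferParams(1.0, -5.0)
        S = np.zeros(100)
        S[40:46] = 5.5
        state = FieldState(np.zeros(100))
        for _ in range(50):
            state = field_step(state, S, kernel, tp, self.dyn, grid100)
        u = [0.0] * 100
        for _ in range(50):
            g = [1.0 / (1.0 + math.exp(-(tp.a * v + tp.b))) for v in u]
            new = []
            for i in range(100):
                drive = sum(kernel[(i - j) % 100] * g[j] for j in range(100))
                new.append(u[i] + (0.01 / 0.1) * (-u[i] + S[i] + drive))
            u = new
        assert np.allclose(state.u, u, atol=1e-9)

    def test_divergence_raises_with_context(self, grid100):
        state = FieldState(np.zeros(100))
        bad = np.full(100, np.inf)
        with pytest.raises(FieldDivergenceError, match="t="):
            field_step(state, bad, np.zeros(100), TransferParams(1, -5), self.dyn, grid100)

    def test_translation_equivariance(self, kernel_params, grid100):
        # homogeneous field: shifting the input shifts the trajectory
        kernel = make_kernel(kernel_params, grid100)
        tp = TransferParams(1.0, -5.0)
        rng = np.random.default_rng(3)
        S = rng.uniform(0, 6, 100)
        shift = 13
        s1 = FieldState(np.zeros(100))
        s2 = FieldState(np.zeros(100))
        for _ in range(200):
            s1 = field_step(s1, S, kernel, tp, self.dyn, grid100)
            s2 = field_step(s2, np.roll(S, shift), kernel, tp, self.dyn, grid100)
        assert np.allclose(np.roll(s1.u, shift), s2.u, atol=1e-8)


class TestMeasures:
    def test_flat_field(self):
        tp = TransferParams(1.0, -5.0)
        state = FieldState(np.full(100, 2.5))
        assert output_measure(state, tp) == pytest.approx(float(transfer(2.5, tp)))
        assert input_measure(state, tp) == pytest.approx(2.5)

    def test_matches_explicit_site_loop(self, rng):
        tp = TransferParams(0.8, -3.0)
        u = rng.normal(0, 3, 100)
        state = FieldState(u)
        best = max(float(transfer(v, tp)) for v in u)
        assert output_measure(state, tp) == pytest.approx(best)
        assert input_measure(state, tp) == pytest.approx(max(u))

    def test_tie_broken_to_lowest_index(self):
        tp = TransferParams(1.0, -5.0)
        u = np.zeros(100)
        u[10] = 4.0
        u[90] = 4.0
        state = FieldState(u)
        # both sites transfer identically; the measure reads site 10
        assert input_measure(state, tp) == pytest.approx(u[10])
        assert int(np.argmax(transfer(u, tp))) == 10


class TestHysteresis:
    dyn = DynamicsConfig(0.1, 0.01)

    @staticmethod
    def _bump(grid):
        d = np.abs(grid.sites - 180.0)
        d = np.minimum(d, 360.0 - d)
        return np.exp(-(d**2) / (2 * 10.8**2))

    def _relax(self, state, S, kernel, tp, grid, n=200):
        for _ in range(n):
            state = field_step(state, S, kernel, tp, self.dyn, grid)
        return state

    def test_detection_threshold_exceeds_release_threshold(self, kernel_params, grid100):
        """Ramping a localized input up and then down: the output turns on
        at a strictly positive amplitude, but on the way down it never
        turns off again before the input is gone - the detection
        threshold strictly exceeds the release threshold, the signature
        of the bistable regime between the detection and reverse
        detection instabilities (at this kernel strength the formed peak
        is fully self-stabilized)."""
        kernel = make_kernel(kernel_params, grid100)
        tp = TransferParams(1.0, -5.0)
        bump = self._bump(grid100)
        state = FieldState(np.zeros(100))
        up_thr = None
        for A in np.arange(0.0, 8.01, 0.25):
            state = self._relax(state, A * bump, kernel, tp, grid100)
            if up_thr is None and output_measure(state, tp) > 0.5:
                up_thr = A
        assert up_thr is not None and up_thr > 0.5, "no detection over the ramp"
        for A in np.arange(8.0, -0.01, -0.25):
            state = self._relax(state, A * bump, kernel, tp, grid100)
        # still detected at zero input: the release threshold lies strictly
        # below the detection threshold (here even below zero)
        state = self._relax(state, np.zeros(100), kernel, tp, grid100, n=600)
        assert output_measure(state, tp) > 0.5


def test_grid_validation():
    with pytest.raises(ValueError):
        FieldGrid(n_sites=2)
    g = FieldGrid(n_sites=100)
    assert g.spacing == pytest.approx(3.6)
    assert g.sites[1] == pytest.approx(3.6)


def test_dynamics_validation():
    with pytest.raises(ValueError):
        DynamicsConfig(tau=0.1, dt=0.2)
    with pytest.raises(ValueError):
        TransferParams(0.0, -5.0)
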