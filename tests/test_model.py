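"""Core neural-mass network: currents, f-I curves, gating, integration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hybridbnm import (DriveTimeSeries, ModelParameters, RegionState,
                       SimulationConfig, StructuralConnectome,
                       compute_input_currents, firing_rate,
                       gating_derivatives, isolated_fixed_point, simulate,
                       step)
from hybridbnm.model import IntegrationDivergedError


class TestInputCurrents:
    def test_rest_no_coupling(self, single_node):
        """With zero gating and no drive only the scaled external input
        remains: I_E = 0.382 nA, I_I = 0.7 * 0.382 nA."""
        p = ModelParameters(recurrence_enabled=False)
        state = RegionState(np.zeros(1), np.zeros(1))
        I_E, I_I = compute_input_currents(state, np.zeros(1), single_node,
                                          np.ones(1), p)
        assert I_E[0] == pytest.approx(0.382)
        assert I_I[0] == pytest.approx(0.2674)

    def test_recurrent_single_node(self, single_node):
        """Direct scalar evaluation with local recurrence on:
        0.382 + 1.4*0.15*0.1 - 0.05 = 0.353 nA."""
        p = ModelParameters(G=0.0, recurrence_enabled=True)
        state = RegionState(np.array([0.1]), np.array([0.05]))
        I_E, _ = compute_input_currents(state, np.zeros(1), single_node,
                                        np.ones(1), p)
        assert I_E[0] == pytest.approx(0.353)

    def test_long_range_term(self):
        """Symmetric two-node coupling: G * C @ S_E adds 0.5*0.2 = 0.1 nA."""
        C = StructuralConnectome(np.array([[0.0, 1.0], [1.0, 0.0]]))
        p = ModelParameters(G=0.5, recurrence_enabled=False)
        state = RegionState(np.full(2, 0.2), np.zeros(2))
        I_E, _ = compute_input_currents(state, np.zeros(2), C, np.ones(2), p)
        assert I_E == pytest.approx([0.382 + 0.1] * 2)

    def test_dimension_mismatch_raises(self, single_node, params):
        state = RegionState(np.zeros(2), np.zeros(2))
        with pytest.raises(ValueError, match="dimension"):
            compute_input_currents(state, np.zeros(2), single_node,
                                   np.ones(2), params)

    def test_nonfinite_drive_raises(self, single_node, params):
        state = RegionState(np.zeros(1), np.zeros(1))
        with pytest.raises(ValueError, match="non-finite"):
            compute_input_currents(state, np.array([np.nan]), single_node,
                                   np.ones(1), params)


class TestFiringRate:
    def test_removable_singularity(self, params):
        """At a*I = b the transfer function equals its limit 1/d."""
        assert firing_rate(125.0 / 310.0, "E", params) == pytest.approx(
            1.0 / 0.16)
        assert firing_rate(177.0 / 615.0, "I", params) == pytest.approx(
            1.0 / 0.087)

    @pytest.mark.parametrize("pop, I, expected", [
        ("E", 0.4, 5.763327647909739),
        ("I", 0.3, 15.649200587363993),
    ])
    def test_scalar_values(self, params, pop, I, expected):
        """Frozen direct evaluations of (a*I-b)/(1-exp(-d*(a*I-b)))."""
        assert firing_rate(I, pop, params) == pytest.approx(expected,
                                                            rel=1e-12)

    @settings(deadline=None, max_examples=60)
    @given(I=st.floats(min_value=-1.0, max_value=2.0),
           pop=st.sampled_from(["E", "I"]))
    def test_nonnegative(self, params, I, pop):
        assert firing_rate(I, pop, params) >= 0.0

    @pytest.mark.parametrize("pop", ["E", "I"])
    def test_strictly_increasing(self, params, pop):
        grid = np.linspace(-1.0, 2.0, 2001)
        r = firing_rate(grid, pop, params)
        assert np.all(np.diff(r) > 0)

    def test_continuous_at_singularity(self, params):
        I0 = 125.0 / 310.0
        eps = np.array([-1e-7, -1e-9, 0.0, 1e-9, 1e-7]) / 310.0
        r = firing_rate(I0 + eps, "E", params)
        assert np.ptp(r) < 1e-6


class TestGatingDerivatives:
    def test_saturated_excitatory_decays(self, params):
        """At S_E = 1 the growth term vanishes: dS_E = -1/tau_E < 0."""
        state = RegionState(np.ones(1), np.zeros(1))
        dS_E, _ = gating_derivatives(state, np.array([500.0]),
                                     np.array([0.0]), params)
        assert dS_E[0] == pytest.approx(-1.0 / 100.0)

    def test_inhibitory_growth(self, params):
        """dS_I = gamma_I * r_I at S_I = 0."""
        state = RegionState(np.zeros(1), np.zeros(1))
        _, dS_I = gating_derivatives(state, np.zeros(1), np.array([10.0]),
                                     params)
        assert dS_I[0] == pytest.approx(1.0e-3 * 10.0)

    def test_inhibitory_fixed_point(self, params):
        """dS_I = 0 exactly at S_I = tau_I * gamma_I * r_I."""
        r_I = 7.3
        state = RegionState(np.zeros(1), np.array([10.0 * 1.0e-3 * r_I]))
        _, dS_I = gating_derivatives(state, np.zeros(1), np.array([r_I]),
                                     params)
        assert dS_I[0] == pytest.approx(0.0, abs=1e-15)


class TestStep:
    def test_fixed_point_is_stationary(self, single_node, params):
        S_E, S_I, _ = isolated_fixed_point(params, J=1.0)
        state = RegionState(np.array([S_E]), np.array([S_I]))
        out = step(state, np.zeros(1), single_node, np.ones(1), params)
        assert out.S_E[0] == pytest.approx(S_E, abs=1e-12)
        assert out.S_I[0] == pytest.approx(S_I, abs=1e-12)

    def test_deterministic_without_noise(self, single_node, params):
        state = RegionState(np.array([0.3]), np.array([0.2]))
        a = step(state, np.array([0.5]), single_node, np.ones(1), params)
        b = step(state, np.array([0.5]), single_node, np.ones(1), params)
        assert a.S_E[0] == b.S_E[0] and a.S_I[0] == b.S_I[0]

    def test_noise_requires_rng(self, single_node):
        p = ModelParameters(noise_sigma=0.01)
        state = RegionState(np.array([0.1]), np.array([0.1]))
        with pytest.raises(ValueError, match="rng"):
            step(state, np.zeros(1), single_node, np.ones(1), p)

    def test_reduced_step_oracle(self, single_node, params):
        """Euler at dt = 0.1 ms stays within 1e-4 of a dt/100 reference
        over 1 s of constant drive, for seeded random initial states."""
        rng = np.random.default_rng(7)
        p = params.with_(w_BG_E=0.01, w_BG_I=0.1)
        for _ in range(10):
            state0 = RegionState(rng.uniform(0, 0.5, 1),
                                 rng.uniform(0, 0.5, 1))
            drive = DriveTimeSeries(
                np.full((1, 1000), rng.uniform(-0.5, 0.5)), 1000.0)
            traces = [
                simulate(single_node, drive, np.ones(1), p,
                         SimulationConfig(dt=dt, initial_state=state0))
                for dt in (0.1, 0.001)
            ]
            coarse, fine = traces
            # truncation error peaks during fast transients; inhibitory
            # gating (10 ms time constant) carries ~10x the E error
            assert np.abs(coarse.S_E - fine.S_E).max() < 5e-4
            assert np.abs(coarse.S_I - fine.S_I).max() < 1e-3


class TestSimulate:
    def test_isolated_node_settles_at_calibration_rate(self, single_node,
                                                       zero_drive, params):
        """Uncoupled, undriven node with J = 1 settles at ~3.06 Hz."""
        trace = simulate(single_node, zero_drive(duration=20.0), np.ones(1),
                         params)
        keep = trace.time >= 5000.0
        assert trace.r_E[0, keep].mean() == pytest.approx(3.06, abs=0.1)

    def test_zero_duration(self, single_node, zero_drive, params):
        trace = simulate(single_node, zero_drive(duration=1.0), np.ones(1),
                         params, SimulationConfig(duration=0.0))
        assert trace.n_samples == 0
        assert trace.sample_rate == 1000.0

    def test_matches_step_reference(self, params):
        """The compiled kernel reproduces the pure-python stepper."""
        C = StructuralConnectome(np.array([[0.0, 0.6], [0.6, 0.0]]))
        p = params.with_(G=0.3, w_BG_E=0.01, w_BG_I=0.1)
        rng = np.random.default_rng(3)
        drive = DriveTimeSeries(rng.standard_normal((2, 50)), 1000.0)
        J = np.array([1.0, 1.2])
        trace = simulate(C, drive, J, p)
        state = RegionState(np.full(2, 0.1), np.full(2, 0.1))
        for k in range(50):
            assert state.S_E == pytest.approx(trace.S_E[:, k], abs=1e-12)
            for _ in range(10):
                state = step(state, drive.values[:, k], C, J, p, dt=0.1)

    def test_determinism(self, connectome8, am_drive8):
        p = ModelParameters(G=0.1, w_BG_E=0.005, w_BG_I=0.05)
        cfg = SimulationConfig(duration=5.0)
        a = simulate(connectome8, am_drive8, np.ones(8), p, cfg)
        b = simulate(connectome8, am_drive8, np.ones(8), p, cfg)
        assert np.array_equal(a.S_E, b.S_E)
        assert np.array_equal(a.r_I, b.r_I)

    def test_noise_seeded_reproducible(self, connectome8, zero_drive):
        p = ModelParameters(G=0.1, noise_sigma=0.01)
        cfg = SimulationConfig(seed=11)
        a = simulate(connectome8, zero_drive(8, 2.0), np.ones(8), p, cfg)
        b = simulate(connectome8, zero_drive(8, 2.0), np.ones(8), p, cfg)
        assert np.array_equal(a.S_E, b.S_E)
        c = simulate(connectome8, zero_drive(8, 2.0), np.ones(8), p,
                     SimulationConfig(seed=12))
        assert not np.array_equal(a.S_E, c.S_E)

    def test_gating_bounded(self, connectome8):
        """S_E stays in [0, 1] and S_I nonnegative under strong drive."""
        p = ModelParameters(G=0.5, w_BG_E=0.1, w_BG_I=0.5)
        rng = np.random.default_rng(5)
        drive = DriveTimeSeries(3 * rng.standard_normal((8, 3000)), 1000.0)
        trace = simulate(connectome8, drive, np.ones(8), p)
        assert trace.S_E.min() >= 0.0 and trace.S_E.max() <= 1.0
        assert trace.S_I.min() >= 0.0
        assert trace.r_E.min() >= 0.0 and trace.r_I.min() >= 0.0

    def test_drive_too_short_raises(self, single_node, zero_drive, params):
        with pytest.raises(ValueError, match="drive holds only"):
            simulate(single_node, zero_drive(duration=1.0), np.ones(1),
                     params, SimulationConfig(duration=2.0))

    def test_rate_mismatch_raises(self, single_node, params):
        drive = DriveTimeSeries(np.zeros((1, 100)), 3000.0)
        with pytest.raises(ValueError, match="integer multiple"):
            simulate(single_node, drive, np.ones(1), params)

    def test_rectified_inhibition_monotone_in_amplitude(self, single_node,
                                                        params):
        """Cycle-averaged inhibitory rate is non-decreasing in the
        amplitude of a zero-mean 10 Hz sinusoid injected into the
        inhibitory population (half-wave rectification)."""
        t = np.arange(10000) / 1000.0
        means = []
        for A in (0.0, 0.05, 0.1, 0.2, 0.4):
            drive = DriveTimeSeries(np.sin(2 * np.pi * 10 * t)[None, :],
                                    1000.0)
            p = params.with_(w_BG_I=A, w_BG_E=0.0)
            trace = simulate(single_node, drive, np.ones(1), p)
            keep = trace.time >= 5000.0
            means.append(trace.r_I[0, keep].mean())
        assert np.all(np.diff(means) >= 0)
        assert means[-1] > means[0]
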