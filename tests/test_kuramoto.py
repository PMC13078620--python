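"""Model definition, integration accuracy, and order-parameter behavior."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from isorhythm import (
    Circuit,
    Forcing,
    IntegrationConfig,
    NaturalFrequencySpec,
    build_circuit,
    complete_digraph,
    critical_coupling,
    forcing_phase,
    integrate,
    mean_order,
    order_parameter,
    phase_velocity,
    subcritical_coupling,
    to_adjacency,
)
from isorhythm.kuramoto import batch_mean_order

TWO_PI = 2.0 * np.pi


class TestCriticalCoupling:
    def test_zero_spread_degenerates_to_zero(self):
        assert critical_coupling(0.0) == 0.0

    @pytest.mark.parametrize(
        "spread,expected",
        [(1.0, 2.0 * np.sqrt(2.0 / np.pi)), (TWO_PI * 0.5, TWO_PI * np.sqrt(2.0 / np.pi))],
    )
    def test_matches_independent_evaluation(self, spread, expected):
        # 2 / (pi * g(0)) with g the zero-mean normal density, evaluated
        # directly through scipy rather than the closed form
        from scipy.stats import norm

        assert critical_coupling(spread) == pytest.approx(expected, abs=1e-12)
        assert critical_coupling(spread) == pytest.approx(
            2.0 / (np.pi * norm.pdf(0.0, scale=spread)), rel=1e-12
        )

    def test_linear_in_spread(self):
        spreads = np.linspace(0.1, 8.0, 17)
        vals = np.array([critical_coupling(s) for s in spreads])
        np.testing.assert_allclose(vals, 2.0 * spreads * np.sqrt(2.0 / np.pi), atol=1e-12)

    def test_negative_spread_rejected(self):
        with pytest.raises(ValueError):
            critical_coupling(-0.1)


class TestSubcriticalCoupling:
    @pytest.mark.parametrize(
        "eps,critical,expected", [(0.0, 1.5958, 1.5958), (0.1, 1.5958, 1.43622), (1.0, 3.3, 0.0)]
    )
    def test_values(self, eps, critical, expected):
        assert subcritical_coupling(critical, eps) == pytest.approx(expected)

    @pytest.mark.parametrize("eps", [-0.01, 1.5])
    def test_epsilon_out_of_range(self, eps):
        with pytest.raises(ValueError):
            subcritical_coupling(1.0, eps)


class TestBuildCircuit:
    def test_zero_spread_gives_identical_frequencies(self):
        c = build_circuit(np.zeros((4, 4)), NaturalFrequencySpec(2.0, 0.0), seed=0)
        np.testing.assert_allclose(c.natural_frequencies, TWO_PI * 2.0)
        assert c.coupling == 0.0

    def test_shape_and_reproducibility(self):
        adj = to_adjacency(complete_digraph(5))
        c1 = build_circuit(adj, NaturalFrequencySpec(2.0, 0.5), seed=7)
        c2 = build_circuit(adj, NaturalFrequencySpec(2.0, 0.5), seed=7)
        assert c1.natural_frequencies.shape == (5,)
        np.testing.assert_array_equal(c1.natural_frequencies, c2.natural_frequencies)

    def test_frequency_sample_mean_converges(self):
        # 1e5 draws in total across seeded circuits: sample mean tempo
        # within 0.01 Hz of the nominal 2 Hz
        spec = NaturalFrequencySpec(2.0, 0.5)
        adj = np.zeros((1000, 1000))
        draws = np.concatenate(
            [build_circuit(adj, spec, seed=s).natural_frequencies for s in range(100)]
        )
        assert draws.size == 100_000
        assert abs(draws.mean() / TWO_PI - 2.0) < 0.01

    def test_structural_errors(self):
        with pytest.raises(ValueError):
            build_circuit(np.zeros((3, 4)), NaturalFrequencySpec(), seed=0)
        with pytest.raises(ValueError):
            build_circuit(np.eye(3), NaturalFrequencySpec(), seed=0)


class TestForcingPhase:
    def test_cases(self):
        assert forcing_phase(0.0, Forcing(tempo=2.0)) == 0.0
        assert forcing_phase(0.25, Forcing(tempo=2.0)) == pytest.approx(np.pi)
        assert forcing_phase(17.3, Forcing(tempo=0.0, initial_phase=1.2)) == pytest.approx(1.2)

    def test_wrapped(self):
        phi = forcing_phase(123.456, Forcing(tempo=3.7, initial_phase=5.0))
        assert 0.0 <= phi < TWO_PI


class TestPhaseVelocity:
    def test_uncoupled_limit_returns_omega(self):
        c = Circuit(3, np.zeros((3, 3)), np.array([1.0, 2.0, 3.0]), 1.0)
        v = phase_velocity(np.array([0.3, 1.0, 2.0]), 0.0, c, Forcing(2.0, 0.0))
        np.testing.assert_allclose(v, c.natural_frequencies)

    def test_aligned_phases_return_omega(self, five_node_circuit):
        f = Forcing(tempo=0.0, relative_strength=2.0, initial_phase=1.0)
        v = phase_velocity(np.full(5, 1.0), 0.0, five_node_circuit, f)
        np.testing.assert_allclose(v, five_node_circuit.natural_frequencies, atol=1e-12)

    def test_two_node_hand_evaluation(self):
        c = Circuit(2, np.array([[0, 1], [1, 0]]), np.array([1.5, 2.5]), 1.0)
        v = phase_velocity(np.array([0.0, np.pi / 2]), 0.0, c, Forcing(2.0, 0.0))
        np.testing.assert_allclose(v, [1.5 + 0.5 * np.sin(np.pi / 2), 2.5 + 0.5 * np.sin(-np.pi / 2)])

    def test_length_mismatch(self, five_node_circuit):
        with pytest.raises(ValueError):
            phase_velocity(np.zeros(4), 0.0, five_node_circuit, Forcing())


class TestIntegrate:
    def test_uncoupled_matches_analytic_rotation(self):
        omega = np.array([1.0, 2.0, 3.0])
        theta0 = np.array([0.1, 0.2, 0.3])
        c = Circuit(3, np.zeros((3, 3)), omega, 0.0)
        cfg = IntegrationConfig(dt=1e-3, duration=10.0, transient=0.0, seed=0)
        tr = integrate(c, Forcing(2.0, 0.0), cfg, initial_phases=theta0)
        expected = np.mod(theta0 + omega * 10.0, TWO_PI)
        assert np.abs(tr.phases[-1] - expected).max() < 1e-6

    def test_rk4_step_halving(self, five_node_circuit, resonant_forcing):
        theta0 = np.linspace(0.0, 5.0, 5)
        finals = []
        for dt in (2e-3, 1e-3):
            cfg = IntegrationConfig(dt=dt, duration=5.0, transient=0.0, seed=0)
            tr = integrate(five_node_circuit, resonant_forcing, cfg, initial_phases=theta0)
            finals.append(tr.phases[-1])
        diff = np.abs(np.angle(np.exp(1j * (finals[0] - finals[1])))).max()
        assert diff < 1e-5

    def test_matches_adaptive_reference(self, five_node_circuit, resonant_forcing):
        theta0 = np.linspace(0.5, 4.5, 5)
        cfg = IntegrationConfig(dt=1e-3, duration=10.0, transient=0.0, seed=0)
        tr = integrate(five_node_circuit, resonant_forcing, cfg, initial_phases=theta0)

        def rhs(t, y):
            return phase_velocity(np.mod(y, TWO_PI), t, five_node_circuit, resonant_forcing)

        ref = solve_ivp(rhs, (0.0, 10.0), theta0, method="DOP853", rtol=1e-11, atol=1e-11)
        err = np.abs(np.angle(np.exp(1j * (tr.phases[-1] - ref.y[:, -1])))).max()
        assert err < 1e-4

    def test_identical_oscillators_lock_to_strong_resonant_forcing(self):
        # spread 0, forcing at the common tempo: with K_ext = 5 the circuit
        # entrains almost perfectly
        omega = np.full(5, TWO_PI * 2.0)
        c = Circuit(5, np.zeros((5, 5)), omega, 1.0)
        cfg = IntegrationConfig(dt=1e-3, duration=20.0, transient=10.0, seed=4)
        tr = integrate(c, Forcing(tempo=2.0, relative_strength=5.0), cfg)
        assert mean_order(tr, 10.0) > 0.95

    def test_order_series_bounded(self, five_node_circuit, fast_config):
        for kext in (0.0, 1.0, 4.0):
            tr = integrate(five_node_circuit, Forcing(1.3, kext), fast_config)
            assert np.all(tr.order_series >= 0.0)
            assert np.all(tr.order_series <= 1.0)

    def test_phase_shift_equivariance(self, five_node_circuit):
        # shifting all initial phases and the forcing phase by a constant
        # is a pure rotation of the frame: R(t) is unchanged
        theta0 = np.linspace(0.2, 5.8, 5)
        shift = 1.234
        cfg = IntegrationConfig(dt=1e-3, duration=2.0, transient=0.0, seed=0)
        t1 = integrate(
            five_node_circuit, Forcing(2.0, 1.0, initial_phase=0.0), cfg, initial_phases=theta0
        )
        t2 = integrate(
            five_node_circuit,
            Forcing(2.0, 1.0, initial_phase=shift),
            cfg,
            initial_phases=theta0 + shift,
        )
        assert np.abs(t1.order_series - t2.order_series).max() < 1e-10

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            IntegrationConfig(dt=2.0, duration=1.0)

    def test_trajectory_csv_roundtrip(self, five_node_circuit, fast_config, tmp_path):
        import pandas as pd

        tr = integrate(five_node_circuit, Forcing(2.0, 1.0), fast_config)
        path = tmp_path / "traj.csv"
        tr.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["time_s"] + [f"phase_{i}" for i in range(5)] + [
            "forcing_phase",
            "R",
        ]
        np.testing.assert_allclose(df["R"].to_numpy(), tr.order_series)


class TestOrderParameter:
    def test_perfect_sync(self):
        assert order_parameter(np.full(7, 2.2)) == pytest.approx(1.0)

    def test_balanced_configuration(self):
        phases = np.arange(6) * TWO_PI / 6
        assert order_parameter(phases) < 1e-12

    def test_two_phase_hand_value(self):
        assert order_parameter(np.array([0.0, np.pi / 2])) == pytest.approx(np.sqrt(2) / 2)

    def test_forcing_node_changes_divisor(self):
        phases = np.zeros(5)
        # forcing anti-phase: (5 - 1) / 6
        assert order_parameter(phases, include_forcing=True, ext_phase=np.pi) == pytest.approx(
            4.0 / 6.0
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            order_parameter(np.array([]))


class TestMeanOrder:
    def test_constant_series(self, five_node_circuit, fast_config):
        tr = integrate(five_node_circuit, Forcing(2.0, 0.0), fast_config)
        object.__setattr__(tr, "order_series", np.full_like(tr.order_series, 0.4))
        assert mean_order(tr, 1.0) == pytest.approx(0.4)

    def test_tail_average_matches_manual(self, five_node_circuit, fast_config):
        tr = integrate(five_node_circuit, Forcing(2.0, 1.0), fast_config)
        manual = tr.order_series[tr.times >= 2.0].mean()
        assert mean_order(tr, 2.0) == pytest.approx(manual, abs=1e-12)

    def test_transient_beyond_duration_rejected(self, five_node_circuit, fast_config):
        tr = integrate(five_node_circuit, Forcing(2.0, 1.0), fast_config)
        with pytest.raises(ValueError):
            mean_order(tr, 100.0)


def test_subcritical_design_finite_size_check():
    """At N=200, K = 0.9 K_c stays well below the partial sync of K = 1.5 K_c."""
    rng = np.random.default_rng(5)
    n = 200
    spec = NaturalFrequencySpec(2.0, 0.5)
    omega = rng.normal(spec.mean_angular, spec.spread_angular, n)
    phases = rng.uniform(0.0, TWO_PI, n)
    adj = to_adjacency(complete_digraph(n))
    kc = critical_coupling(spec.spread_angular)
    cfg = IntegrationConfig(dt=2e-3, duration=20.0, transient=10.0, seed=5)
    quiet = Forcing(tempo=0.0, relative_strength=0.0)
    r_sub = batch_mean_order(adj, omega[None], 0.9 * kc, quiet, cfg, phases[None],
                             include_forcing=False)[0]
    r_sup = batch_mean_order(adj, omega[None], 1.5 * kc, quiet, cfg, phases[None],
                             include_forcing=False)[0]
    assert r_sup - r_sub > 0.2


def test_batch_integrator_agrees_with_single(five_node_circuit, resonant_forcing, fast_config):
    """The vectorized batch R̄ equals the per-trajectory computation."""
    theta0 = np.linspace(0.1, 6.0, 5)
    tr = integrate(five_node_circuit, resonant_forcing, fast_config, initial_phases=theta0)
    r_single = mean_order(tr, fast_config.transient)
    r_batch = batch_mean_order(
        five_node_circuit.adjacency,
        five_node_circuit.natural_frequencies[None],
        five_node_circuit.coupling,
        resonant_forcing,
        fast_config,
        theta0[None],
    )[0]
    assert r_batch == pytest.approx(r_single, abs=1e-12)
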