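import numpy as np
import pytest

from sfnet.bifurcation import network_fixed_point, network_rhs
from sfnet.connectome import ConnectomeVariant, make_variants
from sfnet.dynamics import (
    SimulationConfig,
    SimulationError,
    WCParameters,
    coupling_strength,
    firing_rate,
    simulate,
)
from sfnet.netmodel import LayerMatrix, strength

from conftest import random_layer

STEADY_PQ = (0.0, -1.0)  # unique stable fixed point of the uncoupled node
OSC_PQ = (-2.0, -5.0)  # unique unstable fixed point -> limit cycle


class TestFiringRate:
    def test_midpoint(self):
        assert firing_rate(0.0) == 0.5

    def test_symmetry(self, rng):
        x = rng.normal(size=20) * 5
        np.testing.assert_allclose(firing_rate(x), 1.0 - firing_rate(-x))

    def test_closed_form_value(self):
        assert firing_rate(2.0) == pytest.approx(1.0 / (1.0 + np.exp(-2.0)))

    def test_saturates_without_overflow(self):
        assert firing_rate(1e6) == 1.0
        assert firing_rate(-1e6) < 1e-200


class TestCouplingStrength:
    def test_weighted_variants_unity(self, sc_variants):
        assert coupling_strength(sc_variants["weighted"]) == 1.0
        assert coupling_strength(sc_variants["weighted-topological"]) == 1.0

    def test_binary_k4_inverse_mean_degree(self):
        k4 = LayerMatrix(1.0 - np.eye(4))
        assert coupling_strength(
            ConnectomeVariant("binary", k4, 0.5)
        ) == pytest.approx(1 / 3)

    def test_binary_synthetic_inverse_mean_degree(self, sc_variants):
        binary = sc_variants["binary"]
        expected = 1.0 / strength(binary.matrix).mean()
        assert coupling_strength(binary) == pytest.approx(expected, abs=1e-12)


def _short_config(**kw):
    defaults = dict(total_time=50.0, dt=0.01, burn_in=10.0, seed=3)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestSimulate:
    def test_identical_seeds_bitwise_identical(self, sc_variants):
        layer = sc_variants["weighted"].matrix
        params = WCParameters(P=-2.0, Q=-5.0)
        t1 = simulate(layer, params, _short_config())
        t2 = simulate(layer, params, _short_config())
        assert np.array_equal(t1.u, t2.u)
        assert np.array_equal(t1.v, t2.v)

    def test_epsilon_zero_decouples(self, rng):
        """Network run with eps=0 equals N independent single-node runs."""
        n = 6
        layer = random_layer(rng, n, density=0.8)
        params = WCParameters(P=-2.0, Q=-5.0, epsilon=0.0)
        init = rng.random(2 * n)
        cfg = _short_config(noise_sigma=0.0, initial_state=init)
        net = simulate(layer, params, cfg)
        for i in range(n):
            single_init = np.array([init[i], init[n + i]])
            single = simulate(
                np.zeros((1, 1)), params,
                _short_config(noise_sigma=0.0, initial_state=single_init),
            )
            np.testing.assert_array_equal(net.u[i], single.u[0])
            np.testing.assert_array_equal(net.v[i], single.v[0])

    def test_converges_to_root_solved_fixed_point(self):
        params = WCParameters(P=STEADY_PQ[0], Q=STEADY_PQ[1], epsilon=0.0)
        fp = network_fixed_point(np.zeros((1, 1)), params, np.array([0.5, 0.5]))
        assert fp.converged
        traj = simulate(
            np.zeros((1, 1)), params,
            SimulationConfig(total_time=200.0, dt=0.01, burn_in=0.0,
                            noise_sigma=0.0, seed=0),
        )
        final = np.array([traj.u[0, -1], traj.v[0, -1]])
        assert np.abs(final - fp.x).max() < 1e-6

    def test_sustained_oscillation_in_unstable_regime(self):
        params = WCParameters(P=OSC_PQ[0], Q=OSC_PQ[1], epsilon=0.0)
        fp = network_fixed_point(np.zeros((1, 1)), params, np.array([0.5, 0.5]))
        assert fp.converged and fp.residual < 1e-10
        # the (unique) fixed point is linearly unstable here
        from sfnet.bifurcation import network_jacobian

        eigs = np.linalg.eigvals(network_jacobian(fp.x, np.zeros((1, 1)), params))
        assert eigs.real.max() > 0
        traj = simulate(
            np.zeros((1, 1)), params,
            SimulationConfig(total_time=1000.0, dt=0.01, burn_in=0.0,
                            noise_sigma=0.0, seed=1),
        )
        late = traj.u[0, traj.times > 500]
        assert late.max() - late.min() > 0.1  # non-decaying rhythm

    def test_state_bounded_after_transient(self, sc_variants):
        layer = sc_variants["weighted"].matrix
        traj = simulate(
            layer, WCParameters(P=-2.0, Q=-5.0),
            _short_config(noise_sigma=0.0),
        )
        late = traj.times > 10
        for arr in (traj.u[:, late], traj.v[:, late]):
            assert arr.min() > 0.0 and arr.max() < 1.0

    def test_euler_first_order_convergence(self):
        """Halving dt roughly halves the endpoint error (order-1 scheme)."""
        params = WCParameters(P=0.0, Q=-1.0, epsilon=0.0)
        init = np.array([0.3, 0.7])

        def endpoint(dt):
            traj = simulate(
                np.zeros((1, 1)), params,
                SimulationConfig(total_time=10.0, dt=dt, burn_in=0.0,
                                noise_sigma=0.0, seed=0, stride=1,
                                initial_state=init),
            )
            return np.array([traj.u[0, -1], traj.v[0, -1]])

        ref = endpoint(0.00125)
        e1 = np.abs(endpoint(0.02) - ref).max()
        e2 = np.abs(endpoint(0.01) - ref).max()
        assert 1.5 < e1 / e2 < 3.0

    def test_noise_increment_scaling(self):
        """Variance of (increment - drift) matches the configured amplitude."""
        n = 4
        layer = LayerMatrix(np.zeros((n, n)))
        params = WCParameters(P=0.0, Q=-1.0, epsilon=0.0)
        cfg = SimulationConfig(total_time=50.0, dt=0.01, burn_in=0.0,
                               noise_sigma=0.01, seed=9, stride=1)
        traj = simulate(layer, params, cfg)
        states = np.vstack([traj.u, traj.v])  # (2n, T)
        resid = []
        for t in range(states.shape[1] - 1):
            drift = network_rhs(states[:, t], layer.weights, params)
            step = states[:, t + 1] - states[:, t] - cfg.dt * drift
            resid.append(step[:n])  # noise enters u only
        resid = np.concatenate(resid)
        assert np.var(resid) == pytest.approx(cfg.noise_amplitude**2, rel=0.05)
        # v receives no noise at all
        v_resid = [
            states[n:, t + 1] - states[n:, t]
            - cfg.dt * network_rhs(states[:, t], layer.weights, params)[n:]
            for t in range(states.shape[1] - 1)
        ]
        assert np.abs(np.concatenate(v_resid)).max() < 1e-12

    def test_noise_conventions_differ_tenfold(self):
        amp_a = SimulationConfig(noise_convention="per-step-sd").noise_amplitude
        amp_b = SimulationConfig(noise_convention="intensity").noise_amplitude
        assert amp_b == pytest.approx(10 * amp_a)

    def test_non_finite_state_reports_step(self):
        bad_init = np.full(2, np.nan)
        with pytest.raises(SimulationError, match="step 1"):
            simulate(
                np.zeros((1, 1)), WCParameters(),
                _short_config(initial_state=bad_init),
            )

    def test_config_validation(self):
        with pytest.raises(ValueError, match="burn_in"):
            SimulationConfig(total_time=10.0, burn_in=10.0)
        with pytest.raises(ValueError, match="dt"):
            SimulationConfig(dt=0.0)
        with pytest.raises(ValueError, match="noise_convention"):
            SimulationConfig(noise_convention="bogus")
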