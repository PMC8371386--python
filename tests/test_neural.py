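import numpy as np
import pytest

from ionode.mech import RateParams, gate_rhs, gate_steady_state
from ionode.neural import (
    NetworkSpec,
    NeuralGateModel,
    OptimiserConfig,
    init_weights,
    load_model,
    network_forward,
    nn_discrepancy_rhs,
    nn_full_rhs,
    nn_rates_rhs,
    nn_steady_state,
    save_model,
    train_network,
    zero_network_model,
)
from ionode.state_space import TrainingSet

ACT = RateParams(2.26e-4, 0.0699, 3.45e-5, -0.05462)


def grid_training_set(params, n_a=30, n_v=25, v_range=(-120.0, 50.0)):
    """Noise-free tuples sampled from a mechanistic gate RHS on a grid."""
    a, v = np.meshgrid(np.linspace(0, 1, n_a), np.linspace(*v_range, n_v))
    a, v = a.ravel(), v.ravel()
    return TrainingSet(a, v, gate_rhs(a, v, params))


class TestNetworkForward:
    def test_zero_weights_zero_output(self):
        spec = NetworkSpec(hidden=(8, 8))
        w = [(np.zeros((i, o)), np.zeros(o))
             for i, o in zip(spec.layer_sizes[:-1], spec.layer_sizes[1:])]
        out = network_forward(np.array([[0.3, -0.5]]), w, spec)
        assert np.array_equal(out, np.zeros((1, 1)))

    def test_hand_computed_single_node(self):
        # one hidden node: y = leaky_relu(x1); input 2 -> 2, input -2 -> -0.02
        spec = NetworkSpec(hidden=(1,))
        w = [(np.array([[1.0], [0.0]]), np.zeros(1)),
             (np.array([[1.0]]), np.zeros(1))]
        assert network_forward([[2.0, 99.0]], w, spec)[0, 0] == pytest.approx(2.0)
        assert network_forward([[-2.0, -7.0]], w, spec)[0, 0] == pytest.approx(-0.02)

    def test_output_layer_linearity(self):
        spec = NetworkSpec(hidden=(6,))
        w = init_weights(spec, 3)
        x = np.array([[0.4, -0.7]])
        y1 = network_forward(x, w, spec)
        w2 = list(w)
        W, b = w2[-1]
        w2[-1] = (3.0 * W, 3.0 * b)
        assert network_forward(x, w2, spec) == pytest.approx(3.0 * y1)

    def test_shape_mismatch_rejected(self):
        spec = NetworkSpec(hidden=(4,))
        w = init_weights(spec, 0)
        with pytest.raises(ValueError):
            network_forward(np.ones((2, 3)), w, spec)


class TestModes:
    def test_zero_network_discrepancy_equals_candidate(self):
        model = zero_network_model(mode="discrepancy", candidate=ACT)
        a = np.linspace(0, 1, 11)
        for V in (-100.0, -40.0, 20.0):
            assert np.array_equal(nn_discrepancy_rhs(a, V, model),
                                  gate_rhs(a, V, ACT))

    def test_zero_network_full_is_frozen_gate(self):
        model = zero_network_model(mode="full")
        assert nn_full_rhs(0.3, -50.0, model) == 0.0

    def test_wrong_mode_rejected(self):
        model = zero_network_model(mode="full")
        with pytest.raises(ValueError):
            nn_discrepancy_rhs(0.5, 0.0, model)
        with pytest.raises(ValueError):
            nn_rates_rhs(0.5, 0.0, model)

    def test_missing_candidate_rejected(self):
        spec = NetworkSpec(hidden=(4,))
        with pytest.raises(ValueError):
            NeuralGateModel(spec=spec, weights=init_weights(spec, 0),
                            mode="discrepancy")

    def test_rates_mode_boundary_values(self):
        model = zero_network_model(mode="rates")
        V = -30.0
        # softplus(0) rates: alpha = beta, affine in a
        alpha = nn_rates_rhs(0.0, V, model)
        beta = -nn_rates_rhs(1.0, V, model)
        assert alpha > 0 and beta > 0
        mid = nn_rates_rhs(0.5, V, model)
        assert mid == pytest.approx(alpha * 0.5 - beta * 0.5)

    def test_rates_mode_affine_in_state(self):
        spec = NetworkSpec(n_inputs=1, n_outputs=2, hidden=(8,))
        model = NeuralGateModel(spec=spec, weights=init_weights(spec, 5),
                                mode="rates")
        V = 10.0
        a = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        vals = model.rhs(a, V)
        # second differences of an affine function vanish
        assert np.max(np.abs(np.diff(vals, 2))) < 1e-12


class TestTraining:
    def test_zero_targets_learned(self):
        rng = np.random.default_rng(0)
        ts = TrainingSet(rng.uniform(0, 1, 200), rng.uniform(-100, 40, 200),
                         np.zeros(200))
        model, report = train_network(
            ts, mode="full", spec=NetworkSpec(hidden=(8,)),
            opt=OptimiserConfig(epochs=2500, learning_rate=3e-3,
                                plateau_patience=None), seed=1,
        )
        assert report.final_loss < 1e-6

    def test_learns_mechanistic_surface(self):
        ts = grid_training_set(ACT)
        model, report = train_network(
            ts, mode="full", spec=NetworkSpec(hidden=(32, 32)),
            opt=OptimiserConfig(epochs=3000, learning_rate=3e-3,
                                plateau_patience=None), seed=2,
        )
        pred = model.rhs(ts.a, ts.v)
        rmse = np.sqrt(np.mean((pred - ts.dadt) ** 2))
        assert rmse < 1e-3  # ms^-1, vs the generating RHS on the grid

    def test_discrepancy_training_on_candidate_data_learns_nothing(self):
        # data generated by the candidate itself: the network term stays small
        ts = grid_training_set(ACT)
        model, _ = train_network(
            ts, mode="discrepancy", spec=NetworkSpec(hidden=(16,)),
            opt=OptimiserConfig(epochs=600, plateau_patience=None),
            seed=3, candidate=ACT,
        )
        net_term = np.abs(model._net_dadt(ts.a, ts.v))
        assert np.mean(net_term) < 1e-4
        assert np.max(np.abs(model.rhs(ts.a, ts.v) - ts.dadt)) < 1e-2

    def test_loss_trend_non_increasing(self):
        ts = grid_training_set(ACT, n_a=15, n_v=12)
        _, report = train_network(
            ts, mode="full", spec=NetworkSpec(hidden=(16,)),
            opt=OptimiserConfig(epochs=1500, learning_rate=3e-3,
                                plateau_patience=None), seed=4,
        )
        # smoothed trend decreases from start to finish
        k = 50
        smoothed = np.convolve(report.losses, np.ones(k) / k, mode="valid")
        assert smoothed[-1] < smoothed[0]
        assert report.losses[-1] < report.losses[0] / 10

    def test_deterministic_given_seed(self):
        ts = grid_training_set(ACT, n_a=10, n_v=8)
        opt = OptimiserConfig(epochs=50, plateau_patience=None)
        spec = NetworkSpec(hidden=(8,))
        m1, r1 = train_network(ts, "full", spec, opt, seed=7)
        m2, r2 = train_network(ts, "full", spec, opt, seed=7)
        assert np.array_equal(r1.losses, r2.losses)
        for (W1, b1), (W2, b2) in zip(m1.weights, m2.weights):
            assert np.array_equal(W1, W2) and np.array_equal(b1, b2)

    def test_empty_training_set_rejected(self):
        ts = TrainingSet(np.array([]), np.array([]), np.array([]))
        with pytest.raises(ValueError):
            train_network(ts, seed=0)


class TestSteadyState:
    def test_zero_discrepancy_matches_candidate(self):
        model = zero_network_model(mode="discrepancy", candidate=ACT)
        for V in (-80.0, -20.0, 40.0):
            assert nn_steady_state(model, V) == pytest.approx(
                gate_steady_state(V, ACT), abs=1e-9
            )

    def test_root_contract(self):
        model = zero_network_model(mode="discrepancy", candidate=ACT)
        a_inf = nn_steady_state(model, -40.0)
        assert abs(model.rhs(a_inf, -40.0)) < 1e-8

    def test_matches_long_hold(self):
        ts = grid_training_set(ACT, n_a=20, n_v=15)
        model, _ = train_network(
            ts, mode="full", spec=NetworkSpec(hidden=(16, 16)),
            opt=OptimiserConfig(epochs=1500, learning_rate=3e-3,
                                plateau_patience=None), seed=6,
        )
        from scipy.integrate import solve_ivp

        # hERG activation is slow; hold long enough to be well past 5 tau
        V = -20.0
        a_inf = nn_steady_state(model, V)
        sol = solve_ivp(lambda t, y: [model.rhs(y[0], V)], (0, 60000.0),
                        [0.5], atol=1e-10, rtol=1e-10)
        assert a_inf == pytest.approx(sol.y[0, -1], abs=1e-4)


class TestCheckpointing:
    def _trained(self):
        ts = grid_training_set(ACT, n_a=8, n_v=6)
        model, _ = train_network(
            ts, mode="discrepancy", spec=NetworkSpec(hidden=(8,)),
            opt=OptimiserConfig(epochs=30, plateau_patience=None),
            seed=9, candidate=ACT, inactivation=ACT, g=1.0,
        )
        return model

    def test_round_trip_bitwise(self, tmp_path):
        model = self._trained()
        path = tmp_path / "ckpt.json"
        save_model(model, path)
        back = load_model(path)
        a = np.linspace(0, 1, 7)
        assert np.array_equal(back.rhs(a, -55.0), model.rhs(a, -55.0))
        assert back.mode == model.mode and back.scaling == model.scaling
        assert back.candidate == model.candidate

    def test_truncated_file_rejected(self, tmp_path):
        model = self._trained()
        path = tmp_path / "ckpt.json"
        save_model(model, path)
        path.write_text(path.read_text()[: path.stat().st_size // 2])
        with pytest.raises(ValueError):
            load_model(path)

    def test_version_mismatch_rejected(self, tmp_path):
        path = tmp_path / "ckpt.json"
        path.write_text('{"format_version": 99}')
        with pytest.raises(ValueError, match="version"):
            load_model(path)
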