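import numpy as np
import pytest

from ionode.mech import gate_rhs
from ionode.protocols import StepProtocol, make_activation_protocol, make_deactivation_protocol
from ionode.simulate import SimulationConfig, add_noise, simulate_current, simulate_states
from ionode.state_space import (
    TrainingSet,
    build_training_set,
    estimate_gate_from_trace,
    fit_segment_splines,
    integrate_r_gate,
    read_training_set,
    recover_activation,
    write_training_set,
)


@pytest.fixture(scope="module")
def tight_cfg():
    # near-exact integration, so algebraic identities are tested rather
    # than solver error
    return SimulationConfig(abs_tol=1e-11, rel_tol=1e-10)


@pytest.fixture(scope="module")
def clean_pair(candidate, E_rev, tight_cfg):
    """Noise-free activation/deactivation traces from the candidate model."""
    out = []
    for p in (make_activation_protocol(), make_deactivation_protocol()):
        out.append((simulate_current(candidate, p, tight_cfg, E=E_rev), p))
    return out


class TestRecoverActivation:
    def test_noise_free_inversion_exact(self, candidate, E_rev, tight_cfg, clean_pair):
        trace, p = clean_pair[0]
        r, _ = integrate_r_gate(p, candidate.inactivation, tight_cfg)
        a_est, valid = recover_activation(trace, p, candidate.g, E_rev, r)
        a_true = simulate_states(candidate, p, tight_cfg)["a"]
        assert valid.sum() > 0.8 * len(valid)
        assert np.max(np.abs(a_est[valid] - a_true[valid])) < 1e-6

    def test_sample_at_reversal_masked(self, candidate, E_rev, sim_cfg):
        p = StepProtocol(((100.0, -80.0), (100.0, E_rev), (100.0, 0.0)))
        trace = simulate_current(candidate, p, sim_cfg, E=E_rev)
        r, _ = integrate_r_gate(p, candidate.inactivation, sim_cfg)
        _, valid = recover_activation(trace, p, candidate.g, E_rev, r)
        at_E = (trace.times >= 100.0) & (trace.times < 200.0)
        assert not valid[at_E].any()

    def test_homogeneity_in_conductance(self, candidate, E_rev, tight_cfg, clean_pair):
        trace, p = clean_pair[0]
        r, _ = integrate_r_gate(p, candidate.inactivation, tight_cfg)
        a1, v1 = recover_activation(trace, p, candidate.g, E_rev, r)
        scaled = type(trace)(trace.times, 3.0 * trace.currents, trace.voltages, p)
        a2, v2 = recover_activation(scaled, p, 3.0 * candidate.g, E_rev, r)
        assert np.array_equal(v1, v2)
        assert np.allclose(a1[v1], a2[v2], rtol=1e-12)


class TestSegmentSplines:
    def test_interpolating_spline_reproduces_samples(self, clean_pair):
        trace, p = clean_pair[0]
        I_s, _, ok = fit_segment_splines(trace, p, smoothing=0.0)
        assert np.max(np.abs(I_s[ok] - trace.currents[ok])) < 1e-9

    def test_derivative_matches_analytic(self, candidate, E_rev, sim_cfg):
        # single tail segment: dI/dt has a closed form via the gate ODEs
        p = StepProtocol(((500.0, -80.0), (1000.0, 40.0), (2000.0, -50.0)))
        trace = simulate_current(candidate, p, sim_cfg, E=E_rev)
        _, dIdt, ok = fit_segment_splines(trace, p, smoothing=0.0)
        st = simulate_states(candidate, p, sim_cfg)
        a, r = st["a"], st["r"]
        v = trace.voltages
        dIdt_true = candidate.g * (v - E_rev) * (
            gate_rhs(a, v, candidate.activation) * r
            + a * gate_rhs(r, v, candidate.inactivation)
        )
        sel = ok & (st.times > 1010) & (st.times < 1990)  # interior of tail
        rel = np.abs(dIdt[sel] - dIdt_true[sel]) / np.max(np.abs(dIdt_true[sel]))
        assert np.max(rel) < 1e-3

    def test_segments_do_not_share_samples(self, clean_pair):
        trace, p = clean_pair[0]
        # interpolating splines would be discontinuous across boundaries if
        # they shared samples; check exactness right up to each boundary
        I_s, _, ok = fit_segment_splines(trace, p, smoothing=0.0)
        assert np.max(np.abs(I_s[ok] - trace.currents[ok])) < 1e-9

    def test_short_segment_skipped(self, candidate, E_rev, sim_cfg):
        p = StepProtocol(((500.0, -80.0), (3.0, 40.0), (500.0, -50.0)))
        trace = simulate_current(candidate, p, sim_cfg, E=E_rev)
        _, _, ok = fit_segment_splines(trace, p, smoothing=0.0)
        in_short = (trace.times >= 500.0) & (trace.times < 503.0)
        assert not ok[in_short].any()


class TestDerivativeEstimation:
    def test_round_trip_noise_free(self, candidate, E_rev, tight_cfg, clean_pair):
        """Noise-free recovery reproduces the generating (a, da/dt) surface."""
        for trace, p in clean_pair:
            est = estimate_gate_from_trace(
                trace, p, candidate.g, E_rev, candidate.inactivation, tight_cfg,
                smoothing=0.0, edge_trim=3,
            )
            st = simulate_states(candidate, p, tight_cfg)
            a_true = st["a"]
            dadt_true = gate_rhs(a_true, est.voltages, candidate.activation)
            m = est.valid
            assert np.sqrt(np.mean((est.a[m] - a_true[m]) ** 2)) < 1e-3
            assert np.sqrt(np.mean((est.dadt[m] - dadt_true[m]) ** 2)) < 1e-3

    def test_steady_state_limit(self, candidate, E_rev, sim_cfg):
        # long hold at constant V: dI/dt -> 0 and dr/dt -> 0, so da/dt -> 0
        p = StepProtocol(((20000.0, 0.0),), holding=0.0)
        trace = simulate_current(candidate, p, sim_cfg, E=E_rev)
        est = estimate_gate_from_trace(
            trace, p, candidate.g, E_rev, candidate.inactivation, sim_cfg,
            smoothing=0.0,
        )
        late = est.valid & (est.times > 15000.0)
        assert np.max(np.abs(est.dadt[late])) < 1e-6

    def test_noise_monotonicity(self, candidate, E_rev, sim_cfg):
        """More observation noise never improves the recovered surface."""
        p = StepProtocol(((500.0, -80.0), (1500.0, 40.0), (1500.0, -50.0)))
        clean = simulate_current(candidate, p, sim_cfg, E=E_rev)
        st = simulate_states(candidate, p, sim_cfg)
        dadt_true = gate_rhs(st["a"], clean.voltages, candidate.activation)

        def rmse(sd):
            vals = []
            for seed in (1, 2, 3):
                noisy = add_noise(clean, sd, seed)
                est = estimate_gate_from_trace(
                    noisy, p, candidate.g, E_rev, candidate.inactivation,
                    sim_cfg, v_min=10.0,
                )
                m = est.valid
                vals.append(np.sqrt(np.mean((est.dadt[m] - dadt_true[m]) ** 2)))
            return np.mean(vals)

        errs = [rmse(sd) for sd in (0.0, 0.05, 0.2)]
        assert errs[0] <= errs[1] <= errs[2]


class TestTrainingSet:
    def test_scaling_arithmetic(self):
        ts = TrainingSet(np.array([0.5]), np.array([-80.0]), np.array([0.02]))
        assert ts.a_scaled[0] == 0.5
        assert ts.v_scaled[0] == pytest.approx(-0.8)
        assert ts.dadt_scaled[0] == pytest.approx(20.0)

    def test_unscale_round_trip(self):
        rng = np.random.default_rng(0)
        ts = TrainingSet(rng.uniform(0, 1, 10), rng.uniform(-120, 60, 10),
                         rng.normal(0, 1e-3, 10))
        a, v, d = ts.unscale(ts.a_scaled, ts.v_scaled, ts.dadt_scaled)
        assert np.allclose(a, ts.a, rtol=1e-15)
        assert np.allclose(v, ts.v, rtol=1e-15)
        assert np.allclose(d, ts.dadt, rtol=1e-15)

    def test_masked_samples_excluded(self, candidate, E_rev, sim_cfg, clean_pair):
        trace, p = clean_pair[0]
        est = estimate_gate_from_trace(
            trace, p, candidate.g, E_rev, candidate.inactivation, sim_cfg,
            smoothing=0.0,
        )
        ts = build_training_set(est)
        assert len(ts) == est.valid.sum()
        assert np.all(np.isfinite(ts.dadt))

    def test_empty_input_rejected(self):
        from ionode.state_space import GateEstimate

        empty = GateEstimate(np.arange(3.0), np.zeros(3), np.zeros(3),
                             np.zeros(3), np.zeros(3, dtype=bool))
        with pytest.raises(ValueError):
            build_training_set(empty)

    def test_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        ts = TrainingSet(rng.uniform(0, 1, 20), rng.uniform(-120, 60, 20),
                         rng.normal(0, 1e-3, 20))
        path = tmp_path / "train.csv"
        write_training_set(ts, path)
        back = read_training_set(path)
        assert np.allclose(back.a, ts.a, atol=1e-12)
        assert np.allclose(back.dadt, ts.dadt, atol=1e-15)
        assert back.scaling == ts.scaling
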