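"""Simulation of gate dynamics and whole-cell currents over voltage protocols.

Integration uses the adaptive explicit Runge-Kutta 4(5) pair of
Dormand-Prince (scipy's ``RK45``) with default tolerances atol=1e-6,
rtol=1e-8, restarted at every voltage-step discontinuity so the adaptive
stepper never straddles a jump in the driving term.

For two-state Hodgkin-Huxley gates on piecewise-constant protocols an exact
closed-form propagator is also provided (``simulate_current_analytic``);
it is used as the fast inner loop of candidate-model fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .mech import (
    HHModelParams,
    InvalidParameterError,
    NernstConfig,
    ThreeStateParams,
    gate_rhs,
    gate_steady_state,
    gate_time_constant,
    nernst_potential,
    three_state_steady_state,
)
from .protocols import (
    Protocol,
    ProtocolError,
    SampledProtocol,
    StepProtocol,
    step_boundaries,
    voltage_at,
)


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the failure time."""

    def __init__(self, message: str, t_fail: float | None = None):
        super().__init__(message)
        self.t_fail = t_fail


@dataclass(frozen=True)
class SimulationConfig:
    """Solver and sampling settings.

    ``abs_tol``/``rel_tol`` are the adaptive-stepper tolerances; ``dt`` the
    output sampling interval in ms; ``max_step_sampled`` caps the solver
    step on sampled (time-varying) protocols so no waveform feature is
    skipped.
    """

    abs_tol: float = 1e-6
    rel_tol: float = 1e-8
    dt: float = 1.0
    max_step_sampled: float = 1.0

    def __post_init__(self) -> None:
        if self.abs_tol <= 0 or self.rel_tol <= 0:
            raise InvalidParameterError("solver tolerances must be positive")
        if self.dt <= 0:
            raise InvalidParameterError("sampling interval must be positive")


@dataclass(frozen=True)
class StateTrace:
    """Sampled gate-state trajectories: ``states[i]`` is the i-th state's series."""

    times: np.ndarray
    states: np.ndarray  # shape (n_states, n_times)
    names: tuple[str, ...]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[self.names.index(name)]


@dataclass(frozen=True)
class CurrentTrace:
    """Sampled current (nA) with its time stamps (ms) and voltages (mV)."""

    times: np.ndarray
    currents: np.ndarray
    voltages: np.ndarray
    protocol: Protocol | None = None

    def __post_init__(self) -> None:
        for arr in (self.times, self.currents, self.voltages):
            if np.asarray(arr).shape != np.asarray(self.times).shape:
                raise ValueError("times/currents/voltages must share a shape")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("time stamps must be strictly increasing")
        if not np.all(np.isfinite(self.currents)):
            raise ValueError("currents must be finite")


def sample_times(protocol: Protocol, cfg: SimulationConfig) -> np.ndarray:
    """Uniform output grid 0, dt, 2dt, ... covering the protocol."""
    if isinstance(protocol, SampledProtocol):
        T = protocol.times[-1]
    else:
        T = protocol.total_duration
    return np.arange(0.0, T + cfg.dt / 2, cfg.dt)


def _discontinuities(protocol: Protocol) -> np.ndarray:
    if isinstance(protocol, StepProtocol):
        return step_boundaries(protocol)
    # Sampled waveforms: treat sample-to-sample jumps > 20 mV as steps.
    dv = np.abs(np.diff(protocol.voltages))
    return protocol.times[1:][dv > 20.0]


def integrate_gates(rhs, protocol: Protocol, init, cfg: SimulationConfig,
                    names: tuple[str, ...] | None = None) -> StateTrace:
    """Integrate ``dx/dt = rhs(x, V(t))`` over the protocol.

    The integration is restarted at every voltage discontinuity and the
    dense solution is sampled on the uniform output grid.  ``rhs`` maps a
    state vector and a scalar voltage to the state derivative.
    """
    init = np.atleast_1d(np.asarray(init, dtype=float))
    ts_out = sample_times(protocol, cfg)
    if isinstance(protocol, StepProtocol) and protocol.total_duration <= 0:
        raise ProtocolError("zero total duration")

    bounds = _discontinuities(protocol)
    T = ts_out[-1]
    knots = np.concatenate([[0.0], bounds[(bounds > 0) & (bounds < T)], [T]])
    knots = np.unique(knots)

    is_step = isinstance(protocol, StepProtocol)
    out = np.empty((len(init), len(ts_out)))
    y = init.copy()
    for t0, t1 in zip(knots[:-1], knots[1:]):
        if is_step:
            V_seg = voltage_at(protocol, t0)  # constant within [t0, t1)

            def fun(t, x, V=V_seg):
                return rhs(x, V)

            max_step = np.inf
        else:
            def fun(t, x):
                return rhs(x, voltage_at(protocol, min(t, T)))

            max_step = cfg.max_step_sampled
        # Half-open convention: sample at t1 belongs to the next segment but
        # the state is continuous, so evaluating at t1 from the left is exact.
        sel = (ts_out >= t0) & (ts_out <= t1) if t1 == knots[-1] else (
            (ts_out >= t0) & (ts_out < t1)
        )
        t_eval = np.concatenate([ts_out[sel], [t1]])
        t_eval = np.unique(t_eval)
        sol = solve_ivp(
            fun, (t0, t1), y, method="RK45", t_eval=t_eval,
            atol=cfg.abs_tol, rtol=cfg.rel_tol, max_step=max_step,
        )
        if not sol.success:
            raise IntegrationError(f"solver failed: {sol.message}", t_fail=t0)
        lookup = {t: i for i, t in enumerate(sol.t)}
        for t in ts_out[sel]:
            out[:, np.searchsorted(ts_out, t)] = sol.y[:, lookup[t]]
        y = sol.y[:, -1]
    if names is None:
        names = tuple(f"x{i}" for i in range(len(init)))
    return StateTrace(ts_out, out, names)


# ---------------------------------------------------------------------------
# Channel models
# ---------------------------------------------------------------------------


def _channel_parts(model):
    """Return (rhs, names, open_fn, r_index) for a simulable channel model."""
    if isinstance(model, HHModelParams):
        def rhs(x, V):
            return np.array(
                [gate_rhs(x[0], V, model.activation),
                 gate_rhs(x[1], V, model.inactivation)]
            )
        return rhs, ("a", "r"), (lambda x: x[0]), model.g
    if isinstance(model, ThreeStateParams):
        def rhs(x, V):
            ds = model.rate_matrix(V) @ x[:3]
            dr = gate_rhs(x[3], V, model.inactivation)
            return np.concatenate([ds, [dr]])
        return rhs, ("c1", "c2", "o", "r"), (lambda x: x[2]), model.g
    # NeuralGateModel (duck-typed to avoid a circular import)
    if hasattr(model, "rhs") and hasattr(model, "inactivation"):
        def rhs(x, V):
            return np.array(
                [model.rhs(x[0], V),
                 gate_rhs(x[1], V, model.inactivation)]
            )
        return rhs, ("a", "r"), (lambda x: x[0]), model.g
    raise TypeError(f"not a simulable channel model: {type(model)!r}")


def steady_state_init(model, V_hold: float) -> np.ndarray:
    """Model state at equilibrium for a fixed holding voltage.

    Analytic for mechanistic gates; for neural gates the activation
    equilibrium is found by root bracketing (see ``neural.nn_steady_state``).
    """
    if isinstance(model, HHModelParams):
        return np.array(
            [gate_steady_state(V_hold, model.activation),
             gate_steady_state(V_hold, model.inactivation)]
        )
    if isinstance(model, ThreeStateParams):
        s = three_state_steady_state(V_hold, model)
        return np.concatenate([s, [gate_steady_state(V_hold, model.inactivation)]])
    if hasattr(model, "steady_state"):
        return np.array(
            [model.steady_state(V_hold),
             gate_steady_state(V_hold, model.inactivation)]
        )
    raise TypeError(f"not a simulable channel model: {type(model)!r}")


def simulate_states(model, protocol: Protocol, cfg: SimulationConfig = SimulationConfig()) -> StateTrace:
    """Integrate all gates of ``model`` from steady state at the holding voltage."""
    rhs, names, _, _ = _channel_parts(model)
    init = steady_state_init(model, protocol.holding)
    return integrate_gates(rhs, protocol, init, cfg, names=names)


def simulate_current(model, protocol: Protocol,
                     cfg: SimulationConfig = SimulationConfig(),
                     E: float | None = None) -> CurrentTrace:
    """Simulate the Ohmic whole-cell current I = g * a * r * (V - E).

    Gates start from steady state at the protocol's holding voltage.  The
    activation and inactivation gates are independent; only their product
    enters the current.
    """
    if E is None:
        E = nernst_potential(NernstConfig())
    _, names, open_fn, g = _channel_parts(model)
    st = simulate_states(model, protocol, cfg)
    a = open_fn(st.states)
    r = st["r"]
    v = voltage_at(protocol, st.times)
    return CurrentTrace(st.times, g * a * r * (v - E), v, protocol=protocol)


def simulate_current_analytic(model: HHModelParams, protocol: StepProtocol,
                              cfg: SimulationConfig = SimulationConfig(),
                              E: float | None = None,
                              times: np.ndarray | None = None) -> CurrentTrace:
    """Exact HH-gate simulation on a step protocol via per-segment closed form.

    Within each constant-voltage segment each gate relaxes as
    ``x_inf + (x0 - x_inf) exp(-t/tau)``; chaining segments by continuity
    gives the exact solution, with no solver error.  Used as the fitting
    inner loop.
    """
    if not isinstance(protocol, StepProtocol):
        raise TypeError("analytic simulation requires a step protocol")
    if E is None:
        E = nernst_potential(NernstConfig())
    ts_out = sample_times(protocol, cfg) if times is None else np.asarray(times, float)
    starts = protocol.segment_starts()
    edges = np.concatenate([starts, [protocol.total_duration]])
    a = gate_steady_state(protocol.holding, model.activation)
    r = gate_steady_state(protocol.holding, model.inactivation)
    out_a = np.empty_like(ts_out)
    out_r = np.empty_like(ts_out)
    for i, (t0, t1) in enumerate(zip(edges[:-1], edges[1:])):
        V = protocol.voltages[i]
        last = i == len(protocol.segments) - 1
        sel = (ts_out >= t0) & ((ts_out <= t1) if last else (ts_out < t1))
        dt_local = ts_out[sel] - t0
        for p, x0, out in (
            (model.activation, a, out_a),
            (model.inactivation, r, out_r),
        ):
            x_inf = gate_steady_state(V, p)
            tau = gate_time_constant(V, p)
            out[sel] = x_inf + (x0 - x_inf) * np.exp(-dt_local / tau)
        dt_seg = t1 - t0
        a = gate_steady_state(V, model.activation) + (
            a - gate_steady_state(V, model.activation)
        ) * np.exp(-dt_seg / gate_time_constant(V, model.activation))
        r = gate_steady_state(V, model.inactivation) + (
            r - gate_steady_state(V, model.inactivation)
        ) * np.exp(-dt_seg / gate_time_constant(V, model.inactivation))
    v = voltage_at(protocol, ts_out)
    return CurrentTrace(ts_out, model.g * out_a * out_r * (v - E), v, protocol=protocol)


# ---------------------------------------------------------------------------
# Observation model and masking
# ---------------------------------------------------------------------------


def add_noise(trace: CurrentTrace, sd: float, seed) -> CurrentTrace:
    """Add i.i.d. Gaussian observation noise (mean 0, SD ``sd`` nA).

    Accepts an integer seed or a ``numpy.random.Generator``.  Noise is
    applied to currents only, never to states.
    """
    if sd < 0:
        raise InvalidParameterError("noise SD must be non-negative")
    if sd == 0:
        return trace
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noisy = trace.currents + rng.normal(0.0, sd, size=trace.currents.shape)
    return replace(trace, currents=noisy)


def capacitance_mask(trace: CurrentTrace, protocol: Protocol,
                     blank_ms: float = 5.0) -> np.ndarray:
    """Boolean mask that is False in the first ``blank_ms`` after each step.

    Emulates removal of capacitive-transient samples: for every voltage
    discontinuity at t_b, samples with t in [t_b, t_b + blank_ms) are
    excluded.
    """
    if blank_ms < 0:
        raise InvalidParameterError("blank_ms must be non-negative")
    mask = np.ones(len(trace.times), dtype=bool)
    if blank_ms == 0:
        return mask
    for tb in _discontinuities(protocol):
        mask &= ~((trace.times >= tb) & (trace.times < tb + blank_ms))
    return mask


# ---------------------------------------------------------------------------
# Trace CSV I/O
# ---------------------------------------------------------------------------


def write_trace_csv(trace: CurrentTrace, path: str | Path) -> None:
    pd.DataFrame(
        {"time_ms": trace.times, "voltage_mV": trace.voltages,
         "current_nA": trace.currents}
    ).to_csv(path, index=False)


def read_trace_csv(path: str | Path, protocol: Protocol | None = None) -> CurrentTrace:
    df = pd.read_csv(path)
    missing = {"time_ms", "voltage_mV", "current_nA"} - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV missing columns: {sorted(missing)}")
    return CurrentTrace(
        df["time_ms"].to_numpy(dtype=float),
        df["current_nA"].to_numpy(dtype=float),
        df["voltage_mV"].to_numpy(dtype=float),
        protocol=protocol,
    )
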