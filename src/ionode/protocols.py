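"""Voltage-clamp protocols: step protocols, sampled waveforms, and surrogates.

A protocol is the control signal V(t) of a voltage-clamp experiment.  Step
protocols are ordered (duration, voltage) segments under a half-open
[start, end) convention: the voltage at a step discontinuity belongs to the
new segment.  Sampled protocols are arbitrary waveforms given at strictly
increasing time stamps and linearly interpolated in between.

The ``pr3_like`` / ``pr4_like`` / ``pr5_like`` / ``sinusoidal_like`` /
``ap_like`` generators are parameterised surrogates for the classical hERG
characterisation protocols (activation steady-state, inactivation,
deactivation, sinusoidal and action-potential waveforms).  Genuine archived
waveforms can be loaded from CSV instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class ProtocolError(ValueError):
    """Raised for malformed protocols or out-of-range queries."""


@dataclass(frozen=True)
class StepProtocol:
    """Piecewise-constant voltage protocol.

    ``segments`` is an ordered tuple of (duration_ms, voltage_mV) pairs;
    ``holding`` is the pre-protocol holding voltage used for the initial
    condition.
    """

    segments: tuple[tuple[float, float], ...]
    holding: float = -80.0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ProtocolError("protocol needs at least one segment")
        for i, (dur, v) in enumerate(self.segments):
            if not (dur > 0):
                raise ProtocolError(f"segment {i}: duration must be positive")
            if not np.isfinite(v):
                raise ProtocolError(f"segment {i}: voltage must be finite")

    @property
    def total_duration(self) -> float:
        return float(sum(d for d, _ in self.segments))

    @property
    def durations(self) -> np.ndarray:
        return np.array([d for d, _ in self.segments])

    @property
    def voltages(self) -> np.ndarray:
        return np.array([v for _, v in self.segments])

    def segment_starts(self) -> np.ndarray:
        """Start time of every segment, including t=0."""
        return np.concatenate([[0.0], np.cumsum(self.durations)[:-1]])


@dataclass(frozen=True)
class SampledProtocol:
    """Voltage waveform sampled at strictly increasing time stamps (ms)."""

    times: np.ndarray
    voltages: np.ndarray
    holding: float = -80.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.voltages, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise ProtocolError("times and voltages must be equal-length 1-D arrays")
        if len(t) < 2:
            raise ProtocolError("sampled protocol needs at least two samples")
        if not np.all(np.diff(t) > 0):
            raise ProtocolError("time stamps must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise ProtocolError("times and voltages must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "voltages", v)

    @property
    def total_duration(self) -> float:
        return float(self.times[-1] - self.times[0])


Protocol = StepProtocol | SampledProtocol


def voltage_at(p: Protocol, t):
    """Voltage of protocol ``p`` at time(s) ``t`` (ms from protocol start).

    Step protocols use the half-open [start, end) segment convention;
    sampled protocols interpolate linearly.  Times outside [0, T] raise.
    """
    t_arr = np.asarray(t, dtype=float)
    scalar = t_arr.ndim == 0
    t_arr = np.atleast_1d(t_arr)
    if isinstance(p, StepProtocol):
        T = p.total_duration
        if np.any(t_arr < 0) or np.any(t_arr > T):
            raise ProtocolError("time outside protocol range")
        edges = np.cumsum(p.durations)
        # side='right': t exactly at a boundary belongs to the next segment
        idx = np.searchsorted(edges, t_arr, side="right")
        idx = np.minimum(idx, len(p.segments) - 1)  # t == T maps to last segment
        out = p.voltages[idx]
    else:
        if np.any(t_arr < p.times[0]) or np.any(t_arr > p.times[-1]):
            raise ProtocolError("time outside protocol range")
        out = np.interp(t_arr, p.times, p.voltages)
    return float(out[0]) if scalar else out


def step_boundaries(p: StepProtocol) -> np.ndarray:
    """Times of step discontinuities: cumulative segment starts excluding 0."""
    return np.cumsum(p.durations)[:-1]


def make_activation_protocol(
    test_voltages=(-60.0, -40.0, -20.0, 0.0, 20.0, 40.0),
    hold: float = -80.0,
    durations: tuple[float, float, float] = (500.0, 3000.0, 3000.0),
    deactivation_voltage: float = -40.0,
) -> StepProtocol:
    """Activation steady-state ("pr3-like") surrogate.

    One unit per test voltage: hold -> long activating test step ->
    deactivating tail step, sweeping the test voltages.  Probes activation
    kinetics and steady state over the upper region of (a, V) space.
    """
    if not len(test_voltages):
        raise ProtocolError("need at least one test voltage")
    d_hold, d_test, d_tail = durations
    segs: list[tuple[float, float]] = []
    for v in test_voltages:
        segs += [(d_hold, hold), (d_test, float(v)), (d_tail, deactivation_voltage)]
    return StepProtocol(tuple(segs), holding=hold)


def make_deactivation_protocol(
    tail_voltages=(-120.0, -100.0, -80.0, -60.0, -40.0),
    hold: float = -80.0,
    act_step: tuple[float, float] = (2000.0, 40.0),
    tail_duration: float = 4000.0,
) -> StepProtocol:
    """Deactivation ("pr5-like") surrogate.

    One unit per tail voltage: hold -> fixed strong activating step ->
    long swept tail.  Trajectories traverse the decaying-activation branch
    at low voltages, complementing the activation protocol's coverage.
    """
    if not len(tail_voltages):
        raise ProtocolError("need at least one tail voltage")
    d_act, v_act = act_step
    segs: list[tuple[float, float]] = []
    for v in tail_voltages:
        segs += [(500.0, hold), (d_act, v_act), (tail_duration, float(v))]
    return StepProtocol(tuple(segs), holding=hold)


def make_inactivation_protocol(
    test_voltages=(-120.0, -100.0, -80.0, -60.0, -40.0),
    hold: float = -80.0,
    act_step: tuple[float, float] = (1000.0, 40.0),
    test_duration: float = 50.0,
    post_voltage: float = -40.0,
    post_duration: float = 500.0,
) -> StepProtocol:
    """Inactivation ("pr4-like") surrogate.

    Each unit activates the channel fully, then probes inactivation
    recovery with a brief swept step, then rests briefly at a mild
    deactivating voltage.  Low-voltage excursions are short, so the
    (low V, decaying a) region is barely visited — the coverage gap that
    makes this a poor training companion for deactivation prediction.
    """
    if not len(test_voltages):
        raise ProtocolError("need at least one test voltage")
    d_act, v_act = act_step
    segs: list[tuple[float, float]] = []
    for v in test_voltages:
        segs += [
            (500.0, hold),
            (d_act, v_act),
            (test_duration, float(v)),
            (post_duration, post_voltage),
        ]
    return StepProtocol(tuple(segs), holding=hold)


def make_sinusoidal_protocol(
    hold: float = -80.0,
    dt: float = 1.0,
    amplitude_mV: tuple[float, float, float] = (54.0, 26.0, 10.0),
    omega_per_ms: tuple[float, float, float] = (0.007, 0.037, 0.19),
    centre_mV: float = -30.0,
    sine_duration: float = 5000.0,
) -> SampledProtocol:
    """Condensed sinusoidal ("pr7-like") surrogate.

    A brief activating step followed by a sum of three sinusoids around a
    depolarised centre, then a deactivating step.  Explores fast dynamics
    over a narrower slice of (a, V) space than the step protocols.
    """
    segs = [(250.0, hold), (500.0, 20.0), (500.0, -50.0)]
    t_pre = sum(d for d, _ in segs)
    t = np.arange(0.0, t_pre + sine_duration + 1000.0 + dt / 2, dt)
    v = np.full_like(t, hold)
    start = 0.0
    for d, vv in segs:
        v[(t >= start) & (t < start + d)] = vv
        start += d
    in_sine = (t >= t_pre) & (t < t_pre + sine_duration)
    ts = t[in_sine] - t_pre
    v[in_sine] = centre_mV + sum(
        a * np.sin(w * ts) for a, w in zip(amplitude_mV, omega_per_ms)
    )
    v[t >= t_pre + sine_duration] = -50.0
    v[t >= t_pre + sine_duration + 500.0] = hold
    return SampledProtocol(t, v, holding=hold)


def make_ap_protocol(
    hold: float = -80.0,
    dt: float = 1.0,
    peaks_mV=(40.0, 30.0, 20.0, 40.0, 10.0),
    repolarisation_tau_ms: float = 120.0,
    ap_duration: float = 500.0,
    gap_duration: float = 500.0,
) -> SampledProtocol:
    """Series of action-potential-like waveforms ("pr6-like") surrogate.

    Each beat is an instantaneous upstroke to its peak followed by a smooth
    exponential repolarisation back toward the holding level.
    """
    total = 500.0 + len(peaks_mV) * (ap_duration + gap_duration)
    t = np.arange(0.0, total + dt / 2, dt)
    v = np.full_like(t, hold)
    start = 500.0
    for peak in peaks_mV:
        in_ap = (t >= start) & (t < start + ap_duration)
        ts = t[in_ap] - start
        v[in_ap] = hold + (peak - hold) * np.exp(-ts / repolarisation_tau_ms)
        start += ap_duration + gap_duration
    return SampledProtocol(t, v, holding=hold)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def write_protocol_csv(p: Protocol, path: str | Path) -> None:
    """Write a protocol to CSV.

    Step protocols use columns (duration_ms, voltage_mV); sampled protocols
    use (time_ms, voltage_mV).  A ``# holding_mV=...`` comment line records
    the holding voltage.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# holding_mV={p.holding}\n")
        if isinstance(p, StepProtocol):
            pd.DataFrame(
                {"duration_ms": p.durations, "voltage_mV": p.voltages}
            ).to_csv(fh, index=False)
        else:
            pd.DataFrame(
                {"time_ms": p.times, "voltage_mV": p.voltages}
            ).to_csv(fh, index=False)


def read_protocol_csv(path: str | Path) -> Protocol:
    """Read a protocol written by :func:`write_protocol_csv`.

    The column header determines the protocol kind.  Malformed tables raise
    :class:`ProtocolError` naming the offending row.
    """
    path = Path(path)
    holding = -80.0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# holding_mV="):
            holding = float(first.split("=", 1)[1])
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    cols = set(df.columns)
    if {"duration_ms", "voltage_mV"} <= cols:
        for i, dur in enumerate(df["duration_ms"]):
            if not dur > 0:
                raise ProtocolError(f"row {i}: non-positive duration")
        return StepProtocol(
            tuple(zip(df["duration_ms"].astype(float), df["voltage_mV"].astype(float))),
            holding=holding,
        )
    if {"time_ms", "voltage_mV"} <= cols:
        t = df["time_ms"].to_numpy(dtype=float)
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            raise ProtocolError(f"row {bad[0] + 1}: non-increasing time stamp")
        return SampledProtocol(t, df["voltage_mV"].to_numpy(dtype=float), holding=holding)
    raise ProtocolError(f"unrecognised protocol columns: {sorted(cols)}")
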