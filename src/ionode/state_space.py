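"""State-space estimation: from measured currents to (a, V, da/dt) tuples.

The activation gate a cannot be observed directly in a voltage-clamp
experiment; only the current I = g * a * r * (V - E) is recorded.  Given a
trusted model of the fast inactivation gate r, the activation state is
recovered algebraically,

    a = I / (g * r * (V - E)),

and its time derivative follows from the product rule applied to the
current expression at constant voltage,

    da/dt = (1/r) * ( (dI/dt) / (g * (V - E)) - a * dr/dt ),

where dI/dt is estimated by a univariate smoothing cubic spline fitted
separately on each constant-voltage step (so step discontinuities in I are
never smoothed over) and dr/dt comes from the trusted r-gate model.

The resulting (a, V, da/dt) tuples, scaled to O(1), are the training data
for the neural gate models.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import UnivariateSpline

from .mech import InvalidParameterError, RateParams, gate_rhs, gate_steady_state
from .protocols import Protocol, SampledProtocol, StepProtocol, voltage_at
from .simulate import (
    CurrentTrace,
    SimulationConfig,
    capacitance_mask,
    integrate_gates,
    sample_times,
)

log = logging.getLogger(__name__)

#: Scaling divisors for (a, V, da/dt): voltages in mV and derivatives of
#: order 1e-3 ms^-1 both become O(1) after a -> a, V -> V/100,
#: da/dt -> da/dt * 1000.
DEFAULT_SCALING = (1.0, 100.0, 1e-3)


@dataclass(frozen=True)
class GateEstimate:
    """Pointwise activation estimate with a validity mask.

    Estimates are never clipped to [0, 1]; samples where the algebraic
    inversion is near-singular (V close to E, or r close to zero) are
    flagged invalid instead.
    """

    times: np.ndarray
    a: np.ndarray
    dadt: np.ndarray
    voltages: np.ndarray
    valid: np.ndarray


@dataclass(frozen=True)
class TrainingSet:
    """Scaled (a, V, da/dt) regression tuples with their scaling constants.

    ``scaling`` holds the divisors (s_a, s_V, s_dadt); scaled variables are
    a/s_a, V/s_V, dadt/s_dadt.
    """

    a: np.ndarray
    v: np.ndarray
    dadt: np.ndarray
    scaling: tuple[float, float, float] = DEFAULT_SCALING

    def __len__(self) -> int:
        return len(self.a)

    @property
    def a_scaled(self) -> np.ndarray:
        return self.a / self.scaling[0]

    @property
    def v_scaled(self) -> np.ndarray:
        return self.v / self.scaling[1]

    @property
    def dadt_scaled(self) -> np.ndarray:
        return self.dadt / self.scaling[2]

    def unscale(self, a_s, v_s, dadt_s):
        """Invert the scaling: recover physical (a, V mV, da/dt ms^-1)."""
        return (np.asarray(a_s) * self.scaling[0],
                np.asarray(v_s) * self.scaling[1],
                np.asarray(dadt_s) * self.scaling[2])


def integrate_r_gate(protocol: Protocol, r_model: RateParams,
                     cfg: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Trusted inactivation trajectory r(t) and its analytic derivative dr/dt."""
    st = integrate_gates(
        lambda x, V: np.atleast_1d(gate_rhs(x[0], V, r_model)),
        protocol,
        [gate_steady_state(protocol.holding, r_model)],
        cfg,
        names=("r",),
    )
    r = st.states[0]
    v = voltage_at(protocol, st.times)
    return r, gate_rhs(r, v, r_model)


def recover_activation(trace: CurrentTrace, protocol: Protocol, g: float,
                       E: float, r: np.ndarray,
                       v_min: float = 1.0, r_min: float = 1e-3) -> tuple[np.ndarray, np.ndarray]:
    """Algebraic inversion a = I / (g r (V - E)) with singularity guards.

    Returns (a_estimate, valid_mask).  Samples with |V - E| < ``v_min`` or
    r < ``r_min`` are masked invalid because the denominator amplifies
    noise without bound there.
    """
    if g <= 0:
        raise InvalidParameterError("conductance g must be positive")
    v = voltage_at(protocol, trace.times)
    denom = g * r * (v - E)
    valid = (np.abs(v - E) >= v_min) & (r >= r_min)
    a = np.full_like(trace.currents, np.nan)
    a[valid] = trace.currents[valid] / denom[valid]
    return a, valid


def _segment_slices(times: np.ndarray, protocol: Protocol) -> list[np.ndarray]:
    """Index arrays grouping samples by constant-voltage segment."""
    if isinstance(protocol, StepProtocol):
        edges = np.concatenate([[0.0], np.cumsum(protocol.durations)])
    else:
        dv = np.abs(np.diff(protocol.voltages))
        jumps = protocol.times[1:][dv > 20.0]
        edges = np.concatenate([[times[0]], jumps, [times[-1] + 1.0]])
    out = []
    for t0, t1 in zip(edges[:-1], edges[1:]):
        last = t1 == edges[-1]
        sel = (times >= t0) & ((times <= t1) if last else (times < t1))
        out.append(np.nonzero(sel)[0])
    return out


def estimate_noise_sd(currents: np.ndarray) -> float:
    """Robust noise-SD estimate from first differences (MAD-based).

    For a smooth signal plus white noise the first differences are
    dominated by noise with SD sqrt(2) times the observation SD.
    """
    d = np.diff(currents)
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0))


def fit_segment_splines(trace: CurrentTrace, protocol: Protocol,
                        smoothing: float | None = None,
                        blank_ms: float = 0.0,
                        min_samples: int = 5):
    """Per-segment smoothing cubic splines of the current and its derivative.

    One spline is fitted to each constant-voltage segment (never across a
    step discontinuity), using only samples outside the capacitance blanking
    window.  ``smoothing=None`` ties the spline smoothing factor to
    n_samples * sigma_hat^2 with sigma_hat a robust noise estimate;
    ``smoothing=0`` interpolates exactly.

    Returns per-sample arrays (I_smooth, dIdt, spline_valid): samples in
    skipped (too short) or blanked regions are flagged invalid.
    """
    mask = capacitance_mask(trace, protocol, blank_ms)
    I_s = np.full_like(trace.currents, np.nan)
    dIdt = np.full_like(trace.currents, np.nan)
    ok = np.zeros(len(trace.times), dtype=bool)
    for idx in _segment_slices(trace.times, protocol):
        use = idx[mask[idx]]
        if len(use) < min_samples:
            if len(idx):
                log.warning("segment with %d usable samples skipped", len(use))
            continue
        t = trace.times[use]
        y = trace.currents[use]
        if smoothing is None:
            sd = estimate_noise_sd(y)
            s = len(use) * sd**2
        else:
            s = smoothing
        spl = UnivariateSpline(t, y, k=3, s=s)
        I_s[use] = spl(t)
        dIdt[use] = spl.derivative()(t)
        ok[use] = True
    return I_s, dIdt, ok


def estimate_activation_derivative(a: np.ndarray, r: np.ndarray,
                                   drdt: np.ndarray, dIdt: np.ndarray,
                                   v: np.ndarray, g: float, E: float,
                                   valid: np.ndarray) -> np.ndarray:
    """Product-rule inversion for da/dt on constant-voltage segments.

    With one activation and one inactivation gate (both to the first power)
    and dV/dt = 0 inside a segment:

        da/dt = (1/r) * ( dI/dt / (g (V - E)) - a * dr/dt ).

    Invalid samples propagate as NaN.
    """
    dadt = np.full_like(a, np.nan)
    m = valid & np.isfinite(dIdt)
    dadt[m] = (dIdt[m] / (g * (v[m] - E)) - a[m] * drdt[m]) / r[m]
    return dadt


def estimate_gate_from_trace(trace: CurrentTrace, protocol: Protocol,
                             g: float, E: float, r_model: RateParams,
                             cfg: SimulationConfig = SimulationConfig(),
                             smoothing: float | None = None,
                             blank_ms: float = 0.0,
                             edge_trim: int = 2,
                             v_min: float = 1.0, r_min: float = 1e-3) -> GateEstimate:
    """Full state-space estimation pipeline for one trace.

    Integrates the trusted r gate, smooths the current per segment,
    algebraically recovers a from the smoothed current, and inverts the
    product rule for da/dt.  ``edge_trim`` additionally invalidates that
    many samples at each end of every segment, where spline derivatives
    are least reliable.
    """
    r, drdt = integrate_r_gate(protocol, r_model, cfg)
    I_s, dIdt, spline_ok = fit_segment_splines(
        trace, protocol, smoothing=smoothing, blank_ms=blank_ms
    )
    smooth_trace = CurrentTrace(
        trace.times, np.where(np.isfinite(I_s), I_s, 0.0), trace.voltages,
        protocol=protocol,
    )
    a, inv_ok = recover_activation(
        smooth_trace, protocol, g, E, r, v_min=v_min, r_min=r_min
    )
    v = voltage_at(protocol, trace.times)
    valid = inv_ok & spline_ok
    if edge_trim > 0:
        for idx in _segment_slices(trace.times, protocol):
            if len(idx) > 2 * edge_trim:
                valid[idx[:edge_trim]] = False
                valid[idx[-edge_trim:]] = False
            else:
                valid[idx] = False
    dadt = estimate_activation_derivative(a, r, drdt, dIdt, v, g, E, valid)
    valid = valid & np.isfinite(dadt)
    return GateEstimate(trace.times, a, dadt, v, valid)


def build_training_set(estimates, scaling: tuple[float, float, float] = DEFAULT_SCALING,
                       subsample: int = 1) -> TrainingSet:
    """Concatenate valid samples from one or more gate estimates.

    Masked samples are dropped; ``subsample`` keeps every n-th valid
    sample (training protocols are densely sampled relative to the gate
    time constants).
    """
    if isinstance(estimates, GateEstimate):
        estimates = [estimates]
    a_parts, v_parts, d_parts = [], [], []
    for est in estimates:
        m = est.valid
        a_parts.append(est.a[m][::subsample])
        v_parts.append(est.voltages[m][::subsample])
        d_parts.append(est.dadt[m][::subsample])
    a = np.concatenate(a_parts) if a_parts else np.array([])
    if len(a) == 0:
        raise ValueError("no valid samples to build a training set from")
    return TrainingSet(a, np.concatenate(v_parts), np.concatenate(d_parts),
                       scaling=scaling)


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------


def write_training_set(ts: TrainingSet, csv_path: str | Path) -> None:
    """Write tuples to CSV plus a JSON sidecar holding the scaling constants."""
    csv_path = Path(csv_path)
    pd.DataFrame(
        {"a": ts.a, "v_mV": ts.v, "dadt_per_ms": ts.dadt,
         "a_scaled": ts.a_scaled, "v_scaled": ts.v_scaled,
         "dadt_scaled": ts.dadt_scaled}
    ).to_csv(csv_path, index=False)
    sidecar = csv_path.with_suffix(".json")
    with open(sidecar, "w") as fh:
        json.dump({"scaling_a": ts.scaling[0], "scaling_v_mV": ts.scaling[1],
                   "scaling_dadt_per_ms": ts.scaling[2],
                   "n_samples": len(ts)}, fh, indent=2)


def read_training_set(csv_path: str | Path) -> TrainingSet:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    sidecar = csv_path.with_suffix(".json")
    scaling = DEFAULT_SCALING
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
        scaling = (meta["scaling_a"], meta["scaling_v_mV"],
                   meta["scaling_dadt_per_ms"])
    return TrainingSet(df["a"].to_numpy(float), df["v_mV"].to_numpy(float),
                       df["dadt_per_ms"].to_numpy(float), scaling=scaling)
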