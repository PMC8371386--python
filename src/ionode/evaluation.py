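"""Model evaluation: error tables and state-space coverage diagnostics.

Neural gates are interpolators, not extrapolators: predictions are only
trustworthy inside the (a, V) region visited by the training trajectories.
The coverage map / extrapolation-fraction tools quantify how much of a
prediction trajectory falls outside that region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .protocols import Protocol, voltage_at
from .simulate import CurrentTrace, SimulationConfig, simulate_states, _channel_parts

log = logging.getLogger(__name__)


def mean_absolute_error(pred: CurrentTrace, data: CurrentTrace,
                        mask: np.ndarray | None = None) -> float:
    """Mean |prediction - data| in nA over unmasked samples.

    Traces must share time stamps exactly; this is the summary statistic of
    the model-comparison tables.
    """
    if len(pred.times) != len(data.times) or not np.allclose(
        pred.times, data.times, rtol=0, atol=1e-9
    ):
        raise ValueError("traces are not aligned on the same time stamps")
    err = np.abs(pred.currents - data.currents)
    if mask is not None:
        err = err[mask]
    return float(np.mean(err))


def state_space_trajectory(model, protocol: Protocol,
                           cfg: SimulationConfig = SimulationConfig()) -> np.ndarray:
    """Simulated (a, V) points visited over a protocol, shape (n, 2)."""
    _, names, open_fn, _ = _channel_parts(model)
    st = simulate_states(model, protocol, cfg)
    a = open_fn(st.states)
    v = voltage_at(protocol, st.times)
    return np.column_stack([a, v])


@dataclass(frozen=True)
class CoverageMap:
    """Occupancy histogram over the (a, V) plane."""

    counts: np.ndarray  # shape (n_a_bins, n_v_bins)
    a_edges: np.ndarray
    v_edges: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def occupied(self) -> np.ndarray:
        return self.counts > 0


DEFAULT_A_RANGE = (0.0, 1.0)
DEFAULT_V_RANGE = (-140.0, 60.0)


def coverage_map(trajectories, n_a_bins: int = 50, n_v_bins: int = 50,
                 a_range=DEFAULT_A_RANGE, v_range=DEFAULT_V_RANGE) -> CoverageMap:
    """Histogram the visited (a, V) points of one or more trajectories.

    Points outside the grid ranges are clipped into the edge bins so the
    total count equals the number of samples.
    """
    if isinstance(trajectories, np.ndarray):
        trajectories = [trajectories]
    pts = np.vstack(list(trajectories))
    if len(pts) == 0:
        raise ValueError("no trajectory points")
    a = np.clip(pts[:, 0], a_range[0], a_range[1])
    v = np.clip(pts[:, 1], v_range[0], v_range[1])
    counts, a_edges, v_edges = np.histogram2d(
        a, v, bins=[n_a_bins, n_v_bins], range=[a_range, v_range]
    )
    return CoverageMap(counts, a_edges, v_edges)


def extrapolation_fraction(prediction: np.ndarray, training: CoverageMap,
                           radius: int = 1, warn_above: float | None = 0.2) -> float:
    """Fraction of prediction points outside the trained region.

    A point counts as extrapolating when every training-coverage bin within
    ``radius`` bins (Chebyshev) of its own bin is empty.  Values above
    ``warn_above`` trigger a logged warning.
    """
    occ = training.occupied()
    if radius > 0:
        padded = np.zeros(
            (occ.shape[0] + 2 * radius, occ.shape[1] + 2 * radius), dtype=bool
        )
        padded[radius:-radius, radius:-radius] = occ
        grown = np.zeros_like(occ)
        for di in range(-radius, radius + 1):
            for dj in range(-radius, radius + 1):
                grown |= padded[
                    radius + di: radius + di + occ.shape[0],
                    radius + dj: radius + dj + occ.shape[1],
                ]
        occ = grown
    a = np.clip(prediction[:, 0], training.a_edges[0], training.a_edges[-1])
    v = np.clip(prediction[:, 1], training.v_edges[0], training.v_edges[-1])
    ia = np.clip(np.searchsorted(training.a_edges, a, side="right") - 1,
                 0, occ.shape[0] - 1)
    iv = np.clip(np.searchsorted(training.v_edges, v, side="right") - 1,
                 0, occ.shape[1] - 1)
    frac = float(np.mean(~occ[ia, iv]))
    if warn_above is not None and frac > warn_above:
        log.warning(
            "prediction extrapolates: %.1f%% of points outside the trained "
            "state-space region", 100 * frac,
        )
    return frac
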