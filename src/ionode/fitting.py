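"""Least-squares fitting of the candidate Hodgkin-Huxley model to currents.

The candidate model has 8 kinetic parameters (four exponential-rate
constants per gate) plus the maximal conductance g.  Rate prefactors A are
fitted on a log10 scale (they span orders of magnitude and must stay
positive); voltage sensitivities B are fitted untransformed.  The fit
minimises the sum of squared residuals between the simulated and measured
currents over one or more protocols, with seeded multi-start local
optimisation (scipy ``least_squares`` with bounds).

For piecewise-constant protocols the exact closed-form gate propagator is
used as the simulation inner loop, so objective evaluations are cheap and
carry no solver error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .mech import HHModelParams, NernstConfig, RateParams, nernst_potential
from .protocols import StepProtocol
from .simulate import CurrentTrace, SimulationConfig, simulate_current_analytic

log = logging.getLogger(__name__)

#: Bounds on A (ms^-1, log10) and B (mV^-1): common hERG-fitting practice.
A_BOUNDS = (1e-7, 1e3)
B_BOUNDS = (-1.0, 1.0)
G_BOUNDS = (1e-3, 1e3)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a candidate-model fit."""

    params: HHModelParams
    objective: float
    start_objectives: tuple[float, ...]
    seed: int
    n_starts: int
    success: bool


def _pack(p: HHModelParams) -> np.ndarray:
    a, r = p.activation, p.inactivation
    return np.array([
        np.log10(a.A_alpha), a.B_alpha, np.log10(a.A_beta), a.B_beta,
        np.log10(r.A_alpha), r.B_alpha, np.log10(r.A_beta), r.B_beta,
        np.log10(p.g),
    ])


def _unpack(x: np.ndarray) -> HHModelParams:
    return HHModelParams(
        g=10.0 ** x[8],
        activation=RateParams(10.0 ** x[0], x[1], 10.0 ** x[2], x[3]),
        inactivation=RateParams(10.0 ** x[4], x[5], 10.0 ** x[6], x[7]),
    )


def _bounds() -> tuple[np.ndarray, np.ndarray]:
    loA, hiA = np.log10(A_BOUNDS[0]), np.log10(A_BOUNDS[1])
    loB, hiB = B_BOUNDS
    loG, hiG = np.log10(G_BOUNDS[0]), np.log10(G_BOUNDS[1])
    lo = np.array([loA, loB, loA, loB, loA, loB, loA, loB, loG])
    hi = np.array([hiA, hiB, hiA, hiB, hiA, hiB, hiA, hiB, hiG])
    return lo, hi


def fit_candidate_model(traces, protocols, init: HHModelParams,
                        seed: int = 0, n_starts: int = 3,
                        masks=None, E: float | None = None,
                        cfg: SimulationConfig = SimulationConfig(),
                        perturb_scale: float = 0.1) -> FitResult:
    """Fit the 8 kinetic parameters and conductance to one or more traces.

    ``traces``/``protocols``/``masks`` are parallel sequences; masks select
    the samples entering the residual (e.g. capacitance-blanked).  The
    first start is the supplied initial guess; the remaining starts perturb
    it by seeded Gaussian jitter in the transformed space.  Returns the
    best of all converged starts.
    """
    if isinstance(traces, CurrentTrace):
        traces = [traces]
        protocols = [protocols]
    if masks is None:
        masks = [np.ones(len(t.times), dtype=bool) for t in traces]
    if E is None:
        E = nernst_potential(NernstConfig())
    for p in protocols:
        if not isinstance(p, StepProtocol):
            raise TypeError("candidate fitting supports step protocols only")

    lo, hi = _bounds()
    x0 = np.clip(_pack(init), lo, hi)

    def residuals(x: np.ndarray) -> np.ndarray:
        model = _unpack(x)
        parts = []
        for trace, protocol, mask in zip(traces, protocols, masks):
            sim = simulate_current_analytic(model, protocol, cfg, E=E,
                                            times=trace.times)
            parts.append((sim.currents - trace.currents)[mask])
        return np.concatenate(parts)

    rng = np.random.default_rng(seed)
    starts = [x0]
    for _ in range(n_starts - 1):
        starts.append(np.clip(x0 + rng.normal(0, perturb_scale, size=x0.shape),
                              lo, hi))

    best = None
    start_objs = []
    any_success = False
    for i, s in enumerate(starts):
        try:
            res = least_squares(residuals, s, bounds=(lo, hi), method="trf",
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception as e:  # pragma: no cover - solver blow-up
            log.warning("start %d failed: %s", i, e)
            continue
        obj = float(np.sum(res.fun**2))
        start_objs.append(obj)
        any_success = True
        if best is None or obj < best[0]:
            best = (obj, res.x)
    if not any_success or best is None:
        raise RuntimeError(
            f"candidate fit failed: none of {n_starts} starts converged"
        )
    obj0 = float(np.sum(residuals(x0) ** 2))
    if best[0] > obj0:
        # Never return something worse than the initial guess.
        best = (obj0, x0)
    return FitResult(params=_unpack(best[1]), objective=best[0],
                     start_objectives=tuple(start_objs), seed=seed,
                     n_starts=n_starts, success=True)
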