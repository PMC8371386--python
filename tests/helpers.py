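"""Shared test oracles, independent of the library code paths they check."""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares


def closed_form_gate(times, protocol, p, holding):
    """Exact HH-gate solution on a step protocol: per-segment exponentials.

    x(t) = x_inf + (x0 - x_inf) exp(-(t - t0)/tau) chained by continuity.
    Independent of the package's simulators (only uses rate definitions).
    """
    alpha = lambda V: p.A_alpha * np.exp(p.B_alpha * V)
    beta = lambda V: p.A_beta * np.exp(p.B_beta * V)
    x = alpha(holding) / (alpha(holding) + beta(holding))
    durations = np.array([d for d, _ in protocol.segments])
    voltages = np.array([v for _, v in protocol.segments])
    edges = np.concatenate([[0.0], np.cumsum(durations)])
    out = np.empty_like(np.asarray(times, dtype=float))
    for i, (t0, t1) in enumerate(zip(edges[:-1], edges[1:])):
        V = voltages[i]
        last = i == len(voltages) - 1
        sel = (times >= t0) & ((times <= t1) if last else (times < t1))
        x_inf = alpha(V) / (alpha(V) + beta(V))
        tau = 1.0 / (alpha(V) + beta(V))
        out[sel] = x_inf + (x - x_inf) * np.exp(-(times[sel] - t0) / tau)
        x = x_inf + (x - x_inf) * np.exp(-(t1 - t0) / tau)
    return out


def fit_exponential_sum(t, y, n_exp, n_tau_grid=12):
    """Least-squares fit of y ~ c0 + sum_i c_i exp(-t/tau_i).

    Variable-projection: amplitudes are solved linearly for given taus, and
    only the log-taus are optimised, from a log-spaced multi-start grid.
    Returns the relative residual ||y - fit|| / ||y - mean(y)||.
    """
    t = np.asarray(t, dtype=float) - t[0]
    y = np.asarray(y, dtype=float)
    span = t[-1] - t[0]

    def design(log_taus):
        cols = [np.ones_like(t)]
        for lt in log_taus:
            cols.append(np.exp(-t / np.exp(lt)))
        return np.column_stack(cols)

    def resid(log_taus):
        A = design(log_taus)
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        return A @ coef - y

    denom = np.linalg.norm(y - y.mean())
    if denom == 0:
        return 0.0
    grid = np.log(np.geomspace(span / 300.0, 3.0 * span, n_tau_grid))
    best = np.inf
    rng = np.random.default_rng(0)
    starts = [grid[rng.choice(len(grid), n_exp, replace=False)] for _ in range(8)]
    starts += [np.sort(grid[:: max(1, len(grid) // n_exp)][:n_exp])]
    for s in starts:
        try:
            sol = least_squares(resid, np.sort(s), method="lm", max_nfev=200)
        except Exception:
            continue
        r = np.linalg.norm(sol.fun) / denom
        best = min(best, r)
    return best
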