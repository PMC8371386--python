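"""Biophysical building blocks for Hodgkin-Huxley and Markov gate models.

Units are fixed package-wide: time in ms, voltage in mV, current in nA,
conductance in uS, concentrations in mM; all transition rates in ms^-1.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

#: Ideal gas constant, J K^-1 mol^-1 (CODATA).
GAS_CONSTANT = 8.314
#: Faraday constant, C mol^-1 (CODATA).
FARADAY_CONSTANT = 96485.0


class InvalidParameterError(ValueError):
    """Raised when a model parameter violates its physical constraints."""


@dataclass(frozen=True)
class RateParams:
    """Constants of a voltage-dependent gate with exponential rates.

    The forward (opening) rate is ``alpha(V) = A_alpha * exp(B_alpha * V)``
    and the backward (closing) rate is ``beta(V) = A_beta * exp(B_beta * V)``.
    Prefactors are in ms^-1, voltage sensitivities in mV^-1.
    """

    A_alpha: float
    B_alpha: float
    A_beta: float
    B_beta: float

    def __post_init__(self) -> None:
        if self.A_alpha <= 0 or self.A_beta <= 0:
            raise InvalidParameterError(
                "rate prefactors A_alpha and A_beta must be positive"
            )

    def alpha(self, V):
        return transition_rate(V, self.A_alpha, self.B_alpha)

    def beta(self, V):
        return transition_rate(V, self.A_beta, self.B_beta)


@dataclass(frozen=True)
class HHModelParams:
    """Two-gate Hodgkin-Huxley channel: activation a, inactivation r.

    Current is I = g * a * r * (V - E).  g in uS.  8 kinetic parameters.
    """

    g: float
    activation: RateParams
    inactivation: RateParams

    def __post_init__(self) -> None:
        if self.g <= 0:
            raise InvalidParameterError("conductance g must be positive")


@dataclass(frozen=True)
class ThreeStateParams:
    """Linear three-state activation chain C1 <=> C2 <=> O.

    Each transition rate has the form A*exp(B*V).  ``c1_c2`` holds the
    C1->C2 (alpha) / C2->C1 (beta) pair and ``c2_o`` the C2->O / O->C2
    pair.  Inactivation is an independent two-state r gate shared with the
    candidate model.
    """

    g: float
    c1_c2: RateParams
    c2_o: RateParams
    inactivation: RateParams

    def __post_init__(self) -> None:
        if self.g <= 0:
            raise InvalidParameterError("conductance g must be positive")

    def rate_matrix(self, V: float) -> np.ndarray:
        """3x3 master-equation generator Q with d s/dt = Q @ s, states (C1, C2, O)."""
        k12 = self.c1_c2.alpha(V)
        k21 = self.c1_c2.beta(V)
        k23 = self.c2_o.alpha(V)
        k32 = self.c2_o.beta(V)
        return np.array(
            [
                [-k12, k21, 0.0],
                [k12, -(k21 + k23), k32],
                [0.0, k23, -k32],
            ]
        )


@dataclass(frozen=True)
class NernstConfig:
    """Ingredients of the Nernst reversal potential for a single ion species."""

    T: float = 294.55  # K
    z: int = 1
    K_out: float = 4.0  # mM
    K_in: float = 110.0  # mM

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise InvalidParameterError("temperature must be positive")
        if self.K_out <= 0 or self.K_in <= 0:
            raise InvalidParameterError("ion concentrations must be positive")


def transition_rate(V, A: float, B: float):
    """Voltage-dependent transition rate A*exp(B*V) in ms^-1."""
    if A <= 0:
        raise InvalidParameterError("rate prefactor A must be positive")
    return A * np.exp(B * np.asarray(V, dtype=float))


def gate_rhs(x, V, p: RateParams):
    """Mass-action gate kinetics: dx/dt = alpha(V)(1-x) - beta(V)x.

    ``x`` is not clipped: state-space estimates may transiently leave [0, 1].
    """
    return p.alpha(V) * (1.0 - x) - p.beta(V) * x


def gate_steady_state(V, p: RateParams):
    """Equilibrium open probability x_inf = alpha / (alpha + beta)."""
    a = p.alpha(V)
    b = p.beta(V)
    return a / (a + b)


def gate_time_constant(V, p: RateParams):
    """Relaxation time constant tau = 1 / (alpha + beta) in ms."""
    return 1.0 / (p.alpha(V) + p.beta(V))


def nernst_potential(c: NernstConfig = NernstConfig()) -> float:
    """Nernst reversal potential E = (RT/zF) ln([K]out/[K]in), in mV.

    Negative for physiological potassium gradients ([K]out < [K]in).
    """
    volts = (GAS_CONSTANT * c.T) / (c.z * FARADAY_CONSTANT) * math.log(c.K_out / c.K_in)
    return volts * 1000.0


def hh_current(a, r, V, g: float, E: float):
    """Ohmic current I = g * a * r * (V - E); uS * mV = nA."""
    if g <= 0:
        raise InvalidParameterError("conductance g must be positive")
    return g * np.asarray(a) * np.asarray(r) * (np.asarray(V) - E)


def three_state_rhs(s, V, p: ThreeStateParams) -> np.ndarray:
    """Master-equation derivatives for the C1 <=> C2 <=> O chain.

    Components sum to zero exactly (probability conservation).
    """
    return p.rate_matrix(V) @ np.asarray(s, dtype=float)


def three_state_steady_state(V, p: ThreeStateParams) -> np.ndarray:
    """Stationary occupancy of the chain: null vector of Q, normalised to 1.

    Uses detailed balance along the linear chain, which is exact for a
    birth-death structure.
    """
    k12 = p.c1_c2.alpha(V)
    k21 = p.c1_c2.beta(V)
    k23 = p.c2_o.alpha(V)
    k32 = p.c2_o.beta(V)
    if k21 == 0 or k32 == 0:
        raise InvalidParameterError("degenerate rate matrix: zero backward rate")
    # Unnormalised occupancies relative to C1 via detailed balance.
    c1 = 1.0
    c2 = k12 / k21
    o = c2 * k23 / k32
    s = np.array([c1, c2, o])
    total = s.sum()
    if not np.isfinite(total) or total <= 0:
        raise InvalidParameterError("degenerate rate matrix")
    return s / total


# ---------------------------------------------------------------------------
# Parameter files
# ---------------------------------------------------------------------------

_DEFAULTS_PATH = Path(__file__).parent / "params" / "defaults.json"


def _rate_params_from_dict(d: dict, prefix: str) -> RateParams:
    return RateParams(
        A_alpha=d[f"{prefix}_A_alpha_per_ms"],
        B_alpha=d[f"{prefix}_B_alpha_per_mV"],
        A_beta=d[f"{prefix}_A_beta_per_ms"],
        B_beta=d[f"{prefix}_B_beta_per_mV"],
    )


def load_candidate_params(path: str | Path | None = None) -> HHModelParams:
    """Load candidate (two-gate Hodgkin-Huxley) parameters from a JSON file.

    With no argument, returns the packaged literature-plausible hERG defaults.
    """
    with open(path or _DEFAULTS_PATH) as fh:
        d = json.load(fh)["candidate"]
    return HHModelParams(
        g=d["g_uS"],
        activation=_rate_params_from_dict(d, "activation"),
        inactivation=_rate_params_from_dict(d, "inactivation"),
    )


def load_ground_truth_params(path: str | Path | None = None) -> ThreeStateParams:
    """Load three-state ground-truth parameters from a JSON file."""
    with open(path or _DEFAULTS_PATH) as fh:
        d = json.load(fh)["ground_truth"]
    return ThreeStateParams(
        g=d["g_uS"],
        c1_c2=_rate_params_from_dict(d, "c1_c2"),
        c2_o=_rate_params_from_dict(d, "c2_o"),
        inactivation=_rate_params_from_dict(d, "inactivation"),
    )


def save_candidate_params(p: HHModelParams, path: str | Path) -> None:
    """Write candidate parameters to the flat JSON schema used by the loaders."""
    d = {
        "candidate": {
            "g_uS": p.g,
            "activation_A_alpha_per_ms": p.activation.A_alpha,
            "activation_B_alpha_per_mV": p.activation.B_alpha,
            "activation_A_beta_per_ms": p.activation.A_beta,
            "activation_B_beta_per_mV": p.activation.B_beta,
            "inactivation_A_alpha_per_ms": p.inactivation.A_alpha,
            "inactivation_B_alpha_per_mV": p.inactivation.B_alpha,
            "inactivation_A_beta_per_ms": p.inactivation.A_beta,
            "inactivation_B_beta_per_mV": p.inactivation.B_beta,
        }
    }
    with open(path, "w") as fh:
        json.dump(d, fh, indent=2)
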