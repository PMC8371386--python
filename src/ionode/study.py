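"""End-to-end synthetic-data study: generate, estimate, train, compare.

The study emulates a voltage-clamp characterisation of hERG activation:

1. A generating model — either a three-state activation chain ("ground
   truth", which the two-state candidate cannot represent) or the candidate
   itself (no-discrepancy control) — is simulated over activation- and
   deactivation-style step protocols from steady state at -80 mV, and
   i.i.d. Gaussian noise (default SD 0.1 nA) is added to the currents.
2. The candidate Hodgkin-Huxley model is fitted to the noisy training
   traces as the mechanistic baseline.
3. State-space estimation converts the noisy training currents into
   (a, V, da/dt) tuples using the shared (trusted) inactivation gate.
4. NN-f (full) and NN-d (discrepancy) neural gates are trained on the
   tuples, the latter around the fitted candidate's activation kinetics.
5. All models are simulated over training and unseen prediction protocols
   and compared by mean absolute error, alongside state-space coverage
   diagnostics.

Determinism: a single master seed; every stochastic stage uses a seed
derived by a fixed counter scheme (``derive_seed``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import protocols as proto
from .evaluation import coverage_map, extrapolation_fraction, mean_absolute_error, \
    state_space_trajectory
from .fitting import FitResult, fit_candidate_model
from .mech import (
    HHModelParams,
    NernstConfig,
    ThreeStateParams,
    load_candidate_params,
    load_ground_truth_params,
    nernst_potential,
)
from .neural import NetworkSpec, NeuralGateModel, OptimiserConfig, train_network
from .simulate import (
    CurrentTrace,
    SimulationConfig,
    add_noise,
    simulate_current,
)
from .state_space import build_training_set, estimate_gate_from_trace

log = logging.getLogger(__name__)

#: Mean of |N(0, sd)|: the MAE a perfect model scores against its own noisy
#: trace (half-normal mean), = sd * sqrt(2/pi).
HALF_NORMAL_FACTOR = float(np.sqrt(2.0 / np.pi))


def noise_floor_mae(sd: float = 0.1) -> float:
    """Expected MAE of the noise-free truth against its noisy observation."""
    return sd * HALF_NORMAL_FACTOR


def derive_seed(master: int, index: int) -> int:
    """Deterministic per-stage seed: counter scheme, always below 2^31."""
    return int((master * 1_000_003 + 7919 * index + 12345) % (2**31 - 1))


def default_protocols(dt: float = 1.0) -> dict:
    """The study's protocol suite, keyed by conventional-style names."""
    return {
        "pr3_like": proto.make_activation_protocol(),
        "pr5_like": proto.make_deactivation_protocol(),
        "pr4_like": proto.make_inactivation_protocol(),
        "sinusoidal_like": proto.make_sinusoidal_protocol(dt=dt),
        "ap_like": proto.make_ap_protocol(dt=dt),
    }


@dataclass(frozen=True)
class StudyConfig:
    """Everything that determines a synthetic study run."""

    generator: str = "ground_truth"  # or "candidate"
    master_seed: int = 1
    noise_sd: float = 0.1
    training_protocols: tuple[str, ...] = ("pr3_like", "pr5_like")
    prediction_protocols: tuple[str, ...] = ("pr4_like", "sinusoidal_like", "ap_like")
    hidden: tuple[int, ...] = (64, 64, 64)
    epochs: int = 1200
    batch_size: int | None = 2048
    learning_rate: float = 1e-3
    subsample: int = 2
    dt: float = 1.0
    fit_n_starts: int = 2
    #: Reversal-potential guard for state-space estimation: samples with
    #: |V - E| below this are dropped, since the algebraic inversion
    #: amplifies observation noise by 1/(V - E).  10 mV keeps the noise
    #: amplification within one order of magnitude of the floor.
    v_min: float = 10.0


@dataclass
class StudyReport:
    """Artefacts of one study run."""

    config: StudyConfig
    fit: FitResult
    nn_f: NeuralGateModel
    nn_d: NeuralGateModel
    mae: pd.DataFrame  # rows: model, columns: protocol
    datasets: dict  # name -> (noisy, clean)
    extrapolation: dict  # protocol -> fraction for the NN training coverage


def make_ground_truth_dataset(params: ThreeStateParams, protocols: dict,
                              noise_sd: float = 0.1, seed: int = 0,
                              cfg: SimulationConfig = SimulationConfig(),
                              E: float | None = None) -> dict:
    """Simulate the three-state generator over each protocol and add noise.

    Returns ``{name: (noisy_trace, clean_trace)}``; each protocol's noise
    stream uses its own derived seed so datasets are reproducible
    per-protocol.
    """
    return _make_dataset(params, protocols, noise_sd, seed, cfg, E)


def make_no_discrepancy_dataset(params: HHModelParams, protocols: dict,
                                noise_sd: float = 0.1, seed: int = 0,
                                cfg: SimulationConfig = SimulationConfig(),
                                E: float | None = None) -> dict:
    """Same contract with the candidate model as the generator."""
    return _make_dataset(params, protocols, noise_sd, seed, cfg, E)


def _make_dataset(model, protocols: dict, noise_sd: float, seed: int,
                  cfg: SimulationConfig, E: float | None) -> dict:
    if E is None:
        E = nernst_potential(NernstConfig())
    out = {}
    for i, (name, p) in enumerate(sorted(protocols.items())):
        clean = simulate_current(model, p, cfg, E=E)
        noisy = add_noise(clean, noise_sd, derive_seed(seed, 100 + i))
        out[name] = (noisy, clean)
    return out


def run_synthetic_study(config: StudyConfig = StudyConfig(),
                        protocols: dict | None = None,
                        ground_truth: ThreeStateParams | None = None,
                        candidate: HHModelParams | None = None) -> StudyReport:
    """Run the full study pipeline; deterministic given the config."""
    if protocols is None:
        protocols = default_protocols(config.dt)
    if ground_truth is None:
        ground_truth = load_ground_truth_params()
    if candidate is None:
        candidate = load_candidate_params()
    cfg = SimulationConfig(dt=config.dt)
    E = nernst_potential(NernstConfig())

    if config.generator == "ground_truth":
        generator = ground_truth
    elif config.generator == "candidate":
        generator = candidate
    else:
        raise ValueError(f"unknown generator {config.generator!r}")

    log.info("stage 1: generating synthetic data (%s)", config.generator)
    try:
        datasets = _make_dataset(generator, protocols, config.noise_sd,
                                 config.master_seed, cfg, E)
    except Exception as e:
        raise RuntimeError(f"stage 'generate' failed: {e}") from e

    train_names = list(config.training_protocols)
    train_traces = [datasets[n][0] for n in train_names]
    train_protocols = [protocols[n] for n in train_names]

    log.info("stage 2: fitting candidate model")
    try:
        fit = fit_candidate_model(
            train_traces, train_protocols, init=candidate,
            seed=derive_seed(config.master_seed, 0),
            n_starts=config.fit_n_starts, E=E, cfg=cfg,
        )
    except Exception as e:
        raise RuntimeError(f"stage 'fit' failed: {e}") from e

    log.info("stage 3: state-space estimation")
    # The inactivation gate is shared by construction between generator and
    # candidate ("trusted"), so estimation uses it with the known g.
    r_model = generator.inactivation
    g = generator.g
    try:
        estimates = [
            estimate_gate_from_trace(tr, p, g, E, r_model, cfg,
                                     v_min=config.v_min)
            for tr, p in zip(train_traces, train_protocols)
        ]
        ts = build_training_set(estimates, subsample=config.subsample)
    except Exception as e:
        raise RuntimeError(f"stage 'estimate' failed: {e}") from e

    opt = OptimiserConfig(learning_rate=config.learning_rate,
                          epochs=config.epochs,
                          batch_size=config.batch_size)
    spec = NetworkSpec(hidden=config.hidden)
    log.info("stage 4: training NN-f and NN-d (%d tuples)", len(ts))
    try:
        nn_f, _ = train_network(
            ts, mode="full", spec=spec, opt=opt,
            seed=derive_seed(config.master_seed, 1),
            inactivation=r_model, g=g,
        )
        nn_d, _ = train_network(
            ts, mode="discrepancy", spec=spec, opt=opt,
            seed=derive_seed(config.master_seed, 2),
            candidate=fit.params.activation,
            inactivation=r_model, g=g,
        )
    except Exception as e:
        raise RuntimeError(f"stage 'train' failed: {e}") from e

    log.info("stage 5: simulating and scoring all models")
    models = {"candidate": fit.params, "nn_f": nn_f, "nn_d": nn_d}
    all_names = train_names + list(config.prediction_protocols)
    try:
        mae = pd.DataFrame(index=list(models), columns=all_names, dtype=float)
        for mname, model in models.items():
            for pname in all_names:
                pred = simulate_current(model, protocols[pname], cfg, E=E)
                mae.loc[mname, pname] = mean_absolute_error(
                    pred, datasets[pname][0]
                )
    except Exception as e:
        raise RuntimeError(f"stage 'evaluate' failed: {e}") from e

    log.info("stage 6: coverage diagnostics")
    try:
        train_cov = coverage_map([
            state_space_trajectory(generator, protocols[n], cfg)
            for n in train_names
        ])
        extrap = {
            pname: extrapolation_fraction(
                state_space_trajectory(generator, protocols[pname], cfg),
                train_cov,
            )
            for pname in config.prediction_protocols
        }
    except Exception as e:
        raise RuntimeError(f"stage 'coverage' failed: {e}") from e

    return StudyReport(config=config, fit=fit, nn_f=nn_f, nn_d=nn_d,
                       mae=mae, datasets=datasets, extrapolation=extrap)
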