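"""Neural gate models: learned right-hand sides for the activation ODE.

Three ways of closing the activation-gate ODE da/dt = f(a, V) with a
feedforward network N:

* ``full``        da/dt = N(a, V)                  (pure neural ODE)
* ``discrepancy`` da/dt = f_cand(a, V) + N(a, V)   (neural term corrects a
                  mechanistic candidate model)
* ``rates``       da/dt = N_alpha(V)(1-a) - N_beta(V)a, with positive
                  network outputs, so solutions stay in [0, 1]

Networks operate on scaled variables — a, V/100 inputs and da/dt * 1000
outputs — matching the scaling of the training tuples.  Training is plain
derivative regression (mean-squared error on the state-space estimates)
with Adam; no backpropagation through the ODE solver is needed.

The multilayer perceptron, its backward pass and the Adam optimiser are
implemented directly on numpy arrays; a trained model is a plain JSON
document (weights as nested lists) so checkpoints are portable and
diffable.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
import numpy as np
from scipy.optimize import brentq

from .mech import RateParams, gate_rhs, gate_steady_state
from .state_space import DEFAULT_SCALING, TrainingSet

log = logging.getLogger(__name__)

MODES = ("full", "discrepancy", "rates")


@dataclass(frozen=True)
class NetworkSpec:
    """Feedforward architecture: layer sizes and activation.

    Default is five hidden layers of 200 leaky-ReLU nodes; smaller
    architectures fit the two-input gate surface well and train much
    faster, so study drivers typically override ``hidden``.
    """

    n_inputs: int = 2
    n_outputs: int = 1
    hidden: tuple[int, ...] = (200, 200, 200, 200, 200)
    activation: str = "leaky_relu"
    leak: float = 0.01

    def __post_init__(self) -> None:
        if self.n_inputs < 1 or self.n_outputs < 1 or any(h < 1 for h in self.hidden):
            raise ValueError("layer sizes must be positive")
        if self.activation != "leaky_relu":
            raise ValueError(f"unsupported activation: {self.activation}")

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.n_inputs, *self.hidden, self.n_outputs)


def init_weights(spec: NetworkSpec, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded uniform fan-in initialisation: U(+-1/sqrt(fan_in)) for W and b."""
    rng = np.random.default_rng(seed)
    weights = []
    sizes = spec.layer_sizes
    for n_in, n_out in zip(sizes[:-1], sizes[1:]):
        bound = 1.0 / np.sqrt(n_in)
        W = rng.uniform(-bound, bound, size=(n_in, n_out))
        b = rng.uniform(-bound, bound, size=n_out)
        weights.append((W, b))
    return weights


def network_forward(x, weights, spec: NetworkSpec) -> np.ndarray:
    """Evaluate the network: affine maps with component-wise leaky ReLU.

    ``x`` has shape (n, n_inputs) (or (n_inputs,) for a single point);
    biases are part of every affine map, the output layer is linear.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != spec.n_inputs:
        raise ValueError(
            f"input has {x.shape[1]} features, spec expects {spec.n_inputs}"
        )
    h = x
    for i, (W, b) in enumerate(weights):
        h = h @ W + b
        if i < len(weights) - 1:
            h = np.where(h > 0, h, spec.leak * h)
    return h


def _forward_cached(x, weights, spec):
    """Forward pass retaining pre-activations for backprop."""
    h = x
    cache = [h]
    pre = []
    for i, (W, b) in enumerate(weights):
        z = h @ W + b
        pre.append(z)
        h = np.where(z > 0, z, spec.leak * z) if i < len(weights) - 1 else z
        cache.append(h)
    return h, cache, pre


def _backward(grad_out, weights, spec, cache, pre):
    """Gradients of a scalar loss wrt all weights, given dL/d(output)."""
    grads = [None] * len(weights)
    delta = grad_out
    for i in range(len(weights) - 1, -1, -1):
        W, _ = weights[i]
        grads[i] = (cache[i].T @ delta, delta.sum(axis=0))
        if i > 0:
            delta = delta @ W.T
            slope = np.where(pre[i - 1] > 0, 1.0, spec.leak)
            delta = delta * slope
    return grads


def _softplus(z):
    return np.logaddexp(0.0, z)


@dataclass(frozen=True)
class NeuralGateModel:
    """A trained neural activation gate, simulable as part of the channel.

    Carries everything needed to close the channel model: the network, its
    scaling constants, the mode, the candidate activation parameters
    (required for ``discrepancy`` mode), the trusted inactivation gate and
    the conductance.
    """

    spec: NetworkSpec
    weights: list
    mode: str = "full"
    scaling: tuple[float, float, float] = DEFAULT_SCALING
    candidate: RateParams | None = None
    inactivation: RateParams | None = None
    g: float = 1.0
    seed: int | None = None
    #: (a_min, a_max, V_min, V_max) of the training tuples.  Network inputs
    #: are clamped to this box at evaluation time: neural nets are not
    #: reliable extrapolators, and an unclamped network evaluated outside
    #: the trained region can destabilise the ODE.  Inside the box the
    #: model is unchanged.
    input_range: tuple[float, float, float, float] | None = None
    #: Restoring rate (ms^-1) applied outside the trained a-range (mode
    #: ``full`` only): the clamped network is constant there, so without a
    #: pull-back a positive residual at the box edge would let the state
    #: grow without bound.
    barrier_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.mode == "discrepancy" and self.candidate is None:
            raise ValueError("discrepancy mode requires candidate RateParams")
        expected = self.spec.layer_sizes
        for i, (W, b) in enumerate(self.weights):
            if W.shape != (expected[i], expected[i + 1]) or b.shape != (expected[i + 1],):
                raise ValueError(f"layer {i} weight shape mismatch with spec")

    # -- right-hand sides ---------------------------------------------------

    def _net_dadt(self, a, V):
        """Network contribution in physical units (ms^-1), scalar or array."""
        s_a, s_v, s_d = self.scaling
        a_arr = np.atleast_1d(np.asarray(a, dtype=float))
        v_arr = np.broadcast_to(np.asarray(V, dtype=float), a_arr.shape)
        if self.input_range is not None:
            a_lo, a_hi, v_lo, v_hi = self.input_range
            v_arr = np.clip(v_arr, v_lo, v_hi)
        if self.mode == "rates":
            # the a-dependence stays exactly affine (never clamped) so the
            # mass-action structure keeps solutions inside [0, 1]
            x = (v_arr / s_v)[:, None]
            out = network_forward(x, self.weights, self.spec)
            alpha = _softplus(out[:, 0]) * s_d
            beta = _softplus(out[:, 1]) * s_d
            val = alpha * (1.0 - a_arr) - beta * a_arr
        else:
            if self.input_range is not None:
                a_arr = np.clip(a_arr, a_lo, a_hi)
            x = np.column_stack([a_arr / s_a, v_arr / s_v])
            val = network_forward(x, self.weights, self.spec)[:, 0] * s_d
        return val if np.ndim(a) else float(val[0])

    def _barrier(self, a):
        if self.input_range is None:
            return 0.0 if np.ndim(a) == 0 else np.zeros(np.shape(a))
        a_lo, a_hi = self.input_range[0], self.input_range[1]
        a_arr = np.asarray(a, dtype=float)
        over = np.maximum(a_arr - a_hi, 0.0)
        under = np.maximum(a_lo - a_arr, 0.0)
        val = self.barrier_rate * (under - over)
        return float(val) if np.ndim(a) == 0 else val

    def rhs(self, a, V):
        """da/dt in ms^-1 for the model's mode."""
        if self.mode == "rates":
            return self._net_dadt(a, V)
        if self.mode == "full":
            return self._net_dadt(a, V) + self._barrier(a)
        return gate_rhs(a, V, self.candidate) + self._net_dadt(a, V)

    def steady_state(self, V: float) -> float:
        return nn_steady_state(self, V)


def nn_full_rhs(a, V, model: NeuralGateModel):
    """da/dt for a full-replacement neural gate."""
    if model.mode != "full":
        raise ValueError("model is not in 'full' mode")
    return model.rhs(a, V)


def nn_discrepancy_rhs(a, V, model: NeuralGateModel):
    """da/dt = candidate mechanistic RHS + neural discrepancy term.

    With an identically-zero network this reduces exactly to the candidate
    model's mass-action kinetics.
    """
    if model.mode != "discrepancy":
        raise ValueError("model is not in 'discrepancy' mode")
    return model.rhs(a, V)


def nn_rates_rhs(a, V, model: NeuralGateModel):
    """da/dt = N_alpha(V)(1-a) - N_beta(V)a with softplus-positive rates.

    Affine in ``a`` by construction, so solutions started in [0, 1] stay
    in [0, 1] and keep an open-probability interpretation.
    """
    if model.mode != "rates":
        raise ValueError("model is not in 'rates' mode")
    return model.rhs(a, V)


def nn_steady_state(model: NeuralGateModel, V: float,
                    n_grid: int = 101, tol: float = 1e-12) -> float:
    """Root of the gate RHS in [0, 1] at fixed V, by bracketing.

    Scans a grid for a sign change and refines with Brent's method.  If no
    bracket exists the endpoint with the smallest |rhs| is relaxed by a
    long (10 s) constant-voltage integration and that endpoint is returned
    with a warning.
    """
    grid = np.linspace(0.0, 1.0, n_grid)
    vals = np.asarray(model.rhs(grid, V))
    sign = np.sign(vals)
    idx = np.nonzero(np.diff(sign) != 0)[0]
    if len(idx):
        i = idx[0]
        if vals[i] == 0:
            return float(grid[i])
        return float(brentq(lambda a: model.rhs(a, V), grid[i], grid[i + 1],
                            xtol=tol))
    warnings.warn(
        f"neural gate RHS has no root in [0,1] at V={V} mV; "
        "falling back to a 10 s hold simulation"
    )
    from scipy.integrate import solve_ivp

    a0 = float(grid[np.argmin(np.abs(vals))])
    sol = solve_ivp(lambda t, y: [model.rhs(y[0], V)], (0.0, 10000.0), [a0],
                    method="RK45", atol=1e-6, rtol=1e-8)
    return float(sol.y[0, -1])


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OptimiserConfig:
    """Adam settings for derivative regression."""

    learning_rate: float = 1e-3
    epochs: int = 2000
    batch_size: int | None = None  # None = full batch
    #: Decoupled (AdamW-style) L2 penalty; tempers noise-chasing wiggles in
    #: the learned surface without biasing large coherent features.
    weight_decay: float = 0.0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    plateau_patience: int | None = 200
    plateau_rel_tol: float = 1e-4


@dataclass(frozen=True)
class TrainingReport:
    """Per-epoch loss trajectory and the settings that produced it."""

    losses: np.ndarray
    final_loss: float
    seed: int
    config: OptimiserConfig

    def __post_init__(self) -> None:
        if len(self.losses) == 0 or not np.all(np.isfinite(self.losses)):
            raise ValueError("loss trajectory must be non-empty and finite")


def _training_arrays(ts: TrainingSet, mode: str, candidate: RateParams | None):
    """Scaled regression inputs X and network-output targets y."""
    s_a, s_v, s_d = ts.scaling
    if mode == "rates":
        X = (ts.v / s_v)[:, None]
    else:
        X = np.column_stack([ts.a / s_a, ts.v / s_v])
    if mode == "discrepancy":
        if candidate is None:
            raise ValueError("discrepancy mode requires candidate RateParams")
        resid = ts.dadt - gate_rhs(ts.a, ts.v, candidate)
        y = (resid / s_d)[:, None]
    else:
        y = (ts.dadt / s_d)[:, None]
    return X, y


def train_network(ts: TrainingSet, mode: str = "full",
                  spec: NetworkSpec | None = None,
                  opt: OptimiserConfig = OptimiserConfig(),
                  seed: int = 0,
                  candidate: RateParams | None = None,
                  inactivation: RateParams | None = None,
                  g: float = 1.0) -> tuple[NeuralGateModel, TrainingReport]:
    """Fit a neural gate to state-space-estimated tuples by MSE regression.

    Minimises the mean squared error between the network output and the
    scaled derivative targets (for ``discrepancy`` mode the target is the
    residual after subtracting the candidate model's RHS, so a perfect
    candidate leaves a near-zero network).  Deterministic given ``seed``.
    """
    if len(ts) == 0:
        raise ValueError("empty training set")
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if spec is None:
        spec = NetworkSpec() if mode != "rates" else NetworkSpec(n_inputs=1, n_outputs=2)
    if mode == "rates" and (spec.n_inputs, spec.n_outputs) != (1, 2):
        raise ValueError("rates mode needs a V -> (alpha, beta) network (1 in, 2 out)")

    X, y = _training_arrays(ts, mode, candidate)
    a_scaled = ts.a / ts.scaling[0]
    rng = np.random.default_rng(seed)
    weights = init_weights(spec, seed)
    m = [(np.zeros_like(W), np.zeros_like(b)) for W, b in weights]
    v = [(np.zeros_like(W), np.zeros_like(b)) for W, b in weights]
    n = len(X)
    batch = n if opt.batch_size is None else min(opt.batch_size, n)
    losses = np.empty(opt.epochs)
    step = 0
    best = np.inf
    stall = 0
    n_epochs_run = opt.epochs
    for epoch in range(opt.epochs):
        if batch == n:
            batches = [np.arange(n)]
        else:
            perm = rng.permutation(n)
            batches = [perm[i:i + batch] for i in range(0, n, batch)]
        epoch_loss = 0.0
        for idx in batches:
            xb, yb = X[idx], y[idx]
            out, cache, pre = _forward_cached(xb, weights, spec)
            if mode == "rates":
                sp = _softplus(out)
                pred = (sp[:, 0] * (1.0 - a_scaled[idx])
                        - sp[:, 1] * a_scaled[idx])[:, None]
                err = pred - yb
                sig = 1.0 / (1.0 + np.exp(-out))
                grad_out = np.column_stack([
                    err[:, 0] * (1.0 - a_scaled[idx]) * sig[:, 0],
                    err[:, 0] * (-a_scaled[idx]) * sig[:, 1],
                ]) * (2.0 / len(idx))
                loss = float(np.mean(err**2))
            else:
                err = out - yb
                grad_out = 2.0 * err / len(idx)
                loss = float(np.mean(err**2))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"NaN/inf loss at epoch {epoch}; try a smaller learning rate"
                )
            grads = _backward(grad_out, weights, spec, cache, pre)
            step += 1
            lr_t = opt.learning_rate * (
                np.sqrt(1 - opt.beta2**step) / (1 - opt.beta1**step)
            )
            for i, ((gW, gb), (W, b)) in enumerate(zip(grads, weights)):
                mW, mb = m[i]
                vW, vb = v[i]
                mW = opt.beta1 * mW + (1 - opt.beta1) * gW
                mb = opt.beta1 * mb + (1 - opt.beta1) * gb
                vW = opt.beta2 * vW + (1 - opt.beta2) * gW**2
                vb = opt.beta2 * vb + (1 - opt.beta2) * gb**2
                m[i] = (mW, mb)
                v[i] = (vW, vb)
                decay = 1.0 - opt.learning_rate * opt.weight_decay
                weights[i] = (decay * W - lr_t * mW / (np.sqrt(vW) + opt.eps),
                              decay * b - lr_t * mb / (np.sqrt(vb) + opt.eps))
            epoch_loss += loss * len(idx)
        losses[epoch] = epoch_loss / n
        if opt.plateau_patience is not None:
            if losses[epoch] < best * (1 - opt.plateau_rel_tol):
                best = losses[epoch]
                stall = 0
            else:
                stall += 1
                if stall >= opt.plateau_patience:
                    n_epochs_run = epoch + 1
                    log.info("training stopped on plateau at epoch %d", epoch)
                    break
    losses = losses[:n_epochs_run]
    model = NeuralGateModel(
        spec=spec, weights=weights, mode=mode, scaling=ts.scaling,
        candidate=candidate, inactivation=inactivation, g=g, seed=seed,
        input_range=(float(ts.a.min()), float(ts.a.max()),
                     float(ts.v.min()), float(ts.v.max())),
    )
    report = TrainingReport(losses=losses, final_loss=float(losses[-1]),
                            seed=seed, config=opt)
    return model, report


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

_FORMAT_VERSION = 1


def _rate_params_to_json(p: RateParams | None):
    if p is None:
        return None
    return {"A_alpha": p.A_alpha, "B_alpha": p.B_alpha,
            "A_beta": p.A_beta, "B_beta": p.B_beta}


def _rate_params_from_json(d) -> RateParams | None:
    return None if d is None else RateParams(**d)


def save_model(model: NeuralGateModel, path: str | Path) -> None:
    """Write a checkpoint: JSON header plus nested-list weight payload."""
    doc = {
        "format_version": _FORMAT_VERSION,
        "spec": {
            "n_inputs": model.spec.n_inputs,
            "n_outputs": model.spec.n_outputs,
            "hidden": list(model.spec.hidden),
            "activation": model.spec.activation,
            "leak": model.spec.leak,
        },
        "mode": model.mode,
        "scaling": list(model.scaling),
        "seed": model.seed,
        "g_uS": model.g,
        "candidate": _rate_params_to_json(model.candidate),
        "inactivation": _rate_params_to_json(model.inactivation),
        "input_range": (None if model.input_range is None
                        else list(model.input_range)),
        "weights": [{"W": W.tolist(), "b": b.tolist()} for W, b in model.weights],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path: str | Path) -> NeuralGateModel:
    """Load a checkpoint; raises on version or shape mismatch."""
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as e:
        raise ValueError(f"corrupt checkpoint {path}: {e}") from e
    if doc.get("format_version") != _FORMAT_VERSION:
        raise ValueError(
            f"unsupported checkpoint version {doc.get('format_version')}"
        )
    spec = NetworkSpec(
        n_inputs=doc["spec"]["n_inputs"], n_outputs=doc["spec"]["n_outputs"],
        hidden=tuple(doc["spec"]["hidden"]), activation=doc["spec"]["activation"],
        leak=doc["spec"]["leak"],
    )
    weights = [(np.asarray(w["W"], dtype=float), np.asarray(w["b"], dtype=float))
               for w in doc["weights"]]
    return NeuralGateModel(
        spec=spec, weights=weights, mode=doc["mode"],
        scaling=tuple(doc["scaling"]),
        candidate=_rate_params_from_json(doc["candidate"]),
        inactivation=_rate_params_from_json(doc["inactivation"]),
        g=doc["g_uS"], seed=doc["seed"],
        input_range=(None if doc.get("input_range") is None
                     else tuple(doc["input_range"])),
    )


def zero_network_model(spec: NetworkSpec | None = None, mode: str = "discrepancy",
                       candidate: RateParams | None = None,
                       inactivation: RateParams | None = None,
                       g: float = 1.0,
                       scaling=DEFAULT_SCALING) -> NeuralGateModel:
    """Model whose network is identically zero (useful as a control:
    discrepancy mode then reproduces the candidate model exactly)."""
    if spec is None:
        spec = NetworkSpec(hidden=(4,)) if mode != "rates" else NetworkSpec(
            n_inputs=1, n_outputs=2, hidden=(4,))
    weights = [
        (np.zeros((n_in, n_out)), np.zeros(n_out))
        for n_in, n_out in zip(spec.layer_sizes[:-1], spec.layer_sizes[1:])
    ]
    return NeuralGateModel(spec=spec, weights=weights, mode=mode,
                           scaling=scaling, candidate=candidate,
                           inactivation=inactivation, g=g)
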