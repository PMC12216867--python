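"""Feed-forward 6-32-3 network for solution-property prediction.

The network maps six molecular/state descriptors -- critical temperature,
critical volume, melting temperature, melting enthalpy, molality and
temperature -- to the osmotic coefficient, sugar activity coefficient and
water activity of a binary aqueous sugar solution.  One hidden layer of 32
tanh neurons and a linear output layer; weights are trained by the
Levenberg-Marquardt algorithm with an analytic Jacobian and early stopping on
a validation split.

Inputs and outputs are min-max scaled to [-1, 1] on the training set; the
scaling is serialized with the weights.  The published weight table ships
without scaling (none was reported), so forward passes through those weights
are supported only for sensitivity analysis unless the user supplies scaling.

Garson's connection-weight partitioning quantifies the relative importance of
each input: the input-to-hidden weight magnitudes are shared out per hidden
neuron, weighted by the hidden-to-output magnitudes, summed over hidden
neurons and normalized to 100% per output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from carbotherm import resources

INPUT_NAMES = ("t_c", "v_c", "t_m", "dh_m", "molality", "temperature")
OUTPUT_NAMES = ("phi", "gamma", "a_w")
N_INPUT, N_HIDDEN, N_OUTPUT = 6, 32, 3


class SugarDescriptor(NamedTuple):
    """Network input: descriptors in K, cm^3/mol, J/mol, mol/kg, K."""

    t_c: float
    v_c: float
    t_m: float
    dh_m: float
    molality: float
    temperature: float


class PropertyTriple(NamedTuple):
    """Network output: osmotic coefficient, sugar activity coefficient and
    water activity."""

    phi: float
    gamma: float
    a_w: float


@dataclass(frozen=True)
class AffineScaling:
    """Per-variable min-max map onto [-1, 1]: ``scaled = 2(x-lo)/(hi-lo)-1``."""

    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.lo, dtype=float)
        hi = np.asarray(self.hi, dtype=float)
        if lo.shape != hi.shape or np.any(hi <= lo):
            raise ValueError("scaling requires hi > lo elementwise")
        object.__setattr__(self, "lo", lo)
        object.__setattr__(self, "hi", hi)

    @classmethod
    def fit(cls, data: np.ndarray) -> "AffineScaling":
        lo, hi = data.min(axis=0), data.max(axis=0)
        span = hi - lo
        hi = np.where(span == 0, lo + 1.0, hi)  # constant column guard
        return cls(lo, hi)

    def transform(self, x: np.ndarray) -> np.ndarray:
        return 2.0 * (x - self.lo) / (self.hi - self.lo) - 1.0

    def inverse(self, s: np.ndarray) -> np.ndarray:
        return self.lo + 0.5 * (s + 1.0) * (self.hi - self.lo)


@dataclass
class NetworkWeights:
    """6-32-3 weights plus optional input/output scaling."""

    w_ih: np.ndarray  # (6, 32)
    b_h: np.ndarray  # (32,)
    w_ho: np.ndarray  # (32, 3)
    b_o: np.ndarray  # (3,)
    input_scaling: AffineScaling | None = None
    output_scaling: AffineScaling | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.w_ih = np.asarray(self.w_ih, dtype=float)
        self.b_h = np.asarray(self.b_h, dtype=float)
        self.w_ho = np.asarray(self.w_ho, dtype=float)
        self.b_o = np.asarray(self.b_o, dtype=float)
        expect = {
            "w_ih": (N_INPUT, N_HIDDEN),
            "b_h": (N_HIDDEN,),
            "w_ho": (N_HIDDEN, N_OUTPUT),
            "b_o": (N_OUTPUT,),
        }
        for attr, shape in expect.items():
            if getattr(self, attr).shape != shape:
                raise ValueError(
                    f"{attr} must have shape {shape}, got {getattr(self, attr).shape}"
                )

    @property
    def has_scaling(self) -> bool:
        return self.input_scaling is not None and self.output_scaling is not None


def forward(weights: NetworkWeights, x) -> np.ndarray:
    """Evaluate the network on raw-unit inputs ``x`` (shape (6,) or (n, 6)).

    Warns (does not fail) when an input lies outside the fitted scaling range:
    the prediction is then an extrapolation.
    """
    arr = np.atleast_2d(np.asarray(x, dtype=float))
    if arr.shape[1] != N_INPUT:
        raise ValueError(f"inputs must have {N_INPUT} columns, got {arr.shape[1]}")
    if weights.input_scaling is not None:
        sc = weights.input_scaling
        if np.any(arr < sc.lo) or np.any(arr > sc.hi):
            warnings.warn(
                "input outside the fitted scaling range: extrapolating",
                stacklevel=2,
            )
        arr = sc.transform(arr)
    hidden = np.tanh(arr @ weights.w_ih + weights.b_h)
    out = hidden @ weights.w_ho + weights.b_o
    if weights.output_scaling is not None:
        out = weights.output_scaling.inverse(out)
    return out[0] if np.asarray(x).ndim == 1 else out


def predict(weights: NetworkWeights, descriptor: SugarDescriptor) -> PropertyTriple:
    y = forward(weights, np.asarray(descriptor, dtype=float))
    triple = PropertyTriple(*map(float, y))
    if not 0.0 < triple.a_w <= 1.05:
        warnings.warn(
            f"predicted water activity {triple.a_w:.4f} outside (0, 1.05]",
            stacklevel=2,
        )
    return triple


# ----------------------------------------------------------------- metrics
def mse(pred, obs) -> float:
    """Mean squared error (1/N) sum (obs - pred)^2."""
    p, o = _paired(pred, obs)
    return float(np.mean((o - p) ** 2))


def r_squared(pred, obs) -> float:
    """Coefficient of determination; requires non-degenerate observations."""
    p, o = _paired(pred, obs)
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined: observations have zero variance")
    return 1.0 - float(np.sum((o - p) ** 2)) / ss_tot


def ard_percent(pred, obs) -> float:
    """Average relative deviation (100/N) sum |obs - pred|/obs."""
    p, o = _paired(pred, obs)
    if np.any(o == 0.0):
        raise ValueError("ARD%% undefined for zero observations")
    return float(100.0 * np.mean(np.abs((o - p) / o)))


def _paired(pred, obs):
    p = np.asarray(pred, dtype=float).ravel()
    o = np.asarray(obs, dtype=float).ravel()
    if p.shape != o.shape or p.size == 0:
        raise ValueError("pred and obs must be equal-length and non-empty")
    return p, o


# ------------------------------------------------------------------ Garson
def garson_importance(weights: NetworkWeights, output: int | str = "mean") -> np.ndarray:
    """Relative importance (%) of each input via connection-weight partition.

    ``output`` selects one output index, or ``"mean"`` for the average across
    outputs.  Absolute values are taken on both weight layers; importances sum
    to 100%.
    """
    a = np.abs(weights.w_ih)  # (6, 32)
    col = a.sum(axis=0)
    if np.all(a == 0.0):
        raise ValueError("Garson importance undefined for all-zero weights")
    share = a / np.where(col == 0.0, 1.0, col)
    per_output = []
    for n in range(N_OUTPUT):
        contrib = share * np.abs(weights.w_ho[:, n])[None, :]
        r = contrib.sum(axis=1)
        total = r.sum()
        if total == 0.0:
            raise ValueError(f"Garson importance undefined: output {n} disconnected")
        per_output.append(100.0 * r / total)
    per_output = np.array(per_output)  # (3, 6)
    if output == "mean":
        return per_output.mean(axis=0)
    return per_output[int(output)]


# ----------------------------------------------------------- printed weights
def load_printed_weights() -> NetworkWeights:
    """The published 32-neuron weight table, verbatim, without scaling."""
    doc = resources.load_json("ann_printed_weights.json")
    return NetworkWeights(
        w_ih=np.array(doc["w_ih"]),
        b_h=np.array(doc["b_h"]),
        w_ho=np.array(doc["w_ho"]),
        b_o=np.array(doc["b_o"]),
        metadata={"source": "printed table", "note": doc.get("note", "")},
    )


# ----------------------------------------------------------------- training
@dataclass(frozen=True)
class TrainingConfig:
    """Levenberg-Marquardt training controls.

    Defaults mirror the published setup: 70/15/15 train/validation/test split
    and an epoch cap of 3000; early stopping with 50-epoch patience on the
    validation MSE.
    """

    max_epochs: int = 3000
    tolerance: float = 1e-12
    split: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0
    lm_lambda0: float = 1e-2
    lm_up: float = 10.0
    lm_down: float = 0.1
    patience: int = 50

    def __post_init__(self) -> None:
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass
class TrainingTrace:
    train_mse: list = field(default_factory=list)
    val_mse: list = field(default_factory=list)
    best_val_mse: list = field(default_factory=list)
    test_mse: float = float("nan")
    epochs_run: int = 0


def _split_indices(n: int, split, rng) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    idx = rng.permutation(n)
    n_train = int(round(split[0] * n))
    n_val = int(round(split[1] * n))
    return idx[:n_train], idx[n_train : n_train + n_val], idx[n_train + n_val :]


def _pack(w_ih, b_h, w_ho, b_o) -> np.ndarray:
    return np.concatenate([w_ih.ravel(), b_h, w_ho.ravel(), b_o])


def _unpack(p: np.ndarray):
    i = 0
    w_ih = p[i : i + N_INPUT * N_HIDDEN].reshape(N_INPUT, N_HIDDEN)
    i += N_INPUT * N_HIDDEN
    b_h = p[i : i + N_HIDDEN]
    i += N_HIDDEN
    w_ho = p[i : i + N_HIDDEN * N_OUTPUT].reshape(N_HIDDEN, N_OUTPUT)
    i += N_HIDDEN * N_OUTPUT
    b_o = p[i : i + N_OUTPUT]
    return w_ih, b_h, w_ho, b_o


def _forward_scaled(p: np.ndarray, X: np.ndarray):
    w_ih, b_h, w_ho, b_o = _unpack(p)
    z = X @ w_ih + b_h
    h = np.tanh(z)
    return h @ w_ho + b_o, h


def _residual_and_jacobian(p: np.ndarray, X: np.ndarray, Y: np.ndarray):
    """Residual vector (n*3,) and analytic Jacobian (n*3, n_params)."""
    w_ih, b_h, w_ho, b_o = _unpack(p)
    n = X.shape[0]
    z = X @ w_ih + b_h  # (n, 32)
    h = np.tanh(z)
    y = h @ w_ho + b_o  # (n, 3)
    r = (y - Y).ravel()  # row-major: sample-major, output-minor
    sech2 = 1.0 - h**2  # (n, 32)
    n_par = p.size
    J = np.zeros((n * N_OUTPUT, n_par))
    # d y_o / d w_ho[m, o] = h_m ; d y_o / d b_o[o] = 1
    off_ho = N_INPUT * N_HIDDEN + N_HIDDEN
    off_bo = off_ho + N_HIDDEN * N_OUTPUT
    for o in range(N_OUTPUT):
        rows = slice(o, n * N_OUTPUT, N_OUTPUT)
        J[rows, off_ho + o : off_ho + N_HIDDEN * N_OUTPUT : N_OUTPUT] = h
        J[rows, off_bo + o] = 1.0
        # back through hidden layer: d y_o / d z_m = w_ho[m, o] * sech2_m
        dz = sech2 * w_ho[:, o]  # (n, 32)
        # d z_m / d w_ih[j, m] = X_j ; d z_m / d b_h[m] = 1
        J[rows, : N_INPUT * N_HIDDEN] = np.einsum("nj,nm->njm", X, dz).reshape(n, -1)
        J[rows, N_INPUT * N_HIDDEN : off_ho] = dz
    return r, J


def train(
    inputs: np.ndarray,
    targets: np.ndarray,
    config: TrainingConfig = TrainingConfig(),
) -> tuple[NetworkWeights, TrainingTrace]:
    """Levenberg-Marquardt training with early stopping.

    ``inputs`` (n, 6) and ``targets`` (n, 3) are raw-unit arrays; min-max
    scaling is fitted on the training split and stored with the weights.
    Deterministic for a fixed ``config.seed``.
    """
    X_raw = np.asarray(inputs, dtype=float)
    Y_raw = np.asarray(targets, dtype=float)
    if X_raw.ndim != 2 or X_raw.shape[1] != N_INPUT:
        raise ValueError(f"inputs must be (n, {N_INPUT})")
    if Y_raw.shape != (X_raw.shape[0], N_OUTPUT):
        raise ValueError(f"targets must be (n, {N_OUTPUT})")
    if X_raw.shape[0] < 10 * N_OUTPUT:
        raise ValueError("need at least 10 samples per output to train")
    if not (np.all(np.isfinite(X_raw)) and np.all(np.isfinite(Y_raw))):
        raise ValueError("non-finite training data")

    rng = np.random.default_rng(config.seed)
    i_train, i_val, i_test = _split_indices(X_raw.shape[0], config.split, rng)
    in_sc = AffineScaling.fit(X_raw[i_train])
    out_sc = AffineScaling.fit(Y_raw[i_train])
    X = in_sc.transform(X_raw)
    Y = out_sc.transform(Y_raw)

    p = rng.uniform(-0.5, 0.5, size=N_INPUT * N_HIDDEN + N_HIDDEN + N_HIDDEN * N_OUTPUT + N_OUTPUT)
    lam = config.lm_lambda0
    trace = TrainingTrace()
    best_p = p.copy()
    best_val = np.inf
    stall = 0

    def split_mse(pv, idx):
        y, _ = _forward_scaled(pv, X[idx])
        return float(np.mean((y - Y[idx]) ** 2))

    r, J = _residual_and_jacobian(p, X[i_train], Y[i_train])
    sse = float(r @ r)
    for epoch in range(1, config.max_epochs + 1):
        JtJ = J.T @ J
        g = J.T @ r
        accepted = False
        for _ in range(25):
            try:
                step = np.linalg.solve(JtJ + lam * np.diag(np.diag(JtJ) + 1e-12), -g)
            except np.linalg.LinAlgError:
                lam *= config.lm_up
                continue
            p_new = p + step
            r_new, J_new = _residual_and_jacobian(p_new, X[i_train], Y[i_train])
            sse_new = float(r_new @ r_new)
            if np.isfinite(sse_new) and sse_new < sse:
                p, r, J, sse = p_new, r_new, J_new, sse_new
                lam = max(lam * config.lm_down, 1e-14)
                accepted = True
                break
            lam *= config.lm_up
        trace.epochs_run = epoch
        train_mse = sse / r.size
        val_mse = split_mse(p, i_val) if len(i_val) else train_mse
        trace.train_mse.append(train_mse)
        trace.val_mse.append(val_mse)
        if val_mse < best_val - 1e-18:
            best_val, best_p, stall = val_mse, p.copy(), 0
        else:
            stall += 1
        trace.best_val_mse.append(best_val)
        if not accepted or train_mse < config.tolerance or stall >= config.patience:
            break

    w_ih, b_h, w_ho, b_o = _unpack(best_p)
    weights = NetworkWeights(
        w_ih, b_h, w_ho, b_o,
        input_scaling=in_sc,
        output_scaling=out_sc,
        metadata={
            "seed": config.seed,
            "epochs": trace.epochs_run,
            "split_sizes": (len(i_train), len(i_val), len(i_test)),
            "test_indices": i_test.tolist(),
        },
    )
    if len(i_test):
        y_test, _ = _forward_scaled(best_p, X[i_test])
        trace.test_mse = float(np.mean((y_test - Y[i_test]) ** 2))
    return weights, trace
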