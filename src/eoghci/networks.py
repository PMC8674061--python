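"""From-scratch Elman recurrent (ERNN) and distributed time-delay (DTDNN)
network classifiers.

Both networks share the 16-8-4 architecture: 16 input neurons (one per
convolution feature), 8 hidden neurons, 4 output neurons whose targets
are the 4-bit binary code of the task index.  Hidden and output layers
use the logistic sigmoid so outputs live in (0, 1).

ERNN
    hidden(t) = sigma(W_in x(t) + W_ctx context + b_h), with the context
    layer holding a copy of the previous pattern's hidden activations
    (reset at epoch start / evaluation-batch start).  Trained by
    gradient-descent backpropagation on mean squared error; the context
    is treated as a constant input when differentiating (truncated
    gradient).  The configured learning rate (default .001) is the
    initial rate; by default an adaptive-rate + momentum schedule is
    applied on top, which the plain fixed-rate mode can disable.

DTDNN
    A feedforward 16-8-4 network whose input and hidden layers act on
    tapped delay lines over the within-subject pattern sequence
    (default taps 0..2 on both layers); trained by Levenberg-Marquardt
    on the exact Jacobian unrolled over the delay window.

Training stops when the mean squared error falls below the error goal
(default 0.001) or at the iteration cap (default 1000).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .features import FEATURE_COLUMNS, FeatureVector
from .synthetic import TASKS, Task, task_index

__all__ = [
    "NetworkError",
    "DivergenceError",
    "NetworkConfig",
    "TrainedNetwork",
    "CODEBOOK",
    "encode_labels",
    "decode_output",
    "split_dataset",
    "train_ernn",
    "train_dtdnn",
    "predict",
]


class NetworkError(RuntimeError):
    """Invalid classifier input or unusable network state."""


class DivergenceError(NetworkError):
    """Training error became non-finite."""

    def __init__(self, iteration: int):
        super().__init__(f"training diverged (non-finite error) at "
                         f"iteration {iteration}")
        self.iteration = iteration


# --------------------------------------------------------------------------
# Class coding: task index -> 4-bit binary (MSB first)
# --------------------------------------------------------------------------

N_CODE_BITS = 4


def encode_labels(task: Task) -> np.ndarray:
    """4-bit binary code (MSB first) of the task's index, e.g. 10 -> 1010."""
    t = task_index(task)
    return np.array([(t >> (N_CODE_BITS - 1 - i)) & 1
                     for i in range(N_CODE_BITS)], dtype=float)


#: (11, 4) matrix of all task codes, row order = task index.
CODEBOOK = np.vstack([encode_labels(t) for t in TASKS])


def decode_output(activations: Sequence[float]) -> Task:
    """Nearest code by Euclidean distance; ties go to the lowest task index."""
    a = np.asarray(activations, dtype=float)
    if a.shape != (N_CODE_BITS,) or not np.all(np.isfinite(a)):
        raise NetworkError("decode_output expects 4 finite activations")
    d = np.sum((CODEBOOK - a) ** 2, axis=1)
    return TASKS[int(np.argmin(d))]  # argmin returns the first minimum


def _decode_batch(Y: np.ndarray) -> List[Task]:
    d = ((Y[:, None, :] - CODEBOOK[None, :, :]) ** 2).sum(axis=2)
    return [TASKS[i] for i in np.argmin(d, axis=1)]


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkConfig:
    """Architecture and training settings (defaults follow the study
    protocol: 16-8-4 neurons, learning rate .001, <=1000 iterations,
    error goal 0.001, 75% training split, test error tolerance 0.1)."""

    architecture: str = "ernn"          # "ernn" | "dtdnn"
    n_input: int = 16
    n_hidden: int = 8
    n_output: int = N_CODE_BITS
    learning_rate: float = 0.001
    max_iterations: int = 1000
    error_goal: float = 0.001
    train_fraction: float = 0.75
    test_error_tolerance: float = 0.1
    delays_input: Tuple[int, ...] = (0, 1, 2)   # dtdnn input-layer taps
    delays_hidden: Tuple[int, ...] = (0, 1, 2)  # dtdnn hidden-layer taps
    # gradient-descent schedule (ernn): adaptive rate + momentum on top of
    # the configured initial learning_rate; set adaptive_lr=False for the
    # plain fixed-rate update
    adaptive_lr: bool = True
    momentum: float = 0.9
    lr_increase: float = 1.05
    lr_decrease: float = 0.7
    max_error_ratio: float = 1.04
    shuffle_each_epoch: bool = True
    lm_lambda0: float = 1e-3            # initial LM damping (dtdnn)
    lm_lambda_max: float = 1e10
    # dtdnn evaluation protocol: "steady" fills the tap delay lines with
    # the pattern under evaluation (order-independent, the deployment
    # situation where each command is classified alone); "sequential"
    # runs the delay lines over the batch in row order
    dtdnn_eval: str = "steady"
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_input, self.n_hidden, self.n_output) <= 0:
            raise NetworkError("neuron counts must be positive")
        if not (0 < self.train_fraction < 1):
            raise NetworkError("train_fraction must be in (0, 1)")
        if self.learning_rate < 0:
            raise NetworkError("learning_rate must be >= 0")
        if self.architecture not in ("ernn", "dtdnn"):
            raise NetworkError(f"unknown architecture {self.architecture!r}")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500.0, 500.0)))


def _init_weights(config: NetworkConfig, rng: np.random.Generator,
                  shapes: Dict[str, tuple]) -> Dict[str, np.ndarray]:
    # uniform(-0.5, 0.5) scaled by 1/sqrt(fan-in); fan-in = last axis
    w = {}
    for name, shape in shapes.items():
        fan_in = shape[-1] if len(shape) > 1 else 1
        w[name] = rng.uniform(-0.5, 0.5, size=shape) / math.sqrt(max(fan_in, 1))
    return w


# --------------------------------------------------------------------------
# Trained model container
# --------------------------------------------------------------------------

@dataclass
class TrainedNetwork:
    """Weights + architecture + training trace for either classifier."""

    config: NetworkConfig
    weights: Dict[str, np.ndarray]
    training_curve: List[float]
    final_error: float
    converged: bool
    lm_lambda_exceeded: bool = False

    # ---- forward passes (state reset per evaluation batch) ----

    def forward_batch(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.config.architecture == "ernn":
            return _ernn_forward(self.weights, X)[1]
        if self.config.dtdnn_eval == "steady":
            return _dtdnn_steady_forward(self.weights, X)
        return _dtdnn_forward(self.weights, X, self.config)[1]

    def predict_batch(self, X: np.ndarray) -> List[Task]:
        """Decode every row of X; recurrent/delay state is reset at the
        start of the batch and patterns are evaluated in row order."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.min() < -1e-9 or X.max() > 1 + 1e-9:
            raise NetworkError(
                "inputs outside [0, 1]: features must be normalized with "
                "the model's normalizer before prediction")
        return _decode_batch(self.forward_batch(X))

    # ---- serialization ----

    def to_json(self) -> str:
        cfg = dataclasses.asdict(self.config)
        cfg["delays_input"] = list(self.config.delays_input)
        cfg["delays_hidden"] = list(self.config.delays_hidden)
        return json.dumps({
            "config": cfg,
            "weights": {k: {"shape": list(v.shape), "data": v.ravel().tolist()}
                        for k, v in sorted(self.weights.items())},
            "training_curve": self.training_curve,
            "final_error": self.final_error,
            "converged": self.converged,
            "lm_lambda_exceeded": self.lm_lambda_exceeded,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TrainedNetwork":
        d = json.loads(text)
        cfg = d["config"]
        cfg["delays_input"] = tuple(cfg["delays_input"])
        cfg["delays_hidden"] = tuple(cfg["delays_hidden"])
        weights = {k: np.asarray(v["data"], dtype=float).reshape(v["shape"])
                   for k, v in d["weights"].items()}
        return cls(config=NetworkConfig(**cfg), weights=weights,
                   training_curve=list(d["training_curve"]),
                   final_error=d["final_error"], converged=d["converged"],
                   lm_lambda_exceeded=d.get("lm_lambda_exceeded", False))


def predict(model: TrainedNetwork, fv: FeatureVector) -> Task:
    """Classify one feature vector (must be normalized); state is reset."""
    if not fv.normalized:
        raise NetworkError("predict requires a normalized FeatureVector")
    return model.predict_batch(np.asarray(fv.values, dtype=float)[None, :])[0]


# --------------------------------------------------------------------------
# Stratified train/test split
# --------------------------------------------------------------------------

def split_dataset(features: pd.DataFrame, train_fraction: float = 0.75,
                  seed: int = 0) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-task stratified split with a seeded shuffle.

    Per task with n trials the training share is ceil(train_fraction*n)
    capped at n-1 so at least one trial is always held out (e.g. 10
    trials at 0.75 -> 8 train / 2 test; at 0.999 -> 9/1).
    """
    if not (0 < train_fraction < 1):
        raise NetworkError("train_fraction must be in (0, 1)")
    if "task" not in features.columns:
        raise NetworkError("features frame lacks a 'task' column")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for task in TASKS:
        grp = features.index[features["task"] == task.value].to_numpy()
        if len(grp) < 2:
            raise NetworkError(
                f"cannot stratify: task {task.value!r} has {len(grp)} trials")
        order = rng.permutation(len(grp))
        n_train = min(math.ceil(train_fraction * len(grp)), len(grp) - 1)
        train_idx.extend(grp[order[:n_train]])
        test_idx.extend(grp[order[n_train:]])
    return features.loc[sorted(train_idx)], features.loc[sorted(test_idx)]


def frame_to_xy(df: pd.DataFrame) -> Tuple[np.ndarray, np.ndarray, List[Task]]:
    """(X, targets, labels) from a wide-format features frame."""
    X = df[FEATURE_COLUMNS].to_numpy(dtype=float)
    labels = [Task(t) for t in df["task"]]
    Y = np.vstack([encode_labels(t) for t in labels])
    return X, Y, labels


# --------------------------------------------------------------------------
# ERNN: forward pass and gradients
# --------------------------------------------------------------------------

def _ernn_forward(w: Dict[str, np.ndarray], X: np.ndarray
                  ) -> Tuple[np.ndarray, np.ndarray]:
    """Sequential forward pass, context reset to zeros at batch start.

    Returns (H, Y): hidden and output activations per pattern.
    """
    n = X.shape[0]
    nh = w["b_h"].shape[0]
    H = np.empty((n, nh))
    Y = np.empty((n, w["b_o"].shape[0]))
    c = np.zeros(nh)
    for t in range(n):
        h = _sigmoid(w["W_in"] @ X[t] + w["W_ctx"] @ c + w["b_h"])
        y = _sigmoid(w["W_out"] @ h + w["b_o"])
        H[t] = h
        Y[t] = y
        c = h
    return H, Y


def ernn_pattern_gradients(w: Dict[str, np.ndarray], x: np.ndarray,
                           context: np.ndarray, target: np.ndarray
                           ) -> Tuple[float, Dict[str, np.ndarray]]:
    """Loss and analytic gradients for one pattern with a fixed context.

    Loss is the mean squared error over the 4 outputs; the context is a
    constant input (truncated Elman gradient).  Exposed for the
    finite-difference correctness check.
    """
    h = _sigmoid(w["W_in"] @ x + w["W_ctx"] @ context + w["b_h"])
    y = _sigmoid(w["W_out"] @ h + w["b_o"])
    e = y - target
    loss = float(np.mean(e ** 2))
    k = 2.0 / e.size
    delta_o = k * e * y * (1 - y)
    delta_h = (w["W_out"].T @ delta_o) * h * (1 - h)
    grads = {
        "W_out": np.outer(delta_o, h),
        "b_o": delta_o,
        "W_in": np.outer(delta_h, x),
        "W_ctx": np.outer(delta_h, context),
        "b_h": delta_h,
    }
    return loss, grads


def _ernn_epoch(w: Dict[str, np.ndarray], X: np.ndarray, Y: np.ndarray,
                order: np.ndarray) -> Tuple[float, Dict[str, np.ndarray]]:
    """One sequential pass: mean loss and mean gradients over patterns."""
    grads = {k: np.zeros_like(v) for k, v in w.items()}
    c = np.zeros(w["b_h"].shape[0])
    total = 0.0
    for t in order:
        h = _sigmoid(w["W_in"] @ X[t] + w["W_ctx"] @ c + w["b_h"])
        y = _sigmoid(w["W_out"] @ h + w["b_o"])
        e = y - Y[t]
        total += float(np.mean(e ** 2))
        k = 2.0 / e.size
        delta_o = k * e * y * (1 - y)
        delta_h = (w["W_out"].T @ delta_o) * h * (1 - h)
        grads["W_out"] += np.outer(delta_o, h)
        grads["b_o"] += delta_o
        grads["W_in"] += np.outer(delta_h, X[t])
        grads["W_ctx"] += np.outer(delta_h, c)
        grads["b_h"] += delta_h
        c = h
    n = len(order)
    for k_ in grads:
        grads[k_] /= n
    return total / n, grads


def train_ernn(X: np.ndarray, Y: np.ndarray,
               config: NetworkConfig = NetworkConfig()) -> TrainedNetwork:
    """Train the Elman network by gradient-descent backpropagation.

    Patterns are presented in a stratified-shuffled order each epoch
    with the context reset at epoch start.  With ``adaptive_lr`` the
    rate starts at ``learning_rate`` and is multiplied by
    ``lr_increase`` after an improving epoch, ``lr_decrease`` after a
    rejected (worsening) step; momentum smooths the updates.
    """
    config.validate()
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    rng = np.random.default_rng(config.seed)
    w = _init_weights(config, rng, {
        "W_in": (config.n_hidden, config.n_input),
        "W_ctx": (config.n_hidden, config.n_hidden),
        "b_h": (config.n_hidden,),
        "W_out": (config.n_output, config.n_hidden),
        "b_o": (config.n_output,),
    })
    lr = config.learning_rate
    mc = config.momentum if config.adaptive_lr else 0.0
    velocity = {k: np.zeros_like(v) for k, v in w.items()}
    prev_w = None
    prev_mse = np.inf
    curve: List[float] = []
    for it in range(config.max_iterations):
        order = (rng.permutation(X.shape[0]) if config.shuffle_each_epoch
                 else np.arange(X.shape[0]))
        mse, grads = _ernn_epoch(w, X, Y, order)
        if not np.isfinite(mse):
            raise DivergenceError(it)
        if config.adaptive_lr and mse > prev_mse * config.max_error_ratio \
                and prev_w is not None:
            # reject: restore previous weights, shrink the rate
            w = prev_w
            velocity = {k: np.zeros_like(v) for k, v in w.items()}
            lr *= config.lr_decrease
            mse, grads = _ernn_epoch(w, X, Y, order)
        elif config.adaptive_lr and mse < prev_mse:
            lr *= config.lr_increase
        curve.append(mse)
        if mse < config.error_goal:
            return TrainedNetwork(config=config, weights=w,
                                  training_curve=curve, final_error=mse,
                                  converged=True)
        prev_w = {k: v.copy() for k, v in w.items()}
        prev_mse = mse
        for k in w:
            velocity[k] = mc * velocity[k] - (1 - mc) * lr * grads[k]
            w[k] = w[k] + velocity[k]
    return TrainedNetwork(config=config, weights=w, training_curve=curve,
                          final_error=curve[-1], converged=False)


# --------------------------------------------------------------------------
# DTDNN: forward pass, exact Jacobian, Levenberg-Marquardt
# --------------------------------------------------------------------------

def _dtdnn_forward(w: Dict[str, np.ndarray], X: np.ndarray,
                   config: NetworkConfig
                   ) -> Tuple[np.ndarray, np.ndarray]:
    """Forward pass over the pattern sequence; buffers start at zero.

    h(t) = sigma(b1 + sum_d W1[d] x(t-d)); y(t) = sigma(b2 + sum_d W2[d] h(t-d)).
    """
    T = X.shape[0]
    d_in = config.delays_input
    d_hid = config.delays_hidden
    Zh = np.tile(w["b1"], (T, 1))
    for di, d in enumerate(d_in):
        if d == 0:
            Zh += X @ w["W1"][di].T
        elif d < T:
            Zh[d:] += X[:-d] @ w["W1"][di].T
    H = _sigmoid(Zh)
    Zy = np.tile(w["b2"], (T, 1))
    for di, d in enumerate(d_hid):
        if d == 0:
            Zy += H @ w["W2"][di].T
        elif d < T:
            Zy[d:] += H[:-d] @ w["W2"][di].T
    return H, _sigmoid(Zy)


def _dtdnn_steady_forward(w: Dict[str, np.ndarray],
                          X: np.ndarray) -> np.ndarray:
    """Steady-state response to each pattern held constant: every tap of
    a delay line sees the same pattern, so the taps sum."""
    H = _sigmoid(X @ w["W1"].sum(axis=0).T + w["b1"])
    return _sigmoid(H @ w["W2"].sum(axis=0).T + w["b2"])


def _shift(A: np.ndarray, d: int) -> np.ndarray:
    """Rows delayed by d, zero-padded at the start."""
    if d == 0:
        return A
    out = np.zeros_like(A)
    if d < A.shape[0]:
        out[d:] = A[:-d]
    return out


def _dtdnn_jacobian(w, X, config):
    """Exact Jacobian of the outputs y[t,k] w.r.t. all weights, unrolled
    over the delay window.  Column order matches the parameter packing
    order (W1, b1, W2, b2)."""
    T = X.shape[0]
    nh, ni = config.n_hidden, config.n_input
    no = config.n_output
    d_in, d_hid = config.delays_input, config.delays_hidden
    H, Y = _dtdnn_forward(w, X, config)
    sy = Y * (1 - Y)                 # (T, no)
    sh = H * (1 - H)                 # (T, nh)

    # dW1[d'] and db1 via G[t,k,j] = sy[t,k] * W2[d][k,j] * sh[t-d, j]
    J_W1 = np.zeros((T, no, len(d_in), nh, ni))
    J_b1 = np.zeros((T, no, nh))
    for di, d in enumerate(d_hid):
        shd = _shift(sh, d)
        G = sy[:, :, None] * w["W2"][di][None, :, :] * shd[:, None, :]
        J_b1 += G
        for dj, dp in enumerate(d_in):
            Xd = _shift(X, d + dp)
            J_W1[:, :, dj] += G[:, :, :, None] * Xd[:, None, None, :]
    # dW2[d]: sy[t,k] * h[t-d, j], nonzero only for the k-th output row
    J_W2 = np.zeros((T, no, len(d_hid), no, nh))
    for di, d in enumerate(d_hid):
        Hd = _shift(H, d)
        for k in range(no):
            J_W2[:, k, di, k, :] = sy[:, k:k + 1] * Hd
    J_b2 = np.zeros((T, no, no))
    for k in range(no):
        J_b2[:, k, k] = sy[:, k]
    J = np.hstack([J_W1.reshape(T * no, -1), J_b1.reshape(T * no, -1),
                   J_W2.reshape(T * no, -1), J_b2.reshape(T * no, -1)])
    return J, H, Y


def _pack(w, names):
    return np.concatenate([w[n].ravel() for n in names])


def _unpack(theta, shapes, names):
    out = {}
    i = 0
    for n in names:
        size = int(np.prod(shapes[n]))
        out[n] = theta[i:i + size].reshape(shapes[n])
        i += size
    return out


def lm_step(J: np.ndarray, r: np.ndarray, damping: float) -> np.ndarray:
    """One Levenberg-Marquardt update: solve (J'J + damping*I) delta = J'r.

    With damping -> 0 this is the Gauss-Newton step.
    """
    A = J.T @ J + damping * np.eye(J.shape[1])
    return np.linalg.solve(A, J.T @ r)


def train_dtdnn(X: np.ndarray, Y: np.ndarray,
                config: NetworkConfig = None) -> TrainedNetwork:
    """Train the time-delay network by Levenberg-Marquardt.

    Damping is multiplied by 10 while a step increases the error and
    divided by 10 on acceptance; training stops at the error goal, the
    iteration cap, or when damping exceeds ``lm_lambda_max``.
    """
    if config is None:
        config = NetworkConfig(architecture="dtdnn")
    config.validate()
    if config.architecture != "dtdnn":
        raise NetworkError("train_dtdnn requires architecture='dtdnn'")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    rng = np.random.default_rng(config.seed)
    shapes = {
        "W1": (len(config.delays_input), config.n_hidden, config.n_input),
        "b1": (config.n_hidden,),
        "W2": (len(config.delays_hidden), config.n_output, config.n_hidden),
        "b2": (config.n_output,),
    }
    w = _init_weights(config, rng, shapes)
    names = ["W1", "b1", "W2", "b2"]
    lam = config.lm_lambda0
    curve: List[float] = []
    lam_exceeded = False
    _, Yp = _dtdnn_forward(w, X, config)
    sse = float(np.sum((Yp - Y) ** 2))
    for it in range(config.max_iterations):
        mse = sse / Y.size
        curve.append(mse)
        if not np.isfinite(mse):
            raise DivergenceError(it)
        if mse < config.error_goal:
            return TrainedNetwork(config=config, weights=w,
                                  training_curve=curve, final_error=mse,
                                  converged=True)
        J, _, Yp = _dtdnn_jacobian(w, X, config)
        r = (Yp - Y).ravel()
        theta = _pack(w, names)
        accepted = False
        while not accepted:
            try:
                delta = lm_step(J, r, lam)
            except np.linalg.LinAlgError:
                lam *= 10
                if lam > config.lm_lambda_max:
                    lam_exceeded = True
                    break
                continue
            w_new = _unpack(theta - delta, shapes, names)
            _, Yp_new = _dtdnn_forward(w_new, X, config)
            sse_new = float(np.sum((Yp_new - Y) ** 2))
            if np.isfinite(sse_new) and sse_new < sse:
                w = w_new
                sse = sse_new
                lam = max(lam / 10, 1e-12)
                accepted = True
            else:
                lam *= 10
                if lam > config.lm_lambda_max:
                    lam_exceeded = True
                    break
        if lam_exceeded:
            break
    final = sse / Y.size
    curve.append(final)
    return TrainedNetwork(config=config, weights=w, training_curve=curve,
                          final_error=final,
                          converged=final < config.error_goal,
                          lm_lambda_exceeded=lam_exceeded)
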