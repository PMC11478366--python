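"""Stacked recurrent posture classifiers built from the gate equations.

Architecture (seven conceptual layers): feature input → fully connected
(7 → m) → ReLU → recurrent layer (LSTM, Bi-LSTM, projected LSTM or GRU with
inner size LS) → fully connected (→ 3 classes) → softmax → argmax decision.

LSTM cell, with ``*`` the element-wise product::

    i_t = σ(W_i x_t + U_i h_{t-1} + b_i)
    f_t = σ(W_f x_t + U_f h_{t-1} + b_f + b_forget)
    g_t = tanh(W_c x_t + U_c h_{t-1} + b_c)
    o_t = σ(W_o x_t + U_o h_{t-1} + b_o)
    c_t = f_t * c_{t-1} + i_t * g_t
    h_t = o_t * tanh(c_t)

The constant forget bias (default 1) keeps the forget gate open early in
training.  By convention it is added to the forget-gate pre-activation; a
strict variant placing it on the output gate instead is available via
``forget_bias_gate="output"``.

GRU cell (update gate z, reset gate r, candidate n)::

    z_t = σ(W_z x_t + U_z h_{t-1} + b_z)
    r_t = σ(W_r x_t + U_r h_{t-1} + b_r)
    n_t = tanh(W_n x_t + r_t * (U_n h_{t-1}) + b_n)
    h_t = z_t * h_{t-1} + (1 - z_t) * n_t

The projected LSTM recurs and emits through a linear bottleneck
``p_t = P h_t`` with p < LS, shrinking both the recurrent matrices
(U ∈ R^{4·LS×p}) and the output layer.  The Bi-LSTM runs two independent
cells over the window in opposite directions and concatenates their final
states.

All gradients are exact backpropagation-through-time, verified against
central finite differences in the test suite.  Training is mini-batch
cross-entropy descent (Adam by default) with per-epoch reshuffling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .classic import FeatureScaler
from .config import TrainingConfig
from .core import ParameterError, PointfallError

__all__ = [
    "VARIANTS",
    "RecurrentModelSpec",
    "TrainedModel",
    "lstm_cell_step",
    "gru_cell_step",
    "init_params",
    "forward_stacked",
    "loss_and_grads",
    "train",
    "predict",
    "predict_proba",
    "make_windows",
]

VARIANTS = ("lstm", "bilstm", "projected_lstm", "gru")


@dataclass(frozen=True)
class RecurrentModelSpec:
    """Architecture hyperparameters of one stacked recurrent classifier."""

    variant: str = "lstm"
    input_dim: int = 7
    fc1_dim: int = 32  # m
    hidden: int = 100  # inner size LS
    projection: int = 32  # p, projected variant only (p < LS)
    n_classes: int = 3
    forget_bias: float = 1.0
    forget_bias_gate: str = "forget"  # or "output" (strict printed form)
    window_length: int = 20
    stride: int = 1

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ParameterError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if min(self.input_dim, self.fc1_dim, self.hidden, self.n_classes) < 1:
            raise ParameterError("all dimensions must be positive")
        if self.variant == "projected_lstm" and not 0 < self.projection < self.hidden:
            raise ParameterError("projection dim must satisfy 0 < p < LS")
        if self.forget_bias_gate not in ("forget", "output"):
            raise ParameterError("forget_bias_gate must be 'forget' or 'output'")

    @property
    def recurrent_state_dim(self) -> int:
        """Width of the state fed back and passed to the output layer."""
        if self.variant == "projected_lstm":
            return self.projection
        return self.hidden

    @property
    def fc2_input_dim(self) -> int:
        return 2 * self.hidden if self.variant == "bilstm" else self.recurrent_state_dim


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (np.tanh(0.5 * x) + 1.0)  # numerically stable


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], dtype) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def init_params(spec: RecurrentModelSpec, seed: int = 0, dtype=np.float32) -> dict:
    """Seeded Glorot-uniform initialization; biases start at zero."""
    rng = np.random.default_rng(seed)
    m, H, p, C = spec.fc1_dim, spec.hidden, spec.projection, spec.n_classes
    params: dict[str, np.ndarray] = {
        "W1": _glorot(rng, (spec.input_dim, m), dtype),
        "b1": np.zeros(m, dtype=dtype),
    }

    def lstm_block(prefix: str, state_dim: int) -> None:
        params[f"{prefix}Wx"] = _glorot(rng, (m, 4 * H), dtype)
        params[f"{prefix}Wh"] = _glorot(rng, (state_dim, 4 * H), dtype)
        params[f"{prefix}b"] = np.zeros(4 * H, dtype=dtype)

    if spec.variant == "lstm":
        lstm_block("", H)
    elif spec.variant == "bilstm":
        lstm_block("f_", H)
        lstm_block("r_", H)
    elif spec.variant == "projected_lstm":
        lstm_block("", p)
        params["P"] = _glorot(rng, (H, p), dtype)
    elif spec.variant == "gru":
        params["Wx"] = _glorot(rng, (m, 3 * H), dtype)
        params["Wh"] = _glorot(rng, (H, 3 * H), dtype)
        params["b"] = np.zeros(3 * H, dtype=dtype)

    params["W2"] = _glorot(rng, (spec.fc2_input_dim, C), dtype)
    params["b2"] = np.zeros(C, dtype=dtype)
    return params


# ---------------------------------------------------------------------------
# single cell steps (public, used by the stack and directly testable)


def lstm_cell_step(
    x_t: np.ndarray,
    h_prev: np.ndarray,
    c_prev: np.ndarray,
    Wx: np.ndarray,
    Wh: np.ndarray,
    b: np.ndarray,
    forget_bias: float = 1.0,
    forget_bias_gate: str = "forget",
) -> tuple[np.ndarray, np.ndarray, dict]:
    """One LSTM step; returns (h_t, c_t, cache) with batched inputs (B, ·)."""
    if not (np.all(np.isfinite(x_t)) and np.all(np.isfinite(h_prev)) and np.all(np.isfinite(c_prev))):
        raise ParameterError("non-finite inputs to lstm_cell_step")
    H = b.shape[0] // 4
    pre = x_t @ Wx + h_prev @ Wh + b
    a_i, a_f, a_g, a_o = pre[..., :H], pre[..., H : 2 * H], pre[..., 2 * H : 3 * H], pre[..., 3 * H :]
    if forget_bias_gate == "forget":
        a_f = a_f + forget_bias
    else:
        a_o = a_o + forget_bias
    i, f, o = _sigmoid(a_i), _sigmoid(a_f), _sigmoid(a_o)
    g = np.tanh(a_g)
    c = f * c_prev + i * g
    hc = np.tanh(c)
    h = o * hc
    cache = {"x": x_t, "h_prev": h_prev, "c_prev": c_prev, "i": i, "f": f, "g": g, "o": o,
             "c": c, "hc": hc}
    return h, c, cache


def _lstm_cell_backward(
    dh: np.ndarray, dc: np.ndarray, cache: dict, Wx: np.ndarray, Wh: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Backward through one LSTM step.

    Returns (dx, dh_prev, dc_prev, grads) where grads hold dWx, dWh, db
    contributions of this step.
    """
    i, f, g, o, c_prev, hc = cache["i"], cache["f"], cache["g"], cache["o"], cache["c_prev"], cache["hc"]
    do = dh * hc
    dc = dc + dh * o * (1.0 - hc * hc)
    di = dc * g
    dg = dc * i
    df = dc * c_prev
    dc_prev = dc * f
    da_i = di * i * (1.0 - i)
    da_f = df * f * (1.0 - f)
    da_g = dg * (1.0 - g * g)
    da_o = do * o * (1.0 - o)
    dpre = np.concatenate([da_i, da_f, da_g, da_o], axis=-1)
    grads = {
        "Wx": cache["x"].T @ dpre,
        "Wh": cache["h_prev"].T @ dpre,
        "b": dpre.sum(axis=0),
    }
    dx = dpre @ Wx.T
    dh_prev = dpre @ Wh.T
    return dx, dh_prev, dc_prev, grads


def gru_cell_step(
    x_t: np.ndarray,
    h_prev: np.ndarray,
    Wx: np.ndarray,
    Wh: np.ndarray,
    b: np.ndarray,
) -> tuple[np.ndarray, dict]:
    """One GRU step: h_t = z*h_prev + (1-z)*n; zero weights give h_prev/2."""
    if not (np.all(np.isfinite(x_t)) and np.all(np.isfinite(h_prev))):
        raise ParameterError("non-finite inputs to gru_cell_step")
    H = b.shape[0] // 3
    px = x_t @ Wx + b
    ph = h_prev @ Wh
    a_z = px[..., :H] + ph[..., :H]
    a_r = px[..., H : 2 * H] + ph[..., H : 2 * H]
    z, r = _sigmoid(a_z), _sigmoid(a_r)
    hn = ph[..., 2 * H :]
    a_n = px[..., 2 * H :] + r * hn
    n = np.tanh(a_n)
    h = z * h_prev + (1.0 - z) * n
    cache = {"x": x_t, "h_prev": h_prev, "z": z, "r": r, "n": n, "hn": hn}
    return h, cache


def _gru_cell_backward(
    dh: np.ndarray, cache: dict, Wx: np.ndarray, Wh: np.ndarray
) -> tuple[np.ndarray, np.ndarray, dict]:
    z, r, n, hn, h_prev = cache["z"], cache["r"], cache["n"], cache["hn"], cache["h_prev"]
    H = z.shape[-1]
    dz = dh * (h_prev - n)
    dn = dh * (1.0 - z)
    dh_prev = dh * z
    da_n = dn * (1.0 - n * n)
    dr = da_n * hn
    dhn = da_n * r
    da_z = dz * z * (1.0 - z)
    da_r = dr * r * (1.0 - r)
    dpre_x = np.concatenate([da_z, da_r, da_n], axis=-1)  # grads wrt x-side pre-activations
    dph = np.concatenate([da_z, da_r, dhn], axis=-1)  # grads wrt h_prev @ Wh
    grads = {
        "Wx": cache["x"].T @ dpre_x,
        "Wh": h_prev.T @ dph,
        "b": dpre_x.sum(axis=0),
    }
    dx = dpre_x @ Wx.T
    dh_prev = dh_prev + dph @ Wh.T
    return dx, dh_prev, grads


# ---------------------------------------------------------------------------
# stacked forward / backward


def _softmax(logits: np.ndarray) -> np.ndarray:
    m = logits.max(axis=-1, keepdims=True)
    e = np.exp(logits - m)
    return e / e.sum(axis=-1, keepdims=True)


def forward_stacked(
    windows: np.ndarray, spec: RecurrentModelSpec, params: dict, return_cache: bool = False
):
    """Class probabilities for feature windows of shape (B, T, input_dim).

    Per-frame FC + ReLU, a recurrent pass over the window, final state(s)
    through the output FC and softmax.  Probabilities sum to one to within
    numerical precision.
    """
    X = np.asarray(windows)
    if X.ndim == 2:
        X = X[None]
    if X.ndim != 3 or X.shape[2] != spec.input_dim:
        raise ParameterError(f"windows must be (B, T, {spec.input_dim}), got {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ParameterError("non-finite features")
    B, T, _ = X.shape
    H = spec.hidden
    dtype = params["W1"].dtype
    X = X.astype(dtype, copy=False)

    Z1 = X @ params["W1"] + params["b1"]
    A1 = np.maximum(Z1, 0.0)

    caches: dict = {"Z1": Z1, "A1": A1, "X": X, "steps": []}

    if spec.variant in ("lstm", "projected_lstm"):
        S = spec.recurrent_state_dim
        s = np.zeros((B, S), dtype=dtype)
        c = np.zeros((B, H), dtype=dtype)
        for t in range(T):
            h, c, cache = lstm_cell_step(
                A1[:, t], s, c, params["Wx"], params["Wh"], params["b"],
                spec.forget_bias, spec.forget_bias_gate,
            )
            if spec.variant == "projected_lstm":
                cache["h"] = h
                s = h @ params["P"]
            else:
                s = h
            caches["steps"].append(cache)
        final = s
    elif spec.variant == "bilstm":
        hf = np.zeros((B, H), dtype=dtype)
        cf = np.zeros((B, H), dtype=dtype)
        hr = np.zeros((B, H), dtype=dtype)
        cr = np.zeros((B, H), dtype=dtype)
        fsteps, rsteps = [], []
        for t in range(T):
            hf, cf, cache = lstm_cell_step(
                A1[:, t], hf, cf, params["f_Wx"], params["f_Wh"], params["f_b"],
                spec.forget_bias, spec.forget_bias_gate,
            )
            fsteps.append(cache)
        for t in reversed(range(T)):
            hr, cr, cache = lstm_cell_step(
                A1[:, t], hr, cr, params["r_Wx"], params["r_Wh"], params["r_b"],
                spec.forget_bias, spec.forget_bias_gate,
            )
            rsteps.append(cache)
        caches["steps"] = (fsteps, rsteps)
        final = np.concatenate([hf, hr], axis=-1)
    else:  # gru
        h = np.zeros((B, H), dtype=dtype)
        for t in range(T):
            h, cache = gru_cell_step(A1[:, t], h, params["Wx"], params["Wh"], params["b"])
            caches["steps"].append(cache)
        final = h

    logits = final @ params["W2"] + params["b2"]
    probs = _softmax(logits.astype(np.float64)).astype(dtype)
    if return_cache:
        caches["final"] = final
        caches["probs"] = probs
        return probs, caches
    return probs


def loss_and_grads(
    windows: np.ndarray, targets: np.ndarray, spec: RecurrentModelSpec, params: dict
) -> tuple[float, dict]:
    """Mean cross-entropy and exact BPTT gradients for one mini-batch.

    *targets* are class indices 0 … n_classes-1.
    """
    probs, cache = forward_stacked(windows, spec, params, return_cache=True)
    B, T, _ = cache["X"].shape
    y = np.asarray(targets, dtype=int)
    eps = np.finfo(np.float64).tiny
    loss = float(-np.mean(np.log(np.maximum(probs[np.arange(B), y], eps))))

    dlogits = probs.astype(np.float64)
    dlogits[np.arange(B), y] -= 1.0
    dlogits /= B
    dlogits = dlogits.astype(params["W2"].dtype)

    grads = {k: np.zeros_like(v) for k, v in params.items()}
    grads["W2"] = cache["final"].T @ dlogits
    grads["b2"] = dlogits.sum(axis=0)
    dfinal = dlogits @ params["W2"].T

    A1 = cache["A1"]
    dA1 = np.zeros_like(A1)

    def run_lstm_backward(steps, dh_T, Wx, Wh, prefix, time_order, ds_hook=None):
        """BPTT over cached steps; time_order maps step list position -> frame t."""
        dh = dh_T
        dc = np.zeros_like(steps[0]["c"])
        for pos in range(len(steps) - 1, -1, -1):
            t = time_order[pos]
            if ds_hook is not None:
                dh = ds_hook(pos, dh)
            dx, dh, dc, g = _lstm_cell_backward(dh, dc, steps[pos], Wx, Wh)
            dc = dc
            grads[f"{prefix}Wx"] += g["Wx"]
            grads[f"{prefix}Wh"] += g["Wh"]
            grads[f"{prefix}b"] += g["b"]
            dA1[:, t] += dx
        return dh

    if spec.variant == "lstm":
        run_lstm_backward(cache["steps"], dfinal, params["Wx"], params["Wh"], "", list(range(T)))
    elif spec.variant == "projected_lstm":
        P = params["P"]
        steps = cache["steps"]
        ds = dfinal  # gradient wrt the projected state leaving the last step

        def hook(pos, ds_in):
            # ds_in is d(loss)/d(p_pos); convert to d/d(h_pos) and collect dP
            grads["P"] += steps[pos]["h"].T @ ds_in
            return ds_in @ P.T

        run_lstm_backward(steps, ds, params["Wx"], params["Wh"], "", list(range(T)), ds_hook=hook)
    elif spec.variant == "bilstm":
        H = spec.hidden
        fsteps, rsteps = cache["steps"]
        run_lstm_backward(fsteps, dfinal[:, :H], params["f_Wx"], params["f_Wh"], "f_", list(range(T)))
        run_lstm_backward(
            rsteps, dfinal[:, H:], params["r_Wx"], params["r_Wh"], "r_",
            list(reversed(range(T))),
        )
    else:  # gru
        dh = dfinal
        for t in range(T - 1, -1, -1):
            dx, dh, g = _gru_cell_backward(dh, cache["steps"][t], params["Wx"], params["Wh"])
            grads["Wx"] += g["Wx"]
            grads["Wh"] += g["Wh"]
            grads["b"] += g["b"]
            dA1[:, t] += dx

    dZ1 = dA1 * (cache["Z1"] > 0)
    grads["W1"] = np.einsum("btf,btm->fm", cache["X"], dZ1)
    grads["b1"] = dZ1.sum(axis=(0, 1))
    return loss, grads


# ---------------------------------------------------------------------------
# windowing, training, prediction


def make_windows(
    features: np.ndarray,
    labels: np.ndarray,
    window_length: int = 20,
    stride: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding windows over one track's per-frame features.

    The window label is the majority frame label (ties to the smallest class
    code), keeping samples frame-denominated at the default stride of 1.
    """
    F = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    n = len(F)
    if n < window_length:
        return np.empty((0, window_length, F.shape[1])), np.empty(0, dtype=int)
    starts = np.arange(0, n - window_length + 1, stride)
    X = np.stack([F[s : s + window_length] for s in starts])
    w = np.stack([y[s : s + window_length] for s in starts])
    maj = np.array([np.argmax(np.bincount(row)) for row in w], dtype=int)
    return X, maj


@dataclass
class TrainedModel:
    """A trained stacked recurrent classifier with its learning curve.

    ``curve`` has one record per epoch: mean mini-batch training loss, mean
    training accuracy over batches and (when an eval set is given) held-out
    accuracy at the end of the epoch.
    """

    spec: RecurrentModelSpec
    params: dict
    scaler: Optional[FeatureScaler]
    curve: list[dict]
    classes: np.ndarray  # class codes, position = output index
    config: TrainingConfig

    def save(self, path: Union[str, Path]) -> None:
        path = Path(path)
        payload = {f"param_{k}": v for k, v in self.params.items()}
        if self.scaler is not None:
            payload["scaler_mean"] = self.scaler.mean
            payload["scaler_std"] = self.scaler.std
        import json

        payload["meta"] = np.frombuffer(
            json.dumps(
                {
                    "spec": self.spec.__dict__,
                    "curve": self.curve,
                    "classes": self.classes.tolist(),
                    "config": self.config.__dict__,
                }
            ).encode(),
            dtype=np.uint8,
        )
        np.savez(path, **payload)

    @classmethod
    def load(cls, path: Union[str, Path]) -> "TrainedModel":
        import json

        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(bytes(data["meta"].tobytes()).decode())
            params = {k[6:]: data[k] for k in data.files if k.startswith("param_")}
            scaler = None
            if "scaler_mean" in data.files:
                scaler = FeatureScaler(mean=data["scaler_mean"], std=data["scaler_std"])
        cfg = TrainingConfig(**meta["config"])
        return cls(
            spec=RecurrentModelSpec(**meta["spec"]),
            params=params,
            scaler=scaler,
            curve=meta["curve"],
            classes=np.asarray(meta["classes"], dtype=int),
            config=cfg,
        )


class _Adam:
    def __init__(self, params: dict, lr: float, b1: float = 0.9, b2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= (
                self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
            ).astype(params[k].dtype)


class _SGD:
    def __init__(self, params: dict, lr: float):
        self.lr = lr

    def step(self, params: dict, grads: dict) -> None:
        for k, g in grads.items():
            params[k] -= (self.lr * g).astype(params[k].dtype)


def train(
    windows: np.ndarray,
    labels: np.ndarray,
    spec: RecurrentModelSpec,
    config: Optional[TrainingConfig] = None,
    eval_set: Optional[tuple[np.ndarray, np.ndarray]] = None,
    standardize: bool = True,
    dtype=np.float32,
) -> TrainedModel:
    """Train one stacked recurrent classifier.

    *windows* is ``(N, T, input_dim)``, *labels* class codes.  Per-epoch
    reshuffling uses the run seed; iterations per epoch are
    ``floor(N / batch_size)`` (trailing partial batches are dropped, matching
    the fixed-iteration accounting of the training schedule).
    """
    config = config or TrainingConfig()
    X = np.asarray(windows, dtype=np.float64)
    y_codes = np.asarray(labels, dtype=int)
    if len(X) == 0:
        raise ParameterError("empty training set")
    if len(np.unique(y_codes)) < 2:
        raise ParameterError("training needs at least two classes")
    classes = np.unique(y_codes)
    class_index = {c: i for i, c in enumerate(classes)}
    y = np.array([class_index[c] for c in y_codes])

    scaler = None
    if standardize:
        scaler = FeatureScaler.fit(X.reshape(-1, X.shape[2]))
        X = (X - scaler.mean) / scaler.std
    X = X.astype(dtype)

    if eval_set is not None:
        Xe = np.asarray(eval_set[0], dtype=np.float64)
        if scaler is not None:
            Xe = (Xe - scaler.mean) / scaler.std
        Xe = Xe.astype(dtype)
        ye = np.asarray(eval_set[1], dtype=int)

    spec = replace(spec, n_classes=max(spec.n_classes, len(classes)))
    params = init_params(spec, seed=config.seed, dtype=dtype)
    opt = (_Adam if config.optimizer == "adam" else _SGD)(params, config.learning_rate)
    rng = np.random.default_rng(config.seed)

    n = len(X)
    batch = min(config.batch_size, n)
    iters = max(1, n // batch)
    curve: list[dict] = []
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n) if config.shuffle_each_epoch else np.arange(n)
        losses, accs = [], []
        for it in range(iters):
            sel = order[it * batch : (it + 1) * batch]
            loss, grads = loss_and_grads(X[sel], y[sel], spec, params)
            opt.step(params, grads)
            losses.append(loss)
            probs = forward_stacked(X[sel], spec, params)
            accs.append(float(np.mean(np.argmax(probs, axis=1) == y[sel])))
        record = {
            "epoch": epoch,
            "train_loss": float(np.mean(losses)),
            "train_acc": float(np.mean(accs)),
        }
        if eval_set is not None:
            pe = _predict_indices(Xe, spec, params, n_valid=len(classes))
            record["test_acc"] = float(np.mean(classes[pe] == ye))
        curve.append(record)
    return TrainedModel(
        spec=spec, params=params, scaler=scaler, curve=curve, classes=classes, config=config
    )


def _predict_indices(
    X: np.ndarray, spec: RecurrentModelSpec, params: dict, chunk: int = 512,
    n_valid: Optional[int] = None,
) -> np.ndarray:
    out = np.empty(len(X), dtype=int)
    for s in range(0, len(X), chunk):
        probs = forward_stacked(X[s : s + chunk], spec, params)
        if n_valid is not None:
            probs = probs[:, :n_valid]
        out[s : s + chunk] = np.argmax(probs, axis=1)
    return out


def predict_proba(model: TrainedModel, windows: np.ndarray, chunk: int = 512) -> np.ndarray:
    """Class probabilities, columns ordered as ``model.classes``."""
    if not model.params:
        raise PointfallError("model has no parameters")
    X = np.asarray(windows, dtype=np.float64)
    if model.scaler is not None:
        X = (X - model.scaler.mean) / model.scaler.std
    X = X.astype(model.params["W2"].dtype)
    outs = [
        forward_stacked(X[s : s + chunk], model.spec, model.params)
        for s in range(0, len(X), chunk)
    ]
    return np.concatenate(outs, axis=0)[:, : len(model.classes)]


def predict(model: TrainedModel, windows: np.ndarray) -> np.ndarray:
    """Argmax class codes; ties resolve to the smallest class code."""
    probs = predict_proba(model, windows)
    return model.classes[np.argmax(probs, axis=1)]
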