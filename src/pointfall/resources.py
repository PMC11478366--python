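"""Embedded-deployment accounting: parameters, memory, FLOPs, quantization.

Parameter counts follow the stored-weight structure of each variant
(FC: out·(in+1); LSTM gate block: 4·LS·(in+state+1); GRU block:
3·LS·(in+state+1); the projected variant recurs through a p-dimensional
bottleneck, adding LS·p and shrinking its recurrent matrices).  The
single-precision memory footprint is 4 bytes per parameter.

FLOP counting convention (stated because published formulas differ): one
multiply-accumulate = 2 FLOPs, one nonlinearity application = 1 FLOP, one
elementwise add/multiply = 1 FLOP.  Totals are itemized per layer so they
can be re-derived from the shapes.

Fixed-point Qm.n quantization: signed two's-complement with m integer bits
(including sign) and n fraction bits; round-to-nearest with saturation at
the representable range [−2^(m−1), 2^(m−1) − 2^−n].  Quantized inference
emulates integer arithmetic by requantizing after every matrix product and
every nonlinearity (a wide accumulator is assumed for the dot products);
nonlinearities stand in for fixed-point lookup tables.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import ParameterError
from .recurrent import RecurrentModelSpec, TrainedModel, _softmax

__all__ = [
    "ResourceReport",
    "FixedPointFormat",
    "count_params",
    "memory_footprint",
    "count_flops",
    "quantize_model",
    "quantized_predict",
    "QuantizedModel",
]


@dataclass
class ResourceReport:
    parameter_count: int
    footprint_bytes: int
    flops_per_step: int
    flops_per_window: int
    items: dict  # per-layer breakdown

    def to_dict(self) -> dict:
        return {
            "parameter_count": self.parameter_count,
            "footprint_bytes": self.footprint_bytes,
            "flops_per_step": self.flops_per_step,
            "flops_per_window": self.flops_per_window,
            "items": self.items,
        }


def _fc_params(n_in: int, n_out: int) -> int:
    return n_out * (n_in + 1)


def count_params(spec: RecurrentModelSpec) -> int:
    """Closed-form stored-weight count for one stacked recurrent network."""
    m, H, p, C = spec.fc1_dim, spec.hidden, spec.projection, spec.n_classes
    total = _fc_params(spec.input_dim, m)
    if spec.variant == "lstm":
        total += 4 * H * (m + H + 1)
        total += _fc_params(H, C)
    elif spec.variant == "bilstm":
        total += 2 * (4 * H * (m + H + 1))
        total += _fc_params(2 * H, C)
    elif spec.variant == "projected_lstm":
        total += 4 * H * (m + p + 1) + H * p
        total += _fc_params(p, C)
    elif spec.variant == "gru":
        total += 3 * H * (m + H + 1)
        total += _fc_params(H, C)
    return total


def memory_footprint(spec: RecurrentModelSpec, fmt: Optional["FixedPointFormat"] = None) -> int:
    """Bytes of weight storage: IEEE-754 single precision by default, or
    total_bits/8 per parameter under a fixed-point format."""
    n = count_params(spec)
    if fmt is None:
        return 4 * n
    return fmt.total_bits // 8 * n


def _fc_flops(n_in: int, n_out: int) -> int:
    return 2 * n_in * n_out + n_out  # MACs + bias adds


def count_flops(spec: RecurrentModelSpec, window_length: Optional[int] = None) -> ResourceReport:
    """Itemized FLOP count per recurrent step and per input window."""
    T = window_length or spec.window_length
    m, H, p, C = spec.fc1_dim, spec.hidden, spec.projection, spec.n_classes
    items: dict[str, int] = {}
    items["fc1"] = _fc_flops(spec.input_dim, m)
    items["relu"] = m

    def lstm_step(state: int) -> int:
        gates = 2 * (m + state) * (4 * H) + 4 * H  # matmuls + bias
        activations = 4 * H  # 3 sigmoids + tanh blocks
        cell = 3 * H  # f*c + i*g
        out = 2 * H  # tanh(c), o*(.)
        return gates + activations + cell + out

    if spec.variant == "lstm":
        items["recurrent_step"] = lstm_step(H)
    elif spec.variant == "bilstm":
        items["recurrent_step"] = 2 * lstm_step(H)
    elif spec.variant == "projected_lstm":
        items["recurrent_step"] = lstm_step(p) + 2 * H * p  # + projection matmul
    else:  # gru
        gates = 2 * (m + H) * (3 * H) + 3 * H
        activations = 3 * H
        blend = H + 4 * H  # r*Uh, z*h + (1-z)*n
        items["recurrent_step"] = gates + activations + blend

    items["fc2"] = _fc_flops(spec.fc2_input_dim, C)
    items["softmax"] = 3 * C
    per_step = items["fc1"] + items["relu"] + items["recurrent_step"]
    per_window = per_step * T + items["fc2"] + items["softmax"]
    return ResourceReport(
        parameter_count=count_params(spec),
        footprint_bytes=memory_footprint(spec),
        flops_per_step=per_step,
        flops_per_window=per_window,
        items=items,
    )


# ---------------------------------------------------------------------------
# fixed point


@dataclass(frozen=True)
class FixedPointFormat:
    """Signed two's-complement Qm.n: m integer bits (incl. sign), n fraction."""

    total_bits: int
    integer_bits: int
    fraction_bits: int

    def __post_init__(self) -> None:
        if self.total_bits not in (8, 16, 32):
            raise ParameterError("total_bits must be 8, 16 or 32")
        if self.integer_bits + self.fraction_bits != self.total_bits:
            raise ParameterError("integer_bits + fraction_bits must equal total_bits")

    @classmethod
    def from_string(cls, s: str) -> "FixedPointFormat":
        """Parse ``"8(4.4)"``, ``"16(8.8)"``, ``"32(16.16)"`` or ``"8:4.4"``."""
        mt = re.fullmatch(r"\s*(\d+)\s*[(:]\s*(\d+)\.(\d+)\s*\)?\s*", s)
        if not mt:
            raise ParameterError(f"cannot parse fixed-point format {s!r}")
        return cls(int(mt.group(1)), int(mt.group(2)), int(mt.group(3)))

    @property
    def step(self) -> float:
        return 2.0 ** (-self.fraction_bits)

    @property
    def max_value(self) -> float:
        return 2.0 ** (self.integer_bits - 1) - self.step

    @property
    def min_value(self) -> float:
        return -(2.0 ** (self.integer_bits - 1))

    def quantize(self, x: np.ndarray) -> np.ndarray:
        """Round to the grid, saturating at the representable range."""
        scaled = np.round(np.asarray(x, dtype=np.float64) * 2.0**self.fraction_bits)
        return np.clip(scaled * self.step, self.min_value, self.max_value)

    def __str__(self) -> str:
        return f"{self.total_bits}({self.integer_bits}.{self.fraction_bits})"


@dataclass
class QuantizedModel:
    base: TrainedModel
    fmt: FixedPointFormat
    params: dict  # quantized weights
    saturation_rate: float  # fraction of weights clipped by the format


def quantize_model(model: TrainedModel, fmt: FixedPointFormat) -> QuantizedModel:
    """Post-training weight quantization (no quantization-aware retraining)."""
    qparams = {}
    saturated = 0
    total = 0
    for k, v in model.params.items():
        q = fmt.quantize(v)
        saturated += int(np.sum((v > fmt.max_value) | (v < fmt.min_value)))
        total += v.size
        qparams[k] = q.astype(np.float64)
    rate = saturated / max(total, 1)
    if rate > 0.5:
        warnings.warn(
            f"{rate:.0%} of weights saturate in {fmt}; the integer/fraction "
            "split is likely wrong for this model",
            stacklevel=2,
        )
    return QuantizedModel(base=model, fmt=fmt, params=qparams, saturation_rate=rate)


def _q(fmt: FixedPointFormat, x: np.ndarray) -> np.ndarray:
    return fmt.quantize(x)


def quantized_forward(qmodel: QuantizedModel, windows: np.ndarray) -> np.ndarray:
    """Forward pass with Qm.n weights and activations.

    Every matrix product accumulates in a wide register (float64 stand-in)
    and is requantized; every nonlinearity output is requantized, emulating
    a fixed-point lookup table.
    """
    spec = qmodel.base.spec
    fmt = qmodel.fmt
    P = qmodel.params
    X = np.asarray(windows, dtype=np.float64)
    if qmodel.base.scaler is not None:
        X = (X - qmodel.base.scaler.mean) / qmodel.base.scaler.std
    X = _q(fmt, X)
    B, T, _ = X.shape
    H = spec.hidden

    A1 = _q(fmt, np.maximum(_q(fmt, X @ P["W1"] + P["b1"]), 0.0))

    def sigmoid(v):
        return _q(fmt, 0.5 * (np.tanh(0.5 * v) + 1.0))

    def qtanh(v):
        return _q(fmt, np.tanh(v))

    def lstm_pass(prefix: str, order, state_dim: int):
        s = np.zeros((B, state_dim))
        c = np.zeros((B, H))
        for t in order:
            pre = _q(fmt, A1[:, t] @ P[f"{prefix}Wx"] + s @ P[f"{prefix}Wh"] + P[f"{prefix}b"])
            a_i, a_f, a_g, a_o = pre[:, :H], pre[:, H : 2 * H], pre[:, 2 * H : 3 * H], pre[:, 3 * H :]
            if spec.forget_bias_gate == "forget":
                a_f = a_f + spec.forget_bias
            else:
                a_o = a_o + spec.forget_bias
            i, f, o = sigmoid(a_i), sigmoid(a_f), sigmoid(a_o)
            g = qtanh(a_g)
            c = _q(fmt, f * c + i * g)
            h = _q(fmt, o * qtanh(c))
            if spec.variant == "projected_lstm":
                s = _q(fmt, h @ P["P"])
            else:
                s = h
        return s

    if spec.variant in ("lstm", "projected_lstm"):
        final = lstm_pass("", range(T), spec.recurrent_state_dim)
    elif spec.variant == "bilstm":
        hf = lstm_pass("f_", range(T), H)
        hr = lstm_pass("r_", reversed(range(T)), H)
        final = np.concatenate([hf, hr], axis=1)
    else:  # gru
        h = np.zeros((B, H))
        for t in range(T):
            px = _q(fmt, A1[:, t] @ P["Wx"] + P["b"])
            ph = _q(fmt, h @ P["Wh"])
            z = sigmoid(px[:, :H] + ph[:, :H])
            r = sigmoid(px[:, H : 2 * H] + ph[:, H : 2 * H])
            n = qtanh(px[:, 2 * H :] + _q(fmt, r * ph[:, 2 * H :]))
            h = _q(fmt, z * h + (1.0 - z) * n)
        final = h

    logits = _q(fmt, final @ P["W2"] + P["b2"])
    return _softmax(logits)


def quantized_predict(qmodel: QuantizedModel, windows: np.ndarray, chunk: int = 512) -> np.ndarray:
    """Argmax class codes under fixed-point inference."""
    X = np.asarray(windows, dtype=np.float64)
    classes = qmodel.base.classes
    out = np.empty(len(X), dtype=int)
    for s in range(0, len(X), chunk):
        probs = quantized_forward(qmodel, X[s : s + chunk])[:, : len(classes)]
        out[s : s + chunk] = np.argmax(probs, axis=1)
    return classes[out]
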