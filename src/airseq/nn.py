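"""Minimal NumPy recurrent-network kernel: LSTM cell, BPTT, Adam.

The gated cell follows the standard formulation: input, forget and output
gates with logistic activation, a tanh candidate, Hadamard-product state
updates,

    i_t = σ(W_i x_t + U_i h_{t-1} + b_i)
    f_t = σ(W_f x_t + U_f h_{t-1} + b_f)
    o_t = σ(W_o x_t + U_o h_{t-1} + b_o)
    c̃_t = tanh(W_c x_t + U_c h_{t-1} + b_c)
    c_t = f_t ∗ c_{t-1} + i_t ∗ c̃_t
    h_t = o_t ∗ tanh c_t

All arrays are float64.  Everything is deterministic given the seed of the
Generator used to initialize parameters and drive shuffling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AirseqError

# gate block order inside the stacked weight matrices
_GATES = ("i", "f", "o", "c")


def sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))


@dataclass
class LSTMParams:
    """Stacked LSTM weights: rows ordered (input, forget, output, candidate).

    ``W`` is (4H, D) input-to-gate, ``U`` is (4H, H) recurrent, ``b`` is (4H,).
    Per-gate views (``W_i`` … ``b_c``) are exposed as properties.
    """

    W: np.ndarray
    U: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        H4, D = self.W.shape
        if H4 % 4 != 0:
            raise AirseqError("W must have 4*hidden rows")
        H = H4 // 4
        if self.U.shape != (H4, H) or self.b.shape != (H4,):
            raise AirseqError(
                f"inconsistent LSTM shapes W{self.W.shape} U{self.U.shape} b{self.b.shape}"
            )
        if not (
            np.isfinite(self.W).all()
            and np.isfinite(self.U).all()
            and np.isfinite(self.b).all()
        ):
            raise AirseqError("non-finite LSTM parameters")

    @property
    def hidden_size(self) -> int:
        return self.W.shape[0] // 4

    @property
    def input_size(self) -> int:
        return self.W.shape[1]

    def _block(self, arr, gate):
        H = self.hidden_size
        k = _GATES.index(gate)
        return arr[k * H : (k + 1) * H]

    # per-gate views (read/write)
    @property
    def W_i(self):
        return self._block(self.W, "i")

    @property
    def W_f(self):
        return self._block(self.W, "f")

    @property
    def W_o(self):
        return self._block(self.W, "o")

    @property
    def W_c(self):
        return self._block(self.W, "c")

    @property
    def U_i(self):
        return self._block(self.U, "i")

    @property
    def U_f(self):
        return self._block(self.U, "f")

    @property
    def U_o(self):
        return self._block(self.U, "o")

    @property
    def U_c(self):
        return self._block(self.U, "c")

    @property
    def b_i(self):
        return self._block(self.b, "i")

    @property
    def b_f(self):
        return self._block(self.b, "f")

    @property
    def b_o(self):
        return self._block(self.b, "o")

    @property
    def b_c(self):
        return self._block(self.b, "c")

    @classmethod
    def init(cls, input_size: int, hidden_size: int, rng: np.random.Generator,
             forget_bias: float = 1.0) -> "LSTMParams":
        """Glorot-uniform weights, zero biases except forget-gate bias."""
        H = hidden_size
        lim_w = np.sqrt(6.0 / (input_size + H))
        lim_u = np.sqrt(6.0 / (H + H))
        W = rng.uniform(-lim_w, lim_w, size=(4 * H, input_size))
        U = rng.uniform(-lim_u, lim_u, size=(4 * H, H))
        b = np.zeros(4 * H)
        b[H : 2 * H] = forget_bias
        return cls(W, U, b)

    @classmethod
    def zeros(cls, input_size: int, hidden_size: int) -> "LSTMParams":
        H = hidden_size
        return cls(np.zeros((4 * H, input_size)), np.zeros((4 * H, H)), np.zeros(4 * H))


@dataclass
class LSTMState:
    """Hidden and cell state; componentwise |h| < 1 by construction."""

    h: np.ndarray
    c: np.ndarray


def zero_state(hidden_size: int, batch: int | None = None) -> LSTMState:
    shape = (hidden_size,) if batch is None else (batch, hidden_size)
    return LSTMState(np.zeros(shape), np.zeros(shape))


# ----------------------------------------------------------------------
def _gates(params: LSTMParams, x, h):
    H = params.hidden_size
    z = x @ params.W.T + h @ params.U.T + params.b
    i = sigmoid(z[..., :H])
    f = sigmoid(z[..., H : 2 * H])
    o = sigmoid(z[..., 2 * H : 3 * H])
    g = np.tanh(z[..., 3 * H :])
    return i, f, o, g


def lstm_cell_step(params: LSTMParams, x_t: np.ndarray, state: LSTMState) -> LSTMState:
    """One forward step of the gated cell.

    ``x_t`` may be a single input ``(D,)`` or a batch ``(B, D)``; the state
    shape must match.  Raises on any dimension mismatch.
    """
    x_t = np.asarray(x_t, dtype=float)
    if x_t.shape[-1] != params.input_size:
        raise AirseqError(
            f"input width {x_t.shape[-1]} != expected {params.input_size}"
        )
    if state.h.shape != state.c.shape or state.h.shape[-1] != params.hidden_size:
        raise AirseqError("state shape inconsistent with hidden size")
    i, f, o, g = _gates(params, x_t, state.h)
    c = f * state.c + i * g
    h = o * np.tanh(c)
    return LSTMState(h, c)


# ----------------------------------------------------------------------
# BPTT machinery (batched, time-major)
# ----------------------------------------------------------------------
def lstm_step_cached(params: LSTMParams, x, h, c):
    """One batched step returning the new state plus the backward cache."""
    i, f, o, g = _gates(params, x, h)
    c_new = f * c + i * g
    tanh_c = np.tanh(c_new)
    h_new = o * tanh_c
    return h_new, c_new, (x, h, c, i, f, o, g, tanh_c)


def lstm_forward(params: LSTMParams, x_seq: np.ndarray, h0: np.ndarray, c0: np.ndarray):
    """Run the recurrence over ``x_seq`` of shape (T, B, D).

    Returns (hs, (h_T, c_T), cache) where ``hs`` is (T, B, H) and cache holds
    per-step intermediates for :func:`lstm_backward`.
    """
    T, B, _ = x_seq.shape
    H = params.hidden_size
    hs = np.empty((T, B, H))
    cache = []
    h, c = h0, c0
    for t in range(T):
        h, c, cache_t = lstm_step_cached(params, x_seq[t], h, c)
        cache.append(cache_t)
        hs[t] = h
    return hs, (h, c), cache


def cell_backward(params: LSTMParams, cache_t, dh, dc_in, grads):
    """Backward through one cached step; accumulates into ``grads`` in place.

    Returns (dx_t, dh_prev, dc_prev).
    """
    x_t, h_prev, c_prev, i, f, o, g, tanh_c = cache_t
    dc = dc_in + dh * o * (1.0 - tanh_c**2)
    do = dh * tanh_c
    di = dc * g
    df = dc * c_prev
    dg = dc * i
    dz = np.concatenate(
        [di * i * (1 - i), df * f * (1 - f), do * o * (1 - o), dg * (1 - g**2)],
        axis=-1,
    )
    grads["W"] += dz.T @ x_t
    grads["U"] += dz.T @ h_prev
    grads["b"] += dz.sum(axis=0)
    dx_t = dz @ params.W
    dh_prev = dz @ params.U
    dc_prev = dc * f
    return dx_t, dh_prev, dc_prev


def lstm_backward(params: LSTMParams, cache, dh_seq, dh_last, dc_last):
    """Full BPTT over a cached forward pass.

    ``dh_seq`` is (T, B, H) per-step output gradients (or None), ``dh_last``
    and ``dc_last`` are extra gradients flowing into the final state.
    Returns (dx_seq, dh0, dc0, grads dict with keys W/U/b).
    """
    T = len(cache)
    B, H = dh_last.shape
    grads = {
        "W": np.zeros_like(params.W),
        "U": np.zeros_like(params.U),
        "b": np.zeros_like(params.b),
    }
    dx_seq = np.empty((T, B, params.input_size))
    dh_next = dh_last.copy()
    dc_next = dc_last.copy()
    for t in reversed(range(T)):
        dh = dh_next + (dh_seq[t] if dh_seq is not None else 0.0)
        dx_seq[t], dh_next, dc_next = cell_backward(params, cache[t], dh, dc_next, grads)
    return dx_seq, dh_next, dc_next, grads


# ----------------------------------------------------------------------
class Adam:
    """Adam with global-norm gradient clipping; updates arrays in place."""

    def __init__(self, params: dict, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, clip_norm: float = 5.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict) -> None:
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
            if total > self.clip_norm:
                scale = self.clip_norm / total
                grads = {k: g * scale for k, g in grads.items()}
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            p -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
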