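"""Forecasting models: encoder-decoder LSTM with a weekly-lag input channel,
the same model without it, and two single-network baselines.

The proposed forecaster encodes the 24-hour composite input (previous-day air
quality, previous-day meteorology, week-ago target pollutant) into a context
with an LSTM, then decodes 24 hourly target values autoregressively: each
decoder step consumes the previous output y_{t'-1}, updates its hidden state
s_{t'}, and projects s_{t'} linearly to y_{t'}.  The context is, by default,
the encoder's final (h_T, c_T) handed to the decoder as its initial state; a
uniform mean over all encoder hidden states is available as an alternative
("mean" context rule).  During training the decoder is teacher-forced with a
configurable per-step probability; at inference it always feeds back its own
predictions.

The baselines replace the decoder with a dense 24-output head on the final
encoder state: "lstm" (unidirectional) and "bilstm" (bidirectional,
concatenated final states).  All four variants are trained with Adam on the
mean-squared error of scaled targets; metrics are computed on unscaled
concentrations elsewhere.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .errors import NotFittedError, TrainingError
from .io_station import Scaler
from .nn import (
    Adam,
    LSTMParams,
    cell_backward,
    lstm_backward,
    lstm_forward,
    lstm_step_cached,
)
from .station import HOURS_PER_DAY
from .windowing import SampleWindow, WindowSpec

VARIANTS = ("seq2seq_weekly", "seq2seq", "bilstm", "lstm")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (the architecture itself lives in the model)."""

    epochs: int = 200
    batch_size: int = 32
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    teacher_forcing_ratio: float = 0.5
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.patience < 0:
            raise ValueError("epochs, batch_size must be >= 1 and patience >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not 0.0 <= self.teacher_forcing_ratio <= 1.0:
            raise ValueError("teacher_forcing_ratio must be in [0, 1]")
        if self.optimizer != "adam":
            raise ValueError("only the 'adam' optimizer is implemented")


# ======================================================================
class Seq2SeqForecaster:
    """Encoder-decoder forecaster (variants ``seq2seq_weekly`` / ``seq2seq``)."""

    def __init__(self, window_spec: WindowSpec, hidden_size: int = 64,
                 context_rule: str = "final", seed: int = 0,
                 variant: str = "seq2seq_weekly"):
        if context_rule not in ("final", "mean"):
            raise ValueError("context_rule must be 'final' or 'mean'")
        rng = np.random.default_rng(seed)
        self.variant = variant
        self.window_spec = window_spec
        self.hidden_size = hidden_size
        self.context_rule = context_rule
        self.enc = LSTMParams.init(window_spec.n_features, hidden_size, rng)
        # decoder consumes the scalar previous output; its hidden size equals
        # the encoder's so the context state can be handed over directly
        self.dec = LSTMParams.init(1, hidden_size, rng)
        lim = np.sqrt(6.0 / (hidden_size + 1))
        self.V = rng.uniform(-lim, lim, size=hidden_size)
        self.bv = np.zeros(1)
        self.y0 = np.zeros(1)  # learned start token for the first decoder step
        self.trained_ = False

    # -- parameter plumbing -------------------------------------------
    def parameters(self) -> dict:
        return {
            "enc.W": self.enc.W, "enc.U": self.enc.U, "enc.b": self.enc.b,
            "dec.W": self.dec.W, "dec.U": self.dec.U, "dec.b": self.dec.b,
            "V": self.V, "bv": self.bv, "y0": self.y0,
        }

    @property
    def param_count(self) -> int:
        return sum(v.size for v in self.parameters().values())

    @property
    def encoder_param_count(self) -> int:
        return self.enc.W.size + self.enc.U.size + self.enc.b.size

    # -- forward -------------------------------------------------------
    def encode(self, x: np.ndarray):
        """Context for one window (24, F) or a batch (B, 24, F).

        Returns (h_context, c_context); for a single window both are (H,).
        """
        single = x.ndim == 2
        xb = x[None] if single else x
        h_ctx, c_T, _, _ = self._encode_batch(xb)
        return (h_ctx[0], c_T[0]) if single else (h_ctx, c_T)

    def _encode_batch(self, xb: np.ndarray):
        B = xb.shape[0]
        x_seq = np.ascontiguousarray(xb.transpose(1, 0, 2))
        H = self.hidden_size
        hs, (h_T, c_T), cache = lstm_forward(
            self.enc, x_seq, np.zeros((B, H)), np.zeros((B, H))
        )
        h_ctx = hs.mean(axis=0) if self.context_rule == "mean" else h_T
        return h_ctx, c_T, hs, cache

    def decode(self, context, y_teacher=None, tf_mask=None, with_cache=False):
        """Autoregressive generation of 24 scaled outputs from a context.

        ``context`` is an (h, c) pair, single (H,) or batched (B, H).
        ``tf_mask[t]`` (training only) feeds the observed ``y_teacher[:, t]``
        instead of the prediction into step t+1.
        """
        h_ctx, c_ctx = context
        single = h_ctx.ndim == 1
        h = h_ctx[None] if single else h_ctx
        c = c_ctx[None] if single else c_ctx
        B = h.shape[0]
        preds = np.empty((B, HOURS_PER_DAY))
        dec_cache, dec_hs, sources = [], [], []
        y_in = np.full((B, 1), self.y0[0])
        src = "start"
        for t in range(HOURS_PER_DAY):
            h, c, cache_t = lstm_step_cached(self.dec, y_in, h, c)
            y_t = h @ self.V + self.bv[0]
            preds[:, t] = y_t
            dec_cache.append(cache_t)
            dec_hs.append(h)
            sources.append(src)
            if tf_mask is not None and y_teacher is not None and tf_mask[t]:
                y_in = y_teacher[:, t : t + 1]
                src = "teacher"
            else:
                y_in = y_t[:, None]
                src = "pred"
        out = preds[0] if single else preds
        if with_cache:
            return out, (dec_cache, dec_hs, sources, preds)
        return out

    def forward(self, xb: np.ndarray, y_teacher=None, tf_mask=None) -> np.ndarray:
        h_ctx, c_T, _, _ = self._encode_batch(xb)
        return self.decode((h_ctx, c_T), y_teacher, tf_mask)

    # -- backward ------------------------------------------------------
    def loss_and_grads(self, xb, yb, tf_mask=None):
        B = xb.shape[0]
        h_ctx, c_T, hs, enc_cache = self._encode_batch(xb)
        preds, (dec_cache, dec_hs, sources, _) = self.decode(
            (h_ctx, c_T), y_teacher=yb, tf_mask=tf_mask, with_cache=True
        )
        resid = preds - yb
        loss = float(np.mean(resid**2))
        d_preds = 2.0 * resid / resid.size

        H = self.hidden_size
        dec_g = {"W": np.zeros_like(self.dec.W), "U": np.zeros_like(self.dec.U),
                 "b": np.zeros_like(self.dec.b)}
        dV = np.zeros_like(self.V)
        dbv = np.zeros(1)
        dy0 = np.zeros(1)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        carry = np.zeros(B)  # gradient reaching preds[:, t] through step t+1's input
        for t in reversed(range(HOURS_PER_DAY)):
            dy = d_preds[:, t] + carry
            dV += dec_hs[t].T @ dy
            dbv[0] += dy.sum()
            dh = dy[:, None] * self.V[None, :] + dh_next
            dx, dh_next, dc_next = cell_backward(self.dec, dec_cache[t], dh, dc_next, dec_g)
            if sources[t] == "pred":
                carry = dx[:, 0]
            else:
                carry = np.zeros(B)
                if sources[t] == "start":
                    dy0[0] += dx[:, 0].sum()

        # gradients entering the encoder through the context
        if self.context_rule == "mean":
            T_enc = len(enc_cache)
            dh_seq = np.broadcast_to(dh_next / T_enc, (T_enc, B, H)).copy()
            dh_last = np.zeros((B, H))
        else:
            dh_seq = None
            dh_last = dh_next
        _, _, _, enc_g = lstm_backward(self.enc, enc_cache, dh_seq, dh_last, dc_next)

        grads = {
            "enc.W": enc_g["W"], "enc.U": enc_g["U"], "enc.b": enc_g["b"],
            "dec.W": dec_g["W"], "dec.U": dec_g["U"], "dec.b": dec_g["b"],
            "V": dV, "bv": dbv, "y0": dy0,
        }
        return loss, grads


# ======================================================================
class DirectForecaster:
    """Recurrent encoder + dense 24-output head (variants ``lstm``/``bilstm``)."""

    def __init__(self, window_spec: WindowSpec, hidden_size: int = 64,
                 bidirectional: bool = False, seed: int = 0, variant: str = "lstm"):
        rng = np.random.default_rng(seed)
        self.variant = variant
        self.window_spec = window_spec
        self.hidden_size = hidden_size
        self.bidirectional = bidirectional
        self.context_rule = "final"
        F = window_spec.n_features
        self.fwd = LSTMParams.init(F, hidden_size, rng)
        self.bwd = LSTMParams.init(F, hidden_size, rng) if bidirectional else None
        width = hidden_size * (2 if bidirectional else 1)
        lim = np.sqrt(6.0 / (width + HOURS_PER_DAY))
        self.head_W = rng.uniform(-lim, lim, size=(HOURS_PER_DAY, width))
        self.head_b = np.zeros(HOURS_PER_DAY)
        self.trained_ = False

    def parameters(self) -> dict:
        out = {"fwd.W": self.fwd.W, "fwd.U": self.fwd.U, "fwd.b": self.fwd.b,
               "head.W": self.head_W, "head.b": self.head_b}
        if self.bwd is not None:
            out.update({"bwd.W": self.bwd.W, "bwd.U": self.bwd.U, "bwd.b": self.bwd.b})
        return out

    @property
    def param_count(self) -> int:
        return sum(v.size for v in self.parameters().values())

    @property
    def encoder_param_count(self) -> int:
        n = self.fwd.W.size + self.fwd.U.size + self.fwd.b.size
        if self.bwd is not None:
            n += self.bwd.W.size + self.bwd.U.size + self.bwd.b.size
        return n

    def _run(self, xb):
        B = xb.shape[0]
        H = self.hidden_size
        x_seq = np.ascontiguousarray(xb.transpose(1, 0, 2))
        _, (hT_f, _), cache_f = lstm_forward(self.fwd, x_seq, np.zeros((B, H)), np.zeros((B, H)))
        if self.bwd is not None:
            _, (hT_b, _), cache_b = lstm_forward(
                self.bwd, x_seq[::-1], np.zeros((B, H)), np.zeros((B, H))
            )
            h_final = np.concatenate([hT_f, hT_b], axis=1)
        else:
            hT_b, cache_b = None, None
            h_final = hT_f
        preds = h_final @ self.head_W.T + self.head_b
        return preds, h_final, cache_f, cache_b

    def forward(self, xb, y_teacher=None, tf_mask=None) -> np.ndarray:
        return self._run(xb)[0]

    def loss_and_grads(self, xb, yb, tf_mask=None):
        B = xb.shape[0]
        H = self.hidden_size
        preds, h_final, cache_f, cache_b = self._run(xb)
        resid = preds - yb
        loss = float(np.mean(resid**2))
        d_preds = 2.0 * resid / resid.size

        d_head_W = d_preds.T @ h_final
        d_head_b = d_preds.sum(axis=0)
        dh_final = d_preds @ self.head_W
        zeros = np.zeros((B, H))
        _, _, _, g_f = lstm_backward(self.fwd, cache_f, None, dh_final[:, :H].copy(), zeros.copy())
        grads = {"fwd.W": g_f["W"], "fwd.U": g_f["U"], "fwd.b": g_f["b"],
                 "head.W": d_head_W, "head.b": d_head_b}
        if self.bwd is not None:
            _, _, _, g_b = lstm_backward(
                self.bwd, cache_b, None, dh_final[:, H:].copy(), zeros.copy()
            )
            grads.update({"bwd.W": g_b["W"], "bwd.U": g_b["U"], "bwd.b": g_b["b"]})
        return loss, grads


# ======================================================================
def build_variant(variant: str, window_spec: WindowSpec, hidden_size: int = 64,
                  context_rule: str = "final", seed: int = 0):
    """Construct one of the four model variants.

    The weekly-lag input channel is forced on for ``seq2seq_weekly`` and off
    for every other variant, so the returned model's ``window_spec`` is the
    one to build samples with.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    spec = dataclasses.replace(
        window_spec, include_weekly_channel=(variant == "seq2seq_weekly")
    )
    if variant in ("seq2seq_weekly", "seq2seq"):
        return Seq2SeqForecaster(spec, hidden_size, context_rule, seed, variant=variant)
    return DirectForecaster(
        spec, hidden_size, bidirectional=(variant == "bilstm"), seed=seed, variant=variant
    )


# ======================================================================
def _stack(samples: Sequence[SampleWindow]):
    X = np.stack([s.x for s in samples])
    Y = np.stack([s.y for s in samples])
    return X, Y


def evaluate_loss(model, samples: Sequence[SampleWindow]) -> float:
    """Teacher-free mean-squared error on scaled targets."""
    X, Y = _stack(samples)
    preds = model.forward(X)
    return float(np.mean((preds - Y) ** 2))


def train(model, samples: Sequence[SampleWindow], cfg: TrainConfig,
          val_samples: Optional[Sequence[SampleWindow]] = None) -> List[dict]:
    """Fit a model with Adam on scaled MSE; returns the loss history.

    Teacher forcing (per-step Bernoulli with ``cfg.teacher_forcing_ratio``)
    applies only to the autoregressive decoder and only during training.
    Early stopping monitors the validation loss when ``val_samples`` is given
    (mean training batch loss otherwise) with ``cfg.patience``; the best
    parameters are restored before returning.  Fixed seed, data and config
    give an identical history on one device.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 training samples")
    X, Y = _stack(samples)
    Xv, Yv = _stack(val_samples) if val_samples else (None, None)
    rng = np.random.default_rng(cfg.seed)
    params = model.parameters()
    opt = Adam(params, lr=cfg.learning_rate)

    history: List[dict] = []
    best = np.inf
    best_params = {k: v.copy() for k, v in params.items()}
    bad = 0
    for epoch in range(cfg.epochs):
        perm = rng.permutation(len(X))
        batch_losses = []
        for start in range(0, len(X), cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            tf_mask = rng.random(HOURS_PER_DAY) < cfg.teacher_forcing_ratio
            loss, grads = model.loss_and_grads(X[idx], Y[idx], tf_mask)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            opt.step(grads)
            batch_losses.append(loss)
        train_loss = float(np.mean(batch_losses))
        if Xv is not None:
            preds = model.forward(Xv)
            val_loss = float(np.mean((preds - Yv) ** 2))
            monitor = val_loss
        else:
            val_loss = None
            monitor = train_loss
        history.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        if monitor < best - 1e-12:
            best = monitor
            best_params = {k: v.copy() for k, v in params.items()}
            bad = 0
        else:
            bad += 1
            if bad > cfg.patience:
                break
    for k, v in params.items():
        v[...] = best_params[k]
    model.trained_ = True
    return history


def predict(model, sample: SampleWindow, scaler: Scaler) -> np.ndarray:
    """24 next-day concentrations in original units for one window."""
    if not getattr(model, "trained_", False):
        raise NotFittedError("model must be trained before predict()")
    if not scaler.is_fitted:
        raise NotFittedError("scaler must be fitted before predict()")
    preds_scaled = model.forward(sample.x[None])[0]
    return scaler.inverse_values(preds_scaled, model.window_spec.target_pollutant)


# ======================================================================
# checkpoint serialization (JSON, text-only)
# ======================================================================
def save_model(model, path, scaler: Optional[Scaler] = None,
               extra: Optional[dict] = None) -> None:
    blob = {
        "variant": model.variant,
        "hidden_size": model.hidden_size,
        "context_rule": model.context_rule,
        "window_spec": dataclasses.asdict(model.window_spec),
        "trained": bool(getattr(model, "trained_", False)),
        "arrays": {k: v.tolist() for k, v in model.parameters().items()},
        "scaler": scaler.to_dict() if scaler is not None else None,
        "extra": extra or {},
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(blob, fh)


def load_model(path):
    """Returns (model, scaler-or-None)."""
    with open(path, encoding="utf-8") as fh:
        blob = json.load(fh)
    spec = WindowSpec(**blob["window_spec"])
    model = build_variant(
        blob["variant"], spec, hidden_size=blob["hidden_size"],
        context_rule=blob["context_rule"],
    )
    for k, v in model.parameters().items():
        v[...] = np.asarray(blob["arrays"][k])
    model.trained_ = blob["trained"]
    scaler = Scaler.from_dict(blob["scaler"]) if blob["scaler"] else None
    return model, scaler
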