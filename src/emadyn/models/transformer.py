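"""Autoregressive encoder-decoder Transformer for EMA forecasting.

The decoder stream carries the observation history with causal multi-head
self-attention and sinusoidal positional encoding; the encoder stream carries
the intervention inputs, to which the decoder cross-attends under the same
causal mask (decoder position t sees input rows up to t, which are known when
the forecast for t+1 is issued). Position t of the decoder output predicts
observation t+1. Trained with Adam on randomly sampled context windows.
"""

from __future__ import annotations

import numpy as np

from ._base import BaseForecaster
from .._autograd import Adam, Tensor, concatenate, relu, softmax


def _positional_encoding(T: int, d: int) -> np.ndarray:
    pos = np.arange(T)[:, None]
    i = np.arange(d)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d)
    pe = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return pe


def _causal_mask(T: int) -> np.ndarray:
    return np.triu(np.full((T, T), -1e9), k=1)


class TransformerForecaster(BaseForecaster):
    """Small encoder-decoder Transformer (pure numpy/autograd)."""

    def __init__(self, n_layers: int = 1, n_heads: int = 2, d_model: int = 32,
                 d_ff: int = 64, context: int = 32, lr: float = 1e-3,
                 epochs: int = 100, random_state: int = 0):
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.d_model = d_model
        self.d_ff = d_ff
        self.context = context
        self.lr = lr
        self.epochs = epochs
        self.random_state = random_state

    # ------------------------------------------------------------- components
    def _mha(self, q_in: Tensor, kv_in: Tensor, W: dict, mask: np.ndarray) -> Tensor:
        """Masked multi-head attention; q_in (Tq,d), kv_in (Tk,d)."""
        d_h = self.d_model // self.n_heads
        heads = []
        Q = q_in @ W["Wq"]; K = kv_in @ W["Wk"]; V = kv_in @ W["Wv"]
        for h in range(self.n_heads):
            sl = slice(h * d_h, (h + 1) * d_h)
            Qh, Kh, Vh = Q[:, sl], K[:, sl], V[:, sl]
            scores = (Qh @ Kh.T) * (1.0 / np.sqrt(d_h))
            attn = softmax(scores, axis=-1, additive_mask=mask)
            heads.append(attn @ Vh)
        return concatenate(heads, axis=-1) @ W["Wo"]

    @staticmethod
    def _layernorm(x: Tensor, g: Tensor, b: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) / ((var + 1e-6) ** 0.5) * g + b

    def _init_params(self, rng, n: int, m: int) -> dict:
        d, f = self.d_model, self.d_ff

        def mat(a, b):
            return Tensor(rng.normal(0, 1 / np.sqrt(a), size=(a, b)))

        def attn_block():
            return {"Wq": mat(d, d), "Wk": mat(d, d), "Wv": mat(d, d), "Wo": mat(d, d)}

        def ln():
            return {"g": Tensor(np.ones(d)), "b": Tensor(np.zeros(d))}

        P = {"emb_x": mat(n, d), "emb_u": mat(max(m, 1), d),
             "out_W": mat(d, n), "out_b": Tensor(np.zeros(n))}
        P["enc"] = [{"attn": attn_block(), "ln1": ln(), "ln2": ln(),
                     "ff1": mat(d, f), "ff1b": Tensor(np.zeros(f)),
                     "ff2": mat(f, d), "ff2b": Tensor(np.zeros(d))}
                    for _ in range(self.n_layers)]
        P["dec"] = [{"attn": attn_block(), "cross": attn_block(),
                     "ln1": ln(), "ln2": ln(), "ln3": ln(),
                     "ff1": mat(d, f), "ff1b": Tensor(np.zeros(f)),
                     "ff2": mat(f, d), "ff2b": Tensor(np.zeros(d))}
                    for _ in range(self.n_layers)]
        return P

    @staticmethod
    def _collect(P) -> list:
        out = []
        stack = [P]
        while stack:
            node = stack.pop()
            if isinstance(node, Tensor):
                out.append(node)
            elif isinstance(node, dict):
                stack.extend(node.values())
            elif isinstance(node, list):
                stack.extend(node)
        return out

    def _forward(self, X_win: np.ndarray, U_win: np.ndarray, P: dict) -> Tensor:
        """Predictions for positions 1..T given rows 0..T-1 of X and U."""
        T = X_win.shape[0]
        mask = _causal_mask(T)
        pe = _positional_encoding(T, self.d_model)
        u_in = U_win if U_win.shape[1] else np.zeros((T, 1))
        enc = Tensor(u_in, requires_grad=False) @ P["emb_u"] + Tensor(pe, requires_grad=False)
        for layer in P["enc"]:
            enc = self._layernorm(enc + self._mha(enc, enc, layer["attn"], mask),
                                  layer["ln1"]["g"], layer["ln1"]["b"])
            ff = relu(enc @ layer["ff1"] + layer["ff1b"]) @ layer["ff2"] + layer["ff2b"]
            enc = self._layernorm(enc + ff, layer["ln2"]["g"], layer["ln2"]["b"])
        dec = Tensor(X_win, requires_grad=False) @ P["emb_x"] + Tensor(pe, requires_grad=False)
        for layer in P["dec"]:
            dec = self._layernorm(dec + self._mha(dec, dec, layer["attn"], mask),
                                  layer["ln1"]["g"], layer["ln1"]["b"])
            dec = self._layernorm(dec + self._mha(dec, enc, layer["cross"], mask),
                                  layer["ln2"]["g"], layer["ln2"]["b"])
            ff = relu(dec @ layer["ff1"] + layer["ff1b"]) @ layer["ff2"] + layer["ff2b"]
            dec = self._layernorm(dec + ff, layer["ln3"]["g"], layer["ln3"]["b"])
        return dec @ P["out_W"] + P["out_b"]

    # --------------------------------------------------------------------- fit
    def fit(self, X, U=None):
        X, U = self._validate(X, U)
        T, n = X.shape
        if T < self.context:
            raise ValueError(f"series length {T} is shorter than context "
                             f"{self.context}")
        rng = np.random.default_rng(self.random_state)
        P = self._init_params(rng, n, U.shape[1])
        params = self._collect(P)
        opt = Adam(params, lr=self.lr)
        mask = ~np.isnan(X)
        X0 = np.where(mask, X, 0.0)
        L = self.context
        self.loss_curve_ = []
        for _ in range(self.epochs):
            start = int(rng.integers(0, max(T - L, 0) + 1))
            sl = slice(start, start + L)
            out = self._forward(X0[sl], U[sl], P)
            # position t predicts observation t+1
            tgt_rows = np.arange(start + 1, min(start + L, T))
            pred = out[:tgt_rows.size]
            cm = Tensor(mask[tgt_rows].astype(float), requires_grad=False)
            target = Tensor(X0[tgt_rows], requires_grad=False)
            n_cells = max(mask[tgt_rows].sum(), 1)
            loss = (((pred - target) * cm) ** 2).sum() * (1.0 / n_cells)
            if not np.isfinite(loss.data):
                raise FloatingPointError("non-finite Transformer loss")
            opt.zero_grad()
            loss.backward()
            opt.step()
            self.loss_curve_.append(float(loss.data))
        self._P = P
        self.n_items_, self.n_inputs_ = n, U.shape[1]
        self._X_tail = X0[-L:]
        self._U_tail = U[-L:]
        return self

    # ----------------------------------------------------------------- predict
    def predict(self, U_future=None, horizon: int = 7) -> np.ndarray:
        U_future = self._future_inputs(U_future, horizon, self.n_inputs_)
        X_ctx = self._X_tail.copy()
        U_ctx = self._U_tail.copy()
        preds = np.empty((horizon, self.n_items_))
        for k in range(horizon):
            # attach the input driving this transition to the latest observation
            U_step = U_ctx.copy()
            if U_step.shape[1]:
                U_step[-1] = U_future[k]
            out = self._forward(X_ctx, U_step, self._P)
            preds[k] = out.data[-1]
            X_ctx = np.vstack([X_ctx[1:], preds[k][None, :]])
            U_ctx = np.vstack([U_step[1:], np.zeros((1, self.n_inputs_))]) \
                if U_step.shape[1] else U_step
        return preds
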