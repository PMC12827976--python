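"""Shallow piecewise-linear RNN state-space model trained by BPTT with
generalized teacher forcing (GTF).

Latent dynamics
    z_t = A z_{t-1} + W1 (relu(W2 z_{t-1} + b) - relu(W2 z_{t-1})) + h + C u_{t-1}
    x_t = B z_t + eps_t

A is diagonal by default (shallow-PLRNN convention), optionally dense. During
training the latent state carried forward is the convex combination
alpha * (data-inferred state) + (1 - alpha) * (model state), where the
data-inferred state is pinv(B) x_t; the loss is the masked squared error of
the model-predicted observations. Training is deterministic given the seed.
"""

from __future__ import annotations

import numpy as np

from ._base import BaseForecaster
from .._autograd import Adam, Tensor, relu


class PLRNNForecaster(BaseForecaster):
    """GTF-trained shallow PLRNN.

    Fitted attributes: ``A_`` (l x l), ``W1_, W2_, b_, h_, C_, B_``,
    diagonal observation covariance ``Gamma_``, final latent state
    ``z_last_`` and the training ``loss_curve_``.
    """

    def __init__(self, latent_dim: int = 10, hidden_dim: int = 32,
                 gtf_alpha: float = 0.1, epochs: int = 100, lr: float = 1e-3,
                 seq_len: int = 7, batch_size: int = 16,
                 connectivity: str = "diag", random_state: int = 0):
        self.latent_dim = latent_dim
        self.hidden_dim = hidden_dim
        self.gtf_alpha = gtf_alpha
        self.epochs = epochs
        self.lr = lr
        self.seq_len = seq_len
        self.batch_size = batch_size
        self.connectivity = connectivity
        self.random_state = random_state

    # ----------------------------------------------------------------- helpers
    def _step_t(self, z: Tensor, u: np.ndarray, P: dict) -> Tensor:
        """One latent transition on the tape; ``z`` is (batch, l)."""
        if self.connectivity == "diag":
            lin = z * P["a"]
        else:
            lin = z @ P["A"].T
        pre = z @ P["W2"].T
        phi = relu(pre + P["b"]) - relu(pre)
        out = lin + phi @ P["W1"].T + P["h"]
        if u.shape[1]:
            out = out + Tensor(u, requires_grad=False) @ P["C"].T
        return out

    def latent_step(self, z: np.ndarray, u: np.ndarray) -> np.ndarray:
        """Deterministic numpy transition for rollouts and perturbations."""
        pre = self.W2_ @ z
        phi = self.W1_ @ (np.maximum(pre + self.b_, 0) - np.maximum(pre, 0))
        return self.A_ @ z + phi + self.h_ + self.C_ @ u

    # --------------------------------------------------------------------- fit
    def fit(self, X, U=None):
        if self.seq_len < 2:
            raise ValueError("seq_len must be >= 2")
        if not 0.0 <= self.gtf_alpha <= 1.0:
            raise ValueError("gtf_alpha must lie in [0, 1]")
        X, U = self._validate(X, U)
        T, n = X.shape
        l, H, m = self.latent_dim, self.hidden_dim, U.shape[1]
        rng = np.random.default_rng(self.random_state)

        P = {
            "W1": Tensor(rng.normal(0, 1 / np.sqrt(H), size=(l, H))),
            "W2": Tensor(rng.normal(0, 1 / np.sqrt(l), size=(H, l))),
            "b": Tensor(rng.normal(0, 0.1, size=H)),
            "h": Tensor(np.zeros(l)),
            "C": Tensor(np.zeros((l, m))),
            "B": Tensor(rng.normal(0, 1 / np.sqrt(l), size=(n, l))),
        }
        if self.connectivity == "diag":
            P["a"] = Tensor(rng.uniform(0.3, 0.9, size=l))
        elif self.connectivity == "dense":
            A0 = rng.normal(0, 1, size=(l, l))
            A0 *= 0.5 / np.max(np.abs(np.linalg.eigvals(A0)))
            P["A"] = Tensor(A0)
        else:
            raise ValueError("connectivity must be 'diag' or 'dense'")

        mask = ~np.isnan(X)
        X0 = np.where(mask, X, 0.0)
        row_obs = mask.any(axis=1).astype(float)[:, None]
        opt = Adam(list(P.values()), lr=self.lr)
        alpha = self.gtf_alpha
        L = min(self.seq_len, T)
        n_starts = max(T - L, 1)
        steps_per_epoch = max(1, n_starts // self.batch_size)
        self.loss_curve_ = []

        for epoch in range(self.epochs):
            epoch_loss = 0.0
            for _ in range(steps_per_epoch):
                starts = rng.integers(0, n_starts, size=min(self.batch_size, n_starts))
                Bpinv = np.linalg.pinv(P["B"].data)
                z_data = X0 @ Bpinv.T  # (T, l), detached encoder states
                z = Tensor(z_data[starts], requires_grad=False)
                loss = None
                n_cells = 0
                for s in range(1, L):
                    t_rows = starts + s
                    zbar = self._step_t(z, U[t_rows - 1], P)
                    xhat = zbar @ P["B"].T
                    cm = Tensor(mask[t_rows].astype(float), requires_grad=False)
                    target = Tensor(X0[t_rows], requires_grad=False)
                    sq = ((xhat - target) * cm) ** 2
                    loss = sq.sum() if loss is None else loss + sq.sum()
                    n_cells += int(mask[t_rows].sum())
                    # GTF interpolation toward the data-inferred state
                    ro = Tensor(row_obs[t_rows], requires_grad=False)
                    zd = Tensor(z_data[t_rows], requires_grad=False)
                    z = zbar + (zd - zbar) * (alpha * ro)
                if n_cells == 0:
                    continue
                loss = loss * (1.0 / n_cells)
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"non-finite PLRNN loss at epoch {epoch}; "
                        f"lr={self.lr}, alpha={alpha}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data)
            self.loss_curve_.append(epoch_loss / steps_per_epoch)

        # freeze numpy parameters
        self.A_ = np.diag(P["a"].data) if self.connectivity == "diag" else P["A"].data.copy()
        self.W1_, self.W2_ = P["W1"].data.copy(), P["W2"].data.copy()
        self.b_, self.h_ = P["b"].data.copy(), P["h"].data.copy()
        self.C_, self.B_ = P["C"].data.copy(), P["B"].data.copy()
        self.n_items_, self.n_inputs_ = n, m

        # teacher-forced pass over the full series: residual variance + final state
        Bpinv = np.linalg.pinv(self.B_)
        z_data = X0 @ Bpinv.T
        z = z_data[0]
        resid_sq = np.zeros(n); counts = np.zeros(n)
        for t in range(1, T):
            zbar = self.latent_step(z, U[t - 1])
            xhat = self.B_ @ zbar
            obs = mask[t]
            resid_sq[obs] += (X[t, obs] - xhat[obs]) ** 2
            counts[obs] += 1
            z = zbar + alpha * row_obs[t, 0] * (z_data[t] - zbar)
        gam = np.where(counts > 0, resid_sq / np.maximum(counts, 1), 1.0)
        self.Gamma_ = np.diag(np.maximum(gam, 1e-6))
        self.z_last_ = z
        return self

    # ----------------------------------------------------------------- predict
    def predict(self, U_future=None, horizon: int = 7) -> np.ndarray:
        U_future = self._future_inputs(U_future, horizon, self.n_inputs_)
        z = self.z_last_.copy()
        preds = np.empty((horizon, self.n_items_))
        for k in range(horizon):
            z = self.latent_step(z, U_future[k])
            preds[k] = self.B_ @ z
        return preds
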