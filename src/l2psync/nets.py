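"""A small recurrent convolutional network over per-iteration frames, in
pure numpy.

Backbone of the GraphLRCN classifier: each time frame (an adjacency-masked
phase-agreement matrix, see ``classifiers.encode_lrcn_frames``) passes
through a shared convolutional encoder (3x3 convolution, 2x2 max-pool,
3x3 convolution, then an affine + ReLU projection), the encoded sequence
is consumed by a single-layer LSTM, and the final hidden state feeds a
logistic head.  Convolution is worthwhile here because the generators
number nodes in ring order, so waves travelling along the underlying
lattice appear as local motifs near the adjacency diagonal; a purely
affine frame encoder (``encoder="dense"``) is available for graphs
without such order.

Training is Adam on the binary cross-entropy with mini-batches,
backpropagation through time, and early stopping on a held-out validation
split.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["RecurrentFrameNet"]


def _sigmoid(x):
    return 0.5 * (np.tanh(0.5 * x) + 1.0)


# Convolution in channels-last layout as nine shifted matmuls: for 3x3
# kernels at these sizes this avoids the memory traffic of an im2col.

def _conv_forward(x, W, b):
    """x: (B, H, W, C); W: (3, 3, C, F); same padding.

    Each kernel offset contributes one large 2-D GEMM over the flattened
    shifted input.
    """
    B, H, Wd, C = x.shape
    F = W.shape[3]
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    out = np.broadcast_to(b, (B, H, Wd, F)).copy()
    o2 = out.reshape(-1, F)
    for di in range(3):
        for dj in range(3):
            xs = np.ascontiguousarray(xp[:, di : di + H, dj : dj + Wd, :]).reshape(-1, C)
            o2 += xs @ W[di, dj]
    return out, xp


def _conv_backward(dout, xp, W):
    """Gradients of _conv_forward; ``xp`` is the padded input."""
    B, H, Wd, _ = dout.shape
    C, F = W.shape[2], W.shape[3]
    d2 = dout.reshape(-1, F)
    dW = np.empty_like(W)
    dxp = np.zeros_like(xp)
    for di in range(3):
        for dj in range(3):
            xs = np.ascontiguousarray(xp[:, di : di + H, dj : dj + Wd, :]).reshape(-1, C)
            dW[di, dj] = xs.T @ d2
            dxp[:, di : di + H, dj : dj + Wd, :] += (d2 @ W[di, dj].T).reshape(B, H, Wd, C)
    db = d2.sum(axis=0)
    return dW, db, dxp[:, 1:-1, 1:-1, :]


def _maxpool2(x):
    """2x2 stride-2 max pool (channels last); first-wins tie masks."""
    a = x[:, 0::2, 0::2]
    b = x[:, 0::2, 1::2]
    c = x[:, 1::2, 0::2]
    d = x[:, 1::2, 1::2]
    out = np.maximum(np.maximum(a, b), np.maximum(c, d))
    ma = a == out
    mb = (b == out) & ~ma
    mc = (c == out) & ~ma & ~mb
    md = (d == out) & ~ma & ~mb & ~mc
    return out, (ma, mb, mc, md)


def _maxpool2_backward(dout, masks):
    ma, mb, mc, md = masks
    B, Ho, Wo, C = dout.shape
    dx = np.zeros((B, 2 * Ho, 2 * Wo, C), dtype=dout.dtype)
    dx[:, 0::2, 0::2] = dout * ma
    dx[:, 0::2, 1::2] = dout * mb
    dx[:, 1::2, 0::2] = dout * mc
    dx[:, 1::2, 1::2] = dout * md
    return dx


class RecurrentFrameNet:
    """Shared frame encoder -> LSTM -> logistic head, trained with Adam."""

    def __init__(
        self,
        encoder: str = "conv",
        channels: tuple = (8, 16),
        enc_dim: int = 64,
        hidden_dim: int = 64,
        lr: float = 1e-3,
        max_epochs: int = 30,
        batch_size: int = 64,
        val_fraction: float = 0.1,
        patience: int = 5,
        seed: int = 0,
        dtype=np.float32,
    ):
        if encoder not in ("conv", "dense"):
            raise ValueError("encoder must be 'conv' or 'dense'")
        self.encoder = encoder
        self.channels = tuple(channels)
        self.enc_dim = enc_dim
        self.hidden_dim = hidden_dim
        self.lr = lr
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.val_fraction = val_fraction
        self.patience = patience
        self.seed = seed
        self.dtype = np.dtype(dtype)
        self.params_: dict[str, np.ndarray] | None = None
        self.frame_shape_: tuple | None = None

    # -- shaping ------------------------------------------------------------

    def _prepare(self, F: np.ndarray) -> np.ndarray:
        """To (B, T, H, W) for conv (zero-padded to even size) or (B, T, d) for dense."""
        F = np.asarray(F, dtype=self.dtype)
        if self.encoder == "dense":
            if F.ndim == 4:
                F = F.reshape(F.shape[0], F.shape[1], -1)
            return F
        if F.ndim != 4 or F.shape[2] != F.shape[3]:
            raise ValueError("conv encoder expects (B, T, n, n) square frames")
        n = F.shape[2]
        pad = (-n) % 4  # two 2x2 pools need a multiple of 4
        if pad:
            F = np.pad(F, ((0, 0), (0, 0), (0, pad), (0, pad)))
        return F

    # -- parameters ---------------------------------------------------------

    def _init_params(self, frame_shape: tuple, rng) -> dict[str, np.ndarray]:
        e, h = self.enc_dim, self.hidden_dim

        def glorot(fan_in, fan_out, shape=None):
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-lim, lim, size=shape or (fan_in, fan_out)).astype(self.dtype)

        p = {}
        if self.encoder == "conv":
            (n,) = set(frame_shape)
            c1, c2 = self.channels
            p["W1"] = glorot(9, c1, (3, 3, 1, c1))
            p["b1"] = np.zeros(c1, dtype=self.dtype)
            p["W2"] = glorot(9 * c1, c2, (3, 3, c1, c2))
            p["b2"] = np.zeros(c2, dtype=self.dtype)
            flat = c2 * (n // 4) ** 2
        else:
            (flat,) = frame_shape
        p["We"] = glorot(flat, e)
        p["be"] = np.zeros(e, dtype=self.dtype)
        p["Wx"] = glorot(e, 4 * h)
        p["Wh"] = glorot(h, 4 * h)
        p["b"] = np.zeros(4 * h, dtype=self.dtype)
        p["b"][h : 2 * h] = 1.0  # forget-gate bias
        p["Wo"] = glorot(h, 1)
        p["bo"] = np.zeros(1, dtype=self.dtype)
        return p

    # -- encoder ------------------------------------------------------------

    def _encode_forward(self, Ft, p):
        """One time-slice of frames -> (encoding, cache)."""
        if self.encoder == "dense":
            pre = Ft @ p["We"] + p["be"]
            return np.maximum(pre, 0.0), (pre,)
        x = Ft[:, :, :, None]  # (B, n, n, 1) channels-last
        a1, xp1 = _conv_forward(x, p["W1"], p["b1"])
        r1 = np.maximum(a1, 0.0)
        pool, mask = _maxpool2(r1)
        a2, xp2 = _conv_forward(pool, p["W2"], p["b2"])
        r2 = np.maximum(a2, 0.0)
        pool2, mask2 = _maxpool2(r2)
        flat = pool2.reshape(len(Ft), -1)
        pre = flat @ p["We"] + p["be"]
        return np.maximum(pre, 0.0), (pre, flat, r2, a2, xp2, mask2, mask, a1, xp1)

    def _encode_backward(self, de, cache, Ft, p, g):
        if self.encoder == "dense":
            (pre,) = cache
            dpre = de * (pre > 0)
            g["We"] += Ft.T @ dpre
            g["be"] += dpre.sum(axis=0)
            return
        pre, flat, r2, a2, xp2, mask2, mask, a1, xp1 = cache
        dpre = de * (pre > 0)
        g["We"] += flat.T @ dpre
        g["be"] += dpre.sum(axis=0)
        dpool2 = (dpre @ p["We"].T).reshape(r2.shape[0], r2.shape[1] // 2, r2.shape[2] // 2, -1)
        dr2 = _maxpool2_backward(dpool2, mask2)
        da2 = dr2 * (a2 > 0)
        dW2, db2, dpool = _conv_backward(da2, xp2, p["W2"])
        g["W2"] += dW2
        g["b2"] += db2
        dr1 = _maxpool2_backward(dpool, mask)
        da1 = dr1 * (a1 > 0)
        dW1, db1, _ = _conv_backward(da1, xp1, p["W1"])
        g["W1"] += dW1
        g["b1"] += db1

    # -- forward / backward -------------------------------------------------

    def _forward(self, F, p, want_cache=False):
        """F prepared; returns probabilities (B,) and optional cache."""
        B, T = F.shape[:2]
        h_dim = self.hidden_dim
        # encode all B*T frames in one batched call, then unroll the LSTM
        E_all, enc_cache = self._encode_forward(F.reshape(B * T, *F.shape[2:]), p)
        E_all = E_all.reshape(B, T, -1)
        h = np.zeros((B, h_dim), dtype=F.dtype)
        c = np.zeros((B, h_dim), dtype=F.dtype)
        cache = []
        for t in range(T):
            e_t = E_all[:, t]
            z = e_t @ p["Wx"] + h @ p["Wh"] + p["b"]
            i = _sigmoid(z[:, :h_dim])
            f = _sigmoid(z[:, h_dim : 2 * h_dim])
            gg = np.tanh(z[:, 2 * h_dim : 3 * h_dim])
            o = _sigmoid(z[:, 3 * h_dim :])
            c_prev = c
            c = f * c_prev + i * gg
            tc = np.tanh(c)
            h_prev = h
            h = o * tc
            if want_cache:
                cache.append((e_t, i, f, gg, o, c_prev, tc, h_prev))
        logit = (h @ p["Wo"] + p["bo"])[:, 0]
        prob = _sigmoid(logit)
        return prob, (cache, enc_cache, h) if want_cache else None

    def _backward(self, F, y, p):
        """Mean BCE loss and gradients via BPTT."""
        B, T = F.shape[:2]
        h_dim = self.hidden_dim
        prob, (cache, enc_cache, h_T) = self._forward(F, p, want_cache=True)
        eps = 1e-12
        loss = -np.mean(y * np.log(prob + eps) + (1 - y) * np.log(1 - prob + eps))
        g = {k: np.zeros_like(v) for k, v in p.items()}
        dlogit = ((prob - y) / B)[:, None]
        g["Wo"] = h_T.T @ dlogit
        g["bo"] = dlogit.sum(axis=0)
        dh = dlogit @ p["Wo"].T
        dc = np.zeros((B, h_dim), dtype=F.dtype)
        dE = np.empty((B, T, cache[0][0].shape[1]), dtype=F.dtype)
        for t in range(T - 1, -1, -1):
            e_t, i, f, gg, o, c_prev, tc, h_prev = cache[t]
            do = dh * tc
            dc = dc + dh * o * (1 - tc * tc)
            di = dc * gg
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - gg * gg),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            g["Wx"] += e_t.T @ dz
            g["Wh"] += h_prev.T @ dz
            g["b"] += dz.sum(axis=0)
            dE[:, t] = dz @ p["Wx"].T
            dh = dz @ p["Wh"].T
            dc = dc * f
        self._encode_backward(
            dE.reshape(B * T, -1), enc_cache, F.reshape(B * T, *F.shape[2:]), p, g
        )
        return loss, g

    # -- training -----------------------------------------------------------

    def fit(self, F: np.ndarray, y: np.ndarray) -> "RecurrentFrameNet":
        F = self._prepare(F)
        y = np.asarray(y, dtype=self.dtype)
        rng = np.random.default_rng(self.seed)
        self.frame_shape_ = F.shape[2:]
        p = self._init_params(self.frame_shape_, rng)

        n_val = max(1, int(round(self.val_fraction * len(y))))
        order = rng.permutation(len(y))
        val_idx, train_idx = order[:n_val], order[n_val:]
        F_tr, y_tr = F[train_idx], y[train_idx]
        F_val, y_val = F[val_idx], y[val_idx]

        m = {k: np.zeros_like(v) for k, v in p.items()}
        v = {k: np.zeros_like(v_) for k, v_ in p.items()}
        b1m, b2m, eps = 0.9, 0.999, 1e-8
        step = 0
        best_loss, best_params, bad_epochs = np.inf, None, 0
        for _epoch in range(self.max_epochs):
            idx = rng.permutation(len(y_tr))
            for start in range(0, len(idx), self.batch_size):
                batch = idx[start : start + self.batch_size]
                _, grads = self._backward(F_tr[batch], y_tr[batch], p)
                step += 1
                for k in p:
                    m[k] = b1m * m[k] + (1 - b1m) * grads[k]
                    v[k] = b2m * v[k] + (1 - b2m) * grads[k] ** 2
                    mhat = m[k] / (1 - b1m**step)
                    vhat = v[k] / (1 - b2m**step)
                    p[k] = p[k] - self.lr * mhat / (np.sqrt(vhat) + eps)
            val_prob, _ = self._forward(F_val, p)
            val_loss = -np.mean(
                y_val * np.log(val_prob + 1e-12) + (1 - y_val) * np.log(1 - val_prob + 1e-12)
            )
            if val_loss < best_loss - 1e-5:
                best_loss = val_loss
                best_params = {k: v_.copy() for k, v_ in p.items()}
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs >= self.patience:
                    break
        self.params_ = best_params if best_params is not None else p
        return self

    def predict_proba(self, F: np.ndarray) -> np.ndarray:
        if self.params_ is None:
            raise RuntimeError("net is not fitted")
        F = self._prepare(F)
        if F.shape[0] == 0:
            return np.zeros(0)
        if F.shape[2:] != self.frame_shape_:
            raise ValueError(
                f"frame shape {F.shape[2:]} differs from fitted {self.frame_shape_}"
            )
        prob, _ = self._forward(F, self.params_)
        return prob
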