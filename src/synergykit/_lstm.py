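"""Minimal batched Bi-LSTM engine in numpy.

Implements exactly what the angle regressor needs — stacked
bidirectional LSTM layers with inter-layer dropout, a per-timestep
linear readout, mean-squared-error loss, manual backpropagation through
time, and Adam — with no framework dependency.  All heavy operations
are batched matrix products, so training runs at BLAS speed; float32 is
used by default, float64 is available for gradient checking.

Cell equations (forget-gate LSTM, no peepholes), gates ordered i,f,g,o:

    z_t = x_t Wx + h_{t-1} Wh + b
    i, f, o = sigmoid(z);  g = tanh(z)
    c_t = f * c_{t-1} + i * g
    h_t = o * tanh(c_t)
"""

from __future__ import annotations

import numpy as np


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def init_bilstm_params(
    n_features: int,
    hidden_units: int,
    n_layers: int,
    rng: np.random.Generator,
    dtype=np.float32,
):
    """Uniform(-k, k) initialization with k = 1/sqrt(H) (the standard
    recurrent-net default); forget-gate bias starts at 1."""
    H = hidden_units
    params = []
    for layer in range(n_layers):
        fan_in = n_features if layer == 0 else 2 * H
        k = 1.0 / np.sqrt(H)
        layer_p = {}
        for d in ("f", "b"):
            layer_p[f"Wx_{d}"] = rng.uniform(-k, k, (fan_in, 4 * H)).astype(dtype)
            layer_p[f"Wh_{d}"] = rng.uniform(-k, k, (H, 4 * H)).astype(dtype)
            bias = np.zeros(4 * H, dtype=dtype)
            bias[H : 2 * H] = 1.0
            layer_p[f"b_{d}"] = bias
        params.append(layer_p)
    k = 1.0 / np.sqrt(2 * H)
    out = {
        "Wo": rng.uniform(-k, k, (2 * H, 1)).astype(dtype),
        "bo": np.zeros(1, dtype=dtype),
    }
    return params, out


def _lstm_direction_forward(x, Wx, Wh, b):
    """One direction over x (N, T, F) -> h (N, T, H) plus cache."""
    N, T, _ = x.shape
    H = Wh.shape[0]
    dtype = Wx.dtype
    h = np.zeros((N, H), dtype=dtype)
    c = np.zeros((N, H), dtype=dtype)
    hs = np.empty((N, T, H), dtype=dtype)
    cache = []
    xz = x @ Wx  # precompute input contribution for all t
    for t in range(T):
        z = xz[:, t] + h @ Wh + b
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H : 2 * H])
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = _sigmoid(z[:, 3 * H :])
        c_prev = c
        h_prev = h
        c = f * c_prev + i * g
        tc = np.tanh(c)
        h = o * tc
        hs[:, t] = h
        cache.append((i, f, g, o, c_prev, tc, h_prev))
    return hs, cache


def _lstm_direction_backward(dh_out, x, hs, cache, Wx, Wh):
    """BPTT for one direction.  dh_out (N, T, H) is dL/dh at each step."""
    N, T, F = x.shape
    H = Wh.shape[0]
    dtype = Wx.dtype
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * H, dtype=dtype)
    dx = np.empty_like(x)
    dh_next = np.zeros((N, H), dtype=dtype)
    dc_next = np.zeros((N, H), dtype=dtype)
    dz = np.empty((N, 4 * H), dtype=dtype)
    for t in range(T - 1, -1, -1):
        i, f, g, o, c_prev, tc, h_prev = cache[t]
        dh = dh_out[:, t] + dh_next
        do = dh * tc
        dc = dh * o * (1.0 - tc * tc) + dc_next
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dz[:, :H] = di * i * (1.0 - i)
        dz[:, H : 2 * H] = df * f * (1.0 - f)
        dz[:, 2 * H : 3 * H] = dg * (1.0 - g * g)
        dz[:, 3 * H :] = do * o * (1.0 - o)
        dWx += x[:, t].T @ dz
        dWh += h_prev.T @ dz
        db += dz.sum(axis=0)
        dx[:, t] = dz @ Wx.T
        dh_next = dz @ Wh.T
        dc_next = dc * f
    return dx, dWx, dWh, db


def bilstm_forward(x, params, out, dropout=0.0, rng=None, train=False):
    """Full network forward pass.

    x (N, T, F) -> predictions (N, T).  With train=True, inverted
    dropout with rate ``dropout`` is applied after every Bi-LSTM layer
    and the caches needed for backprop are returned.
    """
    caches = []
    cur = x
    for lp in params:
        hf, cf = _lstm_direction_forward(cur, lp["Wx_f"], lp["Wh_f"], lp["b_f"])
        hb_rev, cb = _lstm_direction_forward(
            cur[:, ::-1], lp["Wx_b"], lp["Wh_b"], lp["b_b"]
        )
        hb = hb_rev[:, ::-1]
        merged = np.concatenate([hf, hb], axis=2)
        mask = None
        if train and dropout > 0.0:
            keep = 1.0 - dropout
            mask = (rng.random(merged.shape) < keep).astype(merged.dtype) / keep
            merged = merged * mask
        caches.append((cur, hf, cf, hb_rev, cb, mask))
        cur = merged
    y = (cur @ out["Wo"]).squeeze(-1) + out["bo"][0]
    return y, cur, caches


def bilstm_backward(dy, last_hidden, caches, params, out):
    """Gradients of the scalar loss given dL/dy (N, T)."""
    grads_out = {
        "Wo": (last_hidden.reshape(-1, last_hidden.shape[-1]).T
               @ dy.reshape(-1, 1)).astype(out["Wo"].dtype),
        "bo": np.array([dy.sum()], dtype=out["bo"].dtype),
    }
    dcur = dy[..., None] * out["Wo"][None, None, :, 0]
    grads = []
    for lp, cache in zip(reversed(params), reversed(caches)):
        x_in, hf, cf, hb_rev, cb, mask = cache
        if mask is not None:
            dcur = dcur * mask
        H = hf.shape[2]
        dhf = dcur[:, :, :H]
        dhb = dcur[:, :, H:]
        dx_f, dWx_f, dWh_f, db_f = _lstm_direction_backward(
            dhf, x_in, hf, cf, lp["Wx_f"], lp["Wh_f"]
        )
        dx_b_rev, dWx_b, dWh_b, db_b = _lstm_direction_backward(
            dhb[:, ::-1], x_in[:, ::-1], hb_rev, cb, lp["Wx_b"], lp["Wh_b"]
        )
        dcur = dx_f + dx_b_rev[:, ::-1]
        grads.append(
            {
                "Wx_f": dWx_f, "Wh_f": dWh_f, "b_f": db_f,
                "Wx_b": dWx_b, "Wh_b": dWh_b, "b_b": db_b,
            }
        )
    grads.reverse()
    return grads, grads_out


def mse_loss_and_grad(y_pred, y_true):
    diff = y_pred - y_true
    loss = float(np.mean(diff * diff))
    return loss, (2.0 / diff.size) * diff


class Adam:
    """Standard Adam with global-norm gradient clipping."""

    def __init__(self, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8, clip=5.0):
        self.lr, self.beta1, self.beta2, self.eps, self.clip = (
            lr, beta1, beta2, eps, clip,
        )
        self.t = 0
        self.m = None
        self.v = None

    def step(self, tensors, grads):
        """Update flat lists of arrays in place."""
        if self.m is None:
            self.m = [np.zeros_like(p) for p in tensors]
            self.v = [np.zeros_like(p) for p in tensors]
        if self.clip is not None:
            total = np.sqrt(sum(float(np.sum(g.astype(np.float64) ** 2))
                                for g in grads))
            if total > self.clip:
                scale = self.clip / (total + 1e-12)
                grads = [g * scale for g in grads]
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, g, m, v in zip(tensors, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= (self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)).astype(
                p.dtype
            )


def flatten_params(params, out):
    flat = []
    for lp in params:
        for key in ("Wx_f", "Wh_f", "b_f", "Wx_b", "Wh_b", "b_b"):
            flat.append(lp[key])
    flat.append(out["Wo"])
    flat.append(out["bo"])
    return flat


def count_params(params, out) -> int:
    return int(sum(p.size for p in flatten_params(params, out)))
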