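"""Minimal recurrent-network numerics for the soft sensor.

A single-purpose numpy implementation of the sensor's fixed architecture:

    LSTM(units, cell activation ReLU) -> dropout -> dense(ReLU) -> dropout
        -> dense(1, non-negative kernel and bias)

Gate conventions follow the common i, f, c, o ordering with sigmoid gate
activations, a configurable cell activation (ReLU here), glorot-uniform input
kernels, an orthogonal recurrent kernel and a unit forget-gate bias.  The
non-negativity constraint on the output layer is enforced by projection after
every optimizer step (and at initialization), so predictions are >= 0 for any
input by construction.  Parameters and activations use a configurable dtype
(float64 by default; float32 halves the arithmetic cost of training) and the
whole stack is fully deterministic given the seed.
"""

from __future__ import annotations

from typing import Dict, List, Optional

import numpy as np
from scipy.special import expit

__all__ = ["LSTMNet", "BatchedNets", "Adam"]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


def _orthogonal(rng: np.random.Generator, rows: int, cols: int):
    a = rng.standard_normal((max(rows, cols), min(rows, cols)))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))
    return q if rows >= cols else q.T


def _sigmoid(z):
    return expit(z)


class LSTMNet:
    """The sensor network: parameters, forward pass, and exact gradients."""

    def __init__(self, n_features: int, lstm_units: int = 23,
                 dense_units: int = 10, dropout: float = 0.2, seed: int = 0,
                 dtype=np.float64):
        self.n_features = int(n_features)
        self.units = int(lstm_units)
        self.dense_units = int(dense_units)
        self.dropout = float(dropout)
        self.dtype = np.dtype(dtype)
        # gate memory layout: [input, forget, output | candidate]
        F, H, D = self.n_features, self.units, self.dense_units
        rng = np.random.default_rng(seed)
        b = np.zeros(4 * H)
        b[H:2 * H] = 1.0  # unit forget bias
        params = {
            "Wx": _glorot(rng, F, 4 * H),
            "Wh": _orthogonal(rng, H, 4 * H),
            "b": b,
            "W1": _glorot(rng, H, D),
            "b1": np.zeros(D),
            "W2": np.abs(_glorot(rng, D, 1)),   # projected to the constraint set
            "b2": np.zeros(1),
        }
        self.params: Dict[str, np.ndarray] = {
            k: v.astype(self.dtype) for k, v in params.items()}

    def count_params(self) -> int:
        return sum(p.size for p in self.params.values())

    # ---------------------------------------------------------------- forward
    def forward(self, X: np.ndarray, rng: Optional[np.random.Generator] = None,
                cache: bool = False):
        """Run the network on a batch of windows X (B, T, F).

        ``rng`` enables (inverted) dropout — training mode.  With
        ``cache=True`` returns (yhat, cache) for a subsequent backward pass.
        """
        p = self.params
        X = np.asarray(X, dtype=self.dtype)
        B, T, F = X.shape
        H = self.units
        xW = X.reshape(B * T, F) @ p["Wx"]
        xW = xW.reshape(B, T, 4 * H) + p["b"]
        h = np.zeros((B, H), dtype=self.dtype)
        c = np.zeros((B, H), dtype=self.dtype)
        if cache:
            dt = self.dtype
            Hs = np.empty((T, B, H), dt); Cs = np.empty((T, B, H), dt)
            Ss = np.empty((T, B, 3 * H), dt); Gs = np.empty((T, B, H), dt)
        for t in range(T):
            z = xW[:, t] + h @ p["Wh"]
            s = _sigmoid(z[:, :3 * H])        # input, forget, output gates
            g = np.maximum(z[:, 3 * H:], 0.0)  # candidate (ReLU cell activation)
            i, f, o = s[:, :H], s[:, H:2 * H], s[:, 2 * H:]
            c_new = f * c + i * g
            h = o * np.maximum(c_new, 0.0)
            if cache:
                Ss[t], Gs[t] = s, g
                Cs[t] = c_new
                Hs[t] = h
            c = c_new
        if rng is not None and self.dropout > 0:
            keep = 1.0 - self.dropout
            m1 = ((rng.random((B, H)) < keep) / keep).astype(self.dtype)
            m2_shape = (B, self.dense_units)
        else:
            m1 = None
        hd = h * m1 if m1 is not None else h
        a1 = np.maximum(hd @ p["W1"] + p["b1"], 0.0)
        if m1 is not None:
            keep = 1.0 - self.dropout
            m2 = ((rng.random(m2_shape) < keep) / keep).astype(self.dtype)
            ad = a1 * m2
        else:
            m2 = None
            ad = a1
        yhat = (ad @ p["W2"] + p["b2"]).ravel()
        if not cache:
            return yhat
        cache_d = dict(X=X, Ss=Ss, Gs=Gs, Cs=Cs, Hs=Hs,
                       m1=m1, m2=m2, hd=hd, a1=a1, ad=ad)
        return yhat, cache_d

    # --------------------------------------------------------------- backward
    def backward(self, cache: dict, dyhat: np.ndarray) -> Dict[str, np.ndarray]:
        """Gradients of a scalar loss w.r.t. every parameter.

        ``dyhat`` is dLoss/dyhat, shape (B,).
        """
        p = self.params
        X = cache["X"]
        B, T, F = X.shape
        H = self.units
        dy = np.asarray(dyhat, dtype=self.dtype)[:, None]
        grads = {k: np.zeros_like(v) for k, v in p.items()}

        grads["W2"] = cache["ad"].T @ dy
        grads["b2"] = dy.sum(axis=0)
        dad = dy @ p["W2"].T
        da1 = dad * cache["m2"] if cache["m2"] is not None else dad
        dz1 = da1 * (cache["a1"] > 0)
        grads["W1"] = cache["hd"].T @ dz1
        grads["b1"] = dz1.sum(axis=0)
        dhd = dz1 @ p["W1"].T
        dh = dhd * cache["m1"] if cache["m1"] is not None else dhd

        Ss, Gs, Cs, Hs = cache["Ss"], cache["Gs"], cache["Cs"], cache["Hs"]
        dZ = np.empty((T, B, 4 * H), self.dtype)
        dc = np.zeros((B, H), self.dtype)
        WhT = p["Wh"].T
        zero = np.zeros((B, H), self.dtype)
        for t in range(T - 1, -1, -1):
            s, g, c = Ss[t], Gs[t], Cs[t]
            i, f, o = s[:, :H], s[:, H:2 * H], s[:, 2 * H:]
            c_prev = Cs[t - 1] if t > 0 else zero
            dc = dc + dh * o * (c > 0)
            dz = dZ[t]
            d_ifo = dz[:, :3 * H]
            d_ifo[:, :H] = dc * g
            d_ifo[:, H:2 * H] = dc * c_prev
            d_ifo[:, 2 * H:] = dh * np.maximum(c, 0.0)
            d_ifo *= s * (1.0 - s)            # fused sigmoid derivative
            dz[:, 3 * H:] = dc * i * (g > 0)
            dh = dz @ WhT
            dc = dc * f
        dZf = dZ.transpose(1, 0, 2).reshape(B * T, 4 * H)
        grads["Wx"] = X.reshape(B * T, F).T @ dZf
        grads["b"] = dZf.sum(axis=0)
        # recurrent kernel: h_{t-1} pairs with dz_t
        Hprev = np.concatenate((np.zeros((1, B, H)), Hs[:-1]), axis=0)
        grads["Wh"] = Hprev.reshape(T * B, H).T @ dZ.reshape(T * B, 4 * H)
        return grads

    def project_constraints(self) -> None:
        np.maximum(self.params["W2"], 0.0, out=self.params["W2"])
        np.maximum(self.params["b2"], 0.0, out=self.params["b2"])


class BatchedNets:
    """Several same-architecture nets trained in lock-step.

    Stacks every parameter along a leading trial axis so that one Python-level
    pass through the sequence serves all trials at once (the per-trial math is
    identical to :class:`LSTMNet`; matmuls broadcast over the stack).  Used to
    run a group's independent training trials — which differ in their weight
    initialization — without multiplying the interpreter overhead.
    """

    def __init__(self, nets: List[LSTMNet]):
        archs = {(n.n_features, n.units, n.dense_units, n.dropout) for n in nets}
        if len(archs) != 1:
            raise ValueError("all stacked nets must share one architecture")
        self.nets = nets
        self.E = len(nets)
        self.n_features, self.units, self.dense_units, self.dropout = archs.pop()
        self.dtype = nets[0].dtype
        self.params = {k: np.stack([n.params[k] for n in nets])
                       for k in nets[0].params}

    def unstack(self) -> List[LSTMNet]:
        """Write the stacked parameters back into the individual nets."""
        for e, net in enumerate(self.nets):
            for k in net.params:
                net.params[k] = self.params[k][e].copy()
        return self.nets

    def forward(self, X: np.ndarray, rng: Optional[np.random.Generator] = None,
                cache: bool = False):
        """X is either (B, T, F) shared across the stack or (E, B, T, F)."""
        p = self.params
        X = np.asarray(X, dtype=self.dtype)
        E, H = self.E, self.units
        B, T, F = X.shape[-3], X.shape[-2], X.shape[-1]
        Xflat = X.reshape(B * T, F) if X.ndim == 3 else X.reshape(E, B * T, F)
        xW = np.matmul(Xflat, p["Wx"])                    # (E, B*T, 4H)
        xW = xW.reshape(E, B, T, 4 * H) + p["b"][:, None, None, :]
        h = np.zeros((E, B, H), self.dtype)
        c = np.zeros((E, B, H), self.dtype)
        if cache:
            dt = self.dtype
            Hs = np.empty((T, E, B, H), dt); Cs = np.empty((T, E, B, H), dt)
            Ss = np.empty((T, E, B, 3 * H), dt); Gs = np.empty((T, E, B, H), dt)
        for t in range(T):
            z = np.matmul(h, p["Wh"]) + xW[:, :, t]
            s = _sigmoid(z[..., :3 * H])
            g = np.maximum(z[..., 3 * H:], 0.0)
            i, f, o = s[..., :H], s[..., H:2 * H], s[..., 2 * H:]
            c = f * c + i * g
            h = o * np.maximum(c, 0.0)
            if cache:
                Ss[t], Gs[t], Cs[t], Hs[t] = s, g, c, h
        if rng is not None and self.dropout > 0:
            keep = 1.0 - self.dropout
            m1 = ((rng.random((E, B, H)) < keep) / keep).astype(self.dtype)
            m2 = ((rng.random((E, B, self.dense_units)) < keep) / keep).astype(self.dtype)
        else:
            m1 = m2 = None
        hd = h * m1 if m1 is not None else h
        a1 = np.maximum(np.matmul(hd, p["W1"]) + p["b1"][:, None, :], 0.0)
        ad = a1 * m2 if m2 is not None else a1
        yhat = (np.matmul(ad, p["W2"]) + p["b2"][:, None, :])[..., 0]  # (E, B)
        if not cache:
            return yhat
        return yhat, dict(X=X, Ss=Ss, Gs=Gs, Cs=Cs, Hs=Hs,
                          m1=m1, m2=m2, hd=hd, a1=a1, ad=ad)

    def backward(self, cache: dict, dyhat: np.ndarray) -> Dict[str, np.ndarray]:
        p = self.params
        X = cache["X"]
        E, H = self.E, self.units
        B, T, F = X.shape[-3], X.shape[-2], X.shape[-1]
        grads: Dict[str, np.ndarray] = {}
        dy = np.asarray(dyhat, dtype=self.dtype)[..., None]  # (E, B, 1)
        grads["W2"] = np.matmul(cache["ad"].transpose(0, 2, 1), dy)
        grads["b2"] = dy.sum(axis=1)
        dad = np.matmul(dy, p["W2"].transpose(0, 2, 1))
        da1 = dad * cache["m2"] if cache["m2"] is not None else dad
        dz1 = da1 * (cache["a1"] > 0)
        grads["W1"] = np.matmul(cache["hd"].transpose(0, 2, 1), dz1)
        grads["b1"] = dz1.sum(axis=1)
        dhd = np.matmul(dz1, p["W1"].transpose(0, 2, 1))
        dh = dhd * cache["m1"] if cache["m1"] is not None else dhd

        Ss, Gs, Cs, Hs = cache["Ss"], cache["Gs"], cache["Cs"], cache["Hs"]
        dZ = np.empty((T, E, B, 4 * H), self.dtype)
        dc = np.zeros((E, B, H), self.dtype)
        WhT = p["Wh"].transpose(0, 2, 1)
        zero = np.zeros((E, B, H), self.dtype)
        for t in range(T - 1, -1, -1):
            s, g, c = Ss[t], Gs[t], Cs[t]
            i, f, o = s[..., :H], s[..., H:2 * H], s[..., 2 * H:]
            c_prev = Cs[t - 1] if t > 0 else zero
            dc = dc + dh * o * (c > 0)
            dz = dZ[t]
            d_ifo = dz[..., :3 * H]
            d_ifo[..., :H] = dc * g
            d_ifo[..., H:2 * H] = dc * c_prev
            d_ifo[..., 2 * H:] = dh * np.maximum(c, 0.0)
            d_ifo *= s * (1.0 - s)
            dz[..., 3 * H:] = dc * i * (g > 0)
            dh = np.matmul(dz, WhT)
            dc = dc * f
        # (T,E,B,.) -> (E, B*T, .) in the b-major order of X.reshape(B*T, F)
        dZf = dZ.transpose(1, 2, 0, 3).reshape(E, B * T, 4 * H)
        if X.ndim == 3:
            grads["Wx"] = np.matmul(X.reshape(B * T, F).T, dZf)
        else:
            grads["Wx"] = np.matmul(X.reshape(E, B * T, F).transpose(0, 2, 1), dZf)
        grads["b"] = dZf.sum(axis=1)
        Hprev = np.concatenate((np.zeros((1, E, B, H), self.dtype), Hs[:-1]), axis=0)
        Hp = Hprev.transpose(1, 0, 2, 3).reshape(E, T * B, H)
        dZt = dZ.transpose(1, 0, 2, 3).reshape(E, T * B, 4 * H)
        grads["Wh"] = np.matmul(Hp.transpose(0, 2, 1), dZt)
        return grads

    def project_constraints(self) -> None:
        np.maximum(self.params["W2"], 0.0, out=self.params["W2"])
        np.maximum(self.params["b2"], 0.0, out=self.params["b2"])


class Adam:
    """Adam optimizer over a net's parameter dict (LSTMNet or BatchedNets)."""

    def __init__(self, net, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.net = net
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in net.params.items()}
        self.v = {k: np.zeros_like(v) for k, v in net.params.items()}
        self.t = 0

    def step(self, grads: Dict[str, np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for k, p in self.net.params.items():
            g = grads[k].reshape(p.shape)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            p -= lr_t * self.m[k] / (np.sqrt(self.v[k]) + self.eps)
        self.net.project_constraints()
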