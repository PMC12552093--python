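"""Minimal vectorized neural-network core: GRU / BiGRU encoders, dense layers,
Adam with step learning-rate decay, and the loss gradients used by the kinetic
regressor and the methylation classifier.

Everything is plain numpy with hand-derived backward passes (verified against
central finite differences in the test suite).  Shapes follow the convention
``(batch, time, channels)`` for sequence inputs.

GRU cell (gates ordered ``r, z, n``; the candidate's recurrent term carries its
own bias, applied before the reset gate, so that::

    r_t = sigmoid(x_t Wx_r + h_{t-1} Wh_r + bx_r + bh_r)
    z_t = sigmoid(x_t Wx_z + h_{t-1} Wh_z + bx_z + bh_z)
    n_t = tanh(x_t Wx_n + bx_n + r_t * (h_{t-1} Wh_n + bh_n))
    h_t = (1 - z_t) * n_t + z_t * h_{t-1}
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np

__all__ = [
    "GRUDirection",
    "BiGRU",
    "Dense",
    "Adam",
    "step_lr",
    "softmax",
    "mse_loss_and_grad",
    "focal_smoothed_loss_and_grad",
]


def _uniform_init(rng: np.random.Generator, shape: tuple[int, ...], scale: float) -> np.ndarray:
    return rng.uniform(-scale, scale, size=shape)


# Optional compiled recurrence kernels; the pure-numpy path below is the
# reference implementation and is used when numba is unavailable.
try:
    from numba import njit as _njit

    @_njit(cache=True)
    def _gru_fwd_kernel(GX, Wh, bh):
        B, T, H3 = GX.shape
        H = H3 // 3
        h = np.zeros((B, H))
        rs = np.empty((B, T, H)); zs = np.empty((B, T, H))
        ns = np.empty((B, T, H)); hps = np.empty((B, T, H))
        ghn = np.empty((B, T, H))
        for t in range(T):
            gh = np.dot(h, Wh)
            for i in range(B):
                for j in range(H):
                    r = 1.0 / (1.0 + np.exp(-(GX[i, t, j] + gh[i, j] + bh[j])))
                    z = 1.0 / (1.0 + np.exp(-(GX[i, t, H + j] + gh[i, H + j] + bh[H + j])))
                    gn = gh[i, 2 * H + j] + bh[2 * H + j]
                    n = np.tanh(GX[i, t, 2 * H + j] + r * gn)
                    hps[i, t, j] = h[i, j]
                    rs[i, t, j] = r; zs[i, t, j] = z; ns[i, t, j] = n
                    ghn[i, t, j] = gn
                    h[i, j] = (1.0 - z) * n + z * h[i, j]
        return h, rs, zs, ns, hps, ghn

    @_njit(cache=True)
    def _gru_bwd_kernel(WhT, rs, zs, ns, hps, ghn, dh_final):
        B, T, H = rs.shape
        dG = np.empty((B, T, 3 * H))
        dGh = np.empty((B, T, 3 * H))
        dh = dh_final.copy()
        for t in range(T - 1, -1, -1):
            for i in range(B):
                for j in range(H):
                    r = rs[i, t, j]; z = zs[i, t, j]; n = ns[i, t, j]
                    dn = dh[i, j] * (1.0 - z)
                    dz = dh[i, j] * (hps[i, t, j] - n)
                    da_n = dn * (1.0 - n * n)
                    dr = da_n * ghn[i, t, j]
                    da_z = dz * z * (1.0 - z)
                    da_r = dr * r * (1.0 - r)
                    dG[i, t, j] = da_r
                    dG[i, t, H + j] = da_z
                    dG[i, t, 2 * H + j] = da_n
                    dGh[i, t, j] = da_r
                    dGh[i, t, H + j] = da_z
                    dGh[i, t, 2 * H + j] = da_n * r
                    dh[i, j] = dh[i, j] * z
            dh += np.dot(np.ascontiguousarray(dGh[:, t]), WhT)
        return dG, dGh

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - exercised only without numba
    _HAVE_NUMBA = False


class GRUDirection:
    """A single-direction GRU returning the final hidden state.

    Parameters are stored in a flat dict so optimizers can iterate them.
    """

    def __init__(self, input_dim: int, hidden: int, rng: np.random.Generator):
        self.input_dim = input_dim
        self.hidden = hidden
        s = 1.0 / math.sqrt(hidden)
        self.params = {
            "Wx": _uniform_init(rng, (input_dim, 3 * hidden), s),
            "Wh": _uniform_init(rng, (hidden, 3 * hidden), s),
            "bx": _uniform_init(rng, (3 * hidden,), s),
            "bh": _uniform_init(rng, (3 * hidden,), s),
        }
        self._cache: dict | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (B, T, D) -> final hidden state (B, H)."""
        B, T, D = x.shape
        H = self.hidden
        Wx, Wh, bx, bh = (self.params[k] for k in ("Wx", "Wh", "bx", "bh"))
        gx = x.reshape(B * T, D) @ Wx
        gx = (gx + bx).reshape(B, T, 3 * H)
        if _HAVE_NUMBA:
            h, rs, zs, ns, hps, ghn = _gru_fwd_kernel(
                np.ascontiguousarray(gx), np.ascontiguousarray(Wh),
                np.ascontiguousarray(bh))
            self._cache = {"x": x, "r": rs, "z": zs, "n": ns, "hp": hps, "ghn": ghn}
            return h
        h = np.zeros((B, H))
        rs = np.empty((B, T, H)); zs = np.empty((B, T, H))
        ns = np.empty((B, T, H)); hps = np.empty((B, T, H))
        ghn = np.empty((B, T, H))
        for t in range(T):
            g_h = h @ Wh + bh
            r = _sigmoid(gx[:, t, :H] + g_h[:, :H])
            z = _sigmoid(gx[:, t, H:2 * H] + g_h[:, H:2 * H])
            n = np.tanh(gx[:, t, 2 * H:] + r * g_h[:, 2 * H:])
            hps[:, t] = h
            h = (1.0 - z) * n + z * h
            rs[:, t] = r; zs[:, t] = z; ns[:, t] = n; ghn[:, t] = g_h[:, 2 * H:]
        self._cache = {"x": x, "r": rs, "z": zs, "n": ns, "hp": hps, "ghn": ghn}
        return h

    def backward(self, dh: np.ndarray) -> tuple[np.ndarray, dict]:
        """dh: gradient w.r.t. final hidden state -> (dx, grads)."""
        c = self._cache
        if c is None:
            raise RuntimeError("backward called before forward")
        x, rs, zs, ns, hps, ghn = c["x"], c["r"], c["z"], c["n"], c["hp"], c["ghn"]
        B, T, D = x.shape
        H = self.hidden
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        if _HAVE_NUMBA:
            dG, dGh = _gru_bwd_kernel(
                np.ascontiguousarray(Wh.T), rs, zs, ns, hps, ghn,
                np.ascontiguousarray(dh))
            return self._collect_grads(x, hps, dG, dGh)
        dG = np.zeros((B, T, 3 * H))   # grads w.r.t. pre-activation input-side gates
        dGh = np.zeros((B, T, 3 * H))  # grads w.r.t. recurrent-side gate terms
        dh = dh.copy()
        for t in range(T - 1, -1, -1):
            r, z, n, hp = rs[:, t], zs[:, t], ns[:, t], hps[:, t]
            dn = dh * (1.0 - z)
            dz = dh * (hp - n)
            dh_prev = dh * z
            da_n = dn * (1.0 - n * n)
            dr = da_n * ghn[:, t]
            da_z = dz * z * (1.0 - z)
            da_r = dr * r * (1.0 - r)
            dG[:, t, :H] = da_r
            dG[:, t, H:2 * H] = da_z
            dG[:, t, 2 * H:] = da_n
            dGh[:, t, :H] = da_r
            dGh[:, t, H:2 * H] = da_z
            dGh[:, t, 2 * H:] = da_n * r
            dh = dh_prev + dGh[:, t] @ Wh.T
        return self._collect_grads(x, hps, dG, dGh)

    def _collect_grads(self, x: np.ndarray, hps: np.ndarray,
                       dG: np.ndarray, dGh: np.ndarray) -> tuple[np.ndarray, dict]:
        B, T, D = x.shape
        H = self.hidden
        dGf = dG.reshape(B * T, 3 * H)
        dGhf = dGh.reshape(B * T, 3 * H)
        grads = {
            "Wx": x.reshape(B * T, D).T @ dGf,
            "Wh": hps.reshape(B * T, H).T @ dGhf,
            "bx": dGf.sum(axis=0),
            "bh": dGhf.sum(axis=0),
        }
        dx = (dGf @ self.params["Wx"].T).reshape(B, T, D)
        return dx, grads


class BiGRU:
    """Bidirectional GRU encoder; output is the concatenation of the two
    directions' final hidden states, shape (B, 2H)."""

    def __init__(self, input_dim: int, hidden: int, rng: np.random.Generator):
        self.fwd = GRUDirection(input_dim, hidden, rng)
        self.bwd = GRUDirection(input_dim, hidden, rng)
        self.hidden = hidden

    @property
    def output_dim(self) -> int:
        return 2 * self.hidden

    def forward(self, x: np.ndarray) -> np.ndarray:
        hf = self.fwd.forward(x)
        hb = self.bwd.forward(x[:, ::-1, :])
        return np.concatenate([hf, hb], axis=1)

    def backward(self, dh: np.ndarray) -> tuple[np.ndarray, dict]:
        H = self.hidden
        dxf, gf = self.fwd.backward(dh[:, :H])
        dxb, gb = self.bwd.backward(dh[:, H:])
        grads = {f"fwd.{k}": v for k, v in gf.items()}
        grads.update({f"bwd.{k}": v for k, v in gb.items()})
        return dxf + dxb[:, ::-1, :], grads

    @property
    def params(self) -> dict[str, np.ndarray]:
        out = {f"fwd.{k}": v for k, v in self.fwd.params.items()}
        out.update({f"bwd.{k}": v for k, v in self.bwd.params.items()})
        return out

    def set_param(self, name: str, value: np.ndarray) -> None:
        side, key = name.split(".", 1)
        getattr(self, side).params[key] = value


class Dense:
    """Affine layer y = x W + b."""

    def __init__(self, input_dim: int, output_dim: int, rng: np.random.Generator):
        s = 1.0 / math.sqrt(input_dim)
        self.params = {
            "W": _uniform_init(rng, (input_dim, output_dim), s),
            "b": _uniform_init(rng, (output_dim,), s),
        }
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, dict]:
        x = self._x
        grads = {"W": x.T @ dy, "b": dy.sum(axis=0)}
        return dy @ self.params["W"].T, grads


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Adam:
    """Adam optimizer over a named parameter dict (Kingma & Ba defaults)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray],
             lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1 ** self.t
        corr2 = 1.0 - b2 ** self.t
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / corr1
            vhat = self.v[k] / corr2
            params[k] -= lr * mhat / (np.sqrt(vhat) + self.eps)


def step_lr(base_lr: float, epoch: int, step_size: int = 10, gamma: float = 0.5) -> float:
    """Learning rate after step decay: ``base_lr * gamma ** floor(epoch / step_size)``.

    ``epoch`` is 0-based, matching the convention that the first ``step_size``
    epochs run at ``base_lr``.
    """
    if step_size < 1:
        raise ValueError("step_size must be >= 1")
    return base_lr * gamma ** (epoch // step_size)


def mse_loss_and_grad(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over all elements, with gradient w.r.t. pred."""
    diff = pred - target
    loss = float(np.mean(diff * diff))
    grad = 2.0 * diff / diff.size
    return loss, grad


def focal_smoothed_loss_and_grad(
    logits: np.ndarray,
    targets: np.ndarray,
    gamma: float = 2.0,
    clamp: float = 1e-7,
) -> tuple[float, np.ndarray]:
    """Focal loss composed with soft (smoothed) two-class targets.

    loss per sample = sum_c  -t_c (1 - p_c)^gamma log(p_c), batch-mean reduced;
    p = softmax(logits).  With hard one-hot targets and gamma=0 this is the
    usual cross-entropy.  Returns (loss, dloss/dlogits).
    """
    p = softmax(logits)
    pc = np.clip(p, clamp, 1.0)
    one_m = 1.0 - pc
    logp = np.log(pc)
    loss = float(np.mean(np.sum(-targets * one_m ** gamma * logp, axis=1)))
    # dl/dp_c for each class, then chain through softmax jacobian
    if gamma == 0.0:
        dl_dp = -targets / pc
    else:
        dl_dp = -targets * (-gamma * one_m ** (gamma - 1.0) * logp + one_m ** gamma / pc)
    # softmax jacobian: dz_k = p_k * (dl_dp_k - sum_c dl_dp_c p_c)
    inner = np.sum(dl_dp * p, axis=1, keepdims=True)
    dlogits = p * (dl_dp - inner) / logits.shape[0]
    return loss, dlogits


def iter_minibatches(n: int, batch: int, rng: np.random.Generator) -> Iterable[np.ndarray]:
    """Seeded shuffled mini-batch index generator for one epoch."""
    order = rng.permutation(n)
    for start in range(0, n, batch):
        yield order[start:start + batch]
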