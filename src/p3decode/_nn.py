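"""NumPy forward/backward engine for the compact convolutional decoder.

No deep-learning framework is assumed: temporal correlations are computed with
FFTs, and gradients for every layer (batch norm, depthwise/separable
convolutions, pooling, dropout, softmax cross-entropy) are hand-derived.
All convolutions are stride-1 with 'same' zero padding, pad_left = (K-1)//2.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as sfft

# ---------------------------------------------------------------------------
# same-padding correlation along the last axis, via FFT
# ---------------------------------------------------------------------------


def _fft_len(t: int, k: int) -> int:
    return sfft.next_fast_len(t + k - 1)


def temporal_corr_forward(x: np.ndarray, w: np.ndarray):
    """Shared-kernel correlation: x (N, C, T), w (F, K) -> y (N, F, C, T).

    y[n,f,c,t] = sum_k w[f,k] * x[n,c,t+k-pad] with zero padding.
    Computation stays in the dtype of ``x`` (float32 for speed in training).
    """
    n_, c_, t_ = x.shape
    f_, k_ = w.shape
    pad = (k_ - 1) // 2
    L = _fft_len(t_, k_)
    xf = sfft.rfft(x, L, axis=-1)
    wrevf = sfft.rfft(np.ascontiguousarray(w[:, ::-1], dtype=x.dtype), L, axis=-1)
    full = sfft.irfft(xf[:, None, :, :] * wrevf[None, :, None, :], L, axis=-1)
    y = full[..., k_ - 1 - pad : k_ - 1 - pad + t_]
    return np.ascontiguousarray(y), (xf, w.shape, t_, L, pad)


def temporal_corr_backward(dy: np.ndarray, w: np.ndarray, cache, need_dx: bool = True):
    xf, wshape, t_, L, pad = cache
    f_, k_ = wshape
    dyf = sfft.rfft(dy, L, axis=-1)
    dx = None
    if need_dx:
        wf = sfft.rfft(np.ascontiguousarray(w, dtype=dy.dtype), L, axis=-1)
        # dx[n,c,t] = sum_{f,k} w[f,k] dy[n,f,c,t-k+pad]  (a convolution)
        dx_full = sfft.irfft(np.einsum("nfcl,fl->ncl", dyf, wf), L, axis=-1)
        dx = np.ascontiguousarray(dx_full[..., pad : pad + t_])
    # dw[f,k] = sum_{n,c,t} x[n,c,t+k-pad] dy[n,f,c,t]  (circular correlation)
    z = sfft.irfft(np.einsum("ncl,nfcl->fl", np.conj(xf), dyf), L, axis=-1)
    idx = (pad - np.arange(k_)) % L
    dw = z[:, idx]
    return dx, dw


def depthwise_corr_forward(x: np.ndarray, w: np.ndarray):
    """Per-map correlation: x (N, F, T), w (F, K) -> y (N, F, T)."""
    n_, f_, t_ = x.shape
    k_ = w.shape[1]
    pad = (k_ - 1) // 2
    L = _fft_len(t_, k_)
    xf = sfft.rfft(x, L, axis=-1)
    wrevf = sfft.rfft(np.ascontiguousarray(w[:, ::-1], dtype=x.dtype), L, axis=-1)
    full = sfft.irfft(xf * wrevf[None], L, axis=-1)
    y = full[..., k_ - 1 - pad : k_ - 1 - pad + t_]
    return np.ascontiguousarray(y), (xf, w.shape, t_, L, pad)


def depthwise_corr_backward(dy: np.ndarray, w: np.ndarray, cache):
    xf, wshape, t_, L, pad = cache
    k_ = wshape[1]
    dyf = sfft.rfft(dy, L, axis=-1)
    wf = sfft.rfft(np.ascontiguousarray(w, dtype=dy.dtype), L, axis=-1)
    dx_full = sfft.irfft(dyf * wf[None], L, axis=-1)
    dx = np.ascontiguousarray(dx_full[..., pad : pad + t_])
    z = sfft.irfft(np.einsum("nfl,nfl->fl", np.conj(xf), dyf), L, axis=-1)
    idx = (pad - np.arange(k_)) % L
    dw = z[:, idx]
    return dx, dw


# ---------------------------------------------------------------------------
# batch normalization over all axes except the feature axis (1)
# ---------------------------------------------------------------------------

BN_EPS = 1e-3
BN_MOMENTUM = 0.99


def _bn_shape(ndim: int, nf: int) -> tuple[int, ...]:
    return (1, nf) + (1,) * (ndim - 2)


def bn_forward(x, gamma, beta, running_mean, running_var, training: bool):
    axes = (0,) + tuple(range(2, x.ndim))
    shape = _bn_shape(x.ndim, x.shape[1])
    if training:
        mu = x.mean(axis=axes)
        var = x.var(axis=axes)
        inv = 1.0 / np.sqrt(var + BN_EPS)
        xhat = (x - mu.reshape(shape)) * inv.reshape(shape)
        running_mean *= BN_MOMENTUM
        running_mean += (1 - BN_MOMENTUM) * mu
        running_var *= BN_MOMENTUM
        running_var += (1 - BN_MOMENTUM) * var
        cache = (xhat, inv, gamma, axes, shape)
        return gamma.reshape(shape) * xhat + beta.reshape(shape), cache
    inv = 1.0 / np.sqrt(running_var + BN_EPS)
    xhat = (x - running_mean.reshape(shape)) * inv.reshape(shape)
    return gamma.reshape(shape) * xhat + beta.reshape(shape), None


def bn_backward(dy, cache):
    xhat, inv, gamma, axes, shape = cache
    m = dy.size // dy.shape[1]
    dgamma = (dy * xhat).sum(axis=axes)
    dbeta = dy.sum(axis=axes)
    dx = (gamma * inv).reshape(shape) / m * (
        m * dy - dbeta.reshape(shape) - xhat * dgamma.reshape(shape)
    )
    return dx, dgamma, dbeta


# ---------------------------------------------------------------------------
# pointwise layers
# ---------------------------------------------------------------------------


def elu_forward(x):
    neg = np.expm1(np.minimum(x, 0.0))
    y = np.where(x > 0, x, neg)
    return y, y


def elu_backward(dy, y):
    return np.where(y > 0, dy, dy * (y + 1.0))


def avgpool_forward(x, k: int):
    n_, f_, t_ = x.shape
    if t_ % k:
        raise ValueError(f"pooling size {k} does not divide length {t_}")
    return x.reshape(n_, f_, t_ // k, k).mean(axis=-1), (x.shape, k)


def avgpool_backward(dy, cache):
    shape, k = cache
    return np.repeat(dy, k, axis=-1).reshape(shape) / k


def dropout_forward(x, p: float, rng: np.random.Generator | None):
    if rng is None or p <= 0:
        return x, None
    mask = (rng.random(x.shape) >= p).astype(x.dtype) / x.dtype.type(1.0 - p)
    return x * mask, mask


def dropout_backward(dy, mask):
    return dy if mask is None else dy * mask


def softmax(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def weighted_ce_loss_grad(probs, labels, sample_w):
    """Mean weighted categorical cross-entropy and its logit gradient."""
    n = probs.shape[0]
    eps = 1e-12
    ll = -np.log(probs[np.arange(n), labels] + eps)
    loss = float(np.mean(sample_w * ll))
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits *= np.asarray(sample_w / n, dtype=probs.dtype)[:, None]
    return loss, dlogits


# ---------------------------------------------------------------------------
# optimizer and constraints
# ---------------------------------------------------------------------------


class Adam:
    """Adam with framework-default hyperparameters (lr 1e-3, 0.9/0.999)."""

    def __init__(self, param_names, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: None for k in param_names}
        self.v = {k: None for k in param_names}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k, g in grads.items():
            if self.m[k] is None:
                self.m[k] = np.zeros_like(params[k])
                self.v[k] = np.zeros_like(params[k])
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def apply_max_norm(w: np.ndarray, max_norm: float, axis) -> None:
    """In-place renormalization so the norm along ``axis`` is <= max_norm."""
    norms = np.sqrt((w**2).sum(axis=axis, keepdims=True))
    factor = np.minimum(1.0, max_norm / np.maximum(norms, 1e-12))
    w *= factor


# ---------------------------------------------------------------------------
# the full network
# ---------------------------------------------------------------------------


DEFAULT_DTYPE = np.float32


def init_params(config, rng: np.random.Generator, dtype=DEFAULT_DTYPE) -> dict:
    f1, d = config.n_temporal_filters, config.depth_multiplier
    f2 = config.n_separable_filters
    c, kt, ks = config.n_channels, config.temporal_kernel_len, config.separable_kernel_len
    feat = f2 * (config.n_samples // (config.pool1 * config.pool2))

    def glorot(shape, fan_in, fan_out):
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-lim, lim, size=shape).astype(dtype)

    return {
        "w_temporal": glorot((f1, kt), kt, kt * f1),
        "bn1_gamma": np.ones(f1, dtype), "bn1_beta": np.zeros(f1, dtype),
        "w_spatial": glorot((f1, d, c), c * f1, c * d),
        "bn2_gamma": np.ones(f2, dtype), "bn2_beta": np.zeros(f2, dtype),
        "w_sep_depth": glorot((f2, ks), ks, ks),
        "w_sep_point": glorot((f2, f2), f2, f2),
        "bn3_gamma": np.ones(f2, dtype), "bn3_beta": np.zeros(f2, dtype),
        "w_dense": glorot((feat, config.n_classes), feat, config.n_classes),
        "b_dense": np.zeros(config.n_classes, dtype),
    }


def init_bn_state(config, dtype=DEFAULT_DTYPE) -> dict:
    f1, f2 = config.n_temporal_filters, config.n_separable_filters
    return {
        "bn1_mean": np.zeros(f1, dtype), "bn1_var": np.ones(f1, dtype),
        "bn2_mean": np.zeros(f2, dtype), "bn2_var": np.ones(f2, dtype),
        "bn3_mean": np.zeros(f2, dtype), "bn3_var": np.ones(f2, dtype),
    }


def forward(x, params, bn_state, config, training=False, drop_rng=None):
    """Run the network; returns (probs, cache). cache is None in inference mode."""
    p = params
    n = x.shape[0]
    f1, d = config.n_temporal_filters, config.depth_multiplier
    f2 = config.n_separable_filters

    h1, c_t = temporal_corr_forward(x, p["w_temporal"])  # (N,F1,C,T)
    h1n, c_b1 = bn_forward(h1, p["bn1_gamma"], p["bn1_beta"],
                           bn_state["bn1_mean"], bn_state["bn1_var"], training)
    h2 = np.einsum("fdc,nfct->nfdt", p["w_spatial"], h1n).reshape(n, f2, -1)
    h2n, c_b2 = bn_forward(h2, p["bn2_gamma"], p["bn2_beta"],
                           bn_state["bn2_mean"], bn_state["bn2_var"], training)
    e2, c_e2 = elu_forward(h2n)
    p2, c_p2 = avgpool_forward(e2, config.pool1)
    d2, m2 = dropout_forward(p2, config.dropout_p if training else 0.0, drop_rng)

    h3, c_d = depthwise_corr_forward(d2, p["w_sep_depth"])
    h4 = np.einsum("of,nft->not", p["w_sep_point"], h3)
    h4n, c_b3 = bn_forward(h4, p["bn3_gamma"], p["bn3_beta"],
                           bn_state["bn3_mean"], bn_state["bn3_var"], training)
    e3, c_e3 = elu_forward(h4n)
    p3, c_p3 = avgpool_forward(e3, config.pool2)
    d3, m3 = dropout_forward(p3, config.dropout_p if training else 0.0, drop_rng)

    flat = d3.reshape(n, -1)
    logits = flat @ p["w_dense"] + p["b_dense"]
    probs = softmax(logits)
    if not training:
        return probs, None
    cache = dict(
        x=x, c_t=c_t, c_b1=c_b1, h1n=h1n, c_b2=c_b2, c_e2=c_e2, c_p2=c_p2,
        m2=m2, d2=d2, c_d=c_d, h3=h3, c_b3=c_b3, c_e3=c_e3, c_p3=c_p3, m3=m3,
        flat=flat, shape_d3=d3.shape,
    )
    return probs, cache


def backward(dlogits, params, cache, config) -> dict:
    p = params
    n = dlogits.shape[0]
    f1, d = config.n_temporal_filters, config.depth_multiplier

    grads: dict[str, np.ndarray] = {}
    grads["w_dense"] = cache["flat"].T @ dlogits
    grads["b_dense"] = dlogits.sum(axis=0)
    dflat = dlogits @ p["w_dense"].T
    dd3 = dflat.reshape(cache["shape_d3"])

    dp3 = dropout_backward(dd3, cache["m3"])
    de3 = avgpool_backward(dp3, cache["c_p3"])
    dh4n = elu_backward(de3, cache["c_e3"])
    dh4, grads["bn3_gamma"], grads["bn3_beta"] = bn_backward(dh4n, cache["c_b3"])
    grads["w_sep_point"] = np.einsum("not,nft->of", dh4, cache["h3"])
    dh3 = np.einsum("of,not->nft", p["w_sep_point"], dh4)
    dd2, grads["w_sep_depth"] = depthwise_corr_backward(dh3, p["w_sep_depth"], cache["c_d"])

    dp2 = dropout_backward(dd2, cache["m2"])
    de2 = avgpool_backward(dp2, cache["c_p2"])
    dh2n = elu_backward(de2, cache["c_e2"])
    dh2, grads["bn2_gamma"], grads["bn2_beta"] = bn_backward(dh2n, cache["c_b2"])
    dh2_4d = dh2.reshape(n, f1, d, -1)
    grads["w_spatial"] = np.einsum("nfdt,nfct->fdc", dh2_4d, cache["h1n"])
    dh1n = np.einsum("fdc,nfdt->nfct", p["w_spatial"], dh2_4d)
    dh1, grads["bn1_gamma"], grads["bn1_beta"] = bn_backward(dh1n, cache["c_b1"])
    _, grads["w_temporal"] = temporal_corr_backward(
        dh1, p["w_temporal"], cache["c_t"], need_dx=False
    )
    return grads


def apply_constraints(params: dict) -> None:
    # spatial depthwise filters: unit max-norm over the channel axis;
    # dense kernel: max-norm 0.25 over its input axis
    apply_max_norm(params["w_spatial"], 1.0, axis=2)
    apply_max_norm(params["w_dense"], 0.25, axis=0)


def n_parameters(params: dict) -> int:
    return int(sum(v.size for v in params.values()))
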