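"""Shared-weight two-stream feedforward predictor and the alpha blend.

One tiny network — fully connected layer (d -> 2), batch normalization,
ReLU, dropout, fully connected output (2 -> 1) — is applied with the *same*
parameters to the community and physician embeddings of each case, yielding
one real-valued score per stream.  The two scores are mixed with a global
weight alpha and squashed to a probability.  Weight sharing is structural:
there is exactly one parameter object, so identical inputs on the two
streams produce identical scores at every point in training.

The backward pass is analytic (the network has ~d*2 + 9 parameters) and is
checked against central finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .errors import ConfigError, NumericError

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1
_HIDDEN = 2  # one unit per stakeholder role; fixed by design


@dataclass
class NetParams:
    """Parameters and batchnorm state of the shared predictor."""

    w_in: np.ndarray          # (d, 2)
    b_in: np.ndarray          # (2,)
    bn_scale: np.ndarray      # (2,)  batchnorm gamma
    bn_shift: np.ndarray      # (2,)  batchnorm beta
    running_mean: np.ndarray  # (2,)
    running_var: np.ndarray   # (2,)
    w_out: np.ndarray         # (2,)
    b_out: float
    dropout_rate: float = 0.1
    mode: str = "train"

    @property
    def d(self) -> int:
        return self.w_in.shape[0]

    def param_dict(self) -> dict[str, np.ndarray]:
        """Trainable parameters only (batchnorm running stats excluded)."""
        return {
            "w_in": self.w_in, "b_in": self.b_in,
            "bn_scale": self.bn_scale, "bn_shift": self.bn_shift,
            "w_out": self.w_out, "b_out": self.b_out,
        }

    def to_checkpoint(self) -> dict:
        ck = {k: (v.tolist() if isinstance(v, np.ndarray) else float(v))
              for k, v in self.param_dict().items()}
        ck["running_mean"] = self.running_mean.tolist()
        ck["running_var"] = self.running_var.tolist()
        ck["dropout_rate"] = self.dropout_rate
        return ck

    @classmethod
    def from_checkpoint(cls, ck: dict) -> "NetParams":
        arr = lambda k: np.asarray(ck[k], dtype=np.float64)
        return cls(
            w_in=arr("w_in"), b_in=arr("b_in"),
            bn_scale=arr("bn_scale"), bn_shift=arr("bn_shift"),
            running_mean=arr("running_mean"), running_var=arr("running_var"),
            w_out=arr("w_out"), b_out=float(ck["b_out"]),
            dropout_rate=float(ck["dropout_rate"]), mode="eval",
        )


def init_params(d: int, rng: np.random.Generator,
                dropout_rate: float = 0.1) -> NetParams:
    """Fan-in-scaled Gaussian init; output bias 0 so initial p is near 0.5."""
    if not 0.0 <= dropout_rate < 1.0:
        raise ConfigError(f"dropout_rate must lie in [0, 1), got {dropout_rate!r}")
    return NetParams(
        w_in=rng.normal(scale=1.0 / np.sqrt(d), size=(d, _HIDDEN)),
        b_in=np.zeros(_HIDDEN),
        bn_scale=np.ones(_HIDDEN),
        bn_shift=np.zeros(_HIDDEN),
        running_mean=np.zeros(_HIDDEN),
        running_var=np.ones(_HIDDEN),
        w_out=rng.normal(scale=1.0 / np.sqrt(_HIDDEN), size=_HIDDEN),
        b_out=0.0,
        dropout_rate=dropout_rate,
    )


def _forward(params: NetParams, E: np.ndarray, train: bool,
             rng: np.random.Generator | None, update_running: bool):
    """Forward pass returning (scores, cache-for-backward)."""
    E = np.asarray(E, dtype=np.float64)
    if E.ndim != 2 or E.shape[1] != params.d:
        raise ValueError(
            f"embedding matrix has shape {E.shape}, expected (n, {params.d})"
        )
    h = E @ params.w_in + params.b_in
    if train:
        mu = h.mean(axis=0)
        var = h.var(axis=0)
        if update_running:
            n = h.shape[0]
            unbiased = var * n / max(n - 1, 1)
            params.running_mean = (1 - _BN_MOMENTUM) * params.running_mean + _BN_MOMENTUM * mu
            params.running_var = (1 - _BN_MOMENTUM) * params.running_var + _BN_MOMENTUM * unbiased
    else:
        mu, var = params.running_mean, params.running_var
    inv_std = 1.0 / np.sqrt(var + _BN_EPS)
    x_hat = (h - mu) * inv_std
    r = params.bn_scale * x_hat + params.bn_shift
    a = np.maximum(r, 0.0)
    if train and params.dropout_rate > 0.0:
        if rng is None:
            raise ValueError("train-mode forward with dropout requires an rng")
        mask = (rng.random(a.shape) >= params.dropout_rate) / (1.0 - params.dropout_rate)
    else:
        mask = np.ones_like(a)
    ad = a * mask
    s = ad @ params.w_out + params.b_out
    cache = dict(E=E, h=h, mu=mu, var=var, inv_std=inv_std, x_hat=x_hat,
                 r=r, a=a, mask=mask, ad=ad, train=train)
    return s, cache


def _backward(params: NetParams, cache: dict, g_s: np.ndarray) -> dict[str, np.ndarray]:
    """Gradients of a scalar loss w.r.t. trainable params, given dL/dscore."""
    grads: dict[str, np.ndarray] = {}
    grads["w_out"] = cache["ad"].T @ g_s
    grads["b_out"] = g_s.sum()
    g_ad = np.outer(g_s, params.w_out)
    g_a = g_ad * cache["mask"]
    g_r = g_a * (cache["r"] > 0.0)
    grads["bn_scale"] = (g_r * cache["x_hat"]).sum(axis=0)
    grads["bn_shift"] = g_r.sum(axis=0)
    g_xhat = g_r * params.bn_scale
    if cache["train"]:
        n = cache["h"].shape[0]
        g_h = (cache["inv_std"] / n) * (
            n * g_xhat
            - g_xhat.sum(axis=0)
            - cache["x_hat"] * (g_xhat * cache["x_hat"]).sum(axis=0)
        )
    else:
        g_h = g_xhat * cache["inv_std"]
    grads["w_in"] = cache["E"].T @ g_h
    grads["b_in"] = g_h.sum(axis=0)
    return grads


def stream_score(E: np.ndarray, params: NetParams,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Score each row of ``E`` with the shared predictor.

    In eval mode (``params.mode == "eval"``) batchnorm uses running
    statistics and dropout is the identity, so the pass is deterministic.
    """
    train = params.mode == "train"
    s, _ = _forward(params, E, train=train, rng=rng, update_running=train)
    return s


def blend_scores(s_comm: np.ndarray, s_phys: np.ndarray, alpha: float) -> np.ndarray:
    """alpha-weighted mixture: alpha * community + (1 - alpha) * physician."""
    if not 0.0 <= alpha <= 1.0:
        raise ConfigError(f"alpha must lie in [0, 1], got {alpha!r}")
    s_comm = np.asarray(s_comm, dtype=np.float64)
    s_phys = np.asarray(s_phys, dtype=np.float64)
    if s_comm.shape != s_phys.shape:
        raise ValueError(f"shape mismatch: {s_comm.shape} vs {s_phys.shape}")
    return alpha * s_comm + (1.0 - alpha) * s_phys


def to_probability(s: np.ndarray) -> np.ndarray:
    """Elementwise logistic transform of scores."""
    s = np.asarray(s, dtype=np.float64)
    if not np.isfinite(s).all():
        raise NumericError("non-finite score passed to to_probability")
    return expit(s)


def binarize(p: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Yes/no recommendation: 1 iff p >= threshold (tie at 0.5 maps to 1)."""
    return (np.asarray(p) >= threshold).astype(np.int64)


class AdamState:
    """Adaptive-moment optimizer state keyed by parameter name."""

    def __init__(self, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray | float] = {}
        self.v: dict[str, np.ndarray | float] = {}

    def step(self, params: NetParams, grads: dict, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(g) if isinstance(g, np.ndarray) else 0.0
                self.v[k] = np.zeros_like(g) if isinstance(g, np.ndarray) else 0.0
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * (g * g)
            m_hat = self.m[k] / (1 - b1 ** self.t)
            v_hat = self.v[k] / (1 - b2 ** self.t)
            update = lr * m_hat / (np.sqrt(v_hat) + self.eps)
            cur = getattr(params, k)
            setattr(params, k, cur - update)


def _bce_with_logits(s: np.ndarray, y: np.ndarray) -> np.ndarray:
    # log(1 + e^s) - y*s, computed stably
    return np.logaddexp(0.0, s) - y * s


def supervised_step(params: NetParams,
                    E_comm: np.ndarray, E_phys: np.ndarray,
                    comm_labels: np.ndarray,
                    phys_labels: np.ndarray, phys_mask: np.ndarray,
                    lr: float,
                    rng: np.random.Generator,
                    opt: AdamState | None = None) -> tuple[NetParams, float]:
    """One gradient step on the combined per-stream endorsement loss.

    L = mean BCE(community score, community label) over the whole batch
      + mean BCE(physician score, physician label) over queried cases only.

    ``phys_mask`` is a boolean vector marking the queried subset of the
    batch; an empty subset contributes zero to loss and gradient.  Returns
    the (mutated) params and the pre-step loss.  Batchnorm running
    statistics are updated by each stream's forward pass.
    """
    comm_labels = np.asarray(comm_labels, dtype=np.float64)
    phys_labels = np.asarray(phys_labels, dtype=np.float64)
    phys_mask = np.asarray(phys_mask, dtype=bool)
    n = E_comm.shape[0]
    n_q = int(phys_mask.sum())

    s_c, cache_c = _forward(params, E_comm, train=True, rng=rng, update_running=True)
    s_p, cache_p = _forward(params, E_phys, train=True, rng=rng, update_running=True)

    loss = _bce_with_logits(s_c, comm_labels).mean()
    if n_q > 0:
        loss += _bce_with_logits(s_p[phys_mask], phys_labels[phys_mask]).mean()
    if not np.isfinite(loss):
        raise NumericError(f"non-finite supervised loss ({loss!r}); aborting run")

    g_c = (expit(s_c) - comm_labels) / n
    g_p = np.zeros(n)
    if n_q > 0:
        g_p[phys_mask] = (expit(s_p[phys_mask]) - phys_labels[phys_mask]) / n_q

    grads_c = _backward(params, cache_c, g_c)
    grads_p = _backward(params, cache_p, g_p)
    grads = {k: grads_c[k] + grads_p[k] for k in grads_c}

    if lr > 0.0:
        if opt is None:
            for k, g in grads.items():
                setattr(params, k, getattr(params, k) - lr * g)
        else:
            opt.step(params, grads, lr)
    return params, float(loss)


def supervised_loss_and_grads(params: NetParams,
                              E_comm: np.ndarray, E_phys: np.ndarray,
                              comm_labels: np.ndarray,
                              phys_labels: np.ndarray, phys_mask: np.ndarray,
                              ) -> tuple[float, dict[str, np.ndarray]]:
    """Loss and analytic gradients without any update (dropout off).

    Used by the finite-difference gradient check; batchnorm runs in
    train (batch-statistics) mode but running stats are left untouched.
    """
    comm_labels = np.asarray(comm_labels, dtype=np.float64)
    phys_labels = np.asarray(phys_labels, dtype=np.float64)
    phys_mask = np.asarray(phys_mask, dtype=bool)
    n = E_comm.shape[0]
    n_q = int(phys_mask.sum())

    saved = params.dropout_rate
    params.dropout_rate = 0.0
    try:
        s_c, cache_c = _forward(params, E_comm, train=True, rng=None, update_running=False)
        s_p, cache_p = _forward(params, E_phys, train=True, rng=None, update_running=False)
    finally:
        params.dropout_rate = saved

    loss = _bce_with_logits(s_c, comm_labels).mean()
    if n_q > 0:
        loss += _bce_with_logits(s_p[phys_mask], phys_labels[phys_mask]).mean()

    g_c = (expit(s_c) - comm_labels) / n
    g_p = np.zeros(n)
    if n_q > 0:
        g_p[phys_mask] = (expit(s_p[phys_mask]) - phys_labels[phys_mask]) / n_q
    grads_c = _backward(params, cache_c, g_c)
    grads_p = _backward(params, cache_p, g_p)
    return float(loss), {k: grads_c[k] + grads_p[k] for k in grads_c}
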