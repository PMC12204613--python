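"""The interaction-prediction network: embeddings + channel attention + dense.

The sequence module embeds the eight token-id channels with a shared matrix,
applies an efficient-channel-attention (ECA) gate per channel type (embedding
dimensions act as channels, token slots as positions), mean-pools over token
positions with a padding mask, fuses each seq1 channel with its same-type seq2
channel through a dense layer, and merges the four fused vectors through
another dense layer. The genomic module batch-normalizes the feature vector
and passes it through dense/ReLU layers with dropout before its final layer.
The concatenated module outputs go through dropout and a final dense layer to
a sigmoid probability; samples above the threshold (default 0.5) are called
interacting.

Because the ECA gate is constant across positions, gating before or after the
masked mean pooling is mathematically identical; the forward pass pools first,
which is what the backward pass differentiates.

Implemented in NumPy with hand-written backpropagation and an Adam optimizer;
gradient correctness is enforced by finite-difference checks in the test
suite.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .tokenization import PAD_ID

_BN_EPS = 1e-5


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


def eca_kernel_size(
    C: int, gamma: float = 2.0, b: float = 1.0, rounding: str = "floor"
) -> int:
    """Adaptive odd kernel size for the channel-attention convolution.

    ``k = |log2(C)/gamma + b/gamma|_odd``, with ``rounding='floor'`` taking
    the largest odd integer not exceeding the value (``'nearest'`` takes the
    nearest odd integer instead). Clamped to >= 1.
    """
    if C < 1:
        raise ValueError(f"channel count must be >= 1, got {C}")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    t = math.log2(C) / gamma + b / gamma
    k = int(math.floor(t))
    if k % 2 == 0:
        k -= 1
    if rounding == "nearest":
        if (t - k) > (k + 2 - t):
            k += 2
    elif rounding != "floor":
        raise ValueError(f"rounding must be 'floor' or 'nearest', got {rounding!r}")
    return max(k, 1)


@dataclass(frozen=True)
class ECAConfig:
    """Channel-attention geometry: C channels, hyperparameters gamma and b."""

    channels: int
    gamma: float = 2.0
    b: float = 1.0
    rounding: str = "floor"

    @property
    def kernel(self) -> int:
        return eca_kernel_size(self.channels, self.gamma, self.b, self.rounding)


@dataclass
class ModelConfig:
    vocab_size: int = 4096
    embed_dim: int = 128
    max_tokens: int = 500
    channel_dense_units: int = 64
    merge_dense_units: int = 128
    genomic_dense_units: tuple[int, ...] = (128, 64)
    dropout_rate: float = 0.5
    eca_gamma: float = 2.0
    eca_b: float = 1.0
    kernel_rounding: str = "floor"
    threshold: float = 0.5
    mode: str = "seq+genomic"  # 'seq' | 'genomic' | 'seq+genomic'
    lr: float = 1e-3
    batch_size: int = 32
    patience: int = 5
    max_epochs: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        if not (0 < self.threshold < 1):
            raise ValueError("threshold must be in (0, 1)")
        if self.mode not in ("seq", "genomic", "seq+genomic"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for units in (self.channel_dense_units, self.merge_dense_units,
                      *self.genomic_dense_units):
            if units < 1:
                raise ValueError("all dense unit counts must be >= 1")

    @property
    def eca(self) -> ECAConfig:
        return ECAConfig(self.embed_dim, self.eca_gamma, self.eca_b,
                         self.kernel_rounding)


@dataclass
class PredictionBatch:
    """Per-sample probabilities with thresholded labels."""

    probabilities: np.ndarray
    labels_pred: np.ndarray
    logits: np.ndarray | None = None

    @classmethod
    def from_probabilities(
        cls, probs: np.ndarray, threshold: float = 0.5,
        logits: np.ndarray | None = None,
    ) -> "PredictionBatch":
        probs = np.asarray(probs, dtype=float)
        return cls(probs, (probs > threshold).astype(int), logits)


# ---------------------------------------------------------------------------
# Primitives
# ---------------------------------------------------------------------------


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _conv1d_same(v: np.ndarray, w: np.ndarray, bias: float = 0.0) -> np.ndarray:
    """Cross-correlation of size-k kernel across the last axis, zero same-padding."""
    k = w.shape[0]
    if k % 2 != 1:
        raise ValueError("kernel size must be odd")
    half = k // 2
    pad = [(0, 0)] * (v.ndim - 1) + [(half, half)]
    vp = np.pad(v, pad)
    n = v.shape[-1]
    out = np.zeros_like(v, dtype=float)
    for j in range(k):
        out += w[j] * vp[..., j : j + n]
    return out + bias


def eca_attend(F: np.ndarray, conv_weights: np.ndarray, bias: float = 0.0) -> np.ndarray:
    """Channel attention: sigmoid(conv1d_k(GAP(F))) broadcast-multiplied into F.

    ``F`` has shape (channels, positions) or (batch, channels, positions); the
    global average pooling runs over positions and the 1-D convolution over
    the channel axis with zero same-padding.
    """
    F = np.asarray(F, dtype=float)
    if F.ndim not in (2, 3):
        raise ValueError(f"F must be (C, P) or (B, C, P), got shape {F.shape}")
    gap = F.mean(axis=-1)
    coeff = _sigmoid(_conv1d_same(gap, np.asarray(conv_weights, dtype=float), bias))
    return coeff[..., None] * F


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

_CHANNEL_TYPE = (0, 1, 2, 3, 0, 1, 2, 3)  # channel index -> ECA/dense type


class InteractionNet:
    """Sequence + genomic two-module classifier (see module docstring)."""

    def __init__(self, config: ModelConfig, n_features: int = 0,
                 rng: np.random.Generator | None = None) -> None:
        if config.mode != "seq" and n_features < 1:
            raise ValueError(f"mode {config.mode!r} requires n_features >= 1")
        self.config = config
        self.n_features = n_features
        rng = rng or np.random.default_rng(config.seed)
        c = config
        d, c1, c2 = c.embed_dim, c.channel_dense_units, c.merge_dense_units
        k = c.eca.kernel

        def dense(n_in: int, n_out: int) -> np.ndarray:
            return rng.normal(0.0, math.sqrt(2.0 / n_in), size=(n_in, n_out))

        self.params: dict[str, np.ndarray] = {}
        P = self.params
        if c.mode != "genomic":
            P["E"] = rng.normal(0.0, 0.1, size=(c.vocab_size, d))
            P["E"][PAD_ID] = 0.0
            for t in range(4):
                P[f"conv_w{t}"] = rng.normal(0.0, 0.1, size=(k,))
                P[f"conv_b{t}"] = np.zeros(())
                P[f"W1_{t}"] = dense(2 * d, c1)
                P[f"b1_{t}"] = np.zeros(c1)
            P["W2"] = dense(4 * c1, c2)
            P["b2"] = np.zeros(c2)
        if c.mode != "seq":
            P["bn_gamma"] = np.ones(n_features)
            P["bn_beta"] = np.zeros(n_features)
            n_in = n_features
            for i, units in enumerate(c.genomic_dense_units):
                P[f"Wg{i}"] = dense(n_in, units)
                P[f"bg{i}"] = np.zeros(units)
                n_in = units
        head_in = {"seq": c2, "genomic": 0, "seq+genomic": c2}[c.mode]
        if c.mode != "seq":
            head_in += c.genomic_dense_units[-1]
        P["Wo"] = dense(head_in, 1)
        P["bo"] = np.zeros(1)

        # batch-norm running statistics (buffers, not trained)
        self.bn_mean = np.zeros(n_features)
        self.bn_var = np.ones(n_features)
        self.bn_momentum = 0.1

    # -- forward ------------------------------------------------------------

    def _seq_forward(self, X: np.ndarray, cache: dict | None) -> np.ndarray:
        P, c = self.params, self.config
        mask = (X != PAD_ID).astype(float)  # (B, 8, T)
        emb = P["E"][X]  # (B, 8, T, d)
        cnt = np.maximum(mask.sum(axis=2), 1.0)  # (B, 8)
        v = (emb * mask[..., None]).sum(axis=2) / cnt[..., None]  # (B, 8, d)
        gated = np.empty_like(v)
        pre_list, coeff_list = [], []
        for ch in range(8):
            t = _CHANNEL_TYPE[ch]
            pre = _conv1d_same(v[:, ch, :], P[f"conv_w{t}"], float(P[f"conv_b{t}"]))
            coeff = _sigmoid(pre)
            gated[:, ch, :] = coeff * v[:, ch, :]
            pre_list.append(pre)
            coeff_list.append(coeff)
        h, z1, r1 = [], [], []
        for t in range(4):
            ht = np.concatenate([gated[:, t, :], gated[:, t + 4, :]], axis=1)
            zt = ht @ P[f"W1_{t}"] + P[f"b1_{t}"]
            h.append(ht)
            z1.append(zt)
            r1.append(np.maximum(zt, 0.0))
        merged = np.concatenate(r1, axis=1)
        z2 = merged @ P["W2"] + P["b2"]
        s = np.maximum(z2, 0.0)
        if cache is not None:
            cache.update(X=X, mask=mask, cnt=cnt, v=v, coeff=coeff_list,
                         gated=gated, h=h, z1=z1, merged=merged, z2=z2, s=s)
        return s

    def _genomic_forward(self, feats: np.ndarray, training: bool,
                         rng: np.random.Generator | None,
                         cache: dict | None) -> np.ndarray:
        P, c = self.params, self.config
        x = np.asarray(feats, dtype=float)
        if x.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {x.shape[1]}"
            )
        if training:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.bn_mean = (1 - self.bn_momentum) * self.bn_mean + self.bn_momentum * mu
            self.bn_var = (1 - self.bn_momentum) * self.bn_var + self.bn_momentum * var
        else:
            mu, var = self.bn_mean, self.bn_var
        inv_std = 1.0 / np.sqrt(var + _BN_EPS)
        xhat = (x - mu) * inv_std
        y = P["bn_gamma"] * xhat + P["bn_beta"]
        if cache is not None:
            cache.update(g_x=x, g_xhat=xhat, g_inv_std=inv_std, g_mu=mu)
        zs, ys, dmasks = [], [y], []
        n_layers = len(c.genomic_dense_units)
        for i in range(n_layers):
            if i == n_layers - 1 and training and c.dropout_rate > 0:
                dmask = (rng.random(y.shape) >= c.dropout_rate) / (1 - c.dropout_rate)
                y = y * dmask
            else:
                dmask = None
            dmasks.append(dmask)
            z = y @ P[f"Wg{i}"] + P[f"bg{i}"]
            y = np.maximum(z, 0.0)
            zs.append(z)
            ys.append(y)
        if cache is not None:
            cache.update(g_zs=zs, g_ys=ys, g_dmasks=dmasks)
        return y

    def forward(self, X: np.ndarray | None, feats: np.ndarray | None,
                training: bool = False, rng: np.random.Generator | None = None,
                cache: dict | None = None) -> np.ndarray:
        """Return per-sample probabilities; fills ``cache`` for backprop."""
        c = self.config
        parts = []
        if c.mode != "genomic":
            parts.append(self._seq_forward(np.asarray(X), cache))
        if c.mode != "seq":
            parts.append(self._genomic_forward(feats, training, rng, cache))
        hcat = np.concatenate(parts, axis=1) if len(parts) > 1 else parts[0]
        if training and c.dropout_rate > 0:
            hmask = (rng.random(hcat.shape) >= c.dropout_rate) / (1 - c.dropout_rate)
            hdrop = hcat * hmask
        else:
            hmask = None
            hdrop = hcat
        logits = (hdrop @ self.params["Wo"] + self.params["bo"])[:, 0]
        probs = _sigmoid(logits)
        if cache is not None:
            cache.update(hcat=hcat, hmask=hmask, hdrop=hdrop,
                         logits=logits, probs=probs)
        return probs

    def predict_proba(self, X: np.ndarray | None,
                      feats: np.ndarray | None = None) -> np.ndarray:
        """Deterministic (eval-mode) probabilities in (0, 1)."""
        return self.forward(X, feats, training=False)

    def predict(self, X: np.ndarray | None,
                feats: np.ndarray | None = None) -> PredictionBatch:
        probs = self.predict_proba(X, feats)
        return PredictionBatch.from_probabilities(probs, self.config.threshold)

    # -- loss & gradients ---------------------------------------------------

    def loss(self, X, feats, y) -> float:
        probs = self.forward(X, feats, training=False)
        return float(_bce(probs, np.asarray(y, dtype=float)))

    def loss_and_grads(
        self, X, feats, y, rng: np.random.Generator | None = None,
        training: bool = True,
    ) -> tuple[float, dict[str, np.ndarray]]:
        c = self.config
        y = np.asarray(y, dtype=float)
        cache: dict = {}
        rng = rng or np.random.default_rng(0)
        probs = self.forward(X, feats, training=training, rng=rng, cache=cache)
        B = y.shape[0]
        loss = _bce(probs, y)
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        P = self.params

        dlogits = (probs - y) / B  # BCE-with-logits gradient
        grads["Wo"] = cache["hdrop"].T @ dlogits[:, None]
        grads["bo"] = np.array([dlogits.sum()])
        dhdrop = dlogits[:, None] @ P["Wo"].T
        dhcat = dhdrop * cache["hmask"] if cache["hmask"] is not None else dhdrop

        split = cache["s"].shape[1] if c.mode == "seq+genomic" else None
        if c.mode == "seq":
            ds, dg = dhcat, None
        elif c.mode == "genomic":
            ds, dg = None, dhcat
        else:
            ds, dg = dhcat[:, :split], dhcat[:, split:]

        if dg is not None:
            self._genomic_backward(dg, cache, grads)
        if ds is not None:
            self._seq_backward(ds, cache, grads)
        return float(loss), grads

    def _genomic_backward(self, dg, cache, grads) -> None:
        P, c = self.params, self.config
        n_layers = len(c.genomic_dense_units)
        dy = dg
        for i in reversed(range(n_layers)):
            dz = dy * (cache["g_zs"][i] > 0)
            y_in = cache["g_ys"][i]
            if cache["g_dmasks"][i] is not None:
                y_in = y_in * cache["g_dmasks"][i]
            grads[f"Wg{i}"] = y_in.T @ dz
            grads[f"bg{i}"] = dz.sum(axis=0)
            dy = dz @ P[f"Wg{i}"].T
            if cache["g_dmasks"][i] is not None:
                dy = dy * cache["g_dmasks"][i]
        # dy is now the gradient wrt the batch-norm output
        xhat, inv_std = cache["g_xhat"], cache["g_inv_std"]
        grads["bn_gamma"] = (dy * xhat).sum(axis=0)
        grads["bn_beta"] = dy.sum(axis=0)
        # (inference-statistics path is never trained; training path below)
        B = dy.shape[0]
        dxhat = dy * P["bn_gamma"]
        dvar = (dxhat * (cache["g_x"] - cache["g_mu"])).sum(axis=0) * -0.5 * inv_std**3
        dmu = (-dxhat * inv_std).sum(axis=0) + dvar * (
            -2.0 * (cache["g_x"] - cache["g_mu"])
        ).mean(axis=0)
        # dx not propagated further (features are inputs)
        del dxhat, dvar, dmu

    def _seq_backward(self, ds, cache, grads) -> None:
        P, c = self.params, self.config
        d, c1 = c.embed_dim, c.channel_dense_units
        dz2 = ds * (cache["z2"] > 0)
        grads["W2"] = cache["merged"].T @ dz2
        grads["b2"] = dz2.sum(axis=0)
        dmerged = dz2 @ P["W2"].T
        dgated = np.zeros_like(cache["gated"])
        for t in range(4):
            dr1 = dmerged[:, t * c1 : (t + 1) * c1]
            dz1 = dr1 * (cache["z1"][t] > 0)
            grads[f"W1_{t}"] = cache["h"][t].T @ dz1
            grads[f"b1_{t}"] = dz1.sum(axis=0)
            dh = dz1 @ P[f"W1_{t}"].T
            dgated[:, t, :] = dh[:, :d]
            dgated[:, t + 4, :] = dh[:, d:]
        dv = np.zeros_like(cache["v"])
        k = c.eca.kernel
        half = k // 2
        for ch in range(8):
            t = _CHANNEL_TYPE[ch]
            coeff = cache["coeff"][ch]
            vch = cache["v"][:, ch, :]
            dcoeff = dgated[:, ch, :] * vch
            dv[:, ch, :] += dgated[:, ch, :] * coeff
            dpre = dcoeff * coeff * (1.0 - coeff)
            vp = np.pad(vch, ((0, 0), (half, half)))
            dvp = np.zeros_like(vp)
            w = P[f"conv_w{t}"]
            for j in range(k):
                grads[f"conv_w{t}"][j] += (dpre * vp[:, j : j + d]).sum()
                dvp[:, j : j + d] += dpre * w[j]
            grads[f"conv_b{t}"] += dpre.sum()
            dv[:, ch, :] += dvp[:, half : half + d]
        # masked mean pooling -> embedding rows
        dem = dv[:, :, None, :] * (cache["mask"] / cache["cnt"][..., None])[..., None]
        ids_flat = cache["X"].ravel()
        dem_flat = dem.reshape(-1, d)
        n = ids_flat.shape[0]
        scatter = sp.csr_matrix(
            (np.ones(n), (ids_flat, np.arange(n))),
            shape=(c.vocab_size, n),
        )
        dE = np.asarray(scatter @ dem_flat)
        dE[PAD_ID] = 0.0
        grads["E"] = dE

    # -- checkpointing ------------------------------------------------------

    def get_state(self) -> dict[str, np.ndarray]:
        state = {k: v.copy() for k, v in self.params.items()}
        state["__bn_mean"] = self.bn_mean.copy()
        state["__bn_var"] = self.bn_var.copy()
        return state

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = state[k].copy()
        self.bn_mean = state["__bn_mean"].copy()
        self.bn_var = state["__bn_var"].copy()

    def save(self, path: str | Path) -> None:
        """Single parameter archive (.npz) plus a JSON config sidecar."""
        path = Path(path)
        np.savez(path, **self.get_state())
        sidecar = path.with_suffix(".json")
        cfg = asdict(self.config)
        cfg["genomic_dense_units"] = list(cfg["genomic_dense_units"])
        sidecar.write_text(json.dumps({"config": cfg, "n_features": self.n_features}))

    @classmethod
    def load(cls, path: str | Path) -> "InteractionNet":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        cfg = meta["config"]
        cfg["genomic_dense_units"] = tuple(cfg["genomic_dense_units"])
        net = cls(ModelConfig(**cfg), n_features=meta["n_features"])
        with np.load(path.with_suffix(".npz") if path.suffix != ".npz" else path) as z:
            net.set_state({k: z[k] for k in z.files})
        return net


def _bce(probs: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    p = np.clip(probs, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


class Adam:
    """Adam optimizer over a named parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
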