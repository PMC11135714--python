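"""A compact NumPy U-net for image-to-image probability maps.

Encoder-decoder with skip connections: each level applies two 3x3
convolutions (ReLU) and 2x2 max pooling on the way down; the decoder
mirrors it with nearest-neighbour upsampling, a 3x3 convolution, optional
skip concatenation and two more convolutions.  A final 1x1 convolution
produces per-pixel logits; the sigmoid of the logits is the probability
that a pixel belongs to the target object.

Everything — convolution via im2col, pooling, the backward pass, Adam with
decoupled weight decay — is implemented directly on NumPy arrays, which is
ample for the small input sizes this pipeline uses and keeps training fully
deterministic under a seed.  Inputs of any size are accepted: frames are
edge-padded to a multiple of 2**depth internally and outputs cropped back.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = ["UNetSpec", "UNet", "AdamW", "bce_with_logits", "sigmoid"]


@dataclass(frozen=True)
class UNetSpec:
    """Architecture hyper-parameters.

    depth: number of down/up levels; filters: channels per level (length =
    depth); skips: whether the skip connection at each level is used.
    """

    depth: int = 3
    filters: tuple[int, ...] = (16, 32, 64)
    skips: tuple[bool, ...] = ()

    def __post_init__(self) -> None:
        if len(self.filters) != self.depth:
            raise ValueError("filters must list one channel count per level")
        if not self.skips:
            object.__setattr__(self, "skips", (True,) * self.depth)
        if len(self.skips) != self.depth:
            raise ValueError("skips must list one flag per level")

    @property
    def bottleneck(self) -> int:
        return self.filters[-1] * 2

    def to_json(self) -> str:
        return json.dumps(
            {"depth": self.depth, "filters": list(self.filters), "skips": list(self.skips)}
        )

    @classmethod
    def from_json(cls, text: str) -> "UNetSpec":
        d = json.loads(text)
        return cls(d["depth"], tuple(d["filters"]), tuple(d["skips"]))


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softplus(z: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, z)


def bce_with_logits(
    logits: np.ndarray, targets: np.ndarray, pos_weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy and its gradient w.r.t. the logits.

    pos_weight scales the loss on positive pixels, countering the heavy
    class imbalance of thin-object masks.
    """
    y = targets.astype(logits.dtype)
    per = pos_weight * y * _softplus(-logits) + (1.0 - y) * _softplus(logits)
    n = logits.size
    s = sigmoid(logits)
    grad = (pos_weight * y * (s - 1.0) + (1.0 - y) * s) / n
    return float(per.mean()), grad


# ---------------------------------------------------------------------------
# layer primitives (NHWC layout)
# ---------------------------------------------------------------------------

def _im2col3(x: np.ndarray) -> np.ndarray:
    n, h, w, c = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    cols = np.empty((n, h, w, 9, c), dtype=x.dtype)
    k = 0
    for di in range(3):
        for dj in range(3):
            cols[:, :, :, k, :] = xp[:, di : di + h, dj : dj + w, :]
            k += 1
    return cols.reshape(n, h, w, 9 * c)


def _col2im3(dcols: np.ndarray, shape: tuple[int, int, int, int]) -> np.ndarray:
    n, h, w, c = shape
    d = dcols.reshape(n, h, w, 9, c)
    dxp = np.zeros((n, h + 2, w + 2, c), dtype=dcols.dtype)
    k = 0
    for di in range(3):
        for dj in range(3):
            dxp[:, di : di + h, dj : dj + w, :] += d[:, :, :, k, :]
            k += 1
    return dxp[:, 1 : h + 1, 1 : w + 1, :]


def _conv_fwd(x, W, b):
    cols = _im2col3(x)
    out = cols @ W + b
    return out, (cols, x.shape, W)


def _conv_bwd(dout, cache):
    cols, xshape, W = cache
    n, h, w, cin = xshape
    f = dout.shape[-1]
    dW = cols.reshape(-1, cols.shape[-1]).T @ dout.reshape(-1, f)
    db = dout.sum(axis=(0, 1, 2))
    dcols = dout @ W.T
    dx = _col2im3(dcols, xshape)
    return dx, dW, db


def _relu_fwd(x):
    mask = x > 0
    return x * mask, mask


def _pool_fwd(x):
    n, h, w, c = x.shape
    xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
    xr = xr.reshape(n, h // 2, w // 2, c, 4)
    idx = xr.argmax(axis=4)
    out = np.take_along_axis(xr, idx[..., None], axis=4)[..., 0]
    return out, (idx, x.shape)


def _pool_bwd(dout, cache):
    idx, (n, h, w, c) = cache
    dxr = np.zeros((n, h // 2, w // 2, c, 4), dtype=dout.dtype)
    np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=4)
    dx = dxr.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
    return dx.reshape(n, h, w, c)


def _up_fwd(x):
    return x.repeat(2, axis=1).repeat(2, axis=2)


def _up_bwd(dout):
    n, h, w, c = dout.shape
    return dout.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class UNet:
    """U-net model; parameters live in a flat name -> array dict."""

    def __init__(self, spec: UNetSpec, seed: int = 0, dtype=np.float32):
        self.spec = spec
        self.dtype = np.dtype(dtype)
        self.params: dict[str, np.ndarray] = {}
        rng = np.random.default_rng(seed)
        f = spec.filters

        def add_conv(name: str, cin: int, cout: int, k: int = 9) -> None:
            scale = np.sqrt(2.0 / (k * cin))
            self.params[f"{name}_W"] = rng.normal(0, scale, (k * cin, cout)).astype(self.dtype)
            self.params[f"{name}_b"] = np.zeros(cout, dtype=self.dtype)

        cin = 1
        for i in range(spec.depth):
            add_conv(f"enc{i}a", cin, f[i])
            add_conv(f"enc{i}b", f[i], f[i])
            cin = f[i]
        add_conv("bota", f[-1], spec.bottleneck)
        add_conv("botb", spec.bottleneck, spec.bottleneck)
        up_in = spec.bottleneck
        for i in reversed(range(spec.depth)):
            add_conv(f"up{i}", up_in, f[i])
            deca_in = f[i] * 2 if spec.skips[i] else f[i]
            add_conv(f"dec{i}a", deca_in, f[i])
            add_conv(f"dec{i}b", f[i], f[i])
            up_in = f[i]
        add_conv("out", f[0], 1, k=1)

    # -- forward / backward ------------------------------------------------
    def _pad_to_grid(self, x: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
        m = 2**self.spec.depth
        h, w = x.shape[1], x.shape[2]
        ph = (-h) % m
        pw = (-w) % m
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, ph), (0, pw), (0, 0)), mode="edge")
        return x, (h, w)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Logits for a batch of frames shaped (n, h, w); caches for backward."""
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 3:
            x = x[..., None]
        x, (h0, w0) = self._pad_to_grid(x)
        cache: dict[str, object] = {"hw": (h0, w0), "padded_hw": x.shape[1:3]}
        p = self.params
        skips = {}
        a = x
        for i in range(self.spec.depth):
            for blk in ("a", "b"):
                z, cache[f"enc{i}{blk}_conv"] = _conv_fwd(a, p[f"enc{i}{blk}_W"], p[f"enc{i}{blk}_b"])
                a, cache[f"enc{i}{blk}_relu"] = _relu_fwd(z)
            skips[i] = a
            a, cache[f"pool{i}"] = _pool_fwd(a)
        for blk in ("a", "b"):
            z, cache[f"bot{blk}_conv"] = _conv_fwd(a, p[f"bot{blk}_W"], p[f"bot{blk}_b"])
            a, cache[f"bot{blk}_relu"] = _relu_fwd(z)
        for i in reversed(range(self.spec.depth)):
            a = _up_fwd(a)
            z, cache[f"up{i}_conv"] = _conv_fwd(a, p[f"up{i}_W"], p[f"up{i}_b"])
            a, cache[f"up{i}_relu"] = _relu_fwd(z)
            if self.spec.skips[i]:
                cache[f"cat{i}_ch"] = a.shape[-1]
                a = np.concatenate([a, skips[i]], axis=-1)
            for blk in ("a", "b"):
                z, cache[f"dec{i}{blk}_conv"] = _conv_fwd(a, p[f"dec{i}{blk}_W"], p[f"dec{i}{blk}_b"])
                a, cache[f"dec{i}{blk}_relu"] = _relu_fwd(z)
        # 1x1 output convolution
        n, h, w, c = a.shape
        logits = a.reshape(-1, c) @ p["out_W"] + p["out_b"]
        logits = logits.reshape(n, h, w)
        cache["out_in"] = a
        self._cache = cache
        return logits[:, :h0, :w0]

    def backward(self, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        cache = self._cache
        p = self.params
        grads: dict[str, np.ndarray] = {}
        h0, w0 = cache["hw"]
        hp, wp = cache["padded_hw"]
        n = dlogits.shape[0]
        if (h0, w0) != (hp, wp):
            full = np.zeros((n, hp, wp), dtype=self.dtype)
            full[:, :h0, :w0] = dlogits
            dlogits = full
        else:
            dlogits = dlogits.astype(self.dtype)
        a = cache["out_in"]
        c = a.shape[-1]
        dflat = dlogits.reshape(-1, 1)
        grads["out_W"] = a.reshape(-1, c).T @ dflat
        grads["out_b"] = dflat.sum(axis=0)
        da = (dflat @ p["out_W"].T).reshape(a.shape)

        def conv_block_bwd(name: str, da: np.ndarray) -> np.ndarray:
            da = da * cache[f"{name}_relu"]
            dx, dW, db = _conv_bwd(da, cache[f"{name}_conv"])
            grads[f"{name}_W"] = dW
            grads[f"{name}_b"] = db
            return dx

        dskips: dict[int, np.ndarray] = {}
        for i in range(self.spec.depth):
            for blk in ("b", "a"):
                da = conv_block_bwd(f"dec{i}{blk}", da)
            if self.spec.skips[i]:
                ch = cache[f"cat{i}_ch"]
                dskips[i] = da[..., ch:]
                da = da[..., :ch]
            da = conv_block_bwd(f"up{i}", da)
            da = _up_bwd(da)
        for blk in ("b", "a"):
            da = conv_block_bwd(f"bot{blk}", da)
        for i in reversed(range(self.spec.depth)):
            da = _pool_bwd(da, cache[f"pool{i}"])
            if i in dskips:
                da = da + dskips[i]
            for blk in ("b", "a"):
                da = conv_block_bwd(f"enc{i}{blk}", da)
        return grads

    # -- inference ----------------------------------------------------------
    def predict_proba(self, frames: np.ndarray, batch_size: int = 16) -> np.ndarray:
        """Per-pixel object probabilities for frames shaped (n, h, w) or (h, w)."""
        single = frames.ndim == 2
        x = np.asarray(frames, dtype=np.float32)
        if single:
            x = x[None]
        if x.max() > 1.5:  # grey levels -> [0, 1]
            x = x / 255.0
        outs = []
        for i in range(0, x.shape[0], batch_size):
            outs.append(sigmoid(self.forward(x[i : i + batch_size])))
        proba = np.concatenate(outs, axis=0)
        return proba[0] if single else proba

    # -- persistence ---------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path, **self.params)
        path.with_suffix(".json").write_text(self.spec.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "UNet":
        path = Path(path)
        spec = UNetSpec.from_json(path.with_suffix(".json").read_text())
        model = cls(spec)
        with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
            model.params = {k: data[k] for k in data.files}
        return model


class AdamW:
    """Adam with decoupled weight decay (decay applied to conv weights only)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 weight_decay: float = 5e-4, betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, p in self.params.items():
            g = grads[k].astype(p.dtype).reshape(p.shape)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            upd = mhat / (np.sqrt(vhat) + self.eps)
            if k.endswith("_W") and self.weight_decay:
                upd = upd + self.weight_decay * p
            p -= self.lr * upd
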