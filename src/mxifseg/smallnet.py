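"""A small convolutional encoder-decoder with skip connections, in pure numpy.

CPU-sized stand-in for the semantic-segmentation networks used by the
bootstrap loop and the reference instance backend. Explicit forward/backward
passes; SGD with momentum, weight decay and global-norm gradient clipping.
Inputs are (C, H, W) float arrays; outputs are per-pixel class logits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["SmallUNet", "SGD", "softmax", "weighted_ce_loss_grad"]


def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-padded 2-D convolution. x: (C,H,W), W: (O,C,k,k), b: (O,)."""
    k = W.shape[-1]
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(1, 2))  # (C,H,W,k,k)
    return np.einsum("chwij,ocij->ohw", win, W, optimize=True) + b[:, None, None]


def _conv_backward(
    x: np.ndarray, W: np.ndarray, dy: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    k = W.shape[-1]
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(1, 2))
    dW = np.einsum("ohw,chwij->ocij", dy, win, optimize=True)
    db = dy.sum(axis=(1, 2))
    dyp = np.pad(dy, ((0, 0), (pad, pad), (pad, pad)))
    dywin = sliding_window_view(dyp, (k, k), axis=(1, 2))  # (O,H,W,k,k)
    Wflip = W[:, :, ::-1, ::-1]
    dx = np.einsum("ohwij,ocij->chw", dywin, Wflip, optimize=True)
    return dx, dW, db


def _pool2(x: np.ndarray) -> np.ndarray:
    c, h, w = x.shape
    return x.reshape(c, h // 2, 2, w // 2, 2).mean(axis=(2, 4))


def _pool2_backward(dy: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(dy, 2, axis=1), 2, axis=2) / 4.0


def _up2(x: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)


def _up2_backward(dy: np.ndarray) -> np.ndarray:
    c, h, w = dy.shape
    return dy.reshape(c, h // 2, 2, w // 2, 2).sum(axis=(2, 4))


def softmax(logits: np.ndarray) -> np.ndarray:
    """Channel-wise softmax over (K, H, W) logits."""
    z = logits - logits.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


def weighted_ce_loss_grad(
    logits: np.ndarray, target: np.ndarray, class_weights: np.ndarray
) -> tuple[float, np.ndarray]:
    """Per-pixel weighted cross-entropy, normalized by the total pixel weight.

    ``target`` holds integer class codes (K classes over (H, W)). Returns the
    scalar loss and d(loss)/d(logits).
    """
    p = softmax(logits)
    k = logits.shape[0]
    onehot = np.stack([(target == c) for c in range(k)]).astype(np.float64)
    wmap = class_weights[target]  # (H, W)
    wsum = wmap.sum()
    eps = 1e-12
    loss = -(wmap * np.log((p * onehot).sum(axis=0) + eps)).sum() / wsum
    dlogits = (p - onehot) * wmap[None] / wsum
    return float(loss), dlogits


class SmallUNet:
    """Encoder-decoder with nearest-neighbor upsampling and skip concatenation.

    ``levels`` encoder levels of 3x3 conv + ReLU + 2x average pool, a
    bottleneck conv, a mirrored decoder, and a 1x1 "head" conv producing
    ``n_classes`` logits. Spatial dims must be divisible by 2**levels.
    """

    def __init__(
        self,
        in_channels: int = 1,
        n_classes: int = 3,
        base_filters: int = 8,
        levels: int = 2,
        seed: int = 0,
    ):
        self.in_channels = in_channels
        self.n_classes = n_classes
        self.base_filters = base_filters
        self.levels = levels
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}

        def he(shape):
            fan_in = np.prod(shape[1:])
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        cin = in_channels
        for l in range(levels):
            f = base_filters * 2**l
            self.params[f"enc{l}_W"] = he((f, cin, 3, 3))
            self.params[f"enc{l}_b"] = np.zeros(f)
            cin = f
        fb = base_filters * 2**levels
        self.params["bott_W"] = he((fb, cin, 3, 3))
        self.params["bott_b"] = np.zeros(fb)
        cup = fb
        for l in range(levels - 1, -1, -1):
            f = base_filters * 2**l
            self.params[f"dec{l}_W"] = he((f, cup + f, 3, 3))
            self.params[f"dec{l}_b"] = np.zeros(f)
            cup = f
        self.params["head_W"] = he((n_classes, cup, 1, 1))
        self.params["head_b"] = np.zeros(n_classes)

    @property
    def head_param_names(self) -> list[str]:
        """The prediction-layer parameters ("heads" for staged fine-tuning)."""
        return ["head_W", "head_b"]

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, dict]:
        if x.ndim != 3 or x.shape[0] != self.in_channels:
            raise ValueError(f"expected ({self.in_channels}, H, W) input, got {x.shape}")
        div = 2**self.levels
        if x.shape[1] % div or x.shape[2] % div:
            raise ValueError(f"spatial dims must be divisible by {div}")
        cache: dict = {"x": x}
        h = x
        skips = []
        for l in range(self.levels):
            z = _conv_forward(h, self.params[f"enc{l}_W"], self.params[f"enc{l}_b"])
            a = np.maximum(z, 0.0)
            cache[f"enc{l}_in"], cache[f"enc{l}_z"], cache[f"enc{l}_a"] = h, z, a
            skips.append(a)
            h = _pool2(a)
        z = _conv_forward(h, self.params["bott_W"], self.params["bott_b"])
        a = np.maximum(z, 0.0)
        cache["bott_in"], cache["bott_z"] = h, z
        h = a
        for l in range(self.levels - 1, -1, -1):
            up = _up2(h)
            cat = np.concatenate([up, skips[l]], axis=0)
            z = _conv_forward(cat, self.params[f"dec{l}_W"], self.params[f"dec{l}_b"])
            a = np.maximum(z, 0.0)
            cache[f"dec{l}_in"], cache[f"dec{l}_z"], cache[f"dec{l}_up_c"] = cat, z, up.shape[0]
            h = a
        logits = _conv_forward(h, self.params["head_W"], self.params["head_b"])
        cache["head_in"] = h
        return logits, cache

    def backward(self, cache: dict, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        dh, grads["head_W"], grads["head_b"] = _conv_backward(
            cache["head_in"], self.params["head_W"], dlogits
        )
        dskip = {}
        for l in range(self.levels):
            dz = dh * (cache[f"dec{l}_z"] > 0)
            dcat, grads[f"dec{l}_W"], grads[f"dec{l}_b"] = _conv_backward(
                cache[f"dec{l}_in"], self.params[f"dec{l}_W"], dz
            )
            cup = cache[f"dec{l}_up_c"]
            dup, dskip[l] = dcat[:cup], dcat[cup:]
            dh = _up2_backward(dup)
        dz = dh * (cache["bott_z"] > 0)
        dh, grads["bott_W"], grads["bott_b"] = _conv_backward(
            cache["bott_in"], self.params["bott_W"], dz
        )
        for l in range(self.levels - 1, -1, -1):
            da = _pool2_backward(dh) + dskip[l]
            dz = da * (cache[f"enc{l}_z"] > 0)
            dh, grads[f"enc{l}_W"], grads[f"enc{l}_b"] = _conv_backward(
                cache[f"enc{l}_in"], self.params[f"enc{l}_W"], dz
            )
        return grads

    def predict_logits(self, x: np.ndarray) -> np.ndarray:
        logits, _ = self.forward(x)
        return logits

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.predict_logits(x))

    def get_state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.array(state[k], dtype=np.float64)

    def save(self, path) -> None:
        np.savez(path, **self.params, _meta=np.array(
            [self.in_channels, self.n_classes, self.base_filters, self.levels]
        ))

    @classmethod
    def load(cls, path) -> "SmallUNet":
        data = np.load(path)
        cin, ncls, bf, lv = (int(v) for v in data["_meta"])
        net = cls(in_channels=cin, n_classes=ncls, base_filters=bf, levels=lv)
        net.set_state({k: data[k] for k in net.params})
        return net


@dataclass
class SGD:
    """Stochastic gradient descent with momentum, weight decay and clipping.

    Gradient clipping rescales the global L2 norm to ``gradient_clip`` when
    exceeded, applied before the momentum update.
    """

    learning_rate: float = 1e-4
    momentum: float = 0.9
    weight_decay: float = 1e-4
    gradient_clip: float = 5.0

    def __post_init__(self):
        self._velocity: dict[str, np.ndarray] = {}

    def step(
        self,
        params: dict[str, np.ndarray],
        grads: dict[str, np.ndarray],
        trainable: list[str] | None = None,
    ) -> None:
        names = list(grads) if trainable is None else [n for n in trainable if n in grads]
        total = np.sqrt(sum(float((grads[n] ** 2).sum()) for n in names))
        scale = self.gradient_clip / total if total > self.gradient_clip else 1.0
        for n in names:
            g = grads[n] * scale + self.weight_decay * params[n]
            v = self._velocity.get(n)
            v = g if v is None else self.momentum * v + g
            self._velocity[n] = v
            params[n] -= self.learning_rate * v
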