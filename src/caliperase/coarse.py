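"""Coarse reconstruction network: a small learned inpainting backend.

A three-layer fully convolutional net (3x3 convs, a dilated middle layer to
widen the receptive field, sigmoid output) maps (corrupted image, mask) to a
rough reconstruction and is trained with an l1 loss on the masked pixels
only — the first, reconstruction-only stage of a two-stage inpainting
design. At restore time only masked pixels are replaced, so pixels outside
the mask stay bit-exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from caliperase.inpaint import InpaintResult
from caliperase.nnet import Adam, conv2d_backward, conv2d_forward, relu, sigmoid


class DataError(ValueError):
    pass


@dataclass
class CoarseNetConfig:
    channels: int = 8
    kernel: int = 3
    dilation: int = 2       # middle layer
    epochs: int = 40
    lr: float = 2e-3
    batch_size: int = 8
    patch: int = 32         # training patch side
    patches_per_image: int = 2


@dataclass
class CoarseNet:
    params: dict[str, np.ndarray]
    config: CoarseNetConfig
    history: list[float] = field(default_factory=list)


def init_coarse_net(config: CoarseNetConfig | None = None, seed: int = 0) -> CoarseNet:
    if config is None:
        config = CoarseNetConfig()
    rng = np.random.default_rng(seed)
    c, k = config.channels, config.kernel
    def w(cout, cin):
        fan_in, fan_out = cin * k * k, cout * k * k
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-lim, lim, size=(cout, cin, k, k))
    params = {
        "W1": w(c, 2), "b1": np.zeros(c),
        "W2": w(c, c), "b2": np.zeros(c),
        "W3": w(1, c), "b3": np.zeros(1),
    }
    return CoarseNet(params=params, config=config)


def _forward(net: CoarseNet, x: np.ndarray) -> dict:
    p, d = net.params, net.config.dilation
    o1, c1 = conv2d_forward(x, p["W1"], p["b1"])
    h1 = relu(o1)
    o2, c2 = conv2d_forward(h1, p["W2"], p["b2"], dilation=d)
    h2 = relu(o2)
    o3, c3 = conv2d_forward(h2, p["W3"], p["b3"])
    out = sigmoid(o3)
    return {"x": x, "o1": o1, "h1": h1, "c1": c1, "o2": o2, "h2": h2,
            "c2": c2, "o3": o3, "c3": c3, "out": out}


def coarse_predict(net: CoarseNet, corrupted: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Raw network output over the full image (no compositing)."""
    m = mask.astype(float)
    x = np.stack([corrupted * (1.0 - m), m])[None]
    return _forward(net, x)["out"][0, 0]


def masked_l1(net: CoarseNet, pairs: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
              ) -> float:
    """Mean masked-pixel l1 reconstruction error over (corrupted, mask, original)."""
    tot = n = 0.0
    for corrupted, mask, original in pairs:
        pred = coarse_predict(net, corrupted, mask)
        m = mask.astype(bool)
        tot += np.abs(pred[m] - original[m]).sum()
        n += m.sum()
    return float(tot / max(n, 1))


def _harvest_patches(pairs, patch: int, per_image: int, rng: np.random.Generator):
    xs, masks, targets = [], [], []
    for corrupted, mask, original in pairs:
        h, w = corrupted.shape
        ys, xs_ = np.nonzero(mask)
        if len(ys) == 0:
            continue
        for _ in range(per_image):
            i = int(rng.integers(0, len(ys)))
            r0 = int(np.clip(ys[i] - patch // 2, 0, h - patch))
            c0 = int(np.clip(xs_[i] - patch // 2, 0, w - patch))
            sl = (slice(r0, r0 + patch), slice(c0, c0 + patch))
            m = mask[sl].astype(float)
            xs.append(np.stack([corrupted[sl] * (1.0 - m), m]))
            masks.append(m)
            targets.append(original[sl])
    return (np.array(xs), np.array(masks), np.array(targets))


def train_coarse_net(pairs: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
                     config: CoarseNetConfig | None = None, seed: int = 0) -> CoarseNet:
    """Train the coarse net on (corrupted, mask, original) image triples.

    Requires at least 50 triples; the per-epoch masked-l1 training loss is
    logged to ``net.history``. Deterministic given (data, config, seed).
    """
    if not pairs:
        raise DataError("empty training set")
    if len(pairs) < 50:
        raise DataError(f"need >= 50 training pairs, got {len(pairs)}")
    if config is None:
        config = CoarseNetConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0A5]))
    net = init_coarse_net(config, seed=seed)
    x, m, t = _harvest_patches(pairs, config.patch, config.patches_per_image, rng)
    if len(x) == 0:
        raise DataError("no masked pixels in the training set")
    opt = Adam(net.params, lr=config.lr)
    n = len(x)
    d = config.dilation
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        n_px = 0.0
        for s in range(0, n, config.batch_size):
            idx = order[s:s + config.batch_size]
            xb, mb, tb = x[idx], m[idx], t[idx]
            cache = _forward(net, xb)
            pred = cache["out"][:, 0]
            diff = pred - tb
            nm = mb.sum()
            if nm == 0:
                continue
            ep_loss += float((np.abs(diff) * mb).sum())
            n_px += nm
            dpred = np.sign(diff) * mb / nm
            dout = (dpred * pred * (1.0 - pred))[:, None]
            p = net.params
            dh2, dw3, db3 = conv2d_backward(dout, cache["c3"], p["W3"], cache["h2"].shape)
            do2 = dh2 * (cache["o2"] > 0)
            dh1, dw2, db2 = conv2d_backward(do2, cache["c2"], p["W2"], cache["h1"].shape,
                                            dilation=d)
            do1 = dh1 * (cache["o1"] > 0)
            _, dw1, db1 = conv2d_backward(do1, cache["c1"], p["W1"], cache["x"].shape)
            opt.step({"W1": dw1, "b1": db1, "W2": dw2, "b2": db2,
                      "W3": dw3, "b3": db3})
        net.history.append(ep_loss / max(n_px, 1))
    return net


def inpaint_coarse(net: CoarseNet, image: np.ndarray, mask: np.ndarray) -> InpaintResult:
    """Restore an image with the coarse net; only masked pixels change."""
    mask = mask.astype(bool)
    pred = coarse_predict(net, image, mask)
    out = image.copy()
    out[mask] = pred[mask]
    return InpaintResult(image=out, mask=mask, backend="coarse_net")
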