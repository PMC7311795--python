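"""Variational information bottleneck (VIB) crop classifier and its baseline.

The encoder maps an image crop to a 2K vector; the first K entries are the
posterior mean mu and the last K pass through a softplus to give the scale
sigma, defining a diagonal Gaussian p(z|x) = N(mu, diag(sigma^2)). The
decoder is a linear map from z to two class logits followed by softmax. The
training objective is the variational bound

    L = E_x,y [ E_{z~p(z|x)} [-log q(y|z)] ]  +  beta * E_x [ KL(p(z|x) || r(z)) ]

with r(z) = N(0, I) and the expectation over z estimated by reparameterized
Monte-Carlo sampling (z = mu + sigma * eps). The matched baseline trains the
identical encoder backbone with a plain cross-entropy at z = mu: the only
differences are the sampling and the KL rate term.

At this size (two hidden layers, ~50-90k parameters on 16x16 crops) the
models train in seconds on one CPU, which is what lets the condition grids
run as ordinary tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from caliperase import nnet
from caliperase.nnet import Adam, cross_entropy, glorot, relu, softmax, softplus


class DataError(ValueError):
    pass


class ShapeError(ValueError):
    pass


@dataclass
class GaussianPosterior:
    """Diagonal-Gaussian encoder output; mu and sigma are (K,) or (N, K)."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.mu.shape != self.sigma.shape:
            raise ShapeError("mu and sigma must have the same shape")
        if not (self.sigma > 0).all():
            raise ValueError("sigma must be strictly positive")


@dataclass
class VIBLossTerms:
    class_term: float
    rate_term: float
    beta: float

    @property
    def total(self) -> float:
        return self.class_term + self.beta * self.rate_term


@dataclass
class ClassifierConfig:
    use_vib: bool = True
    beta: float = 1e-3
    K: int = 32
    epochs: int = 60
    lr: float = 1e-3
    batch_size: int = 32
    arch: str = "mlp"              # "mlp" or "conv"
    hidden: tuple[int, int] = (128, 64)
    conv_channels: tuple[int, int] = (8, 16)
    input_side: int = 16
    n_mc: int = 1


@dataclass
class VIBModel:
    """Encoder + decoder parameters; ``use_vib=False`` marks the baseline."""

    params: dict[str, np.ndarray]
    K: int
    beta: float
    input_side: int
    hidden: tuple[int, int]
    use_vib: bool
    arch: str = "mlp"
    conv_channels: tuple[int, int] = (8, 16)
    history: list[dict] = field(default_factory=list)

    @property
    def input_dim(self) -> int:
        return self.input_side * self.input_side


def init_model(config: ClassifierConfig, seed: int = 0) -> VIBModel:
    rng = np.random.default_rng(seed)
    if config.arch == "mlp":
        d = config.input_side ** 2
        h1, h2 = config.hidden
        params = {
            "W1": glorot(rng, d, h1), "b1": np.zeros(h1),
            "W2": glorot(rng, h1, h2), "b2": np.zeros(h2),
            "W3": glorot(rng, h2, 2 * config.K), "b3": np.zeros(2 * config.K),
            "Wd": glorot(rng, config.K, 2), "bd": np.zeros(2),
        }
    elif config.arch == "conv":
        c1, c2 = config.conv_channels
        side = config.input_side
        if side % 4 != 0:
            raise ValueError("conv arch needs input_side divisible by 4")
        feat = c2 * (side // 4) ** 2
        h = config.hidden[-1]
        def cw(cout, cin):
            lim = np.sqrt(6.0 / (cin * 9 + cout * 9))
            return rng.uniform(-lim, lim, size=(cout, cin, 3, 3))
        params = {
            "C1": cw(c1, 1), "cb1": np.zeros(c1),
            "C2": cw(c2, c1), "cb2": np.zeros(c2),
            "W3": glorot(rng, feat, h), "b3": np.zeros(h),
            "W4": glorot(rng, h, 2 * config.K), "b4": np.zeros(2 * config.K),
            "Wd": glorot(rng, config.K, 2), "bd": np.zeros(2),
        }
    else:
        raise ValueError("arch must be 'mlp' or 'conv'")
    return VIBModel(params=params, K=config.K, beta=config.beta,
                    input_side=config.input_side, hidden=config.hidden,
                    use_vib=config.use_vib, arch=config.arch,
                    conv_channels=config.conv_channels)


def _maxpool2(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
    out = xr.max(axis=(3, 5))
    mask = (xr == out[:, :, :, None, :, None])
    return out, mask


def _maxpool2_backward(dout: np.ndarray, mask: np.ndarray) -> np.ndarray:
    n, c, h2, _, w2, _ = mask.shape
    dxr = mask * dout[:, :, :, None, :, None]
    return dxr.reshape(n, c, h2 * 2, w2 * 2)


def _flatten_crops(model: VIBModel, crops: np.ndarray) -> np.ndarray:
    x = np.asarray(crops, dtype=float)
    if x.ndim == 2 and x.shape == (model.input_side, model.input_side):
        x = x[None]
    if x.ndim == 3:
        if x.shape[1:] != (model.input_side, model.input_side):
            raise ShapeError(f"expected crops of side {model.input_side}, got {x.shape[1:]}")
        x = x.reshape(x.shape[0], model.input_dim)
    elif x.ndim != 2 or x.shape[1] != model.input_dim:
        raise ShapeError(f"expected flat dim {model.input_dim}, got {x.shape}")
    return x


def _encoder_forward(model: VIBModel, x: np.ndarray) -> dict:
    p = model.params
    k = model.K
    if model.arch == "mlp":
        a1 = x @ p["W1"] + p["b1"]
        h1 = relu(a1)
        a2 = h1 @ p["W2"] + p["b2"]
        h2 = relu(a2)
        out = h2 @ p["W3"] + p["b3"]
        cache = {"x": x, "a1": a1, "h1": h1, "a2": a2, "h2": h2}
    else:
        from caliperase.nnet import conv2d_forward
        n = x.shape[0]
        side = model.input_side
        x4 = x.reshape(n, 1, side, side)
        o1, ci1 = conv2d_forward(x4, p["C1"], p["cb1"])
        h1 = relu(o1)
        p1, m1 = _maxpool2(h1)
        o2, ci2 = conv2d_forward(p1, p["C2"], p["cb2"])
        h2 = relu(o2)
        p2, m2 = _maxpool2(h2)
        f = p2.reshape(n, -1)
        a3 = f @ p["W3"] + p["b3"]
        h3 = relu(a3)
        out = h3 @ p["W4"] + p["b4"]
        cache = {"x4": x4, "o1": o1, "ci1": ci1, "m1": m1, "p1": p1,
                 "o2": o2, "ci2": ci2, "m2": m2, "p2": p2,
                 "f": f, "a3": a3, "h3": h3}
    mu, sraw = out[:, :k], out[:, k:]
    cache.update({"mu": mu, "sraw": sraw, "sigma": softplus(sraw)})
    return cache


def _encoder_backward(model: VIBModel, cache: dict, dout: np.ndarray,
                      grads: dict[str, np.ndarray]) -> None:
    """Accumulate encoder parameter grads given d(2K output)."""
    p = model.params
    if model.arch == "mlp":
        grads["W3"] += cache["h2"].T @ dout
        grads["b3"] += dout.sum(axis=0)
        dh2 = dout @ p["W3"].T
        da2 = dh2 * (cache["a2"] > 0)
        grads["W2"] += cache["h1"].T @ da2
        grads["b2"] += da2.sum(axis=0)
        dh1 = da2 @ p["W2"].T
        da1 = dh1 * (cache["a1"] > 0)
        grads["W1"] += cache["x"].T @ da1
        grads["b1"] += da1.sum(axis=0)
    else:
        from caliperase.nnet import conv2d_backward
        grads["W4"] += cache["h3"].T @ dout
        grads["b4"] += dout.sum(axis=0)
        dh3 = dout @ p["W4"].T
        da3 = dh3 * (cache["a3"] > 0)
        grads["W3"] += cache["f"].T @ da3
        grads["b3"] += da3.sum(axis=0)
        df = da3 @ p["W3"].T
        dp2 = df.reshape(cache["p2"].shape)
        dh2 = _maxpool2_backward(dp2, cache["m2"]) * (cache["o2"] > 0)
        dp1, dc2, dcb2 = conv2d_backward(dh2, cache["ci2"], p["C2"],
                                         cache["p1"].shape)
        grads["C2"] += dc2
        grads["cb2"] += dcb2
        dh1 = _maxpool2_backward(dp1, cache["m1"]) * (cache["o1"] > 0)
        _, dc1, dcb1 = conv2d_backward(dh1, cache["ci1"], p["C1"],
                                       cache["x4"].shape)
        grads["C1"] += dc1
        grads["cb1"] += dcb1


def encode(model: VIBModel, crops: np.ndarray) -> GaussianPosterior:
    """Posterior (mu, sigma) for one crop or a batch of crops."""
    x = _flatten_crops(model, crops)
    cache = _encoder_forward(model, x)
    mu, sigma = cache["mu"], cache["sigma"]
    if np.asarray(crops).ndim == 2 and np.asarray(crops).shape == (model.input_side,) * 2:
        return GaussianPosterior(mu=mu[0], sigma=sigma[0])
    return GaussianPosterior(mu=mu, sigma=sigma)


def kl_to_standard_normal(post: GaussianPosterior) -> float | np.ndarray:
    """Closed-form KL( N(mu, diag(sigma^2)) || N(0, I) ).

    Returns a scalar for a single posterior, a per-sample vector for a
    batch. Always >= 0.
    """
    mu, sigma = np.asarray(post.mu, dtype=float), np.asarray(post.sigma, dtype=float)
    if not (sigma > 0).all():
        raise ValueError("sigma must be strictly positive")
    kl = 0.5 * (mu ** 2 + sigma ** 2 - 1.0 - 2.0 * np.log(sigma)).sum(axis=-1)
    return float(kl) if kl.ndim == 0 else kl


def _loss_and_grads(model: VIBModel, x: np.ndarray, y: np.ndarray,
                    n_mc: int, rng: np.random.Generator
                    ) -> tuple[VIBLossTerms, dict[str, np.ndarray]]:
    p = model.params
    n, k = x.shape[0], model.K
    cache = _encoder_forward(model, x)
    mu, sraw, sigma = cache["mu"], cache["sraw"], cache["sigma"]

    grads = {key: np.zeros_like(val) for key, val in p.items()}
    dmu = np.zeros_like(mu)
    dsigma = np.zeros_like(sigma)

    if model.use_vib:
        class_term = 0.0
        for _ in range(n_mc):
            eps = rng.standard_normal(mu.shape)
            z = mu + sigma * eps
            logits = z @ p["Wd"] + p["bd"]
            loss, dlogits = cross_entropy(logits, y)
            class_term += loss / n_mc
            dlogits /= n_mc
            grads["Wd"] += z.T @ dlogits
            grads["bd"] += dlogits.sum(axis=0)
            dz = dlogits @ p["Wd"].T
            dmu += dz
            dsigma += dz * eps
        rate_vec = 0.5 * (mu ** 2 + sigma ** 2 - 1.0 - 2.0 * np.log(sigma)).sum(axis=1)
        rate_term = float(rate_vec.mean())
        dmu += model.beta * mu / n
        dsigma += model.beta * (sigma - 1.0 / sigma) / n
    else:
        z = mu
        logits = z @ p["Wd"] + p["bd"]
        class_term, dlogits = cross_entropy(logits, y)
        grads["Wd"] += z.T @ dlogits
        grads["bd"] += dlogits.sum(axis=0)
        dmu += dlogits @ p["Wd"].T
        rate_term = 0.0

    dsraw = dsigma * nnet.sigmoid(sraw)  # d softplus
    dout = np.concatenate([dmu, dsraw], axis=1)
    _encoder_backward(model, cache, dout, grads)
    beta = model.beta if model.use_vib else 0.0
    return VIBLossTerms(class_term=class_term, rate_term=rate_term, beta=beta), grads


def vib_loss(model: VIBModel, crops: np.ndarray, labels: np.ndarray,
             n_mc: int = 1, seed: int = 0) -> VIBLossTerms:
    """Monte-Carlo VIB loss terms on a batch (no parameter update).

    class_term is the reparameterized estimate of E[-log q(y|z)] averaged
    over the batch and the ``n_mc`` draws; rate_term is the batch-mean KL to
    N(0, I); ``total`` is ``class_term + beta * rate_term`` exactly.
    """
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    x = _flatten_crops(model, crops)
    y = np.asarray(labels, dtype=int)
    if len(y) == 0:
        raise DataError("empty batch")
    rng = np.random.default_rng(seed)
    terms, _ = _loss_and_grads(model, x, y, n_mc, rng)
    return terms


def train_classifier(crops: np.ndarray, labels: np.ndarray,
                     config: ClassifierConfig | None = None, seed: int = 0) -> VIBModel:
    """Train a VIB classifier or its cross-entropy baseline (per config).

    Deterministic given (data, config, seed) in single-threaded mode. The
    per-epoch loss terms are logged to ``model.history``.
    """
    if config is None:
        config = ClassifierConfig()
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise DataError("training data must contain both classes")
    model = init_model(config, seed=seed)
    x = _flatten_crops(model, crops)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC1A55]))
    opt = Adam(model.params, lr=config.lr)
    n = x.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        ep_class = ep_rate = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            terms, grads = _loss_and_grads(model, x[idx], y[idx], config.n_mc, rng)
            opt.step(grads)
            ep_class += terms.class_term
            ep_rate += terms.rate_term
            n_batches += 1
        model.history.append({"epoch": epoch,
                              "class_term": ep_class / n_batches,
                              "rate_term": ep_rate / n_batches})
    return model


def predict(model: VIBModel, crops: np.ndarray, mode: str = "mean",
            n_samples: int = 1, seed: int = 0) -> np.ndarray:
    """Class probabilities per crop.

    mode="mean" decodes deterministically at z = mu; mode="sample" averages
    softmax outputs over ``n_samples`` reparameterized draws.
    """
    x = _flatten_crops(model, crops)
    cache = _encoder_forward(model, x)
    p = model.params
    if mode == "mean":
        return softmax(cache["mu"] @ p["Wd"] + p["bd"])
    if mode != "sample":
        raise ValueError("mode must be 'mean' or 'sample'")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1 in sample mode")
    rng = np.random.default_rng(seed)
    acc = np.zeros((x.shape[0], 2))
    for _ in range(n_samples):
        eps = rng.standard_normal(cache["mu"].shape)
        z = cache["mu"] + cache["sigma"] * eps
        acc += softmax(z @ p["Wd"] + p["bd"])
    return acc / n_samples


def accuracy(model: VIBModel, crops: np.ndarray, labels: np.ndarray) -> float:
    probs = predict(model, crops, mode="mean")
    return float((probs.argmax(axis=1) == np.asarray(labels)).mean())
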