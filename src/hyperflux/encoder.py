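"""Autoencoder compression of spectral stacks into four CMYK variables.

A small fully-connected autoencoder (69 -> 16 -> 4 -> 16 -> 69 by
default) maps each pixel spectrum to a 4-D bottleneck squashed into
[0, 1]^4, which is rendered as a CMYK image. Training minimises pixel
reconstruction error plus ``alpha`` times a group-separation penalty
(the negative Fisher ratio of the bottleneck codes between two patient
groups), so the four colour variables both summarise the spectrum and
highlight where the groups differ. The network and its Adam optimiser
are implemented in numpy with explicit seeding, so training is
deterministic for a fixed seed and data order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from hyperflux.io_core import SpectralStack


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


@dataclass
class EncoderConfig:
    hidden: int = 16
    bottleneck: int = 4
    epochs: int = 60
    batch_size: int = 256
    learning_rate: float = 3e-3
    alpha: float = 0.1  # weight of the group-separation penalty
    max_pixels: int = 50000
    seed: int = 0


@dataclass
class EncoderModel:
    """Trained autoencoder weights plus the scaling needed to apply it."""

    weights: dict[str, np.ndarray]
    input_scale: float
    code_min: np.ndarray  # per-bottleneck-unit min over the training set
    code_max: np.ndarray
    config: EncoderConfig
    history: list[float] = field(default_factory=list)
    group_pair: tuple[str, str] | None = None

    @property
    def n_channels(self) -> int:
        return self.weights["W1"].shape[0]

    def encode(self, X: np.ndarray) -> np.ndarray:
        """Pixel spectra -> raw bottleneck codes in [0, 1]^4."""
        Xs = np.asarray(X, dtype=np.float64) / self.input_scale
        h = np.maximum(Xs @ self.weights["W1"] + self.weights["b1"], 0.0)
        return _sigmoid(h @ self.weights["W2"] + self.weights["b2"])

    def encode_cmyk(self, X: np.ndarray) -> np.ndarray:
        """Codes rescaled per channel to the training-set [min, max] span."""
        z = self.encode(X)
        span = np.where(self.code_max > self.code_min, self.code_max - self.code_min, 1.0)
        return np.clip((z - self.code_min) / span, 0.0, 1.0)

    def decode(self, Z: np.ndarray) -> np.ndarray:
        h = np.maximum(Z @ self.weights["W3"] + self.weights["b3"], 0.0)
        return _softplus(h @ self.weights["W4"] + self.weights["b4"]) * self.input_scale


@dataclass
class CMYKImage:
    """Four-channel (C, M, Y, K) image in [0, 1]."""

    data: np.ndarray  # (x, y, 4)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or self.data.shape[2] != 4:
            raise ValueError("CMYK image must be (x, y, 4)")
        if self.data.min() < -1e-9 or self.data.max() > 1 + 1e-9:
            raise ValueError("CMYK values must lie in [0, 1]")
        self.data = np.clip(self.data, 0.0, 1.0)


def _init_weights(n_in: int, hidden: int, bottleneck: int, rng: np.random.Generator) -> dict:
    def glorot(a: int, b: int) -> np.ndarray:
        return rng.normal(0.0, np.sqrt(2.0 / (a + b)), size=(a, b))

    return {
        "W1": glorot(n_in, hidden),
        "b1": np.zeros(hidden),
        "W2": glorot(hidden, bottleneck),
        "b2": np.zeros(bottleneck),
        "W3": glorot(bottleneck, hidden),
        "b3": np.zeros(hidden),
        "W4": glorot(hidden, n_in),
        "b4": np.zeros(n_in),
    }


def _fisher_penalty_grad(
    Z: np.ndarray, groups: np.ndarray, names: tuple[str, str]
) -> tuple[float, np.ndarray]:
    """Negative Fisher ratio of codes and its gradient wrt the codes.

    J = -||m1 - m2||^2 / (s + eps) with s the summed within-group
    variances of the bottleneck units; minimising J pushes the group
    code means apart relative to their spread.
    """
    eps = 1e-3
    i1, i2 = groups == names[0], groups == names[1]
    n1, n2 = int(i1.sum()), int(i2.sum())
    if n1 == 0 or n2 == 0:
        return 0.0, np.zeros_like(Z)
    m1, m2 = Z[i1].mean(axis=0), Z[i2].mean(axis=0)
    d = m1 - m2
    c1, c2 = Z[i1] - m1, Z[i2] - m2
    s = (c1**2).sum() / n1 + (c2**2).sum() / n2
    denom = s + eps
    num = float(d @ d)
    J = -num / denom
    grad = np.zeros_like(Z)
    # d(num)/dZ
    grad[i1] += (2.0 / n1) * d
    grad[i2] -= (2.0 / n2) * d
    grad_num = grad / denom
    # d(s)/dZ
    grad_s = np.zeros_like(Z)
    grad_s[i1] = (2.0 / n1) * c1
    grad_s[i2] = (2.0 / n2) * c2
    return J, -(grad_num - (num / denom**2) * grad_s)


def train_encoder(
    X: np.ndarray,
    groups: np.ndarray | None = None,
    config: EncoderConfig | None = None,
) -> EncoderModel:
    """Train the CMYK autoencoder on pixel spectra.

    ``X`` is (n_pixels, n_channels), ideally sampled from tissue
    (structure) regions only; ``groups`` labels each pixel's patient
    group. With fewer than two groups the separation penalty is
    disabled and the model falls back to pure reconstruction (warned).
    """
    cfg = config or EncoderConfig()
    X = np.asarray(X, dtype=np.float64)
    rng = np.random.default_rng(cfg.seed)
    if X.shape[0] > cfg.max_pixels:
        sel = rng.choice(X.shape[0], size=cfg.max_pixels, replace=False)
        X = X[sel]
        groups = groups[sel] if groups is not None else None
    names: tuple[str, str] | None = None
    if groups is not None:
        uniq = sorted(np.unique(groups).tolist())
        if len(uniq) >= 2:
            names = (uniq[0], uniq[1])
        else:
            warnings.warn("single-group input: training as a plain autoencoder", stacklevel=2)
            groups = None
    if groups is None and cfg.alpha > 0:
        cfg = EncoderConfig(**{**cfg.__dict__, "alpha": 0.0})

    scale = float(np.quantile(X, 0.99)) or 1.0
    Xs = X / scale
    n, c = Xs.shape
    W = _init_weights(c, cfg.hidden, cfg.bottleneck, rng)
    m_adam = {k: np.zeros_like(v) for k, v in W.items()}
    v_adam = {k: np.zeros_like(v) for k, v in W.items()}
    beta1, beta2, eps_adam = 0.9, 0.999, 1e-8
    t = 0
    history: list[float] = []
    for epoch in range(cfg.epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            xb = Xs[idx]
            gb = groups[idx] if groups is not None else None
            # forward
            h1_pre = xb @ W["W1"] + W["b1"]
            h1 = np.maximum(h1_pre, 0.0)
            z_pre = h1 @ W["W2"] + W["b2"]
            z = _sigmoid(z_pre)
            h2_pre = z @ W["W3"] + W["b3"]
            h2 = np.maximum(h2_pre, 0.0)
            out_pre = h2 @ W["W4"] + W["b4"]
            out = _softplus(out_pre)
            diff = out - xb
            recon = float((diff**2).mean())
            loss = recon
            # backward: d(recon)/d(out) = 2 diff / size
            g_out = 2.0 * diff / diff.size
            g_out_pre = g_out * _sigmoid(out_pre)  # softplus' = sigmoid
            g = {}
            g["W4"] = h2.T @ g_out_pre
            g["b4"] = g_out_pre.sum(axis=0)
            g_h2 = (g_out_pre @ W["W4"].T) * (h2_pre > 0)
            g["W3"] = z.T @ g_h2
            g["b3"] = g_h2.sum(axis=0)
            g_z = g_h2 @ W["W3"].T
            if cfg.alpha > 0 and gb is not None and names is not None:
                J, gJ = _fisher_penalty_grad(z, gb, names)
                loss += cfg.alpha * J
                g_z = g_z + cfg.alpha * gJ
            g_z_pre = g_z * z * (1.0 - z)
            g["W2"] = h1.T @ g_z_pre
            g["b2"] = g_z_pre.sum(axis=0)
            g_h1 = (g_z_pre @ W["W2"].T) * (h1_pre > 0)
            g["W1"] = xb.T @ g_h1
            g["b1"] = g_h1.sum(axis=0)
            t += 1
            for k in W:
                m_adam[k] = beta1 * m_adam[k] + (1 - beta1) * g[k]
                v_adam[k] = beta2 * v_adam[k] + (1 - beta2) * g[k] ** 2
                mhat = m_adam[k] / (1 - beta1**t)
                vhat = v_adam[k] / (1 - beta2**t)
                W[k] = W[k] - cfg.learning_rate * mhat / (np.sqrt(vhat) + eps_adam)
            epoch_loss += loss * len(idx)
        history.append(epoch_loss / n)
    model = EncoderModel(
        weights=W,
        input_scale=scale,
        code_min=np.zeros(cfg.bottleneck),
        code_max=np.ones(cfg.bottleneck),
        config=cfg,
        history=history,
        group_pair=names,
    )
    codes = model.encode(X)
    model.code_min = codes.min(axis=0)
    model.code_max = codes.max(axis=0)
    return model


def encode_stack(stack: SpectralStack, model: EncoderModel) -> CMYKImage:
    """Apply the trained encoder per pixel; output (x, y, 4) in [0, 1]."""
    if stack.n_channels != model.n_channels:
        raise ValueError(
            f"stack has {stack.n_channels} channels, model expects {model.n_channels}"
        )
    h, w = stack.spatial_shape
    codes = model.encode_cmyk(stack.pixels())
    return CMYKImage(data=codes.reshape(h, w, 4))


def render_cmyk(image: CMYKImage) -> np.ndarray:
    """Naive CMYK -> 8-bit RGB: R=(1-C)(1-K), G=(1-M)(1-K), B=(1-Y)(1-K)."""
    c, m, y, k = np.moveaxis(image.data, -1, 0)
    rgb = np.stack([(1 - c) * (1 - k), (1 - m) * (1 - k), (1 - y) * (1 - k)], axis=-1)
    return np.round(rgb * 255.0).astype(np.uint8)


def save_model(model: EncoderModel, path: str) -> None:
    np.savez(
        path,
        input_scale=model.input_scale,
        code_min=model.code_min,
        code_max=model.code_max,
        alpha=model.config.alpha,
        seed=model.config.seed,
        **model.weights,
    )


def load_model(path: str) -> EncoderModel:
    data = np.load(path)
    weights = {k: data[k] for k in ("W1", "b1", "W2", "b2", "W3", "b3", "W4", "b4")}
    cfg = EncoderConfig(
        hidden=weights["W1"].shape[1],
        bottleneck=weights["W2"].shape[1],
        alpha=float(data["alpha"]),
        seed=int(data["seed"]),
    )
    return EncoderModel(
        weights=weights,
        input_scale=float(data["input_scale"]),
        code_min=data["code_min"],
        code_max=data["code_max"],
        config=cfg,
    )
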