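"""1-D CNN feature weighting of denoised gene-expression profiles.

A nine-layer network — convolution, max-pooling, convolution, max-pooling,
batch-normalization, flatten, hidden dense, dropout, output — is trained to
classify samples (by default, vital status) from their denoised key-gene
profile.  The activations of the final max-pooling layer, averaged over
channels, form the feature-weight matrix C used by the step-function gene
score; positions in C map back to contiguous gene windows through the
conv/pool geometry.

Implemented directly on numpy (forward, backprop, Adam); training is
deterministic for a fixed seed and single-threaded execution, which the
100-repeat selection protocol relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

__all__ = [
    "CNNConfig",
    "CNNModel",
    "PoolOutput",
    "FeatureWeightMatrix",
    "split_samples",
    "train_cnn",
    "extract_pool_output",
    "channel_average",
    "repeat_and_select",
    "LAYER_SEQUENCE",
]

#: fixed layer order of the nine-layer architecture
LAYER_SEQUENCE = (
    "convolution",
    "max_pooling",
    "convolution",
    "max_pooling",
    "batch_normalization",
    "flatten",
    "hidden_dense",
    "dropout",
    "output",
)


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""


@dataclass(frozen=True)
class CNNConfig:
    channels: tuple[int, int] = (32, 64)   # conv layer widths; second is tapped (p)
    kernel_sizes: tuple[int, int] = (5, 5)
    pool_widths: tuple[int, int] = (2, 2)
    hidden_units: int = 32
    dropout_rate: float = 0.5
    epochs: int = 100
    learning_rate: float = 1e-2
    weight_decay: float = 0.1
    batch_size: int = 32
    train_fraction: float = 0.7
    repeats: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")

    @property
    def n_layers(self) -> int:
        return len(LAYER_SEQUENCE)

    def layer_names(self) -> tuple[str, ...]:
        return LAYER_SEQUENCE

    def feature_geometry(self, n_features: int) -> tuple[int, int, int]:
        """(n_positions, stride, receptive_field) of the tapped pooling layer."""
        k1, k2 = self.kernel_sizes
        w1, w2 = self.pool_widths
        l_conv1 = n_features - k1 + 1
        l_pool1 = l_conv1 // w1
        l_conv2 = l_pool1 - k2 + 1
        l_pool2 = l_conv2 // w2
        if l_pool2 < 1:
            raise ValueError(
                f"{n_features} features too few for kernels {self.kernel_sizes} "
                f"and pools {self.pool_widths}"
            )
        stride = w1 * w2
        receptive = w1 * (w2 + k2 - 1) + k1 - 1
        return l_pool2, stride, receptive


@dataclass
class PoolOutput:
    """Final max-pooling activations: samples x positions x channels."""

    values: np.ndarray            # (m, n', p)
    feature_positions: pd.DataFrame  # position -> gene window (start, width)
    sample_ids: list[str]

    def __post_init__(self) -> None:
        if not np.isfinite(self.values).all():
            raise ValueError("pooling activations must be finite")
        if self.values.ndim != 3:
            raise ValueError("pool output must be samples x positions x channels")


@dataclass
class FeatureWeightMatrix:
    """Channel-averaged pooling output C, features x samples."""

    values: np.ndarray            # (n', m)
    sample_ids: list[str]
    feature_positions: pd.DataFrame


def channel_average(pool: PoolOutput) -> FeatureWeightMatrix:
    """C[f, s] = mean over channels of A[s, f, ch]."""
    c = pool.values.mean(axis=2).T
    return FeatureWeightMatrix(c, list(pool.sample_ids), pool.feature_positions)


def split_samples(
    sample_ids, labels, train_fraction: float = 0.7, seed: int = 0
) -> tuple[list, list]:
    """Stratified random split into disjoint, exhaustive train/test id lists."""
    ids = np.asarray(sample_ids)
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    classes = list(np.unique(y))
    # largest-remainder allocation keeps the overall train count at
    # round(fraction * n) while staying stratified
    targets = {c: train_fraction * (y == c).sum() for c in classes}
    counts = {c: int(np.floor(t)) for c, t in targets.items()}
    short = int(round(train_fraction * len(y))) - sum(counts.values())
    for c in sorted(classes, key=lambda c: -(targets[c] - counts[c]))[:short]:
        counts[c] += 1
    train_idx: list[int] = []
    for cls in classes:
        idx = np.flatnonzero(y == cls)
        n_train = counts[cls]
        if n_train < 2 or len(idx) - n_train < 1:
            raise ValueError(
                f"class {cls!r} has too few samples ({len(idx)}) for a "
                f"{train_fraction:.0%} split"
            )
        train_idx.extend(rng.permutation(idx)[:n_train])
    mask = np.zeros(len(ids), bool)
    mask[train_idx] = True
    return list(ids[mask]), list(ids[~mask])


# ---------------------------------------------------------------------------
# Layers (forward + backward); minimal, single-purpose
# ---------------------------------------------------------------------------


def _conv1d_forward(x, w, b):
    # x: (B, Cin, L); w: (Cout, Cin, K) -> (B, Cout, L-K+1), valid cross-correlation
    win = np.lib.stride_tricks.sliding_window_view(x, w.shape[2], axis=2)
    return np.einsum("bclk,ock->bol", win, w, optimize=True) + b[None, :, None]


def _conv1d_backward(x, w, grad):
    win = np.lib.stride_tricks.sliding_window_view(x, w.shape[2], axis=2)
    gw = np.einsum("bclk,bol->ock", win, grad, optimize=True)
    gb = grad.sum(axis=(0, 2))
    gx = np.zeros_like(x)
    k = w.shape[2]
    for j in range(k):  # scatter each tap's contribution
        gx[:, :, j : j + grad.shape[2]] += np.einsum(
            "bol,oc->bcl", grad, w[:, :, j], optimize=True
        )
    return gx, gw, gb


def _maxpool_forward(x, width):
    b, c, l = x.shape
    lp = l // width
    xr = x[:, :, : lp * width].reshape(b, c, lp, width)
    arg = xr.argmax(axis=3)
    return xr.max(axis=3), (arg, l)


def _maxpool_backward(grad, cache, width):
    arg, l = cache
    b, c, lp = grad.shape
    gx = np.zeros((b, c, lp, width))
    np.put_along_axis(gx, arg[..., None], grad[..., None], axis=3)
    out = np.zeros((b, c, l))
    out[:, :, : lp * width] = gx.reshape(b, c, lp * width)
    return out


class CNNModel:
    """The nine-layer network with trained parameters and running BN statistics."""

    def __init__(self, config: CNNConfig, n_features: int, rng: np.random.Generator):
        self.config = config
        self.n_features = n_features
        c1, c2 = config.channels
        k1, k2 = config.kernel_sizes
        n_pos, _, _ = config.feature_geometry(n_features)
        flat = c2 * n_pos
        he = lambda *shape, fan: rng.normal(0.0, np.sqrt(2.0 / fan), shape)
        self.params = {
            "w1": he(c1, 1, k1, fan=k1),
            "b1": np.zeros(c1),
            "w2": he(c2, c1, k2, fan=c1 * k2),
            "b2": np.zeros(c2),
            "gamma": np.ones(c2),
            "beta": np.zeros(c2),
            "wh": he(config.hidden_units, flat, fan=flat),
            "bh": np.zeros(config.hidden_units),
            "wo": he(1, config.hidden_units, fan=config.hidden_units),
            "bo": np.zeros(1),
        }
        self.bn_mean = np.zeros(c2)
        self.bn_var = np.ones(c2)
        self.bn_momentum = 0.9
        self.layer_names = LAYER_SEQUENCE

    # -- forward -------------------------------------------------------------

    def forward(self, x, training=False, dropout_rng=None):
        p = self.params
        cache = {"x": x}
        z1 = _conv1d_forward(x, p["w1"], p["b1"])
        a1 = np.maximum(z1, 0.0)
        pool1, cache["p1"] = _maxpool_forward(a1, self.config.pool_widths[0])
        z2 = _conv1d_forward(pool1, p["w2"], p["b2"])
        a2 = np.maximum(z2, 0.0)
        pool2, cache["p2"] = _maxpool_forward(a2, self.config.pool_widths[1])
        if training:
            mean = pool2.mean(axis=(0, 2))
            var = pool2.var(axis=(0, 2))
            self.bn_mean = self.bn_momentum * self.bn_mean + (1 - self.bn_momentum) * mean
            self.bn_var = self.bn_momentum * self.bn_var + (1 - self.bn_momentum) * var
        else:
            mean, var = self.bn_mean, self.bn_var
        xhat = (pool2 - mean[None, :, None]) / np.sqrt(var[None, :, None] + 1e-5)
        bn = p["gamma"][None, :, None] * xhat + p["beta"][None, :, None]
        flat = bn.reshape(bn.shape[0], -1)
        zh = flat @ p["wh"].T + p["bh"]
        ah = np.maximum(zh, 0.0)
        if training and self.config.dropout_rate > 0:
            keep = 1.0 - self.config.dropout_rate
            mask = (dropout_rng.random(ah.shape) < keep) / keep
            ah = ah * mask
            cache["drop"] = mask
        logits = (ah @ p["wo"].T + p["bo"]).ravel()
        cache.update(
            z1=z1, a1=a1, pool1=pool1, z2=z2, a2=a2, pool2=pool2,
            mean=mean, var=var, xhat=xhat, flat=flat, zh=zh, ah=ah,
        )
        return logits, cache

    # -- backward ------------------------------------------------------------

    def backward(self, cache, dlogits):
        p = self.params
        g = {}
        g["wo"] = dlogits[:, None].T @ cache["ah"]
        g["bo"] = np.array([dlogits.sum()])
        dah = dlogits[:, None] @ p["wo"]
        if "drop" in cache:
            dah = dah * cache["drop"]
        dzh = dah * (cache["zh"] > 0)
        g["wh"] = dzh.T @ cache["flat"]
        g["bh"] = dzh.sum(axis=0)
        dflat = dzh @ p["wh"]
        dbn = dflat.reshape(cache["pool2"].shape)
        g["gamma"] = (dbn * cache["xhat"]).sum(axis=(0, 2))
        g["beta"] = dbn.sum(axis=(0, 2))
        # batch-norm backward over (B, L) per channel
        n = dbn.shape[0] * dbn.shape[2]
        dxhat = dbn * p["gamma"][None, :, None]
        inv = 1.0 / np.sqrt(cache["var"][None, :, None] + 1e-5)
        dpool2 = inv / n * (
            n * dxhat
            - dxhat.sum(axis=(0, 2), keepdims=True)
            - cache["xhat"] * (dxhat * cache["xhat"]).sum(axis=(0, 2), keepdims=True)
        )
        da2 = _maxpool_backward(dpool2, cache["p2"], self.config.pool_widths[1])
        dz2 = da2 * (cache["z2"] > 0)
        dpool1, g["w2"], g["b2"] = _conv1d_backward(cache["pool1"], p["w2"], dz2)
        da1 = _maxpool_backward(dpool1, cache["p1"], self.config.pool_widths[0])
        dz1 = da1 * (cache["z1"] > 0)
        _, g["w1"], g["b1"] = _conv1d_backward(cache["x"], p["w1"], dz1)
        return g


def _feature_positions(config: CNNConfig, n_features: int) -> pd.DataFrame:
    n_pos, stride, receptive = config.feature_geometry(n_features)
    start = np.arange(n_pos) * stride
    width = np.minimum(receptive, n_features - start)
    return pd.DataFrame({"position": np.arange(n_pos), "gene_start": start,
                         "window_width": width})


def train_cnn(
    x: pd.DataFrame | np.ndarray,
    y,
    config: CNNConfig,
    seed: int | None = None,
) -> tuple[CNNModel, dict]:
    """Train on a stratified 70/30 split; return the model and held-out metrics.

    ``x`` is features-by-samples (column-aligned with ``y``); labels must be
    binary.  Metrics: held-out accuracy and AUC of the predicted
    probabilities.
    """
    seed = config.seed if seed is None else seed
    is_frame = isinstance(x, pd.DataFrame)
    ids = list(x.columns) if is_frame else list(range(np.asarray(x).shape[1]))
    mat = x.to_numpy(dtype=float) if is_frame else np.asarray(x, float)
    y = np.asarray(y)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if mat.shape[1] != len(y):
        raise ValueError("x columns and labels are not aligned")

    train_ids, test_ids = split_samples(ids, y, config.train_fraction, seed)
    pos = {s: i for i, s in enumerate(ids)}
    tr = np.array([pos[s] for s in train_ids])
    te = np.array([pos[s] for s in test_ids])

    # per-gene centering with one global scale: removes uninformative
    # baselines but preserves relative amplitude along the profile, which is
    # where a planted biomarker's signal lives
    mu = mat[:, tr].mean(axis=1, keepdims=True)
    sd = np.full_like(mu, max(float(mat[:, tr].std(axis=1).mean()), 1e-12))
    norm = (mat - mu) / sd
    x_tr = norm[:, tr].T[:, None, :]   # (B, 1, L)
    x_te = norm[:, te].T[:, None, :]
    y_tr, y_te = y[tr].astype(float), y[te].astype(float)

    rng = np.random.default_rng(seed)
    model = CNNModel(config, mat.shape[0], rng)
    model.norm_mu, model.norm_sd = mu, sd

    adam_m = {k: np.zeros_like(v) for k, v in model.params.items()}
    adam_v = {k: np.zeros_like(v) for k, v in model.params.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    step = 0
    for epoch in range(config.epochs):
        order = rng.permutation(len(y_tr))
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            if len(idx) < 2:
                continue  # batch-norm needs more than one sample
            logits, cache = model.forward(x_tr[idx], training=True, dropout_rng=rng)
            prob = 1.0 / (1.0 + np.exp(-logits))
            loss = np.mean(
                np.logaddexp(0.0, logits) - y_tr[idx] * logits
            )
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite loss at epoch {epoch}")
            grads = model.backward(cache, (prob - y_tr[idx]) / len(idx))
            step += 1
            for k in model.params:
                gk = grads[k]
                if k in ("w1", "w2", "wh", "wo"):
                    gk = gk + config.weight_decay * model.params[k]
                adam_m[k] = b1 * adam_m[k] + (1 - b1) * gk
                adam_v[k] = b2 * adam_v[k] + (1 - b2) * gk**2
                mhat = adam_m[k] / (1 - b1**step)
                vhat = adam_v[k] / (1 - b2**step)
                model.params[k] -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)

    logits_te, _ = model.forward(x_te, training=False)
    prob_te = 1.0 / (1.0 + np.exp(-logits_te))
    acc = float(np.mean((prob_te > 0.5) == (y_te > 0.5)))
    auc = float(roc_auc_score(y_te, prob_te)) if len(np.unique(y_te)) == 2 else 0.5
    metrics = {"accuracy": acc, "auc": auc, "n_train": len(tr), "n_test": len(te),
               "seed": seed}
    return model, metrics


def extract_pool_output(model: CNNModel, x: pd.DataFrame | np.ndarray) -> PoolOutput:
    """Final max-pooling activations for all samples, in inference mode.

    Batch normalization uses the trained running statistics, so single
    samples and all-zero inputs stay finite and reproducible.
    """
    is_frame = isinstance(x, pd.DataFrame)
    ids = list(x.columns) if is_frame else [str(i) for i in range(np.asarray(x).shape[1])]
    mat = x.to_numpy(dtype=float) if is_frame else np.asarray(x, float)
    if mat.shape[0] != model.n_features:
        raise ValueError(
            f"model expects {model.n_features} features, got {mat.shape[0]}"
        )
    norm = (mat - model.norm_mu) / model.norm_sd
    _, cache = model.forward(norm.T[:, None, :], training=False)
    a = np.transpose(cache["pool2"], (0, 2, 1))  # (m, n', p)
    return PoolOutput(a, _feature_positions(model.config, model.n_features), ids)


def repeat_and_select(
    x, y, config: CNNConfig
) -> tuple[CNNModel, dict, FeatureWeightMatrix]:
    """Repeat training with seeds ``seed .. seed+repeats-1``; keep the best run.

    Best = highest held-out AUC, ties broken by accuracy, then by the lowest
    seed.  Returns the winning model, its metrics, and the feature-weight
    matrix extracted from all samples.
    """
    best: tuple | None = None
    failures: list[str] = []
    for i in range(config.repeats):
        try:
            model, metrics = train_cnn(x, y, config, seed=config.seed + i)
        except DivergenceError as exc:
            failures.append(str(exc))
            continue
        key = (metrics["auc"], metrics["accuracy"], -metrics["seed"])
        if best is None or key > best[0]:
            best = (key, model, metrics)
    if best is None:
        raise DivergenceError(
            f"all {config.repeats} training repeats diverged: {failures[:3]}"
        )
    _, model, metrics = best
    weights = channel_average(extract_pool_output(model, x))
    return model, metrics, weights
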