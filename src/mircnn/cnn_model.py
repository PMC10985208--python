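"""Convolutional network for precursor classification.

Architecture (fixed by the tuned hyperparameters): two feature-extraction
blocks — 2x2 convolution (20 then 60 filters, stride 1, no padding) with
ReLU followed by non-overlapping 2x2 max pooling — then a 500-unit
fully connected layer with identity activation and a 2-unit softmax
output.  Training minimizes the negative log likelihood with AdaDelta
(rho 0.95, eps 1e-6), Xavier-uniform initialization, and dropout with
retain probability 0.9 after each hidden layer (training time only;
"dropout coefficient 0.9" is read as the retain probability, the
convention of common deep-learning frameworks — the opposite reading
would drop 90% of activations and cripple training).

With the 7 x 200 input matrix the shape chain is
1x7x200 -> 20x6x199 -> 20x3x99 -> 60x2x98 -> 60x1x49 -> 2940 -> 500 -> 2.

Everything is plain numpy: convolution is an im2col matrix product, and
all gradients are derived analytically.  All randomness (fold split,
oversampling, initialization, batch order, dropout masks) flows from one
user-supplied seed.  Class scores are probabilities; the positive class
is called at p(miRNA) >= 0.5 (ties go to miRNA).

Evaluation protocol: stratified five-fold cross-validation.  The minority
class is oversampled with replacement to exact 1:1 parity inside each
training split only — held-out folds are never resampled — and per-fold
metrics are averaged unweighted.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.model_selection import StratifiedKFold

from .encoding import EncodedMatrix, stack_batch
from .evaluation import MetricsReport, confusion, mean_report, metrics


@dataclass
class CNNConfig:
    """Architecture and training hyperparameters (tuned values as defaults)."""

    conv1_filters: int = 20
    conv2_filters: int = 60
    kernel: Tuple[int, int] = (2, 2)
    pool: Tuple[int, int] = (2, 2)
    fc_units: int = 500
    n_classes: int = 2
    dropout_retain: float = 0.9
    epochs: int = 15
    batch_size: int = 32
    adadelta_rho: float = 0.95
    adadelta_eps: float = 1e-6
    L: int = 200

    def __post_init__(self) -> None:
        if not 0.0 < self.dropout_retain <= 1.0:
            raise ValueError(f"dropout_retain must be in (0, 1], got {self.dropout_retain}")


def conv_forward(
    x: np.ndarray,
    kernels: np.ndarray,
    bias: Optional[np.ndarray] = None,
    activation: str = "relu",
) -> np.ndarray:
    """Valid (no padding), stride-1 convolution followed by ReLU.

    ``x`` is (C, H, W) or (N, C, H, W); ``kernels`` is (F, C, kh, kw).
    Output spatial size is input size minus kernel size plus one per axis.
    """
    single = x.ndim == 3
    if single:
        x = x[None]
    F, C, kh, kw = kernels.shape
    N, Cx, H, W = x.shape
    if Cx != C:
        raise ValueError(f"channel mismatch: input {Cx}, kernels {C}")
    if kh > H or kw > W:
        raise ValueError(f"kernel {kh}x{kw} larger than input {H}x{W}")
    cols, (Ho, Wo) = _im2col(x, kh, kw)
    out = cols @ kernels.reshape(F, -1).T
    if bias is not None:
        out += bias
    out = out.reshape(N, Ho, Wo, F).transpose(0, 3, 1, 2)
    if activation == "relu":
        out = np.maximum(out, 0.0)
    elif activation != "identity":
        raise ValueError(f"unknown activation {activation!r}")
    return out[0] if single else out


def maxpool_forward(x: np.ndarray, window: Tuple[int, int] = (2, 2)) -> np.ndarray:
    """Max over non-overlapping windows (stride = window size); trailing
    rows/columns that do not fill a window are dropped."""
    single = x.ndim == 3
    if single:
        x = x[None]
    out, _ = _maxpool_with_argmax(x, window)
    return out[0] if single else out


def _im2col(x: np.ndarray, kh: int, kw: int) -> Tuple[np.ndarray, Tuple[int, int]]:
    N, C, H, W = x.shape
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))  # (N,C,Ho,Wo,kh,kw)
    Ho, Wo = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N, Ho * Wo, C * kh * kw)
    return np.ascontiguousarray(cols), (Ho, Wo)

def _maxpool_with_argmax(x, window):
    ph, pw = window
    N, C, H, W = x.shape
    Ho, Wo = H // ph, W // pw
    xr = (
        x[:, :, : Ho * ph, : Wo * pw]
        .reshape(N, C, Ho, ph, Wo, pw)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(N, C, Ho, Wo, ph * pw)
    )
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return out, idx


def _xavier(rng: np.random.Generator, shape, fan_in, fan_out, dtype=np.float32):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class TrainedModel:
    """Weights + config; supports forward, backward, and AdaDelta updates."""

    def __init__(self, config: CNNConfig, input_shape: Tuple[int, int, int], seed: int = 0):
        self.config = config
        self.input_shape = input_shape
        self.seed = seed
        self.training_log: List[float] = []
        self.shapes = layer_shapes(config, input_shape)
        flat = self.shapes["flatten"]

        rng = np.random.default_rng(seed)
        kh, kw = config.kernel
        C = input_shape[0]
        f1, f2 = config.conv1_filters, config.conv2_filters
        self.params: Dict[str, np.ndarray] = {
            "W1": _xavier(rng, (f1, C, kh, kw), C * kh * kw, f1 * kh * kw),
            "b1": np.zeros(f1, dtype=np.float32),
            "W2": _xavier(rng, (f2, f1, kh, kw), f1 * kh * kw, f2 * kh * kw),
            "b2": np.zeros(f2, dtype=np.float32),
            "Wf1": _xavier(rng, (flat, config.fc_units), flat, config.fc_units),
            "bf1": np.zeros(config.fc_units, dtype=np.float32),
            "Wf2": _xavier(rng, (config.fc_units, config.n_classes), config.fc_units, config.n_classes),
            "bf2": np.zeros(config.n_classes, dtype=np.float32),
        }
        self._opt_state = {
            k: (np.zeros_like(v), np.zeros_like(v)) for k, v in self.params.items()
        }

    # ---------------- forward ----------------

    def forward(
        self,
        X: np.ndarray,
        train: bool = False,
        rng: Optional[np.random.Generator] = None,
    ) -> Tuple[np.ndarray, dict]:
        """Class probabilities for a batch (N, C, H, W); caches intermediates
        for the backward pass when training."""
        if X.shape[1:] != self.input_shape:
            raise ValueError(f"input shape {X.shape[1:]} != expected {self.input_shape}")
        p = self.params
        cfg = self.config
        cache: dict = {}
        retain = cfg.dropout_retain

        def dropout(a, name):
            if not train or retain >= 1.0:
                return a
            mask = (rng.random(a.shape) < retain).astype(a.dtype) / retain
            cache[name] = mask
            return a * mask

        X = X.astype(np.float32, copy=False)
        cols1, hw1 = _im2col(X, *cfg.kernel)
        z1 = cols1 @ p["W1"].reshape(cfg.conv1_filters, -1).T + p["b1"]
        z1 = z1.reshape(X.shape[0], *hw1, cfg.conv1_filters).transpose(0, 3, 1, 2)
        a1 = np.maximum(z1, 0.0)
        p1, idx1 = _maxpool_with_argmax(a1, cfg.pool)
        d1 = dropout(p1, "m1")

        cols2, hw2 = _im2col(d1, *cfg.kernel)
        z2 = cols2 @ p["W2"].reshape(cfg.conv2_filters, -1).T + p["b2"]
        z2 = z2.reshape(X.shape[0], *hw2, cfg.conv2_filters).transpose(0, 3, 1, 2)
        a2 = np.maximum(z2, 0.0)
        p2, idx2 = _maxpool_with_argmax(a2, cfg.pool)
        d2 = dropout(p2, "m2")

        flat = d2.reshape(X.shape[0], -1)
        h = flat @ p["Wf1"] + p["bf1"]  # identity activation
        hd = dropout(h, "mf")
        logits = hd @ p["Wf2"] + p["bf2"]
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)

        cache.update(
            X=X, cols1=cols1, z1=z1, a1=a1, idx1=idx1, d1=d1,
            cols2=cols2, z2=z2, a2=a2, idx2=idx2, d2=d2,
            flat=flat, hd=hd, probs=probs, hw1=hw1, hw2=hw2,
        )
        return probs, cache

    # ---------------- backward ----------------

    def backward(self, cache: dict, y: np.ndarray) -> Dict[str, np.ndarray]:
        """Gradients of the mean negative log likelihood w.r.t. all params."""
        p = self.params
        cfg = self.config
        N = y.shape[0]
        probs = cache["probs"]

        dlogits = probs.copy()
        dlogits[np.arange(N), y] -= 1.0
        dlogits /= N

        grads: Dict[str, np.ndarray] = {}
        grads["Wf2"] = cache["hd"].T @ dlogits
        grads["bf2"] = dlogits.sum(0)
        dhd = dlogits @ p["Wf2"].T
        if "mf" in cache:
            dhd = dhd * cache["mf"]
        grads["Wf1"] = cache["flat"].T @ dhd
        grads["bf1"] = dhd.sum(0)
        dflat = dhd @ p["Wf1"].T
        dd2 = dflat.reshape(cache["d2"].shape)
        if "m2" in cache:
            dd2 = dd2 * cache["m2"]

        da2 = _maxpool_backward(dd2, cache["idx2"], cache["a2"].shape, cfg.pool)
        dz2 = da2 * (cache["z2"] > 0)
        gW2, gb2, dd1 = _conv_backward(
            dz2, cache["cols2"], p["W2"], cache["d1"].shape, cfg.kernel
        )
        grads["W2"], grads["b2"] = gW2, gb2
        if "m1" in cache:
            dd1 = dd1 * cache["m1"]

        da1 = _maxpool_backward(dd1, cache["idx1"], cache["a1"].shape, cfg.pool)
        dz1 = da1 * (cache["z1"] > 0)
        gW1, gb1, _ = _conv_backward(
            dz1, cache["cols1"], p["W1"], cache["X"].shape, cfg.kernel, need_dx=False
        )
        grads["W1"], grads["b1"] = gW1, gb1
        return grads

    def adadelta_step(self, grads: Dict[str, np.ndarray]) -> None:
        rho, eps = self.config.adadelta_rho, self.config.adadelta_eps
        for k, g in grads.items():
            Eg, Ed = self._opt_state[k]
            g = g.astype(np.float32, copy=False)
            Eg *= rho
            Eg += (1 - rho) * g * g
            dx = -np.sqrt((Ed + eps) / (Eg + eps)) * g
            Ed *= rho
            Ed += (1 - rho) * dx * dx
            self.params[k] += dx

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}


def _maxpool_backward(dout, idx, in_shape, window):
    ph, pw = window
    N, C, H, W = in_shape
    Ho, Wo = dout.shape[2], dout.shape[3]
    dxr = np.zeros((N, C, Ho, Wo, ph * pw), dtype=dout.dtype)
    np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
    dx = np.zeros(in_shape, dtype=dout.dtype)
    dx[:, :, : Ho * ph, : Wo * pw] = (
        dxr.reshape(N, C, Ho, Wo, ph, pw)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(N, C, Ho * ph, Wo * pw)
    )
    return dx


def _conv_backward(dz, cols, W, in_shape, kernel, need_dx=True):
    F = W.shape[0]
    kh, kw = kernel
    N, _, Ho, Wo = dz.shape
    dmat = dz.transpose(0, 2, 3, 1).reshape(N, Ho * Wo, F)
    gW = np.tensordot(cols, dmat, axes=([0, 1], [0, 1])).T.reshape(W.shape)
    gb = dmat.sum(axis=(0, 1))
    dx = None
    if need_dx:
        dcols = dmat @ W.reshape(F, -1)
        C = in_shape[1]
        dcols = dcols.reshape(N, Ho, Wo, C, kh, kw).transpose(0, 3, 1, 2, 4, 5)
        dx = np.zeros(in_shape, dtype=dz.dtype)
        for p_ in range(kh):
            for q in range(kw):
                dx[:, :, p_ : p_ + Ho, q : q + Wo] += dcols[:, :, :, :, p_, q]
    return gW, gb, dx


def layer_shapes(
    config: CNNConfig, input_shape: Tuple[int, int, int]
) -> Dict[str, Tuple[int, ...] | int]:
    """Shape of every feature map in the stack; raises with a per-layer
    trace when the chain degenerates."""
    C, H, W = input_shape
    kh, kw = config.kernel
    ph, pw = config.pool
    chain: Dict[str, Tuple[int, ...] | int] = {"input": (C, H, W)}
    H, W = H - kh + 1, W - kw + 1
    chain["conv1"] = (config.conv1_filters, H, W)
    H, W = H // ph, W // pw
    chain["pool1"] = (config.conv1_filters, H, W)
    H, W = H - kh + 1, W - kw + 1
    chain["conv2"] = (config.conv2_filters, H, W)
    H, W = H // ph, W // pw
    chain["pool2"] = (config.conv2_filters, H, W)
    for name, shape in chain.items():
        if any(s <= 0 for s in shape):
            raise ValueError(f"layer {name} has non-positive shape {shape}; chain: {chain}")
    chain["flatten"] = config.conv2_filters * H * W
    chain["fc1"] = config.fc_units
    chain["output"] = config.n_classes
    return chain


def build_model(
    config: Optional[CNNConfig] = None,
    input_shape: Optional[Tuple[int, int, int]] = None,
    seed: int = 0,
) -> TrainedModel:
    """Fresh Xavier-initialized model (untrained)."""
    config = config or CNNConfig()
    input_shape = input_shape or (1, 7, config.L)
    return TrainedModel(config, input_shape, seed=seed)


def oversample_indices(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices achieving exact 1:1 class balance by sampling the minority
    class with replacement; majority items are never duplicated."""
    y = np.asarray(y)
    idx0 = np.flatnonzero(y == 0)
    idx1 = np.flatnonzero(y == 1)
    if len(idx0) == 0 or len(idx1) == 0:
        raise ValueError("both classes must be present to oversample")
    minority, majority = (idx1, idx0) if len(idx1) < len(idx0) else (idx0, idx1)
    if len(minority) == len(majority):
        return np.arange(len(y))
    extra = rng.choice(minority, size=len(majority) - len(minority), replace=True)
    return np.concatenate([np.arange(len(y)), extra])


def fit_model(
    model: TrainedModel,
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
) -> TrainedModel:
    """Minibatch AdaDelta training; appends per-epoch mean loss to the log."""
    cfg = model.config
    n = X.shape[0]
    for _ in range(cfg.epochs):
        perm = rng.permutation(n)
        losses = []
        for lo in range(0, n, cfg.batch_size):
            sel = perm[lo : lo + cfg.batch_size]
            probs, cache = model.forward(X[sel], train=True, rng=rng)
            eps = np.finfo(np.float32).tiny
            losses.append(float(-np.mean(np.log(probs[np.arange(len(sel)), y[sel]] + eps))))
            grads = model.backward(cache, y[sel])
            model.adadelta_step(grads)
        model.training_log.append(float(np.mean(losses)))
    return model


def predict_proba(model: TrainedModel, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
    """p(miRNA) per sample, dropout inactive."""
    out = np.empty(X.shape[0], dtype=np.float32)
    for lo in range(0, X.shape[0], batch_size):
        probs, _ = model.forward(X[lo : lo + batch_size], train=False)
        out[lo : lo + batch_size] = probs[:, 1]
    return out


def predict(model: TrainedModel, matrix: EncodedMatrix | np.ndarray) -> Tuple[float, int]:
    """(p_miRNA, predicted class) for one encoded precursor.

    The positive class is called at p(miRNA) >= 0.5; an exact tie goes to
    miRNA.
    """
    values = matrix.values if isinstance(matrix, EncodedMatrix) else matrix
    X = values[None, None] if values.ndim == 2 else values
    if X.ndim == 3:
        X = X[None]
    p = float(predict_proba(model, X)[0])
    return p, int(p >= 0.5)


@dataclass
class CVResult:
    """Per-fold models and metrics from stratified cross-validation, plus
    the bookkeeping needed to audit the resampling protocol."""

    fold_models: List[TrainedModel]
    fold_reports: List[MetricsReport]
    mean: MetricsReport
    fold_test_indices: List[np.ndarray]
    fold_train_indices: List[np.ndarray]  # after oversampling
    fold_train_class_counts: List[Tuple[int, int]]
    probabilities: np.ndarray = field(repr=False, default=None)


def train(
    dataset: Sequence[EncodedMatrix],
    config: Optional[CNNConfig] = None,
    folds: int = 5,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold cross-validated training.

    Each training split is oversampled to 1:1 balance (held-out folds
    untouched), a fresh model is trained per fold, and per-fold metrics on
    the held-out fold are averaged unweighted.  Identical seeds reproduce
    the fold assignment, initial weights and final metrics exactly.
    """
    config = config or CNNConfig()
    X, y, _ = stack_batch(list(dataset))
    if np.any(y < 0):
        raise ValueError("all samples must be labeled for training")
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both classes")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X = X.astype(np.float32)

    ss = np.random.SeedSequence(seed)
    split_seed = int(ss.generate_state(1)[0] % (2**31))
    fold_seeds = ss.spawn(folds)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=split_seed)

    fold_models, fold_reports = [], []
    test_idx_list, train_idx_list, class_counts = [], [], []
    probabilities = np.full(len(y), np.nan, dtype=np.float32)
    for f, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        child = fold_seeds[f]
        rng = np.random.default_rng(child)
        bal = tr[oversample_indices(y[tr], rng)]
        model = build_model(config, X.shape[1:], seed=int(child.generate_state(1)[0] % (2**31)))
        fit_model(model, X[bal], y[bal], rng)

        p = predict_proba(model, X[te])
        preds = (p >= 0.5).astype(int)
        report = metrics(*confusion(y[te].tolist(), preds.tolist()))
        probabilities[te] = p

        fold_models.append(model)
        fold_reports.append(report)
        test_idx_list.append(te)
        train_idx_list.append(bal)
        class_counts.append((int((y[bal] == 0).sum()), int((y[bal] == 1).sum())))

    return CVResult(
        fold_models=fold_models,
        fold_reports=fold_reports,
        mean=mean_report(fold_reports),
        fold_test_indices=test_idx_list,
        fold_train_indices=train_idx_list,
        fold_train_class_counts=class_counts,
        probabilities=probabilities,
    )


def save_checkpoint(model: TrainedModel, path: str | Path) -> None:
    cfg = asdict(model.config)
    np.savez(
        path,
        __config__=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8),
        __seed__=np.array([model.seed]),
        __input_shape__=np.array(model.input_shape),
        **model.params,
    )


def load_checkpoint(path: str | Path) -> TrainedModel:
    data = np.load(path)
    cfg_dict = json.loads(bytes(data["__config__"]).decode())
    cfg_dict["kernel"] = tuple(cfg_dict["kernel"])
    cfg_dict["pool"] = tuple(cfg_dict["pool"])
    config = CNNConfig(**cfg_dict)
    model = TrainedModel(config, tuple(data["__input_shape__"]), seed=int(data["__seed__"][0]))
    for k in model.params:
        model.params[k] = data[k]
    return model
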