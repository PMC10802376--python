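"""Voxel classification: separating true MS2 spots from background artifacts.

A small 3D convolutional network classifies 9x11x11 px voxels into 'spot'
vs 'not spot'. Architecture: two 3D convolution layers (4 kernels of
3x3x3, ReLU, 'same' padding), each followed by 2x2x2 max pooling, then a
dense layer of 512 ReLU units with dropout 0.5 during training, and a
single sigmoid output. Training minimises class-weighted binary
cross-entropy with Adam (learning rate 1e-4, batch size 8) over 100
epochs in 5-fold cross-validation, with the training data augmented by
random 90-degree in-plane rotations and axis flips. Class weights equal
half the inverse class fraction, offsetting the ~1:4.5 spot/non-spot
imbalance of a typical hand-labeled set.

The network is implemented directly on NumPy (forward, backward and the
Adam update); the architecture is small enough that this trains in
minutes on one CPU. A logistic-regression fallback on simple spot
features is provided for fast pipeline runs.

Voxel intensities are min-max scaled to [0, 1] per voxel, making the
classifier robust to the absolute intensity scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from ._geom import VOXEL_SHAPE
from .detection import extract_voxel


@dataclass
class VoxelDataset:
    """Labeled voxel windows for classifier training."""

    voxels: np.ndarray  # (n, 9, 11, 11)
    labels: np.ndarray  # (n,) in {0, 1}; 1 = spot

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.voxels.ndim != 4 or self.voxels.shape[1:] != tuple(VOXEL_SHAPE):
            raise ValueError(f"voxels must be (n, {VOXEL_SHAPE})")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary")

    @property
    def class_counts(self):
        n1 = int(self.labels.sum())
        return len(self.labels) - n1, n1


@dataclass
class ClassifierConfig:
    """Training hyper-parameters of the voxel CNN."""

    n_kernels: int = 4
    kernel_size: int = 3
    dense_units: int = 512
    dropout: float = 0.5
    lr: float = 1e-4
    batch_size: int = 8
    epochs: int = 100
    folds: int = 5
    accept_threshold: float = 0.7
    augment: bool = True

    def __post_init__(self):
        if not 0.0 < self.accept_threshold < 1.0:
            raise ValueError("accept_threshold must be in (0, 1)")


def class_weights(labels) -> dict:
    """Half the inverse class fraction per class."""
    labels = np.asarray(labels)
    n = len(labels)
    out = {}
    for c in (0, 1):
        frac = np.mean(labels == c)
        if frac == 0:
            raise ValueError("both classes must be present")
        out[c] = 0.5 / frac
    return out


def normalize_voxels(voxels: np.ndarray) -> np.ndarray:
    """Per-voxel min-max scaling to [0, 1]."""
    v = np.asarray(voxels, dtype=float)
    flat = v.reshape(len(v), -1)
    lo = flat.min(axis=1)[:, None, None, None]
    hi = flat.max(axis=1)[:, None, None, None]
    span = np.where(hi > lo, hi - lo, 1.0)
    return (v - lo) / span


def augment_batch(voxels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random 90-degree in-plane rotations and axis flips.

    Arbitrary-angle 3D rotations would need interpolation on anisotropic
    voxels; the in-plane rotation group preserves pixel values exactly.
    """
    out = voxels.copy()
    for i in range(len(out)):
        k = rng.integers(0, 4)
        if k:
            out[i] = np.rot90(out[i], k=int(k), axes=(1, 2))
        if rng.random() < 0.5:
            out[i] = out[i][::-1]          # z flip
        if rng.random() < 0.5:
            out[i] = out[i][:, ::-1]       # y flip
    return out


# ---------------------------------------------------------------------------
# NumPy 3D convolutional network


def _glorot(rng, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class _Conv3D:
    """3x3x3 'same' convolution via im2col."""

    def __init__(self, rng, c_in, c_out, k=3):
        fan_in, fan_out = c_in * k**3, c_out * k**3
        self.W = _glorot(rng, (k**3 * c_in, c_out), fan_in, fan_out)
        self.b = np.zeros(c_out)
        self.k = k
        self.c_in = c_in

    def _patches(self, x):
        # x: (n, D, H, W, C) zero-padded by k//2
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))
        # win: (n, D, H, W, C, k, k, k) -> (n, D*H*W, k^3*C)
        n, D, H, W = x.shape[:4]
        win = win.transpose(0, 1, 2, 3, 5, 6, 7, 4).reshape(n, D * H * W, -1)
        return win, xp.shape

    def forward(self, x):
        self.x_shape = x.shape
        self.patches, self.pad_shape = self._patches(x)
        n, D, H, W, _ = x.shape
        out = self.patches @ self.W + self.b
        return out.reshape(n, D, H, W, -1)

    def backward(self, dout, need_dx=True):
        n, D, H, W, c_out = dout.shape
        dflat = dout.reshape(n, -1, c_out)
        k2 = self.patches.shape[-1]
        self.dW = self.patches.reshape(-1, k2).T @ dflat.reshape(-1, c_out)
        self.db = dflat.sum(axis=(0, 1))
        if not need_dx:
            return None
        dpatch = dflat @ self.W.T  # (n, DHW, k^3*C)
        # scatter-add back into the padded volume
        k, p = self.k, self.k // 2
        dxp = np.zeros((n,) + self.pad_shape[1:])
        dpatch = dpatch.reshape(n, D, H, W, k, k, k, self.c_in)
        for dz in range(k):
            for dy in range(k):
                for dx in range(k):
                    dxp[:, dz:dz + D, dy:dy + H, dx:dx + W, :] += \
                        dpatch[:, :, :, :, dz, dy, dx, :]
        return dxp[:, p:p + D, p:p + H, p:p + W, :]


class _MaxPool3D:
    """2x2x2 max pooling, stride 2, trailing odd planes dropped."""

    def forward(self, x):
        n, D, H, W, C = x.shape
        d, h, w = D // 2, H // 2, W // 2
        self.in_shape = x.shape
        xt = x[:, :d * 2, :h * 2, :w * 2, :]
        win = xt.reshape(n, d, 2, h, 2, w, 2, C).transpose(0, 1, 3, 5, 2, 4, 6, 7)
        win = win.reshape(n, d, h, w, 8, C)
        self.arg = win.argmax(axis=4)
        return np.take_along_axis(win, self.arg[:, :, :, :, None, :], axis=4)[
            :, :, :, :, 0, :]

    def backward(self, dout):
        n, d, h, w, C = dout.shape
        dwin = np.zeros((n, d, h, w, 8, C))
        np.put_along_axis(dwin, self.arg[:, :, :, :, None, :],
                          dout[:, :, :, :, None, :], axis=4)
        dwin = dwin.reshape(n, d, h, w, 2, 2, 2, C).transpose(0, 1, 4, 2, 5, 3, 6, 7)
        dx = np.zeros(self.in_shape)
        dx[:, :d * 2, :h * 2, :w * 2, :] = dwin.reshape(n, d * 2, h * 2, w * 2, C)
        return dx


class SpotCNN:
    """The small 3D CNN voxel classifier (NumPy implementation)."""

    def __init__(self, seed=0, n_kernels=4, dense_units=512, dropout=0.5,
                 input_shape=VOXEL_SHAPE):
        rng = np.random.default_rng(seed)
        self.conv1 = _Conv3D(rng, 1, n_kernels)
        self.pool1 = _MaxPool3D()
        self.conv2 = _Conv3D(rng, n_kernels, n_kernels)
        self.pool2 = _MaxPool3D()
        D, H, W = input_shape
        flat = (D // 2 // 2) * (H // 2 // 2) * (W // 2 // 2) * n_kernels
        self.W1 = _glorot(rng, (flat, dense_units), flat, dense_units)
        self.b1 = np.zeros(dense_units)
        self.W2 = _glorot(rng, (dense_units, 1), dense_units, 1)
        self.b2 = np.zeros(1)
        self.dropout = dropout
        self._params = None

    def forward(self, x, train=False, rng=None):
        # x: (n, D, H, W) normalized
        a = x[..., None]
        a = self.conv1.forward(a)
        self.m1 = a > 0
        a = a * self.m1
        a = self.pool1.forward(a)
        a = self.conv2.forward(a)
        self.m2 = a > 0
        a = a * self.m2
        a = self.pool2.forward(a)
        self.flat_shape = a.shape
        f = a.reshape(len(x), -1)
        self.f = f
        h = f @ self.W1 + self.b1
        self.mh = h > 0
        h = h * self.mh
        if train and self.dropout > 0:
            keep = (rng.random(h.shape) >= self.dropout) / (1 - self.dropout)
            h = h * keep
            self.keep = keep
        else:
            self.keep = None
        self.h = h
        z = (h @ self.W2 + self.b2).ravel()
        return z  # logits

    def predict_proba(self, x):
        """Deterministic inference probabilities (dropout disabled).

        Accepts raw voxels; per-voxel min-max normalization is applied
        (idempotent on already-normalized input).
        """
        z = self.forward(normalize_voxels(np.asarray(x, dtype=float)), train=False)
        return 1.0 / (1.0 + np.exp(-z))

    def backward(self, dz):
        # dz: dLoss/dlogits, shape (n,)
        dz = dz[:, None]
        self.dW2 = self.h.T @ dz
        self.db2 = dz.sum(axis=0)
        dh = dz @ self.W2.T
        if self.keep is not None:
            dh = dh * self.keep
        dh = dh * self.mh
        self.dW1 = self.f.T @ dh
        self.db1 = dh.sum(axis=0)
        df = dh @ self.W1.T
        da = df.reshape(self.flat_shape)
        da = self.pool2.backward(da)
        da = da * self.m2
        da = self.conv2.backward(da)
        da = self.pool1.backward(da)
        da = da * self.m1
        self.conv1.backward(da, need_dx=False)

    def parameters(self):
        return [(self.conv1, "W"), (self.conv1, "b"),
                (self.conv2, "W"), (self.conv2, "b"),
                (self, "W1"), (self, "b1"), (self, "W2"), (self, "b2")]

    def gradients(self):
        return [self.conv1.dW, self.conv1.db, self.conv2.dW, self.conv2.db,
                self.dW1, self.db1, self.dW2, self.db2]

    def get_weights(self):
        return {name: np.array(getattr(obj, attr))
                for (obj, attr), name in zip(self.parameters(),
                                             ["c1W", "c1b", "c2W", "c2b",
                                              "W1", "b1", "W2", "b2"])}

    def set_weights(self, weights):
        for (obj, attr), name in zip(self.parameters(),
                                     ["c1W", "c1b", "c2W", "c2b",
                                      "W1", "b1", "W2", "b2"]):
            setattr(obj, attr, np.array(weights[name]))

    def save(self, path):
        np.savez(path, **self.get_weights())

    @classmethod
    def load(cls, path, **kwargs):
        model = cls(**kwargs)
        with np.load(path) as data:
            model.set_weights({k: data[k] for k in data.files})
        return model


class _Adam:
    def __init__(self, model: SpotCNN, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-7):
        self.model = model
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(getattr(o, a)) for o, a in model.parameters()]
        self.v = [np.zeros_like(getattr(o, a)) for o, a in model.parameters()]

    def step(self):
        self.t += 1
        grads = self.model.gradients()
        for i, ((obj, attr), g) in enumerate(zip(self.model.parameters(), grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            setattr(obj, attr,
                    getattr(obj, attr) - self.lr * mhat / (np.sqrt(vhat) + self.eps))


def _train_one(x_train, y_train, config: ClassifierConfig, seed):
    rng = np.random.default_rng(seed)
    model = SpotCNN(seed=seed, n_kernels=config.n_kernels,
                    dense_units=config.dense_units, dropout=config.dropout)
    opt = _Adam(model, lr=config.lr)
    weights = class_weights(y_train)
    w = np.where(y_train == 1, weights[1], weights[0])
    n = len(x_train)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb = x_train[idx]
            if config.augment:
                xb = augment_batch(xb, rng)
            yb, wb = y_train[idx], w[idx]
            z = model.forward(xb, train=True, rng=rng)
            p = 1.0 / (1.0 + np.exp(-z))
            if not np.all(np.isfinite(p)):
                raise FloatingPointError("NaN encountered in training "
                                         f"(batch logits: {z})")
            model.backward(wb * (p - yb) / len(yb))
            opt.step()
    return model


def _weighted_bce(y, p, weights):
    w = np.where(y == 1, weights[1], weights[0])
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(np.mean(w * -(y * np.log(p) + (1 - y) * np.log(1 - p))))


def build_and_train_classifier(dataset: VoxelDataset,
                               config: ClassifierConfig | None = None,
                               seed: int = 0):
    """Train the voxel CNN with k-fold cross-validation.

    Returns ``(model, cv_metrics)``: the model retrained on all data and a
    list of per-fold dicts with validation loss and AUC. Fold assignment is
    deterministic under the seed.
    """
    config = config or ClassifierConfig()
    n0, n1 = dataset.class_counts
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present in the dataset")
    x = normalize_voxels(dataset.voxels)
    y = dataset.labels.astype(float)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(x))
    folds = np.array_split(order, config.folds)
    metrics = []
    weights = class_weights(y)
    for i, val_idx in enumerate(folds):
        train_idx = np.setdiff1d(order, val_idx)
        model = _train_one(x[train_idx], y[train_idx], config,
                           seed=int(rng.integers(0, 2**31 - 1)))
        p = model.predict_proba(x[val_idx])
        metrics.append({
            "fold": i,
            "val_loss": _weighted_bce(y[val_idx], p, weights),
            "val_auc": float(roc_auc_score(y[val_idx], p)),
        })
    final = _train_one(x, y, config, seed=int(rng.integers(0, 2**31 - 1)))
    return final, metrics


# ---------------------------------------------------------------------------
# Logistic fallback classifier (not part of the reference method)


class LogisticSpotClassifier:
    """Fast fallback: logistic regression on simple spot features.

    Features per voxel: DoG peak response, fitted Gaussian widths, and
    signal:background. Useful for quick pipeline runs where training the
    CNN is unnecessary; it is not the reference classification method.
    """

    def __init__(self):
        # 'balanced' equals the half-inverse-class-fraction weighting used
        # for the CNN, up to an overall factor
        self.model = LogisticRegression(max_iter=1000, class_weight="balanced")

    @staticmethod
    def features(voxels) -> np.ndarray:
        from .quantification import dog_prefilter, quantify_voxel
        rows = []
        for v in voxels:
            m = quantify_voxel(v)
            dog_peak = float(dog_prefilter(v).max())
            sig = m.sigma_fit if m.sigma_fit is not None else (0, 0, 0)
            rows.append([dog_peak / max(m.background, 1.0), *sig,
                         m.signal_to_background])
        return np.nan_to_num(np.asarray(rows), nan=0.0, posinf=1e6,
                             neginf=-1e6)

    def fit(self, dataset: VoxelDataset):
        self.model.fit(self.features(dataset.voxels), dataset.labels)
        return self

    def predict_proba(self, voxels) -> np.ndarray:
        return self.model.predict_proba(self.features(voxels))[:, 1]


def classify_candidates(model, volume: np.ndarray, candidates,
                        accept_threshold: float = 0.7):
    """Annotate candidates with spot probability and filter.

    ``model`` is anything with ``predict_proba(voxels)``. Candidates whose
    voxel window cannot be extracted are dropped. Returns the annotated
    DataFrame with a ``probability`` column, filtered to
    ``probability >= accept_threshold``.
    """
    df = candidates.copy()
    voxels, keep = [], []
    for i, row in df.iterrows():
        try:
            voxels.append(extract_voxel(volume, (row.z, row.y, row.x)))
            keep.append(i)
        except IndexError:
            continue
    df = df.loc[keep]
    if not len(df):
        df["probability"] = []
        return df
    df = df.assign(probability=model.predict_proba(np.stack(voxels)))
    return df[df["probability"] >= accept_threshold]
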