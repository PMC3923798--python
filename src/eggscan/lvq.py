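"""Learning vector quantization (LVQ2.1) classifier, written from scratch.

An LVQ network holds a competitive layer of m codebook vectors, each
assigned to an output class; prediction is nearest-codebook (Euclidean).
The competitive-layer size follows the sizing rule

    m = round(sqrt(n + l) + a)

with n input neurons, l output neurons and an integer offset a in [1, 10]
(default a = 8, which gives m = 10 for a single scalar feature and two
classes).

LVQ2.1 training ("learnlv2") updates codebooks in pairs: for a training
sample x, let c_i and c_j be the nearest and second-nearest codebooks.  If
they carry different classes, exactly one of them matches x's label, and x
falls inside the relative window

    min(d_i, d_j) / max(d_i, d_j) > (1 - w) / (1 + w)

then the correct codebook moves toward x and the wrong one away, both by
the current learning rate.  The learning rate decays linearly to zero over
the epoch budget; training stops early once the training misclassification
fraction reaches the error goal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LVQArchitecture", "LVQModel", "TrainConfig",
           "size_competitive_layer", "init_codebooks", "train_lvq21", "predict"]


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def size_competitive_layer(n: int, l: int, a: int = 8) -> int:
    """Competitive-layer neuron count m = round(sqrt(n + l) + a), half up."""
    if n < 1:
        raise ValueError("need at least one input neuron")
    if l < 2:
        raise ValueError("need at least two output neurons")
    if not 1 <= int(a) <= 10:
        raise ValueError("offset a must be an integer in [1, 10]")
    return _round_half_up(np.sqrt(n + l) + int(a))


@dataclass(frozen=True)
class LVQArchitecture:
    n: int  # input-layer neurons (feature dimension)
    m: int  # competitive-layer neurons (codebooks)
    l: int  # output-layer neurons (classes)
    a: int = 8

    def __post_init__(self):
        if self.m < self.l:
            raise ValueError("competitive layer must hold >= one codebook per class")


@dataclass
class TrainConfig:
    learning_rate: float = 0.1
    error_goal: float = 0.01
    max_epochs: int = 100
    window: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.learning_rate < 1:
            raise ValueError("learning_rate must lie in [0, 1)")
        if not 0 <= self.error_goal < 1:
            raise ValueError("error_goal must lie in [0, 1)")
        if not 0 < self.window < 1:
            raise ValueError("window must lie in (0, 1)")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


@dataclass
class LVQModel:
    codebooks: np.ndarray         # (m, n)
    codebook_classes: np.ndarray  # (m,) labels
    architecture: LVQArchitecture
    trained: bool = False
    training_error: float = float("nan")
    # min-max scaling bounds, recorded at training time for n > 1
    scale_min: np.ndarray | None = field(default=None, repr=False)
    scale_max: np.ndarray | None = field(default=None, repr=False)

    def _transform(self, X: np.ndarray) -> np.ndarray:
        if self.scale_min is None:
            return X
        span = np.where(self.scale_max > self.scale_min,
                        self.scale_max - self.scale_min, 1.0)
        return (X - self.scale_min) / span


def _as_matrix(features: np.ndarray) -> np.ndarray:
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ValueError("features must be a vector or a (samples, n) matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")
    return X


def _allocate(counts: np.ndarray, m: int) -> np.ndarray:
    """Codebooks per class, proportional to class frequency, each >= 1."""
    k = counts.size
    if m < k:
        raise ValueError(f"m = {m} cannot cover {k} classes")
    quota = counts / counts.sum() * m
    alloc = np.maximum(1, np.floor(quota).astype(int))
    # repair the total: add by largest remainder, trim from the largest alloc
    while alloc.sum() < m:
        remainder = quota - alloc
        alloc[int(np.argmax(remainder))] += 1
    while alloc.sum() > m:
        candidates = np.where(alloc > 1)[0]
        over = candidates[int(np.argmax(alloc[candidates] - quota[candidates]))]
        alloc[over] -= 1
    return alloc


def init_codebooks(features: np.ndarray, labels: np.ndarray, m: int,
                   seed: int = 0, jitter_scale: float = 0.01) -> LVQModel:
    """Class-proportional codebook allocation, initialised at class means.

    Each class receives at least one codebook; within a class every
    codebook starts at the class mean plus seeded Gaussian jitter of
    ``jitter_scale`` times the per-dimension feature spread (so distinct
    codebooks can specialise during training).
    """
    X = _as_matrix(features)
    y = np.asarray(labels)
    if y.shape[0] != X.shape[0]:
        raise ValueError("features and labels disagree in length")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    if np.any(counts == 0):
        raise ValueError("every class needs at least one sample")
    alloc = _allocate(counts.astype(float), m)

    n = X.shape[1]
    spread = X.std(axis=0)
    spread[spread == 0] = 1.0
    rng = np.random.default_rng(seed)
    codebooks = np.empty((m, n), dtype=float)
    codebook_classes = np.empty(m, dtype=classes.dtype)
    pos = 0
    for cls, count in zip(classes, alloc):
        mean = X[y == cls].mean(axis=0)
        for _ in range(count):
            jitter = (rng.normal(0.0, jitter_scale, size=n) * spread
                      if jitter_scale else 0.0)
            codebooks[pos] = mean + jitter
            codebook_classes[pos] = cls
            pos += 1
    arch = LVQArchitecture(n=n, m=m, l=int(classes.size))
    return LVQModel(codebooks=codebooks, codebook_classes=codebook_classes,
                    architecture=arch)


def predict(model: LVQModel, features: np.ndarray) -> np.ndarray:
    """Class of the nearest codebook; ties break to the lowest codebook index.

    Accepts a single feature vector (returns a scalar label) or a
    (samples, n) matrix (returns an array of labels).
    """
    arr = np.asarray(features, dtype=float)
    n = model.architecture.n
    # for a scalar input (n = 1) a 1-D array is a batch of samples;
    # for n > 1 a 1-D array of length n is a single feature vector
    if n == 1:
        single = arr.ndim == 0
        if arr.ndim == 2 and arr.shape[1] != 1:
            raise ValueError(
                f"feature dimension {arr.shape[1]} does not match n = 1"
            )
        X = _as_matrix(arr.reshape(-1))
    else:
        single = arr.ndim == 1
        X = _as_matrix(arr.reshape(1, -1) if single else arr)
    if X.shape[1] != model.architecture.n:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match n = {model.architecture.n}"
        )
    X = model._transform(X)
    d2 = ((X[:, None, :] - model.codebooks[None, :, :]) ** 2).sum(axis=2)
    nearest = np.argmin(d2, axis=1)  # argmin takes the first (lowest index) on ties
    out = model.codebook_classes[nearest]
    return out[0] if single else out


def train_lvq21(model: LVQModel, features: np.ndarray, labels: np.ndarray,
                config: TrainConfig) -> LVQModel:
    """LVQ2.1 training with linearly decaying learning rate.

    Codebook class assignments never change; only positions move.  Returns
    the same model object, flagged trained, with the final training
    misclassification fraction recorded.
    """
    X = _as_matrix(features)
    y = np.asarray(labels)
    if y.shape[0] != X.shape[0]:
        raise ValueError("features and labels disagree in length")
    if X.shape[1] != model.architecture.n:
        raise ValueError("feature dimension does not match the architecture")

    if model.architecture.n > 1 and model.scale_min is None:
        model.scale_min = X.min(axis=0)
        model.scale_max = X.max(axis=0)
        model.codebooks = model._transform(model.codebooks)
    Xs = model._transform(X)

    rng = np.random.default_rng(config.seed)
    window_ratio = (1 - config.window) / (1 + config.window)
    cb = model.codebooks
    cls = model.codebook_classes

    def training_error() -> float:
        d2 = ((Xs[:, None, :] - cb[None, :, :]) ** 2).sum(axis=2)
        return float(np.mean(cls[np.argmin(d2, axis=1)] != y))

    err = training_error()
    for epoch in range(config.max_epochs):
        if err <= config.error_goal:
            break
        alpha = config.learning_rate * (1 - epoch / config.max_epochs)
        if alpha <= 0:
            break
        for idx in rng.permutation(X.shape[0]):
            x = Xs[idx]
            d = np.sqrt(((cb - x) ** 2).sum(axis=1))
            i = int(np.argmin(d))
            d_masked = d.copy()
            d_masked[i] = np.inf
            j = int(np.argmin(d_masked))
            if cls[i] == cls[j]:
                continue
            ci_correct = cls[i] == y[idx]
            cj_correct = cls[j] == y[idx]
            if ci_correct == cj_correct:  # neither matches (multi-class)
                continue
            dmax = max(d[i], d[j])
            if dmax == 0 or min(d[i], d[j]) / dmax <= window_ratio:
                continue
            good, bad = (i, j) if ci_correct else (j, i)
            cb[good] += alpha * (x - cb[good])
            cb[bad] -= alpha * (x - cb[bad])
        err = training_error()

    model.trained = True
    model.training_error = err
    return model
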