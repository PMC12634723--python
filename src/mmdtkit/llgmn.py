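"""Log-linearized Gaussian mixture network (LLGMN) for hold/release decoding.

The LLGMN realises a Gaussian-mixture Bayes posterior as a log-linear model:
the input x (here the 8-channel EMG share vector) is expanded to
(1, x, {x_i x_j}_{i<=j}) so that the log of any Gaussian component density —
a quadratic form in x — is exactly a linear function of the expanded vector.
One weight vector per (class, component) feeds a global softmax; a class
posterior is the sum of its components' softmax mass. One (class, component)
weight vector is pinned at zero for identifiability. Training maximises the
conditional log-likelihood by full-batch gradient ascent.

On top of the classifier this module provides the stream segmenter that
turns a session EMG recording into per-sample hold / release / rest labels
(rest gated by the muscle contraction level) and the hold-time accumulator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .emg import (
    CalibrationProfile,
    EmgRecording,
    mcl_series,
    preprocess_recording,
)

__all__ = [
    "LlgmnModel",
    "MotionLabelSeries",
    "expand_input",
    "expanded_dim",
    "forward",
    "train",
    "classify_motion",
    "total_hold_time",
    "gaussian_bayes_weights",
]

HOLD, RELEASE, REST = "hold", "release", "rest"
DEFAULT_MCL_GATE = 0.05


def expanded_dim(d: int) -> int:
    return 1 + d + d * (d + 1) // 2


def expand_input(x: np.ndarray) -> np.ndarray:
    """Quadratic feature expansion (1, x_1..x_D, x_i*x_j for i <= j)."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input")
    iu = np.triu_indices(x.size)
    quad = np.outer(x, x)[iu]
    return np.concatenate(([1.0], x, quad))


def _expand_batch(X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    iu = np.triu_indices(X.shape[1])
    quad = np.einsum("ni,nj->nij", X, X)[:, iu[0], iu[1]]
    return np.hstack([np.ones((X.shape[0], 1)), X, quad])


@dataclass
class LlgmnModel:
    """Weights of the log-linearized Gaussian mixture classifier.

    ``weights`` has shape (n_classes, n_components, expanded_dim); the last
    (class, component) slice is the zero reference.
    """

    n_classes: int
    n_components: int
    input_dim: int
    weights: np.ndarray
    classes: tuple[str, ...] = (HOLD, RELEASE)
    # optional input standardization learned at training time and applied
    # before feature expansion; None means identity
    input_mean: np.ndarray | None = None
    input_scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        want = (self.n_classes, self.n_components, expanded_dim(self.input_dim))
        if self.weights.shape != want:
            raise ValueError(f"weights shape {self.weights.shape} != {want}")
        if len(self.classes) != self.n_classes:
            raise ValueError("classes tuple must match n_classes")
        for arr in (self.input_mean, self.input_scale):
            if arr is not None and np.asarray(arr).shape != (self.input_dim,):
                raise ValueError("input transform must match input_dim")

    def _transform(self, X: np.ndarray) -> np.ndarray:
        if self.input_mean is None:
            return X
        return (X - self.input_mean) / self.input_scale

    @classmethod
    def zeros(cls, n_classes: int = 2, n_components: int = 1, input_dim: int = 8,
              classes: tuple[str, ...] = (HOLD, RELEASE)) -> "LlgmnModel":
        return cls(n_classes, n_components, input_dim,
                   np.zeros((n_classes, n_components, expanded_dim(input_dim))),
                   classes)

    def to_json(self, path) -> None:
        doc = {
            "n_classes": self.n_classes,
            "n_components": self.n_components,
            "input_dim": self.input_dim,
            "classes": list(self.classes),
            "weights": self.weights.ravel().tolist(),
            "input_mean": (None if self.input_mean is None
                           else np.asarray(self.input_mean).tolist()),
            "input_scale": (None if self.input_scale is None
                            else np.asarray(self.input_scale).tolist()),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path) -> "LlgmnModel":
        with open(path) as fh:
            doc = json.load(fh)
        w = np.array(doc["weights"], dtype=float).reshape(
            doc["n_classes"], doc["n_components"], expanded_dim(doc["input_dim"]))
        mean = doc.get("input_mean")
        scale = doc.get("input_scale")
        return cls(doc["n_classes"], doc["n_components"], doc["input_dim"], w,
                   tuple(doc["classes"]),
                   None if mean is None else np.array(mean, dtype=float),
                   None if scale is None else np.array(scale, dtype=float))


def _posterior_batch(model: LlgmnModel, X: np.ndarray) -> np.ndarray:
    """(n, n_classes) posterior matrix from raw (untransformed) inputs."""
    Xexp = _expand_batch(model._transform(np.atleast_2d(X)))
    scores = np.einsum("ckh,nh->nck", model.weights, Xexp)
    flat = scores.reshape(len(Xexp), -1)
    flat = flat - flat.max(axis=1, keepdims=True)
    q = np.exp(flat)
    q /= q.sum(axis=1, keepdims=True)
    return q.reshape(scores.shape).sum(axis=2)


def forward(model: LlgmnModel, x: np.ndarray) -> np.ndarray:
    """Class posterior for one input vector; sums to one."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.input_dim,):
        raise ValueError(f"expected input of dim {model.input_dim}, got {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input")
    return _posterior_batch(model, x[None, :])[0]


def train(
    samples: list[tuple[np.ndarray, str]],
    lr: float = 0.05,
    epochs: int = 500,
    seed: int = 0,
    n_components: int = 1,
    classes: tuple[str, ...] | None = None,
    init_scale: float = 0.01,
    tol: float = 1e-8,
    standardize: bool = True,
) -> LlgmnModel:
    """Fit LLGMN weights by full-batch gradient ascent on the log-likelihood.

    Deterministic for a fixed seed (seeded small-random init). Training stops
    early once the epoch log-likelihood change falls below ``tol``. With
    ``classes=None`` the class set is inferred from the sample labels
    (hold/release kept in canonical order); explicitly declared classes must
    each have at least one sample. ``standardize`` (default) z-scores the
    inputs on training statistics — the transform is stored in the model and
    applied automatically at inference; it conditions the quadratic feature
    expansion and markedly improves generalisation from few samples.
    """
    if not samples:
        raise ValueError("no training samples")
    X = np.array([np.asarray(x, dtype=float) for x, _ in samples])
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite features in training data")
    labels = [lab for _, lab in samples]
    if classes is None:
        seen = set(labels)
        canonical = [c for c in (HOLD, RELEASE) if c in seen]
        classes = tuple(canonical + sorted(seen - {HOLD, RELEASE}))
    class_index = {c: i for i, c in enumerate(classes)}
    unknown = set(labels) - set(classes)
    if unknown:
        raise ValueError(f"labels {unknown} not in classes {classes}")
    y = np.array([class_index[lab] for lab in labels])
    present = np.bincount(y, minlength=len(classes))
    if np.any(present == 0):
        missing = [c for c, n in zip(classes, present) if n == 0]
        raise ValueError(f"classes with zero samples: {missing}")

    d = X.shape[1]
    M, K = len(classes), n_components
    H = expanded_dim(d)
    rng = np.random.default_rng(seed)
    W = rng.normal(0.0, init_scale, size=(M, K, H))
    W[-1, -1, :] = 0.0  # reference weight set, pinned

    in_mean = in_scale = None
    if standardize:
        in_mean = X.mean(axis=0)
        sd = X.std(axis=0)
        in_scale = np.where(sd > 0, sd, 1.0)
        X = (X - in_mean) / in_scale

    Xexp = _expand_batch(X)
    onehot = np.zeros((len(y), M))
    onehot[np.arange(len(y)), y] = 1.0

    prev_ll = -np.inf
    for _ in range(epochs):
        scores = np.einsum("ckh,nh->nck", W, Xexp)
        flat = scores.reshape(len(Xexp), -1)
        flat = flat - flat.max(axis=1, keepdims=True)
        q = np.exp(flat)
        q /= q.sum(axis=1, keepdims=True)
        q = q.reshape(scores.shape)               # (n, M, K) softmax mass
        p_class = q.sum(axis=2)                   # (n, M)
        p_true = p_class[np.arange(len(y)), y]
        ll = float(np.log(np.clip(p_true, 1e-300, None)).sum())
        # d ll / d score_{n,c,k} = 1{c=y_n} q_nck / p_true_n  -  q_nck
        coef = q * (onehot / np.clip(p_class, 1e-300, None))[:, :, None] - q
        grad = np.einsum("nck,nh->ckh", coef, Xexp)
        W = W + lr * grad
        W[-1, -1, :] = 0.0
        if abs(ll - prev_ll) < tol and np.isfinite(prev_ll):
            prev_ll = ll
            break
        prev_ll = ll

    return LlgmnModel(M, K, d, W, classes, in_mean, in_scale)


def gaussian_bayes_weights(
    means: list[np.ndarray],
    covs: list[np.ndarray],
    priors: list[float] | None = None,
    classes: tuple[str, ...] = (HOLD, RELEASE),
) -> LlgmnModel:
    """Construct exact LLGMN weights for a known single-component Gaussian model.

    Because log N(x; mu, S) is quadratic in x, each class's log joint density
    maps exactly onto one expanded-feature weight vector; the network's
    softmax then reproduces the Bayes posterior. Used as an analytic bridge
    to the brute-force density oracle in tests.
    """
    M = len(means)
    d = len(means[0])
    if priors is None:
        priors = [1.0 / M] * M
    W = np.zeros((M, 1, expanded_dim(d)))
    iu = np.triu_indices(d)
    for c, (mu, S, pi) in enumerate(zip(means, covs, priors)):
        mu = np.asarray(mu, dtype=float)
        S = np.asarray(S, dtype=float)
        P = np.linalg.inv(S)
        A = -0.5 * P                      # x^T A x contributes the quadratic part
        quad = np.where(iu[0] == iu[1], A[iu], 2.0 * A[iu])
        lin = P @ mu
        const = (np.log(pi) - 0.5 * mu @ P @ mu
                 - 0.5 * np.linalg.slogdet(S)[1] - 0.5 * d * np.log(2 * np.pi))
        W[c, 0, 0] = const
        W[c, 0, 1:1 + d] = lin
        W[c, 0, 1 + d:] = quad
    W = W - W[-1, -1]  # pin the reference slice at zero; softmax is shift-invariant
    return LlgmnModel(M, 1, d, W, classes)


@dataclass
class MotionLabelSeries:
    """Per-sample motion labels (hold / release / rest) on a fixed time step."""

    labels: list[str]
    dt: float
    t0: float = 0.0

    def __len__(self) -> int:
        return len(self.labels)

    def to_csv(self, path) -> None:
        import pandas as pd
        t = self.t0 + np.arange(len(self.labels)) * self.dt
        pd.DataFrame({"t": t, "label": self.labels}).to_csv(path, index=False)


def _median_smooth_labels(labels: np.ndarray, width: int) -> np.ndarray:
    """Majority (median over a 3-level code) filter to suppress flicker."""
    code = np.select([labels == REST, labels == RELEASE, labels == HOLD], [0, 1, 2])
    sm = ndimage.median_filter(code, size=width, mode="nearest")
    return np.array([REST, RELEASE, HOLD], dtype=object)[sm]


def classify_motion(
    recording: EmgRecording,
    cal: CalibrationProfile,
    model: LlgmnModel,
    mcl_gate: float = DEFAULT_MCL_GATE,
    smooth_width: int = 5,
) -> MotionLabelSeries:
    """Label every sample of a session recording as hold, release or rest.

    Samples whose MCL falls below ``mcl_gate`` are rest; the rest go through
    the classifier on the normalized channel-share vector. Posterior ties
    break toward release so ambiguity never accrues hold time. A width-5
    median filter removes single-sample flicker (``smooth_width=0`` disables).
    """
    env = preprocess_recording(recording)
    mcl = mcl_series(env, cal)
    active = mcl >= mcl_gate
    labels = np.full(recording.n_samples, REST, dtype=object)
    if np.any(active):
        centered = env[active] - cal.rest
        denom = centered.sum(axis=1)
        ok = denom != 0
        shares = np.zeros_like(centered)
        shares[ok] = centered[ok] / denom[ok, None]
        post = _posterior_batch(model, shares)
        hold_idx = model.classes.index(HOLD)
        is_hold = post[:, hold_idx] > 0.5  # tie at 0.5 -> release
        sub = np.where(is_hold & ok, HOLD, RELEASE)
        labels[np.flatnonzero(active)] = sub
    if smooth_width and smooth_width > 1:
        labels = _median_smooth_labels(labels, smooth_width)
    return MotionLabelSeries(list(labels), dt=1.0 / recording.fs, t0=recording.t0)


def total_hold_time(series: MotionLabelSeries) -> float:
    """Cumulative seconds labelled hold: (count of hold steps) x dt."""
    return sum(1 for lab in series.labels if lab == HOLD) * series.dt
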