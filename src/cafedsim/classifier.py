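"""Classification models operated through flat parameter vectors.

The main model is a text-CNN for user-level binary depression detection:
embedding -> 1-D convolutions (ReLU) at several filter lengths ->
max-over-time pooling per feature map -> concatenation -> dropout ->
fully connected single sigmoid output.  Training minimizes mean binary
cross-entropy plus an l2 penalty on the non-embedding weight matrices
(the embedding participates in the penalty only when it is trainable).

All models expose the same small surface — ``init_params``, ``loss``,
``grad``, ``predict_proba`` — over :class:`~cafedsim.param_model.ParamVector`
so the federated trainers never see architecture internals.  Gradients are
analytic (verified against finite differences in the test-suite).

:class:`LogisticModel` is a convex stand-in with the same surface, used
where trajectories must be checked analytically; :class:`QuadraticModel`
is a strongly convex toy objective for convergence experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Protocol, runtime_checkable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .param_model import ParamVector
from .text_pipeline import (
    EMBEDDING_MODES,
    PAD_ID,
    EmbeddingTable,
    SequenceEncoder,
    make_embedding_layer,
)

__all__ = [
    "SupervisedModel",
    "TextCNNConfig",
    "TextCNN",
    "build_textcnn",
    "LogisticModel",
    "QuadraticModel",
    "predict_labels",
    "accuracy",
    "sgd_run",
]


@runtime_checkable
class SupervisedModel(Protocol):
    def init_params(self, rng: np.random.Generator) -> ParamVector: ...

    def loss(self, pv: ParamVector, X, y) -> float: ...

    def grad(self, pv: ParamVector, X, y, rng: Optional[np.random.Generator] = None) -> ParamVector: ...

    def predict_proba(self, pv: ParamVector, X) -> Optional[np.ndarray]: ...


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softplus(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0) + np.log1p(np.exp(-np.abs(z)))


def _bce(z: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross-entropy from logits (numerically stable)."""
    return float(np.mean(_softplus(z) - y * z))


def _check_binary(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=np.float64).ravel()
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("labels must be binary 0/1")
    return y


def predict_labels(proba: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Label 1 iff p >= threshold (ties go to the positive class)."""
    return (np.asarray(proba) >= threshold).astype(int)


def accuracy(model: SupervisedModel, pv: ParamVector, X, y, threshold: float = 0.5) -> float:
    proba = model.predict_proba(pv, X)
    y = np.asarray(y).ravel()
    return float(np.mean(predict_labels(proba, threshold) == y))


# ---------------------------------------------------------------------------
# Text-CNN
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TextCNNConfig:
    d: int = 32
    filter_sizes: tuple[int, ...] = (3, 4, 5)
    n_filters: int = 128
    dropout_rate: float = 0.5
    l2_coeff: float = 1e-4
    L: int = 400
    mode: str = "nostatic"

    def __post_init__(self) -> None:
        if not self.filter_sizes:
            raise ValueError("filter_sizes must be non-empty")
        if any(fs > self.L for fs in self.filter_sizes):
            raise ValueError("every filter size must be <= sequence length L")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.n_filters <= 0:
            raise ValueError("n_filters must be positive")
        if self.mode not in EMBEDDING_MODES:
            raise ValueError(f"mode must be one of {EMBEDDING_MODES}")


class TextCNN:
    """Sentence-classification CNN with max-over-time pooling.

    Parameter ordering (defining the global entry index k) is fixed by
    registration order: the embedding matrix first when trainable, then
    per filter size the convolution kernel and bias, then the output
    weight vector and bias.  In ``static`` mode the embedding is a frozen
    buffer and is *not* part of the parameter vector, so federated
    arithmetic can never perturb it.
    """

    def __init__(self, cfg: TextCNNConfig, embedding: np.ndarray, emb_trainable: bool, seed: int):
        self.cfg = cfg
        if embedding.shape[1] != cfg.d:
            raise ValueError("embedding width does not match cfg.d")
        self.frozen_embedding = None if emb_trainable else np.asarray(embedding, dtype=np.float64)
        self._template = self._build_template(embedding if emb_trainable else None, seed)

    def _build_template(self, embedding: Optional[np.ndarray], seed: int) -> ParamVector:
        cfg = self.cfg
        rng = np.random.default_rng(seed)
        named: list[tuple[str, np.ndarray]] = []
        if embedding is not None:
            named.append(("embedding", np.asarray(embedding, dtype=np.float64)))
        for fs in cfg.filter_sizes:
            fan_in, fan_out = fs * cfg.d, cfg.n_filters
            scale = np.sqrt(6.0 / (fan_in + fan_out))
            named.append((f"conv{fs}_W", rng.uniform(-scale, scale, size=(cfg.n_filters, fs, cfg.d))))
            named.append((f"conv{fs}_b", np.zeros(cfg.n_filters)))
        n_pooled = cfg.n_filters * len(cfg.filter_sizes)
        scale = np.sqrt(6.0 / (n_pooled + 1))
        named.append(("fc_W", rng.uniform(-scale, scale, size=n_pooled)))
        named.append(("fc_b", np.zeros(1)))
        return ParamVector.from_named(named)

    # -- model surface ----------------------------------------------------
    def init_params(self, rng: Optional[np.random.Generator] = None) -> ParamVector:
        """Initial parameters; a pure function of the construction seed."""
        return self._template.copy()

    def _forward(self, params: dict[str, np.ndarray], X: np.ndarray, dropout_mask=None):
        cfg = self.cfg
        X = np.asarray(X, dtype=np.int64)
        emb = params.get("embedding", self.frozen_embedding)
        E = emb[X]  # (B, L, d)
        pooled, cache = [], []
        for fs in cfg.filter_sizes:
            # windows: (B, P, d, fs) with P = L - fs + 1
            windows = sliding_window_view(E, fs, axis=1)
            pre = np.einsum("bpdf,nfd->bpn", windows, params[f"conv{fs}_W"]) + params[f"conv{fs}_b"]
            act = np.maximum(pre, 0.0)
            arg = act.argmax(axis=1)  # (B, n_filters)
            pooled.append(np.take_along_axis(act, arg[:, None, :], axis=1)[:, 0, :])
            cache.append((windows, pre, arg))
        h = np.concatenate(pooled, axis=1)  # (B, n_filters * |fs|)
        if dropout_mask is not None:
            h = h * dropout_mask
        z = h @ params["fc_W"] + params["fc_b"][0]
        return z, h, E, cache

    def predict_proba(self, pv: ParamVector, X) -> np.ndarray:
        """Evaluation-mode probabilities (dropout off); deterministic."""
        z, *_ = self._forward(pv.unflatten(), X)
        return _sigmoid(z)

    def _l2_terms(self, params: dict[str, np.ndarray]) -> list[str]:
        names = [f"conv{fs}_W" for fs in self.cfg.filter_sizes] + ["fc_W"]
        if "embedding" in params:
            names.append("embedding")
        return names

    def loss(self, pv: ParamVector, X, y) -> float:
        y = _check_binary(y)
        params = pv.unflatten()
        z, *_ = self._forward(params, X)
        reg = sum(float(np.sum(params[n] ** 2)) for n in self._l2_terms(params))
        return _bce(z, y) + self.cfg.l2_coeff * reg

    def grad(self, pv: ParamVector, X, y, rng: Optional[np.random.Generator] = None) -> ParamVector:
        """Analytic gradient; with ``rng`` given, a fresh inverted-dropout
        mask is drawn (training mode), otherwise dropout is off."""
        cfg = self.cfg
        y = _check_binary(y)
        params = pv.unflatten()
        B = len(y)
        n_pooled = cfg.n_filters * len(cfg.filter_sizes)
        mask = None
        if rng is not None and cfg.dropout_rate > 0:
            keep = 1.0 - cfg.dropout_rate
            mask = (rng.random((B, n_pooled)) < keep) / keep
        z, h, E, cache = self._forward(params, X, dropout_mask=mask)
        dz = (_sigmoid(z) - y) / B  # (B,)

        grads = {name: np.zeros_like(arr) for name, arr in params.items()}
        grads["fc_W"] = h.T @ dz
        grads["fc_b"] = np.array([dz.sum()])
        dh = np.outer(dz, params["fc_W"])
        if mask is not None:
            dh = dh * mask

        dE = np.zeros_like(E)
        X = np.asarray(X, dtype=np.int64)
        for i, fs in enumerate(cfg.filter_sizes):
            windows, pre, arg = cache[i]
            W = params[f"conv{fs}_W"]
            dpool = dh[:, i * cfg.n_filters : (i + 1) * cfg.n_filters]  # (B, nf)
            # route through max-over-time, then ReLU
            dpre = np.zeros_like(pre)  # (B, P, nf)
            np.put_along_axis(dpre, arg[:, None, :], dpool[:, None, :], axis=1)
            dpre *= pre > 0
            grads[f"conv{fs}_W"] = np.einsum("bpn,bpdf->nfd", dpre, windows)
            grads[f"conv{fs}_b"] = dpre.sum(axis=(0, 1))
            dwin = np.einsum("bpn,nfd->bpfd", dpre, W)  # (B, P, fs, d)
            P = pre.shape[1]
            for j in range(fs):
                dE[:, j : j + P, :] += dwin[:, :, j, :]
        if "embedding" in grads:
            np.add.at(grads["embedding"], X, dE)
            grads["embedding"][PAD_ID] = 0.0  # padding row stays zero

        for name in self._l2_terms(params):
            grads[name] = grads[name] + 2.0 * cfg.l2_coeff * params[name]
        return ParamVector.from_named((name, grads[name]) for name, _ in pv.keys)


def build_textcnn(
    cfg: TextCNNConfig,
    table: EmbeddingTable,
    seed: int,
    encoder: Optional[SequenceEncoder] = None,
) -> TextCNN:
    """Construct a text-CNN whose initialization is a pure function of ``seed``."""
    rng = np.random.default_rng(seed)
    embedding, trainable = make_embedding_layer(table, cfg.mode, rng, encoder)
    return TextCNN(cfg, embedding, trainable, seed=int(rng.integers(2**31)))


# ---------------------------------------------------------------------------
# Convex stand-ins
# ---------------------------------------------------------------------------


@dataclass
class LogisticModel:
    """l2-regularized binary logistic regression on dense features."""

    dim: int
    l2: float = 0.0
    init_scale: float = 0.0

    def init_params(self, rng: Optional[np.random.Generator] = None) -> ParamVector:
        if self.init_scale > 0 and rng is not None:
            w = rng.normal(0.0, self.init_scale, self.dim)
        else:
            w = np.zeros(self.dim)
        return ParamVector.from_named([("w", w), ("b", np.zeros(1))])

    def _split(self, pv: ParamVector):
        return pv.values[: self.dim], pv.values[self.dim]

    def predict_proba(self, pv: ParamVector, X) -> np.ndarray:
        w, b = self._split(pv)
        return _sigmoid(np.asarray(X, dtype=np.float64) @ w + b)

    def loss(self, pv: ParamVector, X, y) -> float:
        y = _check_binary(y)
        w, b = self._split(pv)
        z = np.asarray(X, dtype=np.float64) @ w + b
        return _bce(z, y) + self.l2 * float(w @ w)

    def grad(self, pv: ParamVector, X, y, rng=None) -> ParamVector:
        y = _check_binary(y)
        X = np.asarray(X, dtype=np.float64)
        w, b = self._split(pv)
        dz = (_sigmoid(X @ w + b) - y) / len(y)
        return ParamVector.from_named([("w", X.T @ dz + 2.0 * self.l2 * w), ("b", np.array([dz.sum()]))])


@dataclass
class QuadraticModel:
    """Strongly convex toy objective F(w) = mean_i 0.5 ||w - x_i||^2.

    The global optimum is the mean of all data points; used for analytic
    convergence checks of the federated trainers.  Labels are ignored.
    """

    dim: int

    def init_params(self, rng: Optional[np.random.Generator] = None) -> ParamVector:
        return ParamVector.from_named([("w", np.zeros(self.dim))])

    def predict_proba(self, pv: ParamVector, X):
        return None

    def loss(self, pv: ParamVector, X, y=None) -> float:
        diff = pv.values[None, :] - np.asarray(X, dtype=np.float64)
        return float(0.5 * np.mean(np.sum(diff**2, axis=1)))

    def grad(self, pv: ParamVector, X, y=None, rng=None) -> ParamVector:
        X = np.asarray(X, dtype=np.float64)
        return ParamVector.from_named([("w", pv.values - X.mean(axis=0))])


# ---------------------------------------------------------------------------
# Local SGD
# ---------------------------------------------------------------------------


def sgd_run(
    model: SupervisedModel,
    pv: ParamVector,
    X,
    y,
    lr: float,
    batch_size: int,
    rng: np.random.Generator,
    n_steps: Optional[int] = None,
) -> ParamVector:
    """Minibatch SGD with a constant learning rate.

    One shuffled pass over the data by default; ``n_steps`` caps (or, by
    drawing fresh permutations, extends) the number of minibatch steps.
    ``rng`` drives both the shuffling and any training-time stochasticity
    of the model (dropout), so a worker's local round is replayable.
    """
    n = len(np.asarray(y)) if y is not None else len(X)
    steps_done = 0
    target = n_steps if n_steps is not None else int(np.ceil(n / batch_size))
    while steps_done < target:
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            Xb = np.asarray(X)[idx]
            yb = np.asarray(y)[idx] if y is not None else None
            g = model.grad(pv, Xb, yb, rng=rng)
            pv = pv.with_values(pv.values - lr * g.values)
            steps_done += 1
            if steps_done >= target:
                break
    return pv
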