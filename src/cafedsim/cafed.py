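"""Staleness-aware asynchronous update rule with push gating and noise.

The server never receives raw gradients.  A worker that pulled the global
model at epoch ``tau`` trains locally and uploads its new model; the server
reconstructs a pseudo-gradient from its stored snapshot,

    g = w_back_i - w_new_i ,

then damps every entry k by an adaptive weight derived from that entry's
staleness — the number of global updates that actually touched entry k
(|g_u^k| > theta) between the worker's pull and now:

    s_k = #{u in [tau, t-1] : |g_u^k| > theta},   clamped at M
    d_k = 1/s_k  if s_k != 0 else 1

and applies

    w_{t+1}^k = w_t^k - d_k * (g^k + beta * N(0, sigma^2)) .

The Gaussian term randomizes each accepted contribution so an observer of
the global sequence cannot recover an individual device's exact update;
``beta`` trades accuracy for privacy (``sigma`` defaults to 1).  Uploads
themselves are thinned by a Bernoulli push gate with success probability
``sigmoid(v)``, cutting communication.

Staleness bookkeeping uses the *clean* pseudo-gradients: the injected
noise is excluded from the |g^k| > theta test, otherwise every entry would
count as touched by every update and the per-entry weighting would
collapse to uniform 1/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .param_model import ParamVector, Timestamp, axpy

__all__ = [
    "CafedConfig",
    "ServerHistory",
    "pseudo_gradient",
    "staleness",
    "adaptive_weight",
    "should_push",
    "server_apply",
]


@dataclass(frozen=True)
class CafedConfig:
    """Hyper-parameters of the asynchronous trainer.

    v       push-gate logit; acceptance probability is sigmoid(v)
    beta    noise magnitude (>= 0); 0 disables randomization
    sigma   noise scale (standard deviation of the unit Gaussian; default 1)
    theta   zero-tolerance for "this update touched entry k"
    stale_cap   upper bound M on effective staleness
    lr      local SGD learning rate gamma
    """

    v: float = 2.0
    beta: float = 0.0
    sigma: float = 1.0
    theta: float = 0.0
    stale_cap: int = 100
    lr: float = 0.1

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if self.stale_cap < 1:
            raise ValueError("stale_cap must be >= 1")
        if self.lr <= 0:
            raise ValueError("lr must be > 0")


@dataclass
class ServerHistory:
    """Per-entry counts of significant global updates.

    ``counts[k]`` is c_k(t): how many of the t applied updates had
    |g_u^k| > theta.  Staleness between a pull snapshot and now is the
    difference of counts, so it is O(P) per push instead of O(P * t).
    ``g_log`` optionally keeps every applied clean pseudo-gradient so
    brute-force recounts can cross-check the incremental counts.
    """

    counts: np.ndarray
    theta: float = 0.0
    keep_g_log: bool = False
    g_log: list[np.ndarray] = field(default_factory=list)

    @classmethod
    def empty(cls, n_entries: int, theta: float = 0.0, keep_g_log: bool = False) -> "ServerHistory":
        return cls(np.zeros(n_entries, dtype=np.int64), theta, keep_g_log)

    def record(self, g: np.ndarray) -> None:
        self.counts += np.abs(g) > self.theta
        if self.keep_g_log:
            self.g_log.append(np.asarray(g, dtype=np.float64).copy())

    def snapshot(self) -> np.ndarray:
        return self.counts.copy()


def pseudo_gradient(w_back_i: ParamVector, w_new_i: ParamVector) -> ParamVector:
    """Server-side reconstruction of a worker's progress: w_back - w_new."""
    return w_back_i - w_new_i


def staleness(
    counts_now: np.ndarray,
    counts_at_pull: np.ndarray,
    stale_cap: int | None = None,
) -> np.ndarray:
    """Per-entry staleness c_k(t) - c_k(tau), optionally clamped at M."""
    s = np.asarray(counts_now, dtype=np.int64) - np.asarray(counts_at_pull, dtype=np.int64)
    if np.any(s < 0):
        raise ValueError("pull snapshot is newer than the server history (tau > t)")
    if stale_cap is not None:
        s = np.minimum(s, stale_cap)
    return s


def staleness_bruteforce(
    g_log: list[np.ndarray], k: int, tau: Timestamp, t: Timestamp, theta: float = 0.0
) -> int:
    """Direct recount over the stored update list — the testing oracle."""
    if tau > t:
        raise ValueError("tau must be <= t")
    return sum(1 for u in range(tau, t) if abs(g_log[u][k]) > theta)


def adaptive_weight(s: np.ndarray | int) -> np.ndarray:
    """Per-entry damping d_k = 1/s (1 when the entry is fresh, s = 0)."""
    s = np.asarray(s, dtype=np.float64)
    if np.any(s < 0):
        raise ValueError("staleness must be non-negative")
    return np.where(s == 0, 1.0, 1.0 / np.where(s == 0, 1.0, s))


def should_push(rng: np.random.Generator, v: float) -> bool:
    """Bernoulli push gate: transmit iff r < sigmoid(v), r ~ U[0, 1]."""
    r = rng.random()
    if v >= 0:
        p = 1.0 / (1.0 + np.exp(-v))
    else:
        ev = np.exp(v)
        p = ev / (1.0 + ev)
    return bool(r < p)


def server_apply(
    w: ParamVector,
    g: ParamVector,
    history: ServerHistory,
    counts_at_pull: np.ndarray,
    cfg: CafedConfig,
    noise_rng: np.random.Generator | None = None,
) -> tuple[ParamVector, np.ndarray, np.ndarray]:
    """Apply one accepted push to the global model.

    Returns the new global model, the clamped per-entry staleness, and
    the per-entry weights used.  Updates ``history`` in place with the
    clean pseudo-gradient (noise excluded) — the caller increments the
    epoch counter.
    """
    w.require_conformable(g)
    s = staleness(history.counts, counts_at_pull, cfg.stale_cap)
    weights = adaptive_weight(s)
    noisy = g.values
    if cfg.beta > 0:
        if noise_rng is None:
            raise ValueError("beta > 0 requires a noise rng")
        noisy = noisy + cfg.beta * noise_rng.normal(0.0, cfg.sigma, size=g.n_entries)
    new_w = axpy(w, g.with_values(noisy), weights)
    history.record(g.values)
    return new_w, s, weights
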