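"""Synchronous Federated Averaging baseline.

Each global round, a (seeded) random fraction of the devices trains
locally from the current global model and the server replaces it with the
shard-size-weighted average of the returned models,

    w_{t+1} = sum_i (|D_i| / sum_j |D_j|) * w_new_i      (over participants).

One round costs one upload and one download per participant; the run log
records both so communication-matched comparisons against the
asynchronous trainer can be drawn from the same CSV schema.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .classifier import SupervisedModel, sgd_run
from .fed_core import RunLog, _evaluate, worker_streams
from .param_model import ParamVector

__all__ = ["FedAvgConfig", "fedavg_round", "run_fedavg"]


@dataclass(frozen=True)
class FedAvgConfig:
    n_devices: int = 10
    fraction: float = 1.0
    local_epochs: int = 1
    batch_size: int = 16
    lr: float = 0.1
    T: int = 200

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError("fraction must be in (0, 1]")
        if int(np.ceil(self.fraction * self.n_devices)) < 1:
            raise ValueError("at least one participant per round required")


def fedavg_round(
    model: SupervisedModel,
    w: ParamVector,
    shards: list[tuple],
    cfg: FedAvgConfig,
    select_rng: np.random.Generator,
    batch_rngs: list[np.random.Generator],
    log: Optional[RunLog] = None,
    now: float = 0.0,
) -> ParamVector:
    """One synchronous round; returns the aggregated global model."""
    n = len(shards)
    m = int(np.ceil(cfg.fraction * n))
    participants = sorted(select_rng.choice(n, size=m, replace=False).tolist())
    if not participants:
        raise ValueError("empty participant set")
    sizes = np.array([len(shards[i][1]) for i in participants], dtype=np.float64)
    weights = sizes / sizes.sum()
    agg = np.zeros_like(w.values)
    for weight, i in zip(weights, participants):
        if log is not None:
            log.log(now, "pull", device=i, tau=None)
        w_new = w.copy()
        for _ in range(cfg.local_epochs):
            w_new = sgd_run(model, w_new, shards[i][0], shards[i][1],
                            cfg.lr, cfg.batch_size, batch_rngs[i])
        if log is not None:
            log.log(now, "push_attempt", device=i, accepted=True)
        agg += weight * w_new.values
    return w.with_values(agg)


def run_fedavg(
    model: SupervisedModel,
    shards: list[tuple],
    cfg: FedAvgConfig,
    master_seed: int,
    *,
    test_data: Optional[tuple] = None,
    eval_every: int = 10,
    init_params: Optional[ParamVector] = None,
) -> tuple[ParamVector, RunLog]:
    """Run ``cfg.T`` synchronous rounds; the log is a pure function of the seed."""
    n = len(shards)
    w = init_params if init_params is not None else model.init_params(np.random.default_rng(master_seed))
    w = w.copy()
    select_rng = np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(3,)))
    batch_rngs = [worker_streams(master_seed, i)[1] for i in range(n)]
    log = RunLog()
    uploads = downloads = 0
    for t in range(1, cfg.T + 1):
        w = fedavg_round(model, w, shards, cfg, select_rng, batch_rngs, log, now=float(t))
        m = int(np.ceil(cfg.fraction * n))
        uploads += m
        downloads += m
        log.log(float(t), "global_update", epoch=t - 1, device=None)
        if t % eval_every == 0 or t == cfg.T:
            acc, loss = _evaluate(model, w, test_data)
            log.log(float(t), "eval", epoch=t, test_accuracy=acc, test_loss=loss)
            log.metrics.append({"epoch": t, "sim_time": float(t),
                                "test_accuracy": acc, "test_loss": loss,
                                "cum_uploads": uploads, "cum_downloads": downloads,
                                "cum_drops": 0})
    return w, log
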