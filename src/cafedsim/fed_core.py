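"""Discrete-event simulation of one server and n asynchronous workers.

Workers pull the global model, train locally for a random (seeded)
duration, and attempt a push when done; the server applies at most one
accepted push per simulation instant and advances its epoch counter with
every applied update.  Virtual time lives in an event queue ordered by
(arrival time, device id), so simultaneous arrivals resolve
deterministically and the whole run log is a pure function of
(configuration, master seed).

Timing model: worker i's local round lasts ``speed_i * LogNormal(mu,
sigma)`` where ``speed_i`` is itself a per-worker log-normal draw —
heterogeneous devices, fast and slow, without any real clock.

After a gated-out (dropped) push the worker discards its local delta,
re-pulls the current global model and starts a fresh round, which keeps
staleness bounded.  Because a dropped delta is never observed, the
simulator evaluates the push gate before spending compute on the local
round; the event stream is identical to train-then-drop.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .cafed import CafedConfig, ServerHistory, pseudo_gradient, server_apply, should_push
from .classifier import SupervisedModel, accuracy, sgd_run
from .param_model import ParamVector, Timestamp

__all__ = [
    "RunLog",
    "ServerState",
    "WorkerState",
    "StallError",
    "server_noise_rng",
    "worker_streams",
    "pull",
    "run_cafed",
    "run_centralized",
]


class StallError(RuntimeError):
    """Raised when the push gate rejects every attempt for too long."""


# ---------------------------------------------------------------------------
# Seed-stream plumbing: every RNG in a run derives from one master seed
# through fixed spawn keys, so streams are independent and replayable.
# ---------------------------------------------------------------------------


def server_noise_rng(master_seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(0,)))


def worker_streams(master_seed: int, i: int):
    """(delay, batch/dropout, push-gate) generators for worker ``i``."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(1, i))
    delay_ss, batch_ss, gate_ss = ss.spawn(3)
    return (
        np.random.default_rng(delay_ss),
        np.random.default_rng(batch_ss),
        np.random.default_rng(gate_ss),
    )


@dataclass
class RunLog:
    """Time-ordered event stream plus per-epoch metric rows."""

    events: list[dict] = field(default_factory=list)
    metrics: list[dict] = field(default_factory=list)

    def log(self, sim_time: float, kind: str, **payload) -> None:
        self.events.append({"sim_time": float(sim_time), "kind": kind, "payload": payload})

    def to_jsonl(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for event in self.events:
                fh.write(json.dumps(event, sort_keys=True) + "\n")

    def metrics_csv(self, path) -> None:
        import csv

        fields = ["epoch", "sim_time", "test_accuracy", "test_loss",
                  "cum_uploads", "cum_downloads", "cum_drops"]
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=fields, extrasaction="ignore")
            writer.writeheader()
            for row in self.metrics:
                writer.writerow(row)


@dataclass
class ServerState:
    w: ParamVector
    t: Timestamp
    history: ServerHistory
    #: device -> (pulled snapshot w_back_i, pull timestamp tau_i, history counts at pull)
    back: dict[int, tuple[ParamVector, Timestamp, np.ndarray]] = field(default_factory=dict)


@dataclass
class WorkerState:
    i: int
    shard: tuple  # (X, y)
    w_local: Optional[ParamVector]
    tau: Timestamp
    speed: float
    delay_rng: np.random.Generator
    batch_rng: np.random.Generator
    gate_rng: np.random.Generator


def pull(server: ServerState, worker: WorkerState) -> None:
    """Worker receives the current global model and its timestamp."""
    snapshot = server.w.copy()
    server.back[worker.i] = (snapshot, server.t, server.history.snapshot())
    worker.w_local = snapshot.copy()
    worker.tau = server.t


def _evaluate(model, w, test_data):
    if test_data is None:
        return None, None
    X_test, y_test = test_data
    loss = float(model.loss(w, X_test, y_test))
    acc = None
    if model.predict_proba(w, X_test) is not None:
        acc = accuracy(model, w, X_test, y_test)
    return acc, loss


def run_cafed(
    model: SupervisedModel,
    shards: list[tuple],
    cfg: CafedConfig,
    T: int,
    master_seed: int,
    *,
    batch_size: int = 16,
    local_steps: Optional[int] = None,
    test_data: Optional[tuple] = None,
    eval_every: int = 10,
    delay_mu: float = 0.0,
    delay_sigma: float = 0.5,
    speed_sigma: float = 0.5,
    keep_g_log: bool = False,
    stall_limit: int = 100_000,
    init_params: Optional[ParamVector] = None,
    delay_streams: Optional[list] = None,
) -> tuple[ParamVector, RunLog, ServerHistory]:
    """Run the asynchronous trainer until exactly ``T`` global updates.

    ``shards`` is one ``(X, y)`` pair per device; ``local_steps=None``
    means one pass over the shard per round (minibatch size 16 by
    default).  ``delay_streams`` optionally scripts each worker's round
    durations (one iterator of positive reals per device) in place of the
    seeded log-normal timing model.  Returns the final global model, the
    replayable run log, and the server's per-entry update history.
    """
    n = len(shards)
    if n < 1:
        raise ValueError("need at least one worker")
    w0 = init_params if init_params is not None else model.init_params(np.random.default_rng(master_seed))
    server = ServerState(
        w=w0.copy(),
        t=0,
        history=ServerHistory.empty(w0.n_entries, cfg.theta, keep_g_log),
    )
    noise_rng = server_noise_rng(master_seed)
    log = RunLog()

    workers = []
    scripted = [iter(s) for s in delay_streams] if delay_streams is not None else None
    for i in range(n):
        delay_rng, batch_rng, gate_rng = worker_streams(master_seed, i)
        speed = 1.0 if scripted else float(delay_rng.lognormal(0.0, speed_sigma))
        workers.append(WorkerState(i, shards[i], None, 0, speed, delay_rng, batch_rng, gate_rng))

    def next_delay(worker: WorkerState) -> float:
        if scripted is not None:
            return float(next(scripted[worker.i]))
        return worker.speed * worker.delay_rng.lognormal(delay_mu, delay_sigma)

    counters = {"cum_uploads": 0, "cum_downloads": 0, "cum_drops": 0}

    def do_pull(worker: WorkerState, now: float) -> None:
        pull(server, worker)
        counters["cum_downloads"] += 1
        log.log(now, "pull", device=worker.i, tau=server.t)

    # (completion time, device id) — the tuple order is the tie-break rule
    queue: list[tuple[float, int]] = []
    for worker in workers:
        do_pull(worker, 0.0)
        heapq.heappush(queue, (next_delay(worker), worker.i))

    drops_since_update = 0
    while server.t < T:
        if not queue:
            raise StallError("event queue empty before reaching T updates")
        now, i = heapq.heappop(queue)
        worker = workers[i]
        accepted = should_push(worker.gate_rng, cfg.v)
        log.log(now, "push_attempt", device=i, accepted=accepted)
        if accepted:
            worker.w_local = sgd_run(
                model, worker.w_local, worker.shard[0], worker.shard[1],
                cfg.lr, batch_size, worker.batch_rng, n_steps=local_steps,
            )
            snapshot, tau, counts_at_pull = server.back[i]
            g = pseudo_gradient(snapshot, worker.w_local)
            server.w, s, _ = server_apply(server.w, g, server.history, counts_at_pull, cfg, noise_rng)
            server.t += 1
            counters["cum_uploads"] += 1
            drops_since_update = 0
            payload = {"epoch": server.t - 1, "device": i, "tau": int(tau),
                       "staleness_epochs": int(server.t - 1 - tau)}
            if keep_g_log:
                payload["staleness"] = [int(x) for x in s]
            log.log(now, "global_update", **payload)
            if server.t % eval_every == 0 or server.t == T:
                acc, loss = _evaluate(model, server.w, test_data)
                log.log(now, "eval", epoch=server.t, test_accuracy=acc, test_loss=loss)
                log.metrics.append({"epoch": server.t, "sim_time": float(now),
                                    "test_accuracy": acc, "test_loss": loss, **counters})
            if server.t >= T:
                break
        else:
            counters["cum_drops"] += 1
            drops_since_update += 1
            log.log(now, "drop", device=i)
            if drops_since_update > stall_limit:
                raise StallError(
                    f"{drops_since_update} consecutive dropped pushes; "
                    f"push gate v={cfg.v} may be too restrictive"
                )
        do_pull(worker, now)
        heapq.heappush(queue, (now + next_delay(worker), i))

    return server.w, log, server.history


def run_centralized(
    model: SupervisedModel,
    train_data: tuple,
    T_epochs: int,
    master_seed: int,
    *,
    lr: float = 0.1,
    batch_size: int = 32,
    test_data: Optional[tuple] = None,
    eval_every: int = 1,
    init_params: Optional[ParamVector] = None,
) -> tuple[ParamVector, RunLog]:
    """All-data-on-the-server baseline: plain minibatch SGD with per-epoch evals."""
    X, y = train_data
    rng = np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(2,)))
    w = init_params if init_params is not None else model.init_params(np.random.default_rng(master_seed))
    w = w.copy()
    log = RunLog()
    for epoch in range(1, T_epochs + 1):
        w = sgd_run(model, w, X, y, lr, batch_size, rng)
        if epoch % eval_every == 0 or epoch == T_epochs:
            acc, loss = _evaluate(model, w, test_data)
            log.log(float(epoch), "eval", epoch=epoch, test_accuracy=acc, test_loss=loss)
            log.metrics.append({"epoch": epoch, "sim_time": float(epoch),
                                "test_accuracy": acc, "test_loss": loss,
                                "cum_uploads": 0, "cum_downloads": 0, "cum_drops": 0})
    return w, log
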