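"""Flat, key-indexed model parameter container.

Asynchronous federated optimization with per-parameter staleness needs a
stable global index ``k`` over every scalar parameter of the model, no
matter what the network architecture looks like.  :class:`ParamVector`
provides that: an ordered list of ``(name, shape)`` keys fixing the
flattening, and a single contiguous float64 vector holding the values.
All server-side arithmetic (pseudo-gradients, staleness-weighted updates,
noise injection) operates entry-wise on this vector.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Protocol, runtime_checkable

import numpy as np

__all__ = [
    "ParamVector",
    "ShapeError",
    "axpy",
    "flatten",
    "unflatten_into",
    "save_checkpoint",
    "load_checkpoint",
    "export_csv",
]

#: Global-epoch index.  The server's timestamp ``t`` equals the number of
#: applied global updates; a worker's pull timestamp ``tau`` never exceeds it.
Timestamp = int

_CHECKPOINT_MAGIC = "CAFEDSIM-CKPT-1"


class ShapeError(ValueError):
    """Raised when two parameter vectors are not conformable."""


@runtime_checkable
class ParameterizedModel(Protocol):
    """Anything exposing named parameters in a deterministic order."""

    def named_parameters(self) -> Iterable[tuple[str, np.ndarray]]: ...

    def set_named_parameters(self, params: Mapping[str, np.ndarray]) -> None: ...


@dataclass(frozen=True)
class ParamVector:
    """Ordered flat view of model parameters.

    Parameters
    ----------
    keys
        Tuple of ``(layer_name, shape)`` descriptors in registration order;
        these define the flattening and the meaning of entry index ``k``.
    values
        1-D float64 array whose length equals the sum of products of shapes.
    """

    keys: tuple[tuple[str, tuple[int, ...]], ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64).ravel()
        object.__setattr__(self, "values", vals)
        expected = sum(int(np.prod(shape, dtype=np.int64)) for _, shape in self.keys)
        if expected != vals.size:
            raise ShapeError(
                f"keys describe {expected} entries but values has {vals.size}"
            )

    @property
    def n_entries(self) -> int:
        return int(self.values.size)

    def conformable(self, other: "ParamVector") -> bool:
        return self.keys == other.keys

    def require_conformable(self, other: "ParamVector") -> None:
        if not self.conformable(other):
            raise ShapeError(f"non-conformable ParamVectors: {self.keys!r} vs {other.keys!r}")

    def with_values(self, values: np.ndarray) -> "ParamVector":
        """Same keys, new values (copy-free view of the given array)."""
        return ParamVector(self.keys, values)

    def copy(self) -> "ParamVector":
        return ParamVector(self.keys, self.values.copy())

    def unflatten(self) -> dict[str, np.ndarray]:
        """Reshape the flat vector back into named arrays."""
        out: dict[str, np.ndarray] = {}
        offset = 0
        for name, shape in self.keys:
            size = int(np.prod(shape, dtype=np.int64))
            out[name] = self.values[offset : offset + size].reshape(shape).copy()
            offset += size
        return out

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other: "ParamVector") -> "ParamVector":
        self.require_conformable(other)
        return self.with_values(self.values + other.values)

    def __sub__(self, other: "ParamVector") -> "ParamVector":
        self.require_conformable(other)
        return self.with_values(self.values - other.values)

    def __mul__(self, scalar: float) -> "ParamVector":
        return self.with_values(self.values * float(scalar))

    __rmul__ = __mul__

    @staticmethod
    def from_named(named: Iterable[tuple[str, np.ndarray]]) -> "ParamVector":
        keys = []
        chunks = []
        for name, arr in named:
            arr = np.asarray(arr, dtype=np.float64)
            keys.append((name, tuple(int(s) for s in arr.shape)))
            chunks.append(arr.ravel())
        values = np.concatenate(chunks) if chunks else np.empty(0)
        return ParamVector(tuple(keys), values)


def flatten(model: ParameterizedModel) -> ParamVector:
    """Flatten a model's parameters in registration order."""
    return ParamVector.from_named(model.named_parameters())


def unflatten_into(model: ParameterizedModel, pv: ParamVector) -> None:
    """Write a flat vector back into a model (inverse of :func:`flatten`)."""
    model.set_named_parameters(pv.unflatten())


def axpy(w: ParamVector, g: ParamVector, coeffs: np.ndarray | float) -> ParamVector:
    """Entry-wise damped update ``out[k] = w[k] - coeffs[k] * g[k]``.

    This is the global-model update applied on every accepted push, with
    ``coeffs`` holding the per-entry adaptive staleness weights.
    """
    w.require_conformable(g)
    coeffs = np.asarray(coeffs, dtype=np.float64)
    if coeffs.ndim not in (0, 1) or (coeffs.ndim == 1 and coeffs.size != w.n_entries):
        raise ShapeError("coeffs must be scalar or match the parameter count")
    return w.with_values(w.values - coeffs * g.values)


# -- checkpoint I/O -------------------------------------------------------
#
# Format: one JSON header line (magic, dtype, keys) terminated by "\n",
# followed by the raw little-endian float64 payload.  The header documents
# the parameter ordering so entry index k is reproducible across processes.


def save_checkpoint(pv: ParamVector, path) -> None:
    header = {
        "magic": _CHECKPOINT_MAGIC,
        "dtype": "<f8",
        "keys": [[name, list(shape)] for name, shape in pv.keys],
    }
    with open(path, "wb") as fh:
        fh.write(json.dumps(header).encode("utf-8") + b"\n")
        fh.write(np.ascontiguousarray(pv.values, dtype="<f8").tobytes())


def load_checkpoint(path) -> ParamVector:
    with open(path, "rb") as fh:
        header = json.loads(fh.readline().decode("utf-8"))
        if header.get("magic") != _CHECKPOINT_MAGIC:
            raise ValueError(f"not a cafedsim checkpoint: {path}")
        keys = tuple((name, tuple(shape)) for name, shape in header["keys"])
        values = np.frombuffer(fh.read(), dtype="<f8")
    return ParamVector(keys, values)


def export_csv(pv: ParamVector, path) -> None:
    """Debug export: one row per scalar entry (layer, within-layer index, value)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["k", "layer", "index", "value"])
        k = 0
        offset = 0
        for name, shape in pv.keys:
            size = int(np.prod(shape, dtype=np.int64))
            for j in range(size):
                writer.writerow([k, name, j, repr(float(pv.values[offset + j]))])
                k += 1
            offset += size
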