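"""Enumeration and validation of binary DAG causal configurations.

A causal configuration among ``M`` labeled channels is an ``M x M`` binary
adjacency matrix with zero diagonal whose directed graph is acyclic;
``A[i, j] == 1`` means channel ``i`` causes channel ``j``.  The canonical
catalog orders configurations by ascending edge count, breaking ties
lexicographically on the row-major flattened adjacency.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CausalConfiguration",
    "DagCatalog",
    "count_dags",
    "enumerate_dags",
    "is_acyclic",
    "edges",
    "ORDERING_RULE",
]

ORDERING_RULE = "edge count ascending, then lexicographic on row-major flattened adjacency"

#: Edge-count to structural-group tag for M = 3.  Advisory only.
_GROUP_TAGS = ("independent", "univariate", "bivariate", "trivariate")

# Enumeration is over all 2^(M(M-1)) off-diagonal assignments; cap the
# exponent so a typo cannot lock the interpreter.
_MAX_ENUMERABLE_EDGE_SLOTS = 20


def _validate_adjacency(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {A.shape}")
    if not np.isin(A, (0, 1)).all():
        raise ValueError("adjacency entries must be 0 or 1")
    if np.diag(A).any():
        raise ValueError("adjacency diagonal must be all zeros")
    return A.astype(np.int8)


def is_acyclic(A: np.ndarray) -> bool:
    """True iff the directed graph of ``A`` contains no directed cycle.

    Uses Kahn-style elimination: repeatedly remove nodes with zero
    in-degree; the graph is acyclic iff every node gets removed.
    """
    A = _validate_adjacency(A)
    alive = np.ones(A.shape[0], dtype=bool)
    while alive.any():
        in_deg = A[alive][:, alive].sum(axis=0)
        removable = in_deg == 0
        if not removable.any():
            return False
        idx = np.flatnonzero(alive)
        alive[idx[removable]] = False
    return True


@dataclass(frozen=True)
class CausalConfiguration:
    """One binary acyclic causal pattern among ``M`` labeled channels."""

    M: int
    A: np.ndarray
    class_index: int

    def __post_init__(self) -> None:
        A = _validate_adjacency(self.A)
        if A.shape[0] != self.M:
            raise ValueError(f"adjacency shape {A.shape} does not match M={self.M}")
        if not is_acyclic(A):
            raise ValueError("adjacency contains a directed cycle")
        A.setflags(write=False)
        object.__setattr__(self, "A", A)

    @property
    def n_edges(self) -> int:
        return int(self.A.sum())

    @property
    def group(self) -> str:
        """Structural-group tag derived from the edge count (M=3 only)."""
        if self.M != 3:
            raise ValueError("group tags are defined for M = 3 only")
        return _GROUP_TAGS[self.n_edges]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CausalConfiguration):
            return NotImplemented
        return self.M == other.M and bool((self.A == other.A).all())

    def __hash__(self) -> int:
        return hash((self.M, self.A.tobytes()))


def edges(config: CausalConfiguration) -> list[tuple[int, int]]:
    """Directed edges ``(i, j)`` with ``a_ij = 1`` in fixed row-major order."""
    return [
        (i, j)
        for i in range(config.M)
        for j in range(config.M)
        if i != j and config.A[i, j]
    ]


def edge_slots(M: int) -> list[tuple[int, int]]:
    """The ordered off-diagonal positions — the universe of possible edges."""
    return [(i, j) for i in range(M) for j in range(M) if i != j]


def count_dags(M: int) -> int:
    """Number of labeled DAGs on ``M`` nodes via the alternating recursion.

    ``a_M = sum_{k=1..M} (-1)^(k-1) C(M, k) 2^(k(M-k)) a_(M-k)``, ``a_0 = 1``.
    """
    if not isinstance(M, (int, np.integer)):
        raise TypeError(f"M must be an integer, got {type(M).__name__}")
    if M < 0:
        raise ValueError(f"M must be non-negative, got {M}")
    a = [1]
    for m in range(1, M + 1):
        a.append(
            sum(
                (-1) ** (k - 1) * math.comb(m, k) * 2 ** (k * (m - k)) * a[m - k]
                for k in range(1, m + 1)
            )
        )
    return a[M]


@dataclass(frozen=True)
class DagCatalog:
    """Canonically ordered list of all DAG configurations on ``M`` nodes."""

    M: int
    configurations: tuple[CausalConfiguration, ...]
    ordering_rule: str = ORDERING_RULE

    def __len__(self) -> int:
        return len(self.configurations)

    def __getitem__(self, k: int) -> CausalConfiguration:
        return self.configurations[k]

    def __iter__(self):
        return iter(self.configurations)

    def index_of(self, A: np.ndarray) -> int:
        """Class index of the configuration with adjacency ``A``."""
        A = _validate_adjacency(A)
        key = A.tobytes()
        for config in self.configurations:
            if config.A.tobytes() == key:
                return config.class_index
        raise KeyError("adjacency not found in catalog (is it acyclic?)")

    def edge_membership(self) -> np.ndarray:
        """Binary matrix ``(n_configs, M(M-1))``: which edge slots each class contains."""
        slots = edge_slots(self.M)
        out = np.zeros((len(self), len(slots)), dtype=np.int8)
        for k, config in enumerate(self.configurations):
            for s, (i, j) in enumerate(slots):
                out[k, s] = config.A[i, j]
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "M": self.M,
                "ordering_rule": self.ordering_rule,
                "configs": [c.A.flatten().astype(int).tolist() for c in self.configurations],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "DagCatalog":
        obj = json.loads(text)
        M = obj["M"]
        configs = tuple(
            CausalConfiguration(M, np.array(flat, dtype=np.int8).reshape(M, M), k)
            for k, flat in enumerate(obj["configs"])
        )
        return cls(M=M, configurations=configs, ordering_rule=obj["ordering_rule"])


def enumerate_dags(M: int) -> DagCatalog:
    """Build the canonical catalog of all labeled DAGs on ``M`` nodes.

    Brute-force enumeration over every zero-diagonal binary matrix with an
    acyclicity check; practical for ``M <= 4``.
    """
    if not isinstance(M, (int, np.integer)) or M < 1:
        raise ValueError(f"M must be a positive integer, got {M!r}")
    slots = edge_slots(M)
    if len(slots) > _MAX_ENUMERABLE_EDGE_SLOTS:
        raise NotImplementedError(
            f"enumeration over 2^{len(slots)} matrices is infeasible; M <= 4 supported"
        )
    found = []
    for bits in itertools.product((0, 1), repeat=len(slots)):
        A = np.zeros((M, M), dtype=np.int8)
        for (i, j), b in zip(slots, bits):
            A[i, j] = b
        if is_acyclic(A):
            found.append(A)
    found.sort(key=lambda A: (int(A.sum()), tuple(A.flatten())))
    configs = tuple(
        CausalConfiguration(M=M, A=A, class_index=k) for k, A in enumerate(found)
    )
    return DagCatalog(M=M, configurations=configs)
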