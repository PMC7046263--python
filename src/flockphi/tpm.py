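"""State-by-node transition probability matrices for binary collective states.

The TPM is the interface between the empirical pipeline (trajectories →
binary states) and the integrated-information machinery: row ``s`` holds,
for each node ``i``, the conditional probability that node ``i`` is ON at
time ``t`` given that the collective state at ``t - Δt`` was ``s``.  Nodes
are conditionally independent given the past state (the canonical IIT 3.0
input form), so the full ``2**n × 2**n`` state-by-state matrix is the row-
wise product of the per-node marginals.

State indexing is little-endian throughout: node 1 (the first individual)
is the least significant bit of the state integer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .binarize import StateSeries

STATE_INDEXING = "little-endian"


def states_to_codes(states: np.ndarray) -> np.ndarray:
    """Pack a (T, N) binary matrix into integer state codes (little-endian)."""
    states = np.asarray(states)
    n = states.shape[1]
    weights = 1 << np.arange(n)
    return states.astype(np.int64) @ weights


def codes_to_states(codes: np.ndarray, n: int) -> np.ndarray:
    codes = np.asarray(codes, dtype=np.int64)
    return (codes[:, None] >> np.arange(n)) & 1


@dataclass
class StateByNodeTPM:
    """``2**n × n`` matrix of conditional ON-probabilities.

    ``occupancy[s]`` counts how often past state ``s`` was observed when the
    matrix was estimated from data (all-ones for analytically specified
    TPMs).
    """

    probs: np.ndarray
    n: int
    state_indexing: str = STATE_INDEXING
    occupancy: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        expected = (1 << self.n, self.n)
        if self.probs.shape != expected:
            raise ValueError(
                f"TPM shape {self.probs.shape} does not match {expected} for n={self.n}"
            )
        if np.any(~np.isfinite(self.probs)) or self.probs.min() < 0 or self.probs.max() > 1:
            raise ValueError("TPM entries must be probabilities in [0, 1]")
        if self.state_indexing != STATE_INDEXING:
            raise ValueError(f"only {STATE_INDEXING!r} state indexing is supported")

    @property
    def n_states(self) -> int:
        return 1 << self.n

    def to_csv(self, path: str | Path) -> None:
        header = ",".join(f"node{i + 1}" for i in range(self.n))
        np.savetxt(path, self.probs, delimiter=",", header=header, comments="")

    @classmethod
    def from_csv(cls, path: str | Path) -> "StateByNodeTPM":
        probs = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        n = probs.shape[1]
        return cls(probs=probs, n=n)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n": self.n,
            "state_indexing": self.state_indexing,
            "probs": self.probs.tolist(),
            "occupancy": None if self.occupancy is None else self.occupancy.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "StateByNodeTPM":
        payload = json.loads(Path(path).read_text())
        if payload.get("state_indexing", STATE_INDEXING) != STATE_INDEXING:
            raise ValueError("unsupported state indexing in TPM file")
        occ = payload.get("occupancy")
        return cls(
            probs=np.asarray(payload["probs"], dtype=float),
            n=int(payload["n"]),
            occupancy=None if occ is None else np.asarray(occ, dtype=float),
        )


@dataclass
class ConnectivityMatrix:
    """Directed adjacency between nodes; ``adjacency[j, i]`` is the edge j→i.

    The default is the completely connected network including self-loops.
    Zeroing the diagonal removes each node's dependence on its own past
    (the no-self-loop variant), realised by marginalising the corresponding
    past bit uniformly.
    """

    adjacency: np.ndarray

    @classmethod
    def complete(cls, n: int, self_loops: bool = True) -> "ConnectivityMatrix":
        adj = np.ones((n, n), dtype=np.int8)
        if not self_loops:
            np.fill_diagonal(adj, 0)
        return cls(adjacency=adj)

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]


def estimate_tpm(series: StateSeries | np.ndarray, smoothing: float = 0.0) -> StateByNodeTPM:
    """Maximum-likelihood state-by-node TPM from a binary state series.

    Entry (s, i) is the fraction of transitions out of collective state ``s``
    in which node ``i`` was ON at the next step.  Past states never visited
    are filled with the maximum-entropy value 0.5 (or smoothed counts when
    ``smoothing`` α > 0, which adds α pseudo-observations of ON and OFF to
    every cell).
    """
    states = series.states if isinstance(series, StateSeries) else np.asarray(series)
    if states.ndim != 2 or states.shape[0] < 2:
        raise ValueError("state series must be a (T, N) matrix with T >= 2")
    n = states.shape[1]
    codes = states_to_codes(states)
    nstates = 1 << n
    on_counts = np.zeros((nstates, n))
    visits = np.bincount(codes[:-1], minlength=nstates).astype(np.float64)
    np.add.at(on_counts, codes[:-1], states[1:].astype(np.float64))
    probs = np.full((nstates, n), 0.5)
    if smoothing > 0.0:
        probs = (on_counts + smoothing) / (visits[:, None] + 2.0 * smoothing)
    else:
        seen = visits > 0
        probs[seen] = on_counts[seen] / visits[seen, None]
    return StateByNodeTPM(probs=probs, n=n, occupancy=visits)


def state_by_state(tpm: StateByNodeTPM) -> np.ndarray:
    """Expand a state-by-node TPM to the full ``2**n × 2**n`` transition matrix.

    Nodes are conditionally independent given the past state, so
    P(s → s') is the product over nodes of the matching marginal.
    """
    n = tpm.n
    future = codes_to_states(np.arange(1 << n), n)  # (2^n, n)
    p = tpm.probs[:, None, :]  # (past, 1, node)
    bits = future[None, :, :]  # (1, future, node)
    return np.prod(np.where(bits == 1, p, 1.0 - p), axis=2)


def apply_connectivity(tpm: StateByNodeTPM, cm: ConnectivityMatrix) -> StateByNodeTPM:
    """Marginalise away the influence of absent edges.

    For every missing edge j→i, node i's conditional ON-probability is
    averaged uniformly over node j's past state, removing that dependence
    while leaving all present edges intact.
    """
    if cm.n != tpm.n:
        raise ValueError("connectivity matrix size does not match TPM")
    n = tpm.n
    probs = tpm.probs.copy()
    codes = np.arange(1 << n)
    for i in range(n):
        for j in range(n):
            if cm.adjacency[j, i]:
                continue
            partner = codes ^ (1 << j)
            probs[:, i] = 0.5 * (probs[:, i] + probs[partner, i])
    return StateByNodeTPM(probs=probs, n=n, occupancy=tpm.occupancy)


def load_state_table(path: str | Path) -> StateByNodeTPM:
    """Import a TPM laid out as a spreadsheet-style state table.

    Expected layout: one row per past collective state, an optional leading
    ``state`` column holding the binary pattern (node 1 first), and one
    probability column per node.  Rows may appear in any order when the
    state column is present; otherwise rows are taken to be in little-endian
    state order.
    """
    import pandas as pd

    df = pd.read_csv(path, dtype=str)
    cols = list(df.columns)
    first = df[cols[0]].astype(str).str.strip()
    has_state_col = str(cols[0]).lower() == "state" or bool(
        first.str.fullmatch(r"[01]+").all() and (first.str.len() == len(cols) - 1).all()
    )
    if has_state_col and len(cols) > 1:
        patterns = first
        probs_df = df[cols[1:]]
        n = len(cols) - 1
        probs = np.zeros((1 << n, n))
        seen = np.zeros(1 << n, dtype=bool)
        for pattern, row in zip(patterns, probs_df.to_numpy(dtype=float)):
            if len(pattern) != n or set(pattern) - {"0", "1"}:
                raise ValueError(f"bad state pattern {pattern!r}")
            code = int(pattern[::-1], 2)  # node 1 written first -> low bit
            probs[code] = row
            seen[code] = True
        if not seen.all():
            raise ValueError("state table does not cover all collective states")
        return StateByNodeTPM(probs=probs, n=n)
    probs = df.to_numpy(dtype=float)
    n = probs.shape[1]
    return StateByNodeTPM(probs=probs, n=n)
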