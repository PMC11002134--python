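"""Small-world coupling graphs W(n, K, p) and their Laplacians.

The Watts-Strogatz construction starts from a ring of ``n`` nodes each
linked to its ``K`` nearest neighbours (``K/2`` per side) and rewires one
endpoint of every ring edge with probability ``p``; rewiring moves edges
but never adds or removes them, so the edge count stays ``n K / 2``.
Generation is delegated to :func:`networkx.watts_strogatz_graph` (the
classic rewiring dialect, deterministic given the seed); this module owns
the validated adjacency container, the coupling Laplacian
``L = A - diag(k)`` and a plain-text edge-list format.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import networkx as nx
import numpy as np

__all__ = [
    "SmallWorldSpec",
    "Network",
    "generate_small_world",
    "laplacian",
    "write_edge_list",
    "read_edge_list",
]


@dataclass(frozen=True)
class SmallWorldSpec:
    """W(n, K, p) parameters: node count, ring neighbours (even), rewiring p."""

    n: int
    K: int
    p: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.K % 2 != 0:
            raise ValueError(f"K must be even (total ring neighbours), got {self.K}")
        if not (0 <= self.K <= max(self.n - 1, 0)):
            raise ValueError(f"K must satisfy 0 <= K <= n-1, got K={self.K}, n={self.n}")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")


class Network:
    """Unweighted undirected graph as a validated adjacency matrix."""

    def __init__(self, adjacency: np.ndarray):
        A = np.asarray(adjacency, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency must have a zero diagonal (no self-loops)")
        if not np.all(np.isin(A, (0.0, 1.0))):
            raise ValueError("adjacency entries must be 0 or 1")
        self.adjacency = A

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    @property
    def laplacian(self) -> np.ndarray:
        """Coupling Laplacian L = A - diag(k); every row sums to zero."""
        return self.adjacency - np.diag(self.degrees)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edges(self):
        """Undirected edges as (i, j) pairs with i < j, sorted."""
        i, j = np.nonzero(np.triu(self.adjacency))
        return list(zip(i.tolist(), j.tolist()))

    def __eq__(self, other) -> bool:
        return isinstance(other, Network) and np.array_equal(
            self.adjacency, other.adjacency)


def generate_small_world(spec: SmallWorldSpec) -> Network:
    """Watts-Strogatz small-world network; deterministic given spec.seed."""
    g = nx.watts_strogatz_graph(spec.n, spec.K, spec.p, seed=spec.seed)
    A = nx.to_numpy_array(g, nodelist=range(spec.n), dtype=float)
    return Network(A)


def laplacian(network: Network) -> np.ndarray:
    """L = A - diag(k) for a validated network."""
    return network.laplacian


def write_edge_list(network: Network, sink: Union[str, Path, io.TextIOBase]) -> None:
    """Write ``# n=<int>`` header then one ``i j`` line per edge (i < j, 0-based)."""
    lines = [f"# n={network.n}"]
    lines += [f"{i} {j}" for i, j in network.edges()]
    text = "\n".join(lines) + "\n"
    if isinstance(sink, (str, Path)):
        Path(sink).write_text(text)
    else:
        sink.write(text)


def read_edge_list(source: Union[str, Path, io.TextIOBase]) -> Network:
    """Parse the edge-list format back into a Network.

    Raises ``ValueError`` naming the offending line for malformed input,
    out-of-range indices, self-loops and duplicate edges.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    lines = text.splitlines()
    if not lines or not lines[0].startswith("# n="):
        raise ValueError("line 1: expected header '# n=<int>'")
    try:
        n = int(lines[0][4:])
    except ValueError:
        raise ValueError("line 1: could not parse node count from header") from None
    if n < 1:
        raise ValueError("line 1: node count must be >= 1")
    A = np.zeros((n, n))
    for lineno, raw in enumerate(lines[1:], start=2):
        stripped = raw.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split()
        if len(parts) != 2:
            raise ValueError(f"line {lineno}: expected 'i j', got {raw!r}")
        try:
            i, j = int(parts[0]), int(parts[1])
        except ValueError:
            raise ValueError(f"line {lineno}: non-integer node index in {raw!r}") from None
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"line {lineno}: node index out of range [0, {n})")
        if i == j:
            raise ValueError(f"line {lineno}: self-loop {i} {j} not allowed")
        if A[i, j]:
            raise ValueError(f"line {lineno}: duplicate edge {i} {j}")
        A[i, j] = A[j, i] = 1.0
    return Network(A)
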