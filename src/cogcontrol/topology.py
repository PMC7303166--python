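"""Population interaction structures.

Agents live on an undirected graph that defines who they learn from, whose
strategies affect their payoffs, and whose behaviour shapes their local
environment.  Three families are supported:

* ``ring`` — each agent is connected to k/2 neighbours on each side,
* ``complete`` — every pair of agents is connected (the well-mixed limit),
* ``small_world`` — a Watts–Strogatz rewiring of the ring, resampled until
  connected.

"Global" interaction along any dimension is modelled by querying the complete
graph (equivalently, the whole population), so a single :class:`Topology`
object per run suffices; scenario flags select the scope per dimension.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Iterable, Literal

import networkx as nx
import numpy as np

__all__ = [
    "Topology",
    "make_ring",
    "make_complete",
    "make_small_world",
    "neighborhood",
    "write_edgelist",
    "read_edgelist",
]

Kind = Literal["ring", "complete", "small_world", "custom"]


class Topology:
    """An undirected, connected interaction graph over ``n_agents`` agents.

    Adjacency is stored in CSR-like arrays for fast neighbourhood queries;
    regular graphs (all degrees equal) additionally carry dense neighbour
    index matrices so that neighbourhood means over the whole population are
    a single fancy-indexing operation.

    Invariants: no self-loops, symmetry (j adjacent to i iff i adjacent to j),
    and every agent has at least one neighbour.
    """

    def __init__(
        self,
        n_agents: int,
        edges: Iterable[tuple[int, int]],
        kind: Kind = "custom",
        k: int | None = None,
        rewiring_rate: float | None = None,
    ):
        self.n_agents = int(n_agents)
        self.kind = kind
        self.k = k
        self.rewiring_rate = rewiring_rate

        nbrs: list[set[int]] = [set() for _ in range(self.n_agents)]
        for i, j in edges:
            i, j = int(i), int(j)
            if i == j:
                raise ValueError(f"self-loop on agent {i}")
            if not (0 <= i < self.n_agents and 0 <= j < self.n_agents):
                raise ValueError(f"edge ({i}, {j}) out of range")
            nbrs[i].add(j)
            nbrs[j].add(i)
        degrees = np.array([len(s) for s in nbrs], dtype=np.intp)
        if self.n_agents == 0 or degrees.min() == 0:
            raise ValueError("every agent must have at least one neighbour")

        self.degrees = degrees
        self._indptr = np.concatenate(([0], np.cumsum(degrees)))
        self._indices = np.concatenate(
            [np.fromiter(sorted(s), dtype=np.intp, count=len(s)) for s in nbrs]
        )
        # Regular graphs admit dense (n, d) neighbour matrices.
        self._regular_degree = int(degrees[0]) if (degrees == degrees[0]).all() else None
        if self._regular_degree is not None:
            d = self._regular_degree
            self._excl_mat = self._indices.reshape(self.n_agents, d)
            incl = np.empty((self.n_agents, d + 1), dtype=np.intp)
            incl[:, 0] = np.arange(self.n_agents)
            incl[:, 1:] = self._excl_mat
            self._incl_mat = np.sort(incl, axis=1)
        else:
            self._excl_mat = None
            self._incl_mat = None
        self._is_complete = self._regular_degree == self.n_agents - 1

    # -- queries ---------------------------------------------------------

    @property
    def adjacency(self) -> tuple[frozenset[int], ...]:
        """Per-agent neighbour sets (excluding self)."""
        return tuple(frozenset(self.neighbors(i).tolist()) for i in range(self.n_agents))

    def neighbors(self, i: int) -> np.ndarray:
        """Sorted neighbour indices of agent ``i`` (self excluded)."""
        if not (0 <= i < self.n_agents):
            raise IndexError(f"agent index {i} out of range for n={self.n_agents}")
        return self._indices[self._indptr[i] : self._indptr[i + 1]]

    @property
    def n_edges(self) -> int:
        return int(self.degrees.sum()) // 2

    def is_connected(self) -> bool:
        g = nx.Graph(self.edge_list())
        g.add_nodes_from(range(self.n_agents))
        return nx.is_connected(g)

    def edge_list(self) -> list[tuple[int, int]]:
        """Unordered edges as sorted (i, j) pairs with i < j."""
        out = []
        for i in range(self.n_agents):
            for j in self.neighbors(i):
                if i < j:
                    out.append((i, int(j)))
        return out

    # -- bulk neighbourhood statistics -----------------------------------

    def neighborhood_mean(self, x: np.ndarray, include_self: bool = True) -> np.ndarray:
        """Mean of ``x`` over each agent's neighbourhood.

        Returns an array of length ``n_agents``.  On the complete graph the
        including-self mean is the population mean for every agent, which is
        exploited so that local scopes on the full graph are exactly
        equivalent to global scopes.
        """
        x = np.asarray(x, dtype=float)
        if self._is_complete:
            if include_self:
                return np.full(self.n_agents, x.mean())
            return (x.sum() - x) / (self.n_agents - 1)
        if self._regular_degree is not None:
            mat = self._incl_mat if include_self else self._excl_mat
            return x[mat].mean(axis=1)
        sums = np.add.reduceat(x[self._indices], self._indptr[:-1])
        if include_self:
            return (sums + x) / (self.degrees + 1)
        return sums / self.degrees

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        extra = "" if self.rewiring_rate is None else f", beta={self.rewiring_rate}"
        return f"Topology({self.kind}, n={self.n_agents}, k={self.k}{extra})"


def _check_ring_args(n: int, k: int) -> None:
    if n < 3:
        raise ValueError(f"need n >= 3 agents for a ring, got {n}")
    if k % 2 != 0 or k <= 0:
        raise ValueError(f"ring degree k must be a positive even integer, got {k}")
    if k >= n:
        raise ValueError(f"ring degree k={k} must be < n={n}")


def make_ring(n: int, k: int = 2) -> Topology:
    """Ring lattice: agent i is adjacent to i±1, …, i±k/2 (mod n)."""
    _check_ring_args(n, k)
    edges = [(i, (i + off) % n) for i in range(n) for off in range(1, k // 2 + 1)]
    # modular wrap can duplicate edges when k = n - 1; the Topology ctor
    # stores sets, so duplicates collapse harmlessly
    return Topology(n, edges, kind="ring", k=k)


def make_complete(n: int) -> Topology:
    """Complete graph on ``n`` agents (every pair adjacent)."""
    if n < 2:
        raise ValueError(f"need n >= 2 agents for a complete graph, got {n}")
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
    return Topology(n, edges, kind="complete", k=n - 1)


def make_small_world(n: int, k: int, rewiring_rate: float, seed: int) -> Topology:
    """Watts–Strogatz small-world graph, resampled until connected.

    Starts from ``make_ring(n, k)`` and rewires each clockwise edge with
    probability ``rewiring_rate`` to a uniformly chosen endpoint, forbidding
    self-loops and duplicate edges (the canonical construction, as provided
    by networkx).  Deterministic given ``seed``.
    """
    _check_ring_args(n, k)
    if not (0.0 <= rewiring_rate <= 1.0):
        raise ValueError(f"rewiring_rate must lie in [0, 1], got {rewiring_rate}")
    g = nx.connected_watts_strogatz_graph(n, k, rewiring_rate, tries=1000, seed=int(seed))
    return Topology(n, g.edges(), kind="small_world", k=k, rewiring_rate=rewiring_rate)


def neighborhood(top: Topology, i: int, include_self: bool = False) -> set[int]:
    """Neighbour set of agent ``i``, optionally including ``i`` itself."""
    out = set(int(j) for j in top.neighbors(i))
    if include_self:
        out.add(int(i))
    return out


def write_edgelist(top: Topology, path: str | Path) -> None:
    """Serialize as one ``i j`` pair per line (0-based, i < j)."""
    buf = io.StringIO()
    for i, j in top.edge_list():
        buf.write(f"{i} {j}\n")
    Path(path).write_text(buf.getvalue())


def read_edgelist(path: str | Path, n_agents: int | None = None, kind: Kind = "custom") -> Topology:
    """Load a topology written by :func:`write_edgelist`."""
    edges = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        i, j = line.split()
        edges.append((int(i), int(j)))
    if n_agents is None:
        n_agents = max(max(e) for e in edges) + 1
    return Topology(n_agents, edges, kind=kind)
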