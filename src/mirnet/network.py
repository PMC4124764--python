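"""Interaction-network I/O, preprocessing, and degree-preserving randomization.

The protein–protein interaction (PPI) network is the substrate for all
downstream propagation: genes are nodes, experimentally supported
interactions are undirected edges. Analyses run on the largest connected
component. The permutation null model is built from degree-preserving
randomizations of this network (Maslov–Sneppen edge switching), which keep
every gene's number of interaction partners fixed while destroying all
higher-order structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionNetwork",
    "RandomNetworkEnsemble",
    "load_network",
    "largest_component",
    "edge_switch_randomize",
    "build_ensemble",
]


@dataclass(frozen=True)
class InteractionNetwork:
    """An undirected, simple gene-interaction graph.

    Nodes are opaque gene identifiers (strings). Edges are stored as
    canonically ordered (min, max) tuples; the graph contains no self-loops
    and no duplicate edges. ``node_order`` fixes a deterministic
    lexicographic ordering used for all matrix representations and
    tie-breaking downstream.
    """

    node_order: tuple[str, ...]
    edge_list: tuple[tuple[str, str], ...]
    _index: dict[str, int] = field(repr=False, compare=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self._index:
            object.__setattr__(
                self, "_index", {g: i for i, g in enumerate(self.node_order)}
            )

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], nodes: Iterable[str] = ()
    ) -> "InteractionNetwork":
        """Build a network from an edge iterable, dropping self-loops and
        duplicates. ``nodes`` may add isolated nodes."""
        node_set: set[str] = set(nodes)
        edge_set: set[tuple[str, str]] = set()
        n_loops = 0
        for u, v in edges:
            if u == v:
                n_loops += 1
                continue
            node_set.update((u, v))
            edge_set.add((u, v) if u <= v else (v, u))
        if n_loops:
            logger.info("dropped %d self-loop(s)", n_loops)
        order = tuple(sorted(node_set))
        return cls(order, tuple(sorted(edge_set)))

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.node_order)

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        return frozenset(self.edge_list)

    @property
    def N(self) -> int:
        """Number of genes in the network (the ranking length downstream)."""
        return len(self.node_order)

    @property
    def n_edges(self) -> int:
        return len(self.edge_list)

    def index_of(self, gene: str) -> int:
        return self._index[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def degrees(self) -> dict[str, int]:
        deg = dict.fromkeys(self.node_order, 0)
        for u, v in self.edge_list:
            deg[u] += 1
            deg[v] += 1
        return deg

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_order)
        g.add_edges_from(self.edge_list)
        return g

    def edge_index_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Edge endpoints as two integer arrays in ``node_order`` indexing."""
        if not self.edge_list:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        ui = np.fromiter(
            (self._index[u] for u, _ in self.edge_list), dtype=np.int64
        )
        vi = np.fromiter(
            (self._index[v] for _, v in self.edge_list), dtype=np.int64
        )
        return ui, vi

    def write_edge_list(self, path: str | Path, header: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header:
                fh.write(f"# {line}\n")
            for u, v in self.edge_list:
                fh.write(f"{u}\t{v}\n")


def load_network(source: str | Path | Iterable[str], delimiter: str | None = None
                 ) -> InteractionNetwork:
    """Read an undirected network from a two-column edge list.

    Lines starting with ``#`` are ignored; by default columns are split on
    any whitespace. Duplicate edges (in either orientation) are collapsed
    and self-loops dropped with a logged count.

    Raises
    ------
    ValueError
        If the input has no edges, or a data row has fewer than two columns.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            lines = fh.readlines()
    else:
        lines = list(source)
    edges: list[tuple[str, str]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = [c for c in line.split(delimiter) if c]
        if len(cols) < 2:
            raise ValueError(
                f"edge list line {lineno} has fewer than 2 columns: {line!r}"
            )
        edges.append((cols[0], cols[1]))
    if not edges:
        raise ValueError("edge list contains no edges")
    return InteractionNetwork.from_edges(edges)


def largest_component(net: InteractionNetwork) -> InteractionNetwork:
    """Return the connected component with the most nodes.

    Ties between equally sized components are broken by the
    lexicographically smallest member node.
    """
    if net.N == 0:
        raise ValueError("network is empty")
    comps = [set(c) for c in nx.connected_components(net.to_networkx())]
    max_size = max(len(c) for c in comps)
    candidates = [c for c in comps if len(c) == max_size]
    best = min(candidates, key=min)
    edges = [(u, v) for u, v in net.edge_list if u in best]
    return InteractionNetwork(tuple(sorted(best)), tuple(edges))


def edge_switch_randomize(
    net: InteractionNetwork, n_swap_attempts: int, rng_seed: int
) -> InteractionNetwork:
    """Degree-preserving randomization by attempted double-edge swaps.

    Each attempt picks two distinct edges (a,b),(c,d) and a random pairing
    of their endpoints; the rewiring is applied only when it creates neither
    a self-loop nor a duplicate edge, so the output is always a simple graph
    with exactly the input degree sequence. Rejected attempts are counted
    and logged. Deterministic given ``rng_seed``.
    """
    if n_swap_attempts < 1:
        raise ValueError("n_swap_attempts must be >= 1")
    m = net.n_edges
    if m < 2:
        return net
    rng = np.random.default_rng(rng_seed)
    edges = list(net.edge_list)
    edge_set = set(edges)
    rejected = 0
    done = 0
    chunk = 4096
    while done < n_swap_attempts:
        k = min(chunk, n_swap_attempts - done)
        picks = rng.integers(0, m, size=(k, 2))
        orient = rng.integers(0, 2, size=k)
        for t in range(k):
            i, j = int(picks[t, 0]), int(picks[t, 1])
            if i == j:
                rejected += 1
                continue
            a, b = edges[i]
            c, d = edges[j]
            if orient[t]:
                # (a,b),(c,d) -> (a,d),(c,b)
                e1 = (a, d) if a <= d else (d, a)
                e2 = (c, b) if c <= b else (b, c)
            else:
                # (a,b),(c,d) -> (a,c),(b,d)
                e1 = (a, c) if a <= c else (c, a)
                e2 = (b, d) if b <= d else (d, b)
            if e1[0] == e1[1] or e2[0] == e2[1] or e1 == e2 \
                    or e1 in edge_set or e2 in edge_set:
                rejected += 1
                continue
            edge_set.discard(edges[i])
            edge_set.discard(edges[j])
            edges[i] = e1
            edges[j] = e2
            edge_set.add(e1)
            edge_set.add(e2)
        done += k
    logger.debug(
        "edge switching: %d attempts, %d rejected", n_swap_attempts, rejected
    )
    return InteractionNetwork(net.node_order, tuple(sorted(edge_set)))


@dataclass(frozen=True)
class RandomNetworkEnsemble:
    """A lazily generated ensemble of degree-preserving randomizations.

    Member ``i`` is reproducible from ``(rng_seed + i)`` alone; networks are
    generated on demand so the ensemble never holds more than one
    randomization in memory at a time.
    """

    source: InteractionNetwork
    n_networks: int
    swaps_per_edge: int
    rng_seed: int

    @property
    def source_degree_sequence(self) -> Mapping[str, int]:
        return self.source.degrees()

    @property
    def n_swap_attempts(self) -> int:
        return max(1, self.swaps_per_edge * self.source.n_edges)

    def member(self, i: int) -> InteractionNetwork:
        if not 0 <= i < self.n_networks:
            raise IndexError(f"ensemble has {self.n_networks} members")
        return edge_switch_randomize(
            self.source, self.n_swap_attempts, self.rng_seed + i
        )

    def __len__(self) -> int:
        return self.n_networks

    def __iter__(self) -> Iterator[InteractionNetwork]:
        for i in range(self.n_networks):
            yield self.member(i)


def build_ensemble(
    net: InteractionNetwork,
    n_networks: int,
    swaps_per_edge: int = 10,
    rng_seed: int = 0,
) -> RandomNetworkEnsemble:
    """Construct the randomized-network ensemble used as the permutation null.

    ``swaps_per_edge`` scales the number of attempted swaps to 10x the edge
    count by default, a standard mixing length for Maslov–Sneppen
    randomization.
    """
    if n_networks < 1:
        raise ValueError("n_networks must be >= 1")
    return RandomNetworkEnsemble(net, n_networks, swaps_per_edge, rng_seed)
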