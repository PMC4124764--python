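"""Random walk with restart (RWR) on an interaction network.

RWR measures the global network proximity of every gene to a seed set.
A walker starts on the seeds and at each step either moves to a uniformly
chosen neighbor (probability 1−α) or restarts at the seeds (probability α):

    p ← (1−α) · W · p + α · p0

where W is the column-normalized adjacency matrix and p0 is uniform over
the seed genes. The fixed point p assigns each gene a steady-state
probability; sorting by it yields the gene ranking consumed by the
enrichment scan. Larger α keeps the walker closer to the seeds; the
default α = 0.7 sits in the 0.5–0.9 range where ranking performance is
stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import scipy.sparse as sp

from .genesets import GeneSet
from .network import InteractionNetwork

logger = logging.getLogger(__name__)

__all__ = ["RWRConfig", "RankedGeneList", "RWRSolver", "rwr_propagate", "rank_of"]


@dataclass(frozen=True)
class RWRConfig:
    """Parameters of the walk: restart probability ``alpha`` in (0,1),
    L1 convergence tolerance ``tol``, and an iteration cap."""

    alpha: float = 0.7
    tol: float = 1e-10
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass(frozen=True)
class RankedGeneList:
    """All N network genes ordered by descending steady-state probability.

    Ties are broken by ascending gene identifier so that the ranking — and
    therefore every enrichment score computed from it — is deterministic.
    Ranks are 1-based.
    """

    order: tuple[str, ...]
    probabilities: Mapping[str, float]
    _ranks: dict[str, int] = field(repr=False, compare=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self._ranks:
            object.__setattr__(
                self, "_ranks", {g: i + 1 for i, g in enumerate(self.order)}
            )

    @property
    def N(self) -> int:
        return len(self.order)

    def rank(self, gene: str) -> int:
        if gene not in self._ranks:
            raise KeyError(f"gene {gene!r} is not in the ranking")
        return self._ranks[gene]

    def write_tsv(self, path: str | Path, header: Iterable[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header:
                fh.write(f"# {line}\n")
            fh.write("gene\tprobability\trank\n")
            for i, g in enumerate(self.order, start=1):
                fh.write(f"{g}\t{self.probabilities[g]:.10g}\t{i}\n")


class RWRSolver:
    """Reusable RWR engine for one network.

    Builds the column-normalized sparse transition matrix once so that many
    seed sets can be propagated on the same network cheaply (the all-pairs
    scorer runs one solver per network in the null ensemble). Genes with no
    interactions keep their mass via an implicit self-loop, so the
    probability vector remains a distribution on any input.
    """

    def __init__(self, net: InteractionNetwork, cfg: RWRConfig | None = None):
        self.net = net
        self.cfg = cfg or RWRConfig()
        n = net.N
        ui, vi = net.edge_index_arrays()
        deg = np.zeros(n, dtype=np.float64)
        np.add.at(deg, ui, 1.0)
        np.add.at(deg, vi, 1.0)
        rows = np.concatenate([vi, ui])
        cols = np.concatenate([ui, vi])
        safe_deg = np.where(deg > 0, deg, 1.0)
        data = 1.0 / safe_deg[cols]
        isolated = np.nonzero(deg == 0)[0]
        if isolated.size:
            rows = np.concatenate([rows, isolated])
            cols = np.concatenate([cols, isolated])
            data = np.concatenate([data, np.ones(isolated.size)])
        self.W = sp.csr_matrix((data, (rows, cols)), shape=(n, n))

    def steady_state(self, seed_indices: np.ndarray) -> np.ndarray:
        """Iterate p ← (1−α)Wp + αp0 to the fixed point; returns the
        probability vector over ``net.node_order``."""
        cfg = self.cfg
        n = self.net.N
        p0 = np.zeros(n)
        p0[seed_indices] = 1.0 / len(seed_indices)
        p = p0.copy()
        restart = cfg.alpha * p0
        walk = 1.0 - cfg.alpha
        for it in range(cfg.max_iter):
            p_new = walk * (self.W @ p) + restart
            delta = np.abs(p_new - p).sum()
            p = p_new
            if delta < cfg.tol:
                break
        else:
            logger.warning(
                "RWR did not reach tol=%g in %d iterations (last L1 change %g)",
                cfg.tol, cfg.max_iter, delta,
            )
        return p

    def rank_genes(self, p: np.ndarray) -> RankedGeneList:
        """Sort descending by probability, ties by ascending gene ID.

        ``node_order`` is lexicographically sorted, so a stable sort on
        −probability realizes the tie-break."""
        idx = np.argsort(-p, kind="stable")
        order = tuple(self.net.node_order[i] for i in idx)
        probs = {self.net.node_order[i]: float(p[i]) for i in range(self.net.N)}
        return RankedGeneList(order, probs)

    def seed_indices(self, seeds: GeneSet | Iterable[str]) -> np.ndarray:
        members = seeds.members if isinstance(seeds, GeneSet) else set(seeds)
        idx = np.array(
            sorted(self.net.index_of(g) for g in members if g in self.net),
            dtype=np.int64,
        )
        if idx.size == 0:
            name = seeds.set_id if isinstance(seeds, GeneSet) else "<anonymous>"
            raise ValueError(
                f"no seed gene of set {name!r} is present in the network"
            )
        return idx

    def propagate(self, seeds: GeneSet | Iterable[str]) -> RankedGeneList:
        return self.rank_genes(self.steady_state(self.seed_indices(seeds)))


def rwr_propagate(
    net: InteractionNetwork, seeds: GeneSet, cfg: RWRConfig | None = None
) -> RankedGeneList:
    """Propagate from ``seeds`` and return the full ranked gene list."""
    return RWRSolver(net, cfg).propagate(seeds)


def rank_of(ranking: RankedGeneList, gene: str) -> int:
    """1-based rank of ``gene`` in the ranked list; error if absent."""
    return ranking.rank(gene)
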