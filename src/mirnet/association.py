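"""All-pairs association scoring with permutation significance.

The significance of an observed combined enrichment score is assessed
against the same score recomputed on an ensemble of degree-preserving
randomizations of the interaction network: with k the number of null
scores greater than or equal to the observed one, p = k / n_null. Pairs
passing a p-value threshold δ (strictly p < δ) become edges of the
bipartite miRNA–disease network.

Cost model: one RWR propagation per (network, seed set) is enough for all
pairs, so scoring D diseases × M miRNAs against an ensemble of R networks
takes (R+1)·(D+M) propagations instead of (R+1)·D·M·2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genesets import GeneSetCollection
from .network import InteractionNetwork, RandomNetworkEnsemble
from .rwr import RWRConfig, RWRSolver

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationRecord",
    "BipartiteNetwork",
    "permutation_pvalue",
    "score_all_pairs",
    "build_bipartite",
    "write_associations",
    "read_associations",
]


@dataclass(frozen=True)
class AssociationRecord:
    """Scored miRNA–disease pair: bidirectional enrichment scores, the
    combined score, and its permutation significance."""

    mirna_id: str
    disease_id: str
    es1: float
    es2: float
    es: float
    k: int
    n_null: int

    @property
    def p_value(self) -> float:
        return self.k / self.n_null


def permutation_pvalue(observed_es: float, null_ess: Sequence[float]
                       ) -> tuple[int, float]:
    """Permutation p-value: fraction of null scores ≥ the observed score.

    Ties count toward k, so p can never be smaller than warranted by the
    ensemble size; p = 0 is possible when the observed score beats every
    null exactly.
    """
    nulls = np.asarray(null_ess, dtype=float)
    if nulls.size == 0:
        raise ValueError("null score list is empty")
    k = int((nulls >= observed_es).sum())
    return k, k / nulls.size


def _es_matrix(
    net: InteractionNetwork,
    diseases: GeneSetCollection,
    mirnas: GeneSetCollection,
    cfg: RWRConfig,
    beta: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """ES1, ES2, ES arrays of shape (n_diseases, n_mirnas) on one network.

    Equivalent to running ``score_pair_es`` per pair, but each (network,
    seed-set) propagation runs once and positions are scored via boolean
    masks. Increments follow the running-sum definition exactly.
    """
    solver = RWRSolver(net, cfg)
    N = net.N

    def member_mask(coll: GeneSetCollection) -> dict[str, np.ndarray]:
        masks = {}
        for gs in coll:
            m = np.zeros(N, dtype=bool)
            for g in gs.members:
                if g in net:
                    m[net.index_of(g)] = True
            n = int(m.sum())
            if n == 0:
                raise ValueError(f"set {gs.set_id!r} has no gene in the network")
            if n >= N:
                raise ValueError(f"set {gs.set_id!r} covers the whole network")
            masks[gs.set_id] = m
        return masks

    d_masks = member_mask(diseases)
    m_masks = member_mask(mirnas)

    def rank_order(seed_mask: np.ndarray) -> np.ndarray:
        idx = np.nonzero(seed_mask)[0]
        p = solver.steady_state(idx)
        return np.argsort(-p, kind="stable")

    def es_against(order: np.ndarray, query_mask: np.ndarray) -> float:
        hits = query_mask[order]
        n = int(query_mask.sum())
        steps = np.where(hits, (N - n) / n, -n / (N - n))
        return float(np.cumsum(steps).max())

    es1 = np.empty((len(diseases), len(mirnas)))
    es2 = np.empty_like(es1)
    m_ids = mirnas.ids
    d_ids = diseases.ids
    m_orders = {mid: rank_order(m_masks[mid]) for mid in m_ids}
    for i, did in enumerate(d_ids):
        d_order = rank_order(d_masks[did])
        for j, mid in enumerate(m_ids):
            es1[i, j] = es_against(d_order, m_masks[mid])
            es2[i, j] = es_against(m_orders[mid], d_masks[did])
    return es1, es2, beta * es1 + (1.0 - beta) * es2


def score_all_pairs(
    net: InteractionNetwork,
    ensemble: RandomNetworkEnsemble,
    diseases: GeneSetCollection,
    mirnas: GeneSetCollection,
    cfg: RWRConfig | None = None,
    beta: float = 0.5,
) -> list[AssociationRecord]:
    """Score every (disease, miRNA) pair and attach permutation p-values.

    The observed combined score comes from ``net``; null scores recompute
    the same statistic, with the same seed sets, on each ensemble member.
    Records are ordered by disease then miRNA.
    """
    if not 0.0 < beta < 1.0:
        raise ValueError(f"beta must be in (0,1), got {beta}")
    cfg = cfg or RWRConfig()
    es1, es2, es = _es_matrix(net, diseases, mirnas, cfg, beta)
    k = np.zeros_like(es, dtype=np.int64)
    n_null = len(ensemble)
    for r, rand_net in enumerate(ensemble):
        _, _, null_es = _es_matrix(rand_net, diseases, mirnas, cfg, beta)
        k += null_es >= es
        if (r + 1) % 100 == 0:
            logger.info("scored null network %d/%d", r + 1, n_null)
    records = []
    for i, did in enumerate(diseases.ids):
        for j, mid in enumerate(mirnas.ids):
            records.append(
                AssociationRecord(
                    mid, did,
                    float(es1[i, j]), float(es2[i, j]), float(es[i, j]),
                    int(k[i, j]), n_null,
                )
            )
    return records


@dataclass(frozen=True)
class BipartiteNetwork:
    """Thresholded miRNA–disease network.

    Edges are (mirna, disease, p_value) triples with p strictly below the
    threshold δ; node sets contain exactly the endpoints of edges.
    """

    edges: tuple[tuple[str, str, float], ...]
    threshold: float
    disease_classes: dict[str, str] = field(default_factory=dict)

    @property
    def mirna_nodes(self) -> tuple[str, ...]:
        return tuple(sorted({m for m, _, _ in self.edges}))

    @property
    def disease_nodes(self) -> tuple[str, ...]:
        return tuple(sorted({d for _, d, _ in self.edges}))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def mirna_neighbors(self, disease: str) -> frozenset[str]:
        return frozenset(m for m, d, _ in self.edges if d == disease)

    def disease_neighbors(self, mirna: str) -> frozenset[str]:
        return frozenset(d for m, d, _ in self.edges if m == mirna)

    def incidence_frame(self) -> pd.DataFrame:
        """Binary incidence matrix: rows = miRNAs, columns = diseases."""
        mat = pd.DataFrame(
            0, index=list(self.mirna_nodes), columns=list(self.disease_nodes),
            dtype=np.int8,
        )
        for m, d, _ in self.edges:
            mat.loc[m, d] = 1
        return mat

    def write_tsv(self, path: str | Path, header: Iterable[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header:
                fh.write(f"# {line}\n")
            fh.write("mirna\tdisease\tp_value\tdisease_class\n")
            for m, d, p in self.edges:
                cls = self.disease_classes.get(d, "Unknown")
                fh.write(f"{m}\t{d}\t{p:.10g}\t{cls}\n")


def build_bipartite(
    records: Iterable[AssociationRecord],
    delta: float = 0.05,
    classes: Mapping[str, str] | None = None,
) -> BipartiteNetwork:
    """Connect pairs with p-value strictly below δ into a bipartite network.

    δ only controls how many associations become edges; within a disease
    the ranking of miRNAs by p-value is unaffected by the choice of δ.
    """
    if not 0.0 < delta <= 1.0:
        raise ValueError(f"delta must be in (0,1], got {delta}")
    edges = tuple(
        sorted(
            (r.mirna_id, r.disease_id, r.p_value)
            for r in records
            if r.p_value < delta
        )
    )
    classes = dict(classes or {})
    kept = {d for _, d, _ in edges}
    return BipartiteNetwork(
        edges, delta, {d: c for d, c in classes.items() if d in kept}
    )


_ASSOC_COLUMNS = ["mirna", "disease", "es1", "es2", "es", "k", "n_null", "p_value"]


def write_associations(
    records: Iterable[AssociationRecord],
    path: str | Path,
    header: Iterable[str] = (),
) -> None:
    """Write the association table as TSV (with optional # header lines)."""
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        fh.write("\t".join(_ASSOC_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.mirna_id}\t{r.disease_id}\t{r.es1:.17g}\t{r.es2:.17g}"
                f"\t{r.es:.17g}\t{r.k}\t{r.n_null}\t{r.p_value:.17g}\n"
            )


def read_associations(path: str | Path) -> list[AssociationRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    return [
        AssociationRecord(
            str(row["mirna"]), str(row["disease"]),
            float(row["es1"]), float(row["es2"]), float(row["es"]),
            int(row["k"]), int(row["n_null"]),
        )
        for _, row in df.iterrows()
    ]
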