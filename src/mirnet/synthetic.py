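"""Seeded synthetic fixtures for every pipeline stage.

Real inputs to the method are a curated interactome, disease-gene sets,
and voted miRNA target sets — none of which are bundled. This module
generates structurally analogous data with known ground truth:

* a scale-free interaction network (preferential attachment), matching
  the hub-dominated degree distribution of a curated PPI network;
* disease gene sets drawn mostly from one connected neighborhood
  ("module_cohesion"), emulating the local clustering of disease genes;
* miRNA target sets for planted positives drawn from within distance 1
  of their paired disease module with probability ``signal_fraction``
  (``signal_placement="within"``: disease genes and their neighbors), or
  from the exclusive frontier (``signal_placement="adjacent"``: adjacent
  to, but never overlapping, the disease genes — association signal then
  exists only through network proximity, invisible to overlap tests);
  negatives draw targets uniformly;
* disease classes whose members share part of one class-level
  neighborhood, planting within-class regulator sharing.

Every generator is deterministic given its seed. Separate direct
generators produce bipartite networks with planted class structure and
planted block incidence matrices for the analysis-stage tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .association import BipartiteNetwork
from .evaluation import LabeledPairs
from .genesets import GeneSet, GeneSetCollection
from .network import InteractionNetwork, largest_component

__all__ = [
    "SyntheticSpec",
    "SyntheticData",
    "generate",
    "generate_class_bipartite",
    "generate_block_incidence",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Study-condition parameters for the synthetic generator.

    ``attachment`` is the number of edges each new gene brings in the
    preferential-attachment growth (mean degree ≈ 2·attachment).
    ``module_cohesion`` is the probability that a disease gene comes from
    the disease's connected neighborhood rather than anywhere in the
    network. ``signal_fraction`` is the probability that a positive
    miRNA's target comes from the signal pool of its paired disease
    module; ``signal_placement`` chooses that pool — ``"within"`` for the
    disease genes plus their distance-1 neighbors, ``"adjacent"`` for the
    neighbors only (targets then never overlap the disease genes).
    ``within_class_regulator_overlap`` is the probability that a cohesive
    disease gene is drawn from the class-shared neighborhood instead of
    the disease's own.
    """

    n_genes: int = 500
    attachment: int = 3
    n_diseases: int = 10
    disease_module_size: int = 12
    module_cohesion: float = 0.9
    n_mirnas: int = 20
    targets_per_mirna: int = 15
    signal_fraction: float = 0.8
    signal_placement: str = "within"
    n_classes: int = 3
    within_class_regulator_overlap: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "attachment", "n_diseases",
                     "disease_module_size", "n_mirnas", "targets_per_mirna",
                     "n_classes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("module_cohesion", "signal_fraction",
                     "within_class_regulator_overlap"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.signal_placement not in ("within", "adjacent"):
            raise ValueError(
                f"signal_placement must be 'within' or 'adjacent', "
                f"got {self.signal_placement!r}"
            )
        if self.disease_module_size > self.n_genes:
            raise ValueError("disease_module_size exceeds n_genes")
        if self.targets_per_mirna > self.n_genes:
            raise ValueError("targets_per_mirna exceeds n_genes")


@dataclass(frozen=True)
class SyntheticData:
    network: InteractionNetwork
    diseases: GeneSetCollection
    mirnas: GeneSetCollection
    labels: LabeledPairs
    classes: dict[str, str]
    pairing: dict[str, str]  # mirna -> paired disease


def _bfs_pool(g: nx.Graph, start: str, size: int) -> list[str]:
    pool = []
    for node in nx.bfs_tree(g, start):
        pool.append(node)
        if len(pool) >= size:
            break
    return pool


def generate(spec: SyntheticSpec) -> SyntheticData:
    """Generate a full synthetic study from one seed (see module docstring)."""
    rng = np.random.default_rng(spec.rng_seed)
    ba_seed = int(rng.integers(2**31))
    g = nx.barabasi_albert_graph(spec.n_genes, spec.attachment, seed=ba_seed)
    mapping = {i: f"g{i:05d}" for i in g.nodes}
    g = nx.relabel_nodes(g, mapping)
    net = largest_component(InteractionNetwork.from_edges(g.edges()))
    genes = np.array(net.node_order)
    gnx = net.to_networkx()

    pool_size = 3 * spec.disease_module_size
    class_ids = [f"class{c}" for c in range(spec.n_classes)]
    class_pools = {
        cid: _bfs_pool(gnx, str(rng.choice(genes)), pool_size)
        for cid in class_ids
    }

    diseases: dict[str, GeneSet] = {}
    classes: dict[str, str] = {}
    for i in range(spec.n_diseases):
        did = f"D{i:03d}"
        cid = class_ids[i % spec.n_classes]
        classes[did] = cid
        own_pool = _bfs_pool(gnx, str(rng.choice(genes)), pool_size)
        members: set[str] = set()
        while len(members) < spec.disease_module_size:
            if rng.random() < spec.module_cohesion:
                if rng.random() < spec.within_class_regulator_overlap:
                    members.add(str(rng.choice(class_pools[cid])))
                else:
                    members.add(str(rng.choice(own_pool)))
            else:
                members.add(str(rng.choice(genes)))
        diseases[did] = GeneSet(did, frozenset(members))
    disease_coll = GeneSetCollection(diseases, "disease", dict(classes))

    mirnas: dict[str, GeneSet] = {}
    pairing: dict[str, str] = {}
    positives: set[tuple[str, str]] = set()
    negatives: set[tuple[str, str]] = set()
    n_pos = spec.n_mirnas // 2
    for j in range(spec.n_mirnas):
        mid = f"mir{j:03d}"
        did = f"D{j % spec.n_diseases:03d}"
        pairing[mid] = did
        is_positive = j < n_pos
        targets: set[str] = set()
        if is_positive:
            module = diseases[did].members
            frontier = {nb for gmem in module for nb in gnx.neighbors(gmem)}
            if spec.signal_placement == "adjacent":
                pool = sorted(frontier - module)
            else:  # "within": distance <= 1 of the module
                pool = sorted(frontier | module)
            while len(targets) < spec.targets_per_mirna:
                if pool and rng.random() < spec.signal_fraction:
                    targets.add(str(rng.choice(pool)))
                else:
                    targets.add(str(rng.choice(genes)))
            positives.add((did, mid))
        else:
            targets.update(
                rng.choice(genes, size=spec.targets_per_mirna, replace=False)
            )
            negatives.add((did, mid))
        mirnas[mid] = GeneSet(mid, frozenset(targets))
    mirna_coll = GeneSetCollection(mirnas, "mirna")

    return SyntheticData(
        net, disease_coll, mirna_coll,
        LabeledPairs(frozenset(positives), frozenset(negatives)),
        classes, pairing,
    )


def generate_class_bipartite(
    n_classes: int = 4,
    diseases_per_class: int = 6,
    mirnas_per_class: int = 8,
    n_background_mirnas: int = 20,
    p_in: float = 0.8,
    p_out: float = 0.05,
    threshold: float = 0.05,
    rng_seed: int = 0,
) -> BipartiteNetwork:
    """Bipartite network with planted within-class regulator sharing.

    Each class owns a pool of miRNAs; a disease links to each miRNA of its
    own class's pool with probability ``p_in`` and to any other miRNA with
    probability ``p_out``. Edge p-values are drawn uniformly below the
    threshold (their exact values are irrelevant to the modularity and
    clustering analyses, which use the binary incidence).
    """
    rng = np.random.default_rng(rng_seed)
    n_mirnas = n_classes * mirnas_per_class + n_background_mirnas
    mirna_ids = [f"mir{j:03d}" for j in range(n_mirnas)]
    edges = []
    classes = {}
    for c in range(n_classes):
        cls = f"class{c}"
        own = set(range(c * mirnas_per_class, (c + 1) * mirnas_per_class))
        for i in range(diseases_per_class):
            did = f"D{c:02d}_{i:02d}"
            classes[did] = cls
            for j, mid in enumerate(mirna_ids):
                p_link = p_in if j in own else p_out
                if rng.random() < p_link:
                    edges.append((mid, did, float(rng.uniform(0, threshold))))
    return BipartiteNetwork(tuple(sorted(edges)), threshold, classes)


def generate_block_incidence(
    n_blocks: int = 3,
    mirnas_per_block: int = 10,
    diseases_per_block: int = 8,
    flip_prob: float = 0.05,
    threshold: float = 0.05,
    rng_seed: int = 0,
) -> tuple[BipartiteNetwork, dict[str, int], dict[str, int]]:
    """Block-diagonal incidence matrix with flip noise, as a bipartite net.

    Returns the network plus the planted block label of every miRNA and
    disease, for comparing recovered clusters against the ground truth.
    """
    rng = np.random.default_rng(rng_seed)
    edges = []
    row_labels: dict[str, int] = {}
    col_labels: dict[str, int] = {}
    n_rows = n_blocks * mirnas_per_block
    n_cols = n_blocks * diseases_per_block
    for r in range(n_rows):
        row_labels[f"mir{r:03d}"] = r // mirnas_per_block
    for c in range(n_cols):
        col_labels[f"D{c:03d}"] = c // diseases_per_block
    for r in range(n_rows):
        for c in range(n_cols):
            linked = row_labels[f"mir{r:03d}"] == col_labels[f"D{c:03d}"]
            if rng.random() < flip_prob:
                linked = not linked
            if linked:
                edges.append(
                    (f"mir{r:03d}", f"D{c:03d}", float(rng.uniform(0, threshold)))
                )
    net = BipartiteNetwork(tuple(sorted(edges)), threshold, {})
    return net, row_labels, col_labels


def write_fixture_dir(data: SyntheticData, out_dir: str | Path,
                      header: tuple[str, ...] = ()) -> dict[str, Path]:
    """Write the generated study to the formats the CLI consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "network": out / "network.tsv",
        "diseases": out / "diseases.gmt",
        "mirnas": out / "mirnas.gmt",
        "labels": out / "labels.tsv",
        "classes": out / "classes.tsv",
    }
    data.network.write_edge_list(paths["network"], header)
    data.diseases.write_gmt(paths["diseases"], header)
    data.mirnas.write_gmt(paths["mirnas"], header)
    with open(paths["labels"], "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        for d, m in sorted(data.labels.positives):
            fh.write(f"{d}\t{m}\t1\n")
        for d, m in sorted(data.labels.negatives):
            fh.write(f"{d}\t{m}\t0\n")
    with open(paths["classes"], "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        for d, c in sorted(data.classes.items()):
            fh.write(f"{d}\t{c}\n")
    return paths
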