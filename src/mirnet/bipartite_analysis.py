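"""Global and modular analysis of the bipartite miRNA–disease network.

Covers four read-outs of the thresholded network: degree tables for both
node kinds; the mean disease degree per disease class; the BD/BH
modularity pair quantifying whether diseases of one class cluster through
shared miRNA regulators; and two-way hierarchical clustering of the binary
incidence matrix (city-block distance, complete linkage) to extract
co-regulated miRNA–disease modules.

BD/BH here use a shared-neighbor-ratio reconstruction (the original exact
formulas are not published in the main text): with s(d_i, d_j) the number
of miRNAs linked to both diseases,

    BD(class) = mean s over within-class disease pairs
                / mean s over all disease pairs,
    BH(class) = mean s over (in-class, out-of-class) pairs
                / mean s over all disease pairs.

BD > 1 means diseases of the class share regulators more than a typical
disease pair; BH < 1 means that sharing is class-specific; BD > BH is the
clustering signature. Random class labels give BD ≈ 1 in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from scipy import stats

from .association import AssociationRecord, BipartiteNetwork

__all__ = [
    "ClassModularity",
    "CoModule",
    "CorrelationResult",
    "degree_tables",
    "class_average_degree",
    "bd_bh",
    "all_class_modularity",
    "cluster_bipartite",
    "degree_correlations",
]


@dataclass(frozen=True)
class ClassModularity:
    class_name: str
    bd: float
    bh: float
    n_diseases: int


@dataclass(frozen=True)
class CoModule:
    """A co-regulated module: a joint miRNA set and disease set whose
    incidence block is dense."""

    mirnas: frozenset[str]
    diseases: frozenset[str]
    provenance: dict = field(default_factory=dict, compare=False)


@dataclass(frozen=True)
class CorrelationResult:
    r_targets: float
    p_targets: float
    r_ratio: float
    p_ratio: float
    n: int


def degree_tables(net: BipartiteNetwork) -> tuple[pd.Series, pd.Series]:
    """Degree of every miRNA and every disease in the bipartite network,
    each sorted descending (ties by identifier)."""
    if net.n_edges == 0:
        raise ValueError("bipartite network has no edges")
    m_deg: dict[str, int] = {}
    d_deg: dict[str, int] = {}
    for m, d, _ in net.edges:
        m_deg[m] = m_deg.get(m, 0) + 1
        d_deg[d] = d_deg.get(d, 0) + 1
    mirna = pd.Series(m_deg, name="degree").sort_index()
    disease = pd.Series(d_deg, name="degree").sort_index()
    return (
        mirna.sort_values(ascending=False, kind="stable"),
        disease.sort_values(ascending=False, kind="stable"),
    )


def class_average_degree(net: BipartiteNetwork) -> pd.DataFrame:
    """Number of diseases and mean disease degree per disease class.

    Diseases without a class label are grouped under ``Unknown``. Returned
    sorted by average degree descending.
    """
    _, d_deg = degree_tables(net)
    rows = []
    classes: dict[str, list[int]] = {}
    for d, deg in d_deg.items():
        cls = net.disease_classes.get(d, "Unknown")
        classes.setdefault(cls, []).append(int(deg))
    for cls in sorted(classes):
        degs = classes[cls]
        rows.append(
            {"disease_class": cls, "n_diseases": len(degs),
             "avg_degree": float(np.mean(degs))}
        )
    df = pd.DataFrame(rows).set_index("disease_class")
    return df.sort_values("avg_degree", ascending=False, kind="stable")


def _shared_neighbor_counts(net: BipartiteNetwork) -> tuple[list[str], np.ndarray]:
    """s(d_i, d_j) matrix: number of miRNAs linked to both diseases."""
    diseases = list(net.disease_nodes)
    inc = net.incidence_frame().to_numpy()  # mirnas x diseases
    s = inc.T.astype(np.int64) @ inc.astype(np.int64)
    return diseases, s


def bd_bh(net: BipartiteNetwork, class_name: str) -> ClassModularity:
    """BD and BH modularity of one disease class (see module docstring).

    Requires at least two in-class diseases, at least one out-of-class
    disease, and a nonzero overall level of regulator sharing.
    """
    diseases, s = _shared_neighbor_counts(net)
    labels = np.array(
        [net.disease_classes.get(d, "Unknown") for d in diseases]
    )
    in_cls = labels == class_name
    n_in = int(in_cls.sum())
    if n_in < 2:
        raise ValueError(
            f"class {class_name!r} has {n_in} disease(s) in the network; "
            "BD needs at least 2"
        )
    n = len(diseases)
    if n_in == n:
        raise ValueError(
            f"class {class_name!r} covers every disease; BH is undefined"
        )
    iu = np.triu_indices(n, k=1)
    all_pairs = s[iu]
    mean_all = all_pairs.mean()
    if mean_all == 0:
        raise ValueError("no disease pair shares a miRNA; BD/BH undefined")
    within = s[np.ix_(in_cls, in_cls)][np.triu_indices(n_in, k=1)]
    between = s[np.ix_(in_cls, ~in_cls)].ravel()
    bd = float(within.mean() / mean_all)
    bh = float(between.mean() / mean_all)
    return ClassModularity(class_name, bd, bh, n_in)


def all_class_modularity(net: BipartiteNetwork) -> pd.DataFrame:
    """BD/BH table for every class with >= 2 diseases in the network."""
    counts: dict[str, int] = {}
    for d in net.disease_nodes:
        cls = net.disease_classes.get(d, "Unknown")
        counts[cls] = counts.get(cls, 0) + 1
    rows = []
    for cls in sorted(counts):
        if counts[cls] < 2 or counts[cls] == len(net.disease_nodes):
            continue
        cm = bd_bh(net, cls)
        rows.append(
            {"disease_class": cls, "bd": cm.bd, "bh": cm.bh,
             "n_diseases": cm.n_diseases}
        )
    return pd.DataFrame(rows).set_index("disease_class")


def _cut_labels(matrix: np.ndarray, k: int) -> np.ndarray:
    dist = ssd.pdist(matrix, metric="cityblock")
    link = sch.linkage(dist, method="complete")
    return sch.fcluster(link, t=k, criterion="maxclust")


def cluster_bipartite(
    net: BipartiteNetwork,
    n_modules: int,
    min_density: float = 0.8,
) -> list[CoModule]:
    """Two-way hierarchical clustering of the binary incidence matrix.

    Rows (miRNAs) and columns (diseases) are clustered independently with
    city-block distance and complete linkage, each dendrogram is cut into
    ``n_modules`` clusters, and every (row-cluster, column-cluster) block
    whose edge density reaches ``min_density`` becomes a co-regulated
    module. Cluster assignments for both axes are attached to each module's
    provenance for downstream evaluation.
    """
    inc = net.incidence_frame()
    mat = inc.to_numpy(dtype=float)
    if mat.shape[0] < 2 or mat.shape[1] < 2:
        raise ValueError("clustering needs >= 2 nodes on each side")
    if not mat.any():
        raise ValueError("incidence matrix is all zero")
    row_labels = _cut_labels(mat, n_modules)
    col_labels = _cut_labels(mat.T, n_modules)
    mirnas = np.array(inc.index)
    diseases = np.array(inc.columns)
    modules: list[CoModule] = []
    for rc in np.unique(row_labels):
        rmask = row_labels == rc
        best = None
        for cc in np.unique(col_labels):
            cmask = col_labels == cc
            block = mat[np.ix_(rmask, cmask)]
            density = float(block.mean())
            if best is None or density > best[0]:
                best = (density, cc, cmask)
        density, cc, cmask = best
        if density >= min_density:
            modules.append(
                CoModule(
                    frozenset(mirnas[rmask]),
                    frozenset(diseases[cmask]),
                    provenance={
                        "n_modules": int(n_modules),
                        "row_cluster": int(rc),
                        "col_cluster": int(cc),
                        "density": density,
                        "row_assignments": dict(
                            zip(mirnas.tolist(), row_labels.tolist())
                        ),
                        "col_assignments": dict(
                            zip(diseases.tolist(), col_labels.tolist())
                        ),
                    },
                )
            )
    return modules


def degree_correlations(
    records: Sequence[AssociationRecord],
    mirna_target_counts: Mapping[str, int],
    disease_gene_counts: Mapping[str, int],
    delta: float = 0.05,
) -> CorrelationResult:
    """Pearson correlations of miRNA degree against target-set properties.

    Degree is the number of diseases linked at threshold δ. The first
    correlation is against the miRNA's target count, the second against the
    ratio of disease genes among its targets to its target count. Only
    miRNAs with at least one edge enter; needs >= 3 such miRNAs and
    non-constant inputs.
    """
    degree: dict[str, int] = {}
    for r in records:
        if r.p_value < delta:
            degree[r.mirna_id] = degree.get(r.mirna_id, 0) + 1
    mirnas = sorted(m for m in degree if m in mirna_target_counts)
    if len(mirnas) < 3:
        raise ValueError("need at least 3 miRNAs with edges and target counts")
    deg = np.array([degree[m] for m in mirnas], dtype=float)
    n_targets = np.array([mirna_target_counts[m] for m in mirnas], dtype=float)
    ratio = np.array(
        [disease_gene_counts.get(m, 0) / mirna_target_counts[m] for m in mirnas]
    )
    for name, arr in (("degree", deg), ("target count", n_targets),
                      ("disease-gene ratio", ratio)):
        if np.allclose(arr, arr[0]):
            raise ValueError(f"{name} is constant; correlation undefined")
    r_t, p_t = stats.pearsonr(deg, n_targets)
    r_r, p_r = stats.pearsonr(deg, ratio)
    return CorrelationResult(float(r_t), float(p_t), float(r_r), float(p_r),
                             len(mirnas))
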