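"""Disease-gene and miRNA-target set handling.

Two collections drive the method: disease→causal-gene sets (seeds for one
propagation direction) and miRNA→target sets (seeds for the other). Target
evidence from multiple prediction databases is consolidated by a vote
filter — a (miRNA, gene) pair is kept only when at least ``min_databases``
distinct databases report it — and both collections are intersected with
the interaction network, discarding sets left with too few in-network
genes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .network import InteractionNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "load_gmt",
    "vote_filter_targets",
    "annotate_to_network",
    "load_evidence",
]


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers (a disease's genes or a miRNA's targets)."""

    set_id: str
    members: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class GeneSetCollection:
    """A keyed collection of gene sets of one kind ('disease' or 'mirna'),
    with optional class labels (e.g. the 18 disease classes)."""

    sets: dict[str, GeneSet]
    kind: str
    class_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("disease", "mirna"):
            raise ValueError(f"kind must be 'disease' or 'mirna', got {self.kind!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, set_id: str) -> GeneSet:
        return self.sets[set_id]

    def __contains__(self, set_id: str) -> bool:
        return set_id in self.sets

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(self.sets)

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for gs in self.sets.values():
            out |= gs.members
        return frozenset(out)

    def write_gmt(self, path: str | Path, header: Iterable[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header:
                fh.write(f"# {line}\n")
            for sid, gs in self.sets.items():
                desc = self.class_labels.get(sid, ".")
                genes = "\t".join(sorted(gs.members))
                fh.write(f"{sid}\t{desc}\t{genes}\n")


def load_gmt(source: str | Path | Iterable[str], kind: str) -> GeneSetCollection:
    """Read gene sets from GMT-like TSV: set_id, description/class, genes...

    For ``kind='disease'`` the second column, when not ``.`` or empty, is
    recorded as the disease-class label. Member lists are deduplicated.
    Rows with an empty gene list are skipped with a warning; duplicate
    set_ids are an error.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            lines = fh.readlines()
    else:
        lines = list(source)
    sets: dict[str, GeneSet] = {}
    class_labels: dict[str, str] = {}
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 2:
            raise ValueError(f"GMT line {lineno}: expected >=2 columns")
        sid, desc = cols[0], cols[1]
        genes = frozenset(g for g in cols[2:] if g)
        if sid in sets:
            raise ValueError(f"duplicate set id {sid!r} at line {lineno}")
        if not genes:
            warnings.warn(f"GMT line {lineno}: set {sid!r} has no genes; skipped")
            continue
        sets[sid] = GeneSet(sid, genes)
        if kind == "disease" and desc not in ("", "."):
            class_labels[sid] = desc
    return GeneSetCollection(sets, kind, class_labels)


def vote_filter_targets(
    per_database_pairs: Iterable[tuple[str, str, str]],
    min_databases: int = 3,
) -> GeneSetCollection:
    """Keep (miRNA, gene) target pairs supported by enough distinct databases.

    ``per_database_pairs`` are (mirna, gene, database) evidence rows; a pair
    reported several times by the same database counts once. The default of
    three concurring databases trades coverage for reliability.
    """
    if min_databases < 1:
        raise ValueError("min_databases must be >= 1")
    support: dict[tuple[str, str], set[str]] = {}
    for mirna, gene, db in per_database_pairs:
        support.setdefault((mirna, gene), set()).add(db)
    kept: dict[str, set[str]] = {}
    for (mirna, gene), dbs in support.items():
        if len(dbs) >= min_databases:
            kept.setdefault(mirna, set()).add(gene)
    sets = {m: GeneSet(m, frozenset(genes)) for m, genes in sorted(kept.items())}
    return GeneSetCollection(sets, "mirna")


def annotate_to_network(
    coll: GeneSetCollection,
    net: InteractionNetwork,
    min_genes: int = 5,
) -> GeneSetCollection:
    """Intersect every set with the network's genes and drop small sets.

    A set survives only when strictly more than ``min_genes`` of its members
    lie in the network (the miRNA inclusion rule; pass ``min_genes=0`` to
    keep every nonempty disease set). Idempotent.
    """
    if net.N == 0:
        raise ValueError("network is empty")
    sets: dict[str, GeneSet] = {}
    labels: dict[str, str] = {}
    for sid, gs in coll.sets.items():
        members = frozenset(g for g in gs.members if g in net)
        if len(members) > min_genes and members:
            sets[sid] = GeneSet(sid, members)
            if sid in coll.class_labels:
                labels[sid] = coll.class_labels[sid]
    n_dropped = len(coll.sets) - len(sets)
    if n_dropped:
        logger.info(
            "annotation dropped %d/%d %s set(s) with <= %d in-network genes",
            n_dropped, len(coll.sets), coll.kind, min_genes,
        )
    return GeneSetCollection(sets, coll.kind, labels)


def load_evidence(source: str | Path | Iterable[str]) -> list[tuple[str, str, str]]:
    """Read (mirna, gene, database) evidence rows from TSV."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            lines = fh.readlines()
    else:
        lines = list(source)
    rows: list[tuple[str, str, str]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 3:
            raise ValueError(f"evidence line {lineno}: expected 3 columns")
        rows.append((cols[0], cols[1], cols[2]))
    return rows
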