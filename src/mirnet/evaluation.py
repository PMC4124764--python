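"""ROC evaluation of association scores and the overlap-based baseline.

Labeled positive/negative (disease, miRNA) pairs are scored by their
permutation p-values: a pair is called positive when p ≤ δ, and the
decision threshold δ is swept over every distinct p-value to trace the
ROC curve (sensitivity = TP/(TP+FN), specificity = TN/(TN+FP)); the area
under it is computed by trapezoidal integration and coincides with the
Mann–Whitney concordance probability.

The comparison baseline scores a pair by the hypergeometric upper-tail
probability of the overlap between the miRNA's targets and the disease's
genes — direct overlap only, no network proximity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import AssociationRecord
from .genesets import GeneSet
from .network import InteractionNetwork

__all__ = ["LabeledPairs", "ROCResult", "roc_auc", "hypergeometric_baseline",
           "roc_auc_from_scores"]


@dataclass(frozen=True)
class LabeledPairs:
    """Known-association positives and negative controls, as
    (disease, mirna) pairs; the two sets must be disjoint."""

    positives: frozenset[tuple[str, str]]
    negatives: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        overlap = self.positives & self.negatives
        if overlap:
            raise ValueError(f"pairs labeled both positive and negative: {sorted(overlap)[:5]}")
        if not self.positives or not self.negatives:
            raise ValueError("need at least one positive and one negative pair")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LabeledPairs":
        df = pd.read_csv(path, sep="\t", comment="#",
                         names=["disease", "mirna", "label"], header=None)
        pos = frozenset(
            (str(r.disease), str(r.mirna)) for r in df.itertuples() if int(r.label) == 1
        )
        neg = frozenset(
            (str(r.disease), str(r.mirna)) for r in df.itertuples() if int(r.label) == 0
        )
        return cls(pos, neg)


@dataclass(frozen=True)
class ROCResult:
    """Confusion-table sweep and area under the ROC curve."""

    table: pd.DataFrame  # threshold, tp, fp, tn, fn, sensitivity, specificity
    auc: float


def roc_auc_from_scores(
    pos_scores: Sequence[float], neg_scores: Sequence[float]
) -> ROCResult:
    """ROC sweep for p-value-like scores (smaller = stronger prediction).

    Thresholds run over all distinct scores plus a below-minimum sentinel,
    predicting positive at score ≤ δ; equal scores move together, so ties
    contribute diagonal ROC segments and the trapezoidal AUC equals the
    concordance statistic with half-credit for ties.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need scores for both positives and negatives")
    all_scores = np.concatenate([pos, neg])
    thresholds = np.concatenate(
        [[np.min(all_scores) - 1.0], np.unique(all_scores)]
    )
    rows = []
    for delta in thresholds:
        tp = int((pos <= delta).sum())
        fn = pos.size - tp
        fp = int((neg <= delta).sum())
        tn = neg.size - fp
        rows.append(
            {
                "threshold": float(delta), "tp": tp, "fp": fp, "tn": tn,
                "fn": fn,
                "sensitivity": tp / (tp + fn),
                "specificity": tn / (tn + fp),
            }
        )
    table = pd.DataFrame(rows)
    fpr = 1.0 - table["specificity"].to_numpy()
    tpr = table["sensitivity"].to_numpy()
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(table, auc)


def roc_auc(
    records: Sequence[AssociationRecord], labels: LabeledPairs
) -> ROCResult:
    """ROC/AUC of the permutation p-values against labeled pairs.

    Every labeled pair must have a scored record; missing pairs are
    reported in the error.
    """
    scores: Mapping[tuple[str, str], float] = {
        (r.disease_id, r.mirna_id): r.p_value for r in records
    }
    missing = sorted(
        p for p in (labels.positives | labels.negatives) if p not in scores
    )
    if missing:
        raise ValueError(f"labeled pairs without association records: {missing[:10]}")
    pos = [scores[p] for p in sorted(labels.positives)]
    neg = [scores[p] for p in sorted(labels.negatives)]
    return roc_auc_from_scores(pos, neg)


def hypergeometric_baseline(
    disease: GeneSet, targets: GeneSet, net: InteractionNetwork
) -> float:
    """Upper-tail hypergeometric p-value of the target/disease-gene overlap.

    Population = the N network genes; successes = in-network disease genes;
    draws = in-network targets; P(X >= observed overlap). Captures direct
    overlap only — the comparison point for the propagation-based score.
    """
    dg = {g for g in disease.members if g in net}
    tg = {g for g in targets.members if g in net}
    if not dg or not tg:
        raise ValueError("both gene sets must intersect the network")
    overlap = len(dg & tg)
    return float(stats.hypergeom.sf(overlap - 1, net.N, len(dg), len(tg)))
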