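# Methods notes

## Model and procedure

The package scores a miRNA–disease pair by how strongly the miRNA's
target genes (TG, n₁ genes) and the disease's causal genes (DG, n₂
genes) point at each other under network propagation, then calibrates
that score against degree-preserving network randomizations.

1. **Propagation.** Random walk with restart on the largest connected
   component of the PPI network: p ← (1−α)Wp + αp₀, W the
   column-normalized adjacency, p₀ uniform over the seed set. The fixed
   point exists and is unique for α ∈ (0,1) because (1−α)W is a
   contraction; the iterate conserves probability mass at every step
   (columns of W sum to 1). Genes in components with no seed receive
   exactly 0.
2. **Enrichment.** Rank all N genes by steady-state probability
   (descending; ties broken by ascending gene identifier so results are
   deterministic). Walk the ranking; the running sum gains (N−n)/n on
   query-set genes and loses n/(N−n) otherwise; ES is the maximum
   prefix value. ES₁ scans the targets in the disease-seeded ranking,
   ES₂ scans the disease genes in the target-seeded ranking;
   ES = β·ES₁ + (1−β)·ES₂.
3. **Significance.** Re-score the pair on each member of an ensemble of
   edge-switched networks (identical degree sequence, structure
   otherwise destroyed); p = k/n_null with k the count of null scores ≥
   observed (ties count, so p is never optimistically small; p = 0 is
   possible and reported as such, with k stored).
4. **Network construction and analysis.** Pairs with p strictly below δ
   form a bipartite network analyzed for degrees, per-class average
   degree, BD/BH class modularity, and two-way hierarchically clustered
   co-modules.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| α (restart) | 0.7 | walker locality; ranking performance is stable for α in 0.5–0.9, so the center of that band is used |
| tol, max_iter | 1e-10 (L1), 1000 | with α=0.7 the contraction factor is 0.3, so ~20 iterations suffice; the cap only matters for α near 0 |
| β (direction weight) | 0.5 | both propagation directions weighted equally |
| δ (edge threshold) | 0.05 | strict (p < δ); δ changes how many pairs connect, never the p-value ordering within a disease |
| n_null | 1000 (library), 100 in tests | permutation resolution is 1/n_null; tests and the acceptance script use 100 to keep desk-scale runs in seconds |
| swaps per edge | 10 | attempted double-edge swaps per edge, standard Maslov–Sneppen mixing; attempts creating self-loops or duplicate edges are rejected and counted |
| vote filter | ≥ 3 distinct databases | evidence reliability filter for (miRNA, gene) target pairs |
| annotation filter | > 5 in-network genes (miRNAs), > 0 (diseases) | sets too small to score meaningfully are dropped; strict inequality |

## Numerical choices

- **Normalization**: column-normalized adjacency (each neighbor of gene
  j receives 1/deg(j)); the symmetric D^{-1/2}AD^{-1/2} variant is a
  known alternative and was deliberately not used — the column form is
  the standard walk formulation in gene-prioritization work.
- **Zero-degree genes** get an implicit self-loop column so the
  probability vector remains a distribution on any input (relevant only
  for degenerate inputs; largest-component extraction and
  degree-preserving randomization never produce them).
- **Tie-breaks**: ranking ties by ascending gene ID; hierarchical
  clustering follows scipy's deterministic merge order on the given
  matrix ordering; the bipartite edge criterion is strictly p < δ, so
  ties at δ are excluded.
- **ES without positive deviation** (possible in tiny instances): the
  maximum — a negative number — is returned with a warning rather than
  clamped, keeping the statistic a pure prefix maximum.
- **ES increments as defined** sum to N−2n at the full prefix, not 0;
  this is intentionally not the zero-sum GSEA normalization.
- **Cost**: per network, one sparse propagation per seed set serves all
  pairs, so an all-pairs run over R null networks costs
  (R+1)·(D+M) propagations rather than 2·(R+1)·D·M; a transparency test
  verifies the cached path equals per-pair recomputation exactly.

## BD/BH (reconstruction)

The exact published formulas for the paired bipartite modularity
measures are not available; the implementation uses a shared-neighbor
ratio that satisfies every qualitative property claimed for them. With
s(dᵢ,dⱼ) the number of miRNAs linked to both diseases:
BD = mean s over within-class disease pairs ÷ mean s over all disease
pairs; BH = mean s over (in-class, out-of-class) pairs ÷ the same
denominator. BD > 1 and BH < 1 indicate class-specific regulator
sharing; random class labels give BD ≈ 1 in expectation (verified by a
label-permutation test). These values should be read as this package's
definition, not as the original measure.

## Synthetic data: what it emulates, what it does not

The generator produces a preferential-attachment network (hub-dominated
degree distribution, like a curated interactome; a configuration-model
alternative was considered and dropped as redundant for the properties
under test), disease modules sampled from seeded breadth-first
neighborhoods (module_cohesion mixes in uniform genes), planted
positive miRNAs whose targets fall near their disease module with
probability signal_fraction, and disease classes that share part of a
class-level neighborhood (within_class_regulator_overlap). Target
placement is either "within" (distance ≤ 1 of the module, the default:
targets may be disease genes) or "adjacent" (frontier only: proximity
signal with zero overlap, which the hypergeometric baseline cannot
see). Study-scale defaults (400–500 genes, 10 diseases of ~12 genes,
20–40 miRNAs of 15 targets, n_null = 100) are a desk-scale analog of
the real setting (9028 genes, 269 diseases, 499 miRNAs, n_null = 1000)
with roughly preserved set-size-to-network ratios.

What passing tests on this data do **not** show: real interactomes have
study bias, false edges, and community structure beyond degree; real
disease gene sets overlap across diseases; real target predictions have
correlated errors across databases. Synthetic recovery AUC is an
internal-consistency check of the machinery, not an estimate of
performance on curated data.

## Known limitations

- **Null anti-conservativeness under modular disease sets.** The
  permutation null randomizes the network, not the gene sets. A disease
  whose genes form a tight module scores high ES₂ on the real network
  against any miRNA, because randomization destroys the module. With
  cohesive synthetic modules and purely random targets, ~10% of pairs
  fall below p = 0.05. Calibration (uniform p-values) holds under the
  complete null — unstructured disease sets and unstructured targets —
  which is what the calibration test runs. Consumers should read p as
  "surprise relative to a degree-matched random interactome", not as a
  pair-specific false-positive rate; no multiple-testing correction is
  applied, by design.
- **Pooled-AUC spread.** Planted-signal recovery at the default study
  scale varies substantially across generator seeds (roughly 0.67–0.91
  pooled over all diseases) because per-disease difficulty differs —
  the same reason per-disease performance spreads widely in real
  evaluations. The acceptance check runs the default-seed study.
- **Confusion-matrix semantics.** Standard definitions are used
  (negative calls at p > δ), which are the ones consistent with
  sensitivity = TP/(TP+FN) and specificity = TN/(TN+FP).
- Edge switching preserves degrees but not connectivity; propagation on
  a disconnected randomized network is well-defined (unseeded
  components get zero mass), so no connectivity repair is attempted.
- Gene identifiers are opaque strings; no identifier mapping or isoform
  handling is performed.
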