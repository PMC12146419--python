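"""Intrinsic miRNA similarities.

Four similarity layers feed the predictor:

* **Sequence similarity** — Smith–Waterman local alignment scores,
  normalised as ``SW(m1,m2) = sp(m1,m2) / sqrt(sp(m1,m1) * sp(m2,m2))``.
* **Disease semantic similarity** — each disease contributes ``Δ^k`` to its
  descendants, where ``k`` is the shortest child→parent distance in the
  disease DAG (MeSH-style); two diseases are compared through their shared
  ancestors.
* **miRNA functional similarity** — diseases annotated to the two miRNAs
  are matched best-against-best and averaged.
* **GIP kernel similarity** — a Gaussian kernel on rows of the binary
  miRNA–disease adjacency with bandwidth scaled by the mean squared
  profile norm.

Functional and GIP similarity are fused entrywise: functional wins where it
is positive, GIP fills the zeros (miRNAs without disease annotations).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from Bio import Align
from scipy.spatial.distance import squareform, pdist

from .datamodel import AssociationNetwork, DataModelError, DiseaseDAG, MirnaSet, SimilarityMatrix


@dataclass(frozen=True)
class ScoringScheme:
    """Nucleotide scoring for Smith–Waterman local alignment.

    ``gap_open`` is charged for the first position of a gap and
    ``gap_extend`` for each subsequent position (affine gaps).
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch > 0:
            raise ValueError("mismatch score must be <= 0")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")


def _make_aligner(s: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = s.match
    aligner.mismatch_score = s.mismatch
    aligner.open_gap_score = s.gap_open
    aligner.extend_gap_score = s.gap_extend
    return aligner


def smith_waterman_score(a: str, b: str, scheme: ScoringScheme | None = None) -> float:
    """Optimal local-alignment score of two RNA sequences (affine gaps)."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    scheme = scheme or ScoringScheme()
    return float(_make_aligner(scheme).score(a, b))


def sequence_similarity_matrix(
    mirnas: MirnaSet, scheme: ScoringScheme | None = None
) -> SimilarityMatrix:
    """Normalised pairwise Smith–Waterman similarity over a miRNA set."""
    scheme = scheme or ScoringScheme()
    aligner = _make_aligner(scheme)
    n = len(mirnas.ids)
    seqs = [mirnas.sequences[m] for m in mirnas.ids]
    self_scores = np.array([aligner.score(s, s) for s in seqs])
    assert (self_scores > 0).all(), "self-alignment score must be positive"
    vals = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            sp = aligner.score(seqs[i], seqs[j])
            vals[i, j] = vals[j, i] = sp / np.sqrt(self_scores[i] * self_scores[j])
    return SimilarityMatrix(mirnas.ids, vals)


@dataclass(frozen=True)
class SemanticValueMap:
    """Decayed contributions ``Δ^k`` of a disease's ancestors (and itself)."""

    anchor: str
    values: Mapping[str, float]


def semantic_contributions(dag: DiseaseDAG, disease: str, delta: float = 0.5) -> SemanticValueMap:
    """``SV(t) = Δ^k`` with ``k`` the shortest child→parent distance from the anchor."""
    if not 0 < delta < 1:
        raise ValueError("delta must lie in (0, 1)")
    layers = dag.ancestor_layers(disease)  # raises on unknown disease
    return SemanticValueMap(disease, {t: delta**k for t, k in layers.items()})


def semantic_value(sv: SemanticValueMap) -> float:
    """Total semantic value: the sum of all ancestor contributions (>= 1)."""
    return float(sum(sv.values.values()))


def disease_semantic_similarity(
    dag: DiseaseDAG, a: str, b: str, delta: float = 0.5
) -> float:
    """Shared-ancestor similarity of two diseases, in [0, 1]."""
    sva = semantic_contributions(dag, a, delta)
    svb = semantic_contributions(dag, b, delta)
    common = set(sva.values) & set(svb.values)
    num = sum(sva.values[t] + svb.values[t] for t in common)
    return float(num / (semantic_value(sva) + semantic_value(svb)))


def disease_set_similarity(
    dag: DiseaseDAG, disease: str, disease_set: Iterable[str],
    delta: float = 0.5, agg: str = "max",
) -> float:
    """Similarity of one disease to a set: best (default) or mean match."""
    ds = list(disease_set)
    if not ds:
        raise ValueError("disease set must be non-empty")
    scores = [disease_semantic_similarity(dag, disease, t, delta) for t in ds]
    if agg == "max":
        return float(max(scores))
    if agg == "mean":
        return float(np.mean(scores))
    raise ValueError(f"unknown aggregation {agg!r}")


def _dss_matrix(dag: DiseaseDAG, diseases: list[str], delta: float) -> np.ndarray:
    """Dense pairwise disease semantic similarity over ``diseases``."""
    svs = [semantic_contributions(dag, d, delta) for d in diseases]
    sems = np.array([semantic_value(sv) for sv in svs])
    n = len(diseases)
    out = np.eye(n)
    for i in range(n):
        vi = svs[i].values
        for j in range(i + 1, n):
            vj = svs[j].values
            common = vi.keys() & vj.keys()
            if common:
                num = sum(vi[t] + vj[t] for t in common)
                out[i, j] = out[j, i] = num / (sems[i] + sems[j])
    return out


def functional_similarity_matrix(
    dag: DiseaseDAG, assoc: AssociationNetwork, delta: float = 0.5, agg: str = "max"
) -> SimilarityMatrix:
    """miRNA functional similarity from disease annotation sets.

    For miRNAs with disease sets DT1 (n1) and DT2 (n2), each disease is
    matched against the other set (``agg`` = max by default) and the 2-way
    sums are averaged over n1 + n2.  miRNAs with no annotated disease get
    zero off-diagonal similarity (the GIP kernel fills those via fusion).
    """
    if assoc.entity_kind != "disease":
        raise DataModelError("functional similarity requires a disease network")
    unknown = [d for d in assoc.entity_ids if d not in dag.nodes]
    if unknown:
        raise DataModelError(f"disease {unknown[0]!r} in network but not in DAG")
    diseases = list(assoc.entity_ids)
    dss = _dss_matrix(dag, diseases, delta)
    sets = [np.nonzero(assoc.adjacency[i])[0] for i in range(len(assoc.mirna_ids))]
    n = len(assoc.mirna_ids)
    vals = np.eye(n)
    reduce = np.max if agg == "max" else np.mean
    for i in range(n):
        si = sets[i]
        if si.size == 0:
            continue
        for j in range(i + 1, n):
            sj = sets[j]
            if sj.size == 0:
                continue
            block = dss[np.ix_(si, sj)]
            vals[i, j] = vals[j, i] = (
                reduce(block, axis=1).sum() + reduce(block, axis=0).sum()
            ) / (si.size + sj.size)
    return SimilarityMatrix(assoc.mirna_ids, vals)


def gip_similarity_matrix(assoc: AssociationNetwork, gamma_prime: float = 1.0) -> SimilarityMatrix:
    """Gaussian interaction-profile kernel over the rows of a bipartite adjacency.

    The bandwidth is ``γ = γ' / mean_i ||y_i||²`` so that the kernel scale
    adapts to the density of the network.
    """
    y = assoc.adjacency.astype(float)
    mean_sq = float((y**2).sum(axis=1).mean())
    if mean_sq == 0:
        raise DataModelError("all-zero adjacency: GIP bandwidth undefined")
    gamma = gamma_prime / mean_sq
    sq = squareform(pdist(y, metric="sqeuclidean")) if len(y) > 1 else np.zeros((1, 1))
    vals = np.exp(-gamma * sq)
    np.fill_diagonal(vals, 1.0)
    return SimilarityMatrix(assoc.mirna_ids, vals)


def fuse_similarities(fs: SimilarityMatrix, gip: SimilarityMatrix) -> SimilarityMatrix:
    """Entrywise fusion: functional similarity where positive, else GIP."""
    if fs.ids != gip.ids:
        raise DataModelError("similarity matrices are indexed by different miRNA sets")
    return SimilarityMatrix(fs.ids, np.where(fs.values > 0, fs.values, gip.values))
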