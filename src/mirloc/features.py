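"""Feature construction: from raw inputs to the five fusion branches.

Branch inputs to the classifier head:

* ``seq`` — rows of the normalised Smith–Waterman similarity matrix;
* ``disease`` / ``drug`` / ``mrna_net`` — node2vec embeddings of the three
  bipartite networks (later refined in-model by hypergraph convolution);
* ``mrna_loc`` — the 7-dim propagated mRNA localisation evidence.

The fused functional/GIP similarity is computed from the disease branch
and drives hypergraph construction for all three network branches.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datamodel import FeatureMatrix, SimilarityMatrix
from .dataset import LocalizationDataset
from .embedding import Node2vecParams, embed_network
from .hypergraph import build_incidence, normalized_operator
from .localization import propagate_mrna_localization
from .similarity import (
    ScoringScheme,
    fuse_similarities,
    functional_similarity_matrix,
    gip_similarity_matrix,
    sequence_similarity_matrix,
)

#: Branch evaluation order; also the token order in the fusion head.
BRANCH_ORDER = ("seq", "disease", "drug", "mrna_net", "mrna_loc")

#: Branches whose features pass through hypergraph refinement.
HYPERGRAPH_BRANCHES = ("disease", "drug", "mrna_net")


@dataclass(frozen=True)
class FeatureParams:
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    node2vec: Node2vecParams = field(default_factory=Node2vecParams)
    delta: float = 0.5          # semantic decay per DAG layer
    gamma_prime: float = 1.0    # GIP bandwidth scale
    set_agg: str = "max"        # disease-vs-set aggregation
    tau: float = 0.5            # similarity hyperedge threshold
    fallback_k: int | None = 5
    loc_mode: str = "mean"


@dataclass(frozen=True)
class FeatureBundle:
    """Everything the fusion model consumes, aligned to one miRNA order."""

    mirna_ids: tuple[str, ...]
    branches: dict[str, FeatureMatrix]
    operators: dict[str, np.ndarray]  # branch -> hypergraph operator A_hat
    seq_sim: SimilarityMatrix
    fused_sim: SimilarityMatrix


def build_features(
    dataset: LocalizationDataset, params: FeatureParams | None = None
) -> FeatureBundle:
    """Run the full feature pipeline on one dataset."""
    params = params or FeatureParams()
    seq_sim = sequence_similarity_matrix(dataset.mirnas, params.scoring)
    fs = functional_similarity_matrix(
        dataset.dag, dataset.disease_net, params.delta, params.set_agg
    )
    gip = gip_similarity_matrix(dataset.disease_net, params.gamma_prime)
    fused = fuse_similarities(fs, gip)

    branches: dict[str, FeatureMatrix] = {
        "seq": FeatureMatrix(dataset.mirnas.ids, seq_sim.values, "seq"),
        "mrna_loc": propagate_mrna_localization(
            dataset.mrna_net, dataset.mrna_loc, params.loc_mode
        ),
    }
    nets = {"disease": dataset.disease_net, "drug": dataset.drug_net,
            "mrna_net": dataset.mrna_net}
    operators: dict[str, np.ndarray] = {}
    for offset, (branch, net) in enumerate(nets.items()):
        # decorrelate the three embedding runs while staying seed-reproducible
        n2v = replace(params.node2vec, seed=params.node2vec.seed + offset)
        branches[branch] = embed_network(net, n2v)
        hg = build_incidence(fused, net, params.tau, params.fallback_k)
        operators[branch] = normalized_operator(hg)
    return FeatureBundle(dataset.mirnas.ids, branches, operators, seq_sim, fused)
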