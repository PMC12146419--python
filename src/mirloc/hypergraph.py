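"""Hypergraph construction and convolution over miRNA nodes.

Hyperedges come from two sources: (1) for each miRNA, the group of miRNAs
whose fused similarity to it reaches a threshold tau (with a top-k fallback
so no anchor is left without neighbours), and (2) for each entity in a
bipartite association network, the set of miRNAs linked to it.  Hyperedges
with fewer than two members carry no higher-order information and are
dropped; duplicate member sets are merged.

The convolution operator is the symmetric normalisation

    A_hat = D_v^{-1/2} H W B^{-1} H^T D_v^{-1/2}

with H the incidence matrix, W diagonal hyperedge weights, B the hyperedge
degrees (column sums) and D_v the node degrees (row sums of H W).  Nodes in
no hyperedge pass through unchanged (identity row), so isolated miRNAs keep
their raw embeddings.  Layer-wise propagation is
``X^{l+1} = sigma(A_hat X^l W^l)`` with ReLU on hidden layers and a linear
final layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import AssociationNetwork, DataModelError, SimilarityMatrix


@dataclass(frozen=True)
class Hypergraph:
    node_ids: tuple[str, ...]
    incidence: np.ndarray  # |nodes| x |hyperedges|, binary
    edge_weights: np.ndarray
    edge_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        h = np.asarray(self.incidence)
        if h.shape[0] != len(self.node_ids) or h.shape[1] != len(self.edge_labels):
            raise DataModelError("incidence shape does not match node/edge lists")
        if h.size and not np.isin(h, (0, 1)).all():
            raise DataModelError("incidence must be binary")
        if (h.sum(axis=0) < 2).any():
            raise DataModelError("every hyperedge must contain at least 2 nodes")
        if (np.asarray(self.edge_weights) <= 0).any():
            raise DataModelError("hyperedge weights must be positive")
        object.__setattr__(self, "incidence", h.astype(float))
        object.__setattr__(self, "edge_weights", np.asarray(self.edge_weights, dtype=float))


@dataclass(frozen=True)
class HGConvParams:
    layers: int = 3
    hidden_dim: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.layers <= 8:
            raise ValueError("layers must be in [1, 8]")


def build_incidence(
    sim: SimilarityMatrix,
    assoc: AssociationNetwork,
    tau: float = 0.5,
    fallback_k: int | None = 5,
) -> Hypergraph:
    """Build the miRNA hypergraph from fused similarity and one association network.

    One similarity hyperedge is anchored at each miRNA ``i``:
    ``{i} ∪ {j : sim(i,j) >= tau}``.  If an anchor has no neighbour at tau
    and ``fallback_k`` is set, its ``fallback_k`` most-similar positive
    neighbours are used instead.  One association hyperedge per entity
    groups the miRNAs linked to it.  Size-<2 hyperedges are dropped and
    duplicate member sets merged (first label wins).
    """
    if sim.ids != assoc.mirna_ids:
        raise DataModelError("similarity and association networks index different miRNAs")
    if not 0 < tau < 1:
        raise ValueError("tau must lie in (0, 1)")
    n = len(sim.ids)
    columns: dict[frozenset[int], str] = {}

    def add_edge(members: frozenset[int], label: str) -> None:
        if len(members) >= 2 and members not in columns:
            columns[members] = label

    s = sim.values
    for i in range(n):
        nbrs = {j for j in np.nonzero(s[i] >= tau)[0] if j != i}
        if not nbrs and fallback_k:
            order = np.argsort(-s[i])
            nbrs = {int(j) for j in order if j != i and s[i, j] > 0}
            nbrs = set(list(sorted(nbrs, key=lambda j: (-s[i, j], j)))[:fallback_k])
        add_edge(frozenset(nbrs | {i}), f"sim:{sim.ids[i]}")
    for j, entity in enumerate(assoc.entity_ids):
        members = frozenset(int(i) for i in np.nonzero(assoc.adjacency[:, j])[0])
        add_edge(members, f"assoc:{entity}")

    if not columns:
        raise DataModelError(
            "no hyperedge with >= 2 members; lower tau or densify the association network"
        )
    labels = tuple(columns.values())
    h = np.zeros((n, len(columns)), dtype=float)
    for col, members in enumerate(columns):
        h[list(members), col] = 1.0
    return Hypergraph(sim.ids, h, np.ones(len(columns)), labels)


def normalized_operator(hg: Hypergraph) -> np.ndarray:
    """Symmetrically normalised hypergraph smoothing operator A_hat.

    Nodes belonging to no hyperedge get an identity row/column so their
    features pass through convolution unchanged.
    """
    h = hg.incidence
    w = hg.edge_weights
    b = h.sum(axis=0)  # hyperedge degrees, >= 2 by construction
    dv = (h * w).sum(axis=1)  # node degrees
    isolated = dv == 0
    dv_inv_sqrt = np.divide(1.0, np.sqrt(dv), out=np.zeros_like(dv), where=~isolated)
    a_hat = (h * (w / b)) @ h.T
    a_hat = dv_inv_sqrt[:, None] * a_hat * dv_inv_sqrt[None, :]
    a_hat[isolated, isolated] = 1.0
    return a_hat


def hgconv_forward(
    a_hat: np.ndarray,
    x0: np.ndarray,
    weights: list[np.ndarray],
    final_linear: bool = True,
) -> np.ndarray:
    """Stacked hypergraph convolution: ReLU on hidden layers, linear final layer."""
    x = np.asarray(x0, dtype=float)
    for layer, w in enumerate(weights):
        if x.shape[1] != w.shape[0]:
            raise DataModelError(
                f"layer {layer}: feature width {x.shape[1]} does not match weight rows {w.shape[0]}"
            )
        x = a_hat @ x @ w
        last = layer == len(weights) - 1
        if not (last and final_linear):
            x = np.maximum(x, 0.0)
    return x
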