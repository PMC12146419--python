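"""Node2vec embeddings of the bipartite association networks.

Each miRNA–entity network (disease, drug, mRNA) is turned into an
undirected unweighted graph whose nodes are the miRNAs plus the entities
(namespaced to avoid id collisions).  Second-order biased random walks
(return parameter ``p``, in–out parameter ``q``) generate a corpus that a
skip-gram model with negative sampling turns into vectors; only the miRNA
rows are kept, ordered by the canonical miRNA order.

With ``p = q = 1`` the walk is a plain first-order random walk and a fully
vectorised sampler is used; other settings take the explicit second-order
path.  Training is single-threaded and reproducible from the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import coo_matrix

from .datamodel import AssociationNetwork, FeatureMatrix

logger = logging.getLogger(__name__)

_BRANCH_BY_KIND = {"disease": "disease", "drug": "drug", "mrna": "mrna_net"}


@dataclass(frozen=True)
class Node2vecParams:
    dim: int = 128
    num_walks: int = 10
    walk_length: int = 80
    window: int = 10
    p: float = 1.0
    q: float = 1.0
    epochs: int = 5
    negative: int = 5
    batch_size: int = 4096
    lr: float = 0.025
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim <= 0 or self.num_walks <= 0 or self.walk_length < 2:
            raise ValueError("dim and num_walks must be positive, walk_length >= 2")
        if self.p <= 0 or self.q <= 0:
            raise ValueError("p and q must be positive")


def build_bipartite_graph(assoc: AssociationNetwork) -> nx.Graph:
    """Undirected graph on namespaced miRNA and entity nodes, one edge per association."""
    g = nx.Graph()
    g.add_nodes_from(f"mirna::{m}" for m in assoc.mirna_ids)
    g.add_nodes_from(f"{assoc.entity_kind}::{e}" for e in assoc.entity_ids)
    rows, cols = np.nonzero(assoc.adjacency)
    g.add_edges_from(
        (f"mirna::{assoc.mirna_ids[i]}", f"{assoc.entity_kind}::{assoc.entity_ids[j]}")
        for i, j in zip(rows, cols)
    )
    return g


def _csr_adjacency(graph: nx.Graph, nodes: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Neighbour lists in CSR form (indptr, indices), neighbours sorted."""
    pos = {n: i for i, n in enumerate(nodes)}
    indptr = [0]
    indices: list[int] = []
    for n in nodes:
        nbrs = sorted(pos[m] for m in graph.neighbors(n))
        indices.extend(nbrs)
        indptr.append(len(indices))
    return np.asarray(indptr, dtype=np.int64), np.asarray(indices, dtype=np.int64)


def _first_order_walks(indptr, indices, n_nodes, params, rng) -> list[np.ndarray]:
    """Vectorised uniform random walks (the p = q = 1 case)."""
    walks: list[np.ndarray] = []
    deg = np.diff(indptr)
    for _ in range(params.num_walks):
        cur = np.arange(n_nodes)
        trace = np.full((params.walk_length, n_nodes), -1, dtype=np.int64)
        trace[0] = cur
        alive = deg[cur] > 0
        for step in range(1, params.walk_length):
            if not alive.any():
                break
            act = np.nonzero(alive)[0]
            c = cur[act]
            offs = (rng.random(len(act)) * deg[c]).astype(np.int64)
            nxt = indices[indptr[c] + offs]
            cur[act] = nxt
            trace[step, act] = nxt
            alive[act] = deg[nxt] > 0
        for col in range(n_nodes):
            w = trace[:, col]
            walks.append(w[w >= 0])
    return walks


def _second_order_walk(indptr, indices, start, params, rng) -> np.ndarray:
    walk = [start]
    deg = indptr[start + 1] - indptr[start]
    if deg == 0:
        return np.asarray(walk)
    prev = -1
    cur = start
    for _ in range(params.walk_length - 1):
        nbrs = indices[indptr[cur]: indptr[cur + 1]]
        if len(nbrs) == 0:
            break
        if prev < 0:
            weights = np.ones(len(nbrs))
        else:
            prev_nbrs = indices[indptr[prev]: indptr[prev + 1]]
            weights = np.where(np.isin(nbrs, prev_nbrs), 1.0, 1.0 / params.q)
            weights[nbrs == prev] = 1.0 / params.p
        weights /= weights.sum()
        prev, cur = cur, int(rng.choice(nbrs, p=weights))
        walk.append(cur)
    return np.asarray(walk)


def biased_random_walks(graph: nx.Graph, params: Node2vecParams) -> list[list[str]]:
    """``num_walks`` walks per node; reproducible bit-for-bit from the seed."""
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    nodes = sorted(graph.nodes)
    indptr, indices = _csr_adjacency(graph, nodes)
    rng = np.random.default_rng(params.seed)
    if params.p == 1.0 and params.q == 1.0:
        walks = _first_order_walks(indptr, indices, len(nodes), params, rng)
    else:
        walks = [
            _second_order_walk(indptr, indices, start, params, rng)
            for _ in range(params.num_walks)
            for start in range(len(nodes))
        ]
    return [[nodes[i] for i in w] for w in walks]


def _walk_pairs(walks: list[np.ndarray], window: int) -> tuple[np.ndarray, np.ndarray]:
    centers: list[np.ndarray] = []
    contexts: list[np.ndarray] = []
    for w in walks:
        for d in range(1, min(window, len(w) - 1) + 1):
            centers.append(w[:-d])
            contexts.append(w[d:])
            centers.append(w[d:])
            contexts.append(w[:-d])
    if not centers:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(centers), np.concatenate(contexts)


def _scatter_sub(w: np.ndarray, idx: np.ndarray, grad: np.ndarray) -> None:
    """w[idx] -= grad, averaging over duplicate indices within the batch.

    Hub nodes (e.g. a drug linked to many miRNAs) can occur thousands of
    times in one batch; summing their per-pair gradients at full learning
    rate diverges, so each row takes the mean gradient of its occurrences.
    """
    counts = np.bincount(idx, minlength=w.shape[0]).astype(float)
    m = coo_matrix(
        (1.0 / counts[idx], (idx, np.arange(len(idx)))), shape=(w.shape[0], len(idx))
    ).tocsr()
    w -= m @ grad


def skipgram_embed(
    walks: list[list[str]], params: Node2vecParams, vocab: list[str] | None = None
) -> dict[str, np.ndarray]:
    """Skip-gram with negative sampling over walk windows.

    Every node in ``vocab`` (default: every node appearing in the walks)
    receives a vector; nodes never visited keep a zero vector.
    """
    if not walks:
        raise ValueError("no walks to train on")
    if vocab is None:
        vocab = sorted({n for w in walks for n in w})
    pos = {n: i for i, n in enumerate(vocab)}
    nv = len(vocab)
    iwalks = [np.asarray([pos[n] for n in w], dtype=np.int64) for w in walks]
    centers, contexts = _walk_pairs(iwalks, params.window)

    rng = np.random.default_rng(params.seed)
    w_in = (rng.random((nv, params.dim)) - 0.5) / params.dim
    w_out = np.zeros((nv, params.dim))

    counts = np.bincount(np.concatenate(iwalks) if iwalks else np.empty(0, int), minlength=nv)
    visited = np.zeros(nv, dtype=bool)
    visited[centers] = True  # isolated nodes never enter a context pair
    if centers.size:
        noise = counts.astype(float) ** 0.75
        noise /= noise.sum()
        n_pairs = len(centers)
        total_batches = max(1, params.epochs * int(np.ceil(n_pairs / params.batch_size)))
        batch_no = 0
        for _ in range(params.epochs):
            order = rng.permutation(n_pairs)
            for lo in range(0, n_pairs, params.batch_size):
                sel = order[lo: lo + params.batch_size]
                c, o = centers[sel], contexts[sel]
                neg = rng.choice(nv, size=(len(sel), params.negative), p=noise)
                lr = params.lr * max(1e-4 / params.lr, 1.0 - batch_no / total_batches)
                batch_no += 1
                vc, vo, vn = w_in[c], w_out[o], w_out[neg]
                g_pos = _sigmoid(np.einsum("bd,bd->b", vc, vo)) - 1.0
                g_neg = _sigmoid(np.einsum("bd,bkd->bk", vc, vn))
                grad_c = g_pos[:, None] * vo + np.einsum("bk,bkd->bd", g_neg, vn)
                grad_o = g_pos[:, None] * vc
                grad_n = g_neg[..., None] * vc[:, None, :]
                _scatter_sub(w_in, c, lr * grad_c)
                _scatter_sub(w_out, o, lr * grad_o)
                _scatter_sub(w_out, neg.ravel(), lr * grad_n.reshape(-1, params.dim))
    unvisited = int((~visited).sum())
    if unvisited:
        logger.info("skipgram_embed: %d nodes never visited; zero vectors", unvisited)
        w_in[~visited] = 0.0
    return {n: w_in[pos[n]] for n in vocab}


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def embed_network(assoc: AssociationNetwork, params: Node2vecParams) -> FeatureMatrix:
    """Node2vec feature matrix for the miRNA rows of one association network."""
    graph = build_bipartite_graph(assoc)
    walks = biased_random_walks(graph, params)
    vectors = skipgram_embed(walks, params, vocab=sorted(graph.nodes))
    values = np.stack([vectors[f"mirna::{m}"] for m in assoc.mirna_ids])
    return FeatureMatrix(assoc.mirna_ids, values, _BRANCH_BY_KIND[assoc.entity_kind])
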