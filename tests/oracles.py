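"""Independent brute-force oracles used to pin expected values.

Each oracle is a literal, unoptimised evaluation of the defining formula,
written without reference to the package implementation it checks.
"""

from __future__ import annotations

import numpy as np

NEG = -1e18


def sw_affine_dp(a: str, b: str, match: float, mismatch: float,
                 gap_open: float, gap_extend: float) -> float:
    """Quadratic Gotoh DP for local alignment with affine gaps.

    ``gap_open`` is the score of the first gapped position, ``gap_extend``
    of each subsequent one (a length-L gap scores open + (L-1)*extend).
    """
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)  # gap in b (consume a)
    Iy = np.full((n + 1, m + 1), NEG)  # gap in a (consume b)
    M[0, :] = M[:, 0] = 0.0
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(0.0, max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]) + s)
            Ix[i, j] = max(M[i - 1, j] + gap_open, Ix[i - 1, j] + gap_extend)
            Iy[i, j] = max(M[i, j - 1] + gap_open, Iy[i, j - 1] + gap_extend)
            best = max(best, M[i, j])
    return best


def dag_semantic_similarity(parent_edges: set[tuple[str, str]], a: str, b: str,
                            delta: float) -> float:
    """Literal evaluation of the shared-ancestor similarity via BFS layers."""

    def layers(node: str) -> dict[str, int]:
        dist = {node: 0}
        frontier = [node]
        while frontier:
            nxt = []
            for child in frontier:
                for (c, p) in parent_edges:
                    if c == child and (p not in dist or dist[p] > dist[child] + 1):
                        dist[p] = dist[child] + 1
                        nxt.append(p)
            frontier = nxt
        return dist

    sva = {t: delta**k for t, k in layers(a).items()}
    svb = {t: delta**k for t, k in layers(b).items()}
    common = set(sva) & set(svb)
    sem_a, sem_b = sum(sva.values()), sum(svb.values())
    return sum(sva[t] + svb[t] for t in common) / (sem_a + sem_b)


def gip_entrywise(adjacency: np.ndarray, gamma_prime: float = 1.0) -> np.ndarray:
    """Direct per-entry Gaussian interaction-profile kernel."""
    y = adjacency.astype(float)
    n = len(y)
    gamma = gamma_prime / (np.mean([np.dot(y[i], y[i]) for i in range(n)]))
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            d = y[i] - y[j]
            out[i, j] = np.exp(-gamma * np.dot(d, d))
    return out


def hypergraph_operator_dense(h: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Literal D_v^{-1/2} H W B^{-1} H^T D_v^{-1/2} with identity patch rows."""
    b_deg = np.diag(h.sum(axis=0))
    d_v = np.diag((h @ np.diag(w)).sum(axis=1))
    with np.errstate(divide="ignore"):
        d_inv = np.diag([0.0 if d == 0 else d**-0.5 for d in np.diag(d_v)])
    a = d_inv @ h @ np.diag(w) @ np.linalg.inv(b_deg) @ h.T @ d_inv
    for i in range(len(h)):
        if d_v[i, i] == 0:
            a[i, i] = 1.0
    return a


def attention_loops(q: np.ndarray, k: np.ndarray, v: np.ndarray,
                    wq: np.ndarray, wk: np.ndarray, wv: np.ndarray,
                    wo: np.ndarray, n_heads: int) -> np.ndarray:
    """Loop-based multi-head scaled dot-product attention over tokens."""
    n, tokens, d = q.shape
    dk = d // n_heads
    out = np.zeros((n, tokens, d))
    for s in range(n):
        heads = []
        for h in range(n_heads):
            sl = slice(h * dk, (h + 1) * dk)
            qh = q[s] @ wq[:, sl]
            kh = k[s] @ wk[:, sl]
            vh = v[s] @ wv[:, sl]
            scores = qh @ kh.T / np.sqrt(dk)
            e = np.exp(scores - scores.max(axis=1, keepdims=True))
            att = e / e.sum(axis=1, keepdims=True)
            heads.append(att @ vh)
        out[s] = np.concatenate(heads, axis=1) @ wo
    return out


def auc_pair_counting(y: np.ndarray, s: np.ndarray) -> float:
    """Concordant-pair AUC with ties counted one half."""
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def average_precision_steps(y: np.ndarray, s: np.ndarray) -> float:
    """Step-wise average precision: sum precision at each recall increment."""
    order = np.argsort(-s, kind="stable")
    y = np.asarray(y)[order]
    n_pos = y.sum()
    tp = 0
    total = 0.0
    for rank, label in enumerate(y, start=1):
        if label == 1:
            tp += 1
            total += tp / rank
    return total / n_pos
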