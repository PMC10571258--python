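"""Partition and cover quality / agreement measures.

Agreement between clusterings: NMI and ARI for disjoint partitions,
omega index and set-based overlapping NMI for covers.  Quality of a
clustering against the network: signed modularity Q, modularity density
Qds, and their overlapping extensions with equal-split belonging
coefficients.  Multi-community calls are scored with sensitivity /
specificity / F1 over node-level positives.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from .graph import Cover, Partition, WeightedGraph

__all__ = [
    "ConfusionCounts",
    "nmi",
    "ari",
    "modularity_signed",
    "modularity_density",
    "omega_index",
    "overlapping_nmi",
    "overlapping_quality",
    "multicommunity_f1",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n_nodes(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _aligned_labels(p: Partition, q: Partition) -> tuple[np.ndarray, np.ndarray]:
    if set(p.node_ids) != set(q.node_ids):
        raise ValueError("partitions cover different node sets")
    if p.node_ids == q.node_ids:
        return p.labels, q.labels
    qd = q.as_dict()
    return p.labels, np.array([qd[v] for v in p.node_ids])


def nmi(p: Partition, q: Partition) -> float:
    """Normalized mutual information, arithmetic-mean normalization."""
    a, b = _aligned_labels(p, q)
    return float(normalized_mutual_info_score(a, b, average_method="arithmetic"))


def ari(p: Partition, q: Partition) -> float:
    """Adjusted Rand index (pair counting, permutation-model chance)."""
    a, b = _aligned_labels(p, q)
    return float(adjusted_rand_score(a, b))


# ---------------------------------------------------------------------------
# modularity family


def _split_signs(g: WeightedGraph) -> tuple[sp.csr_array, sp.csr_array]:
    A = g.offdiag()
    return A.maximum(0), -(A.minimum(0))


def _newman_q(A: sp.csr_array, labels: np.ndarray) -> float:
    """Classic Newman-Girvan Q on a non-negative adjacency (no diagonal)."""
    two_w = A.sum()
    if two_w == 0:
        return 0.0
    K = labels.max() + 1
    n = A.shape[0]
    H = sp.csr_array((np.ones(n), (np.arange(n), labels)), shape=(n, K))
    intra = np.asarray((H.T @ A @ H).todense()).diagonal()
    strength = np.bincount(labels, weights=np.asarray(A.sum(axis=1)).ravel(), minlength=K)
    return float(np.sum(intra / two_w - (strength / two_w) ** 2))


def modularity_signed(g: WeightedGraph, p: Partition) -> float:
    """Signed modularity: positive- and negative-subgraph Q combined.

    Q = (2w+/(2w+ + 2w-)) Q+ - (2w-/(2w+ + 2w-)) Q-, where Q+/- are
    classic Q of the positive / negated-negative subgraphs and w+/- the
    corresponding total weights.  Reduces exactly to classic Q when the
    network has no negative edges.
    """
    if g.n_nodes == 0:
        raise ValueError("empty graph")
    labels = _labels_for_graph(g, p)
    Ap, An = _split_signs(g)
    wp, wn = Ap.sum() / 2.0, An.sum() / 2.0
    if wp + wn == 0:
        return 0.0
    qp = _newman_q(Ap, labels) if wp > 0 else 0.0
    qn = _newman_q(An, labels) if wn > 0 else 0.0
    return float((wp * qp - wn * qn) / (wp + wn))


def _labels_for_graph(g: WeightedGraph, p: Partition) -> np.ndarray:
    if set(p.node_ids) != set(g.node_ids):
        raise ValueError("partition does not cover the graph's node set")
    if p.node_ids == g.node_ids:
        return p.labels
    d = p.as_dict()
    return np.array([d[v] for v in g.node_ids])


def _qds_terms(
    A: sp.csr_array, B: np.ndarray, sizes: np.ndarray
) -> float:
    """Split-penalized density-weighted modularity given a belonging
    matrix B (n x K, rows summing to 1) and effective community sizes."""
    two_w = A.sum()
    if two_w == 0:
        return 0.0
    K = B.shape[1]
    M = B.T @ (A @ B)  # K x K weighted (co-)linking, M_cc = 2 * w_in_c
    strength_in = M.diagonal() / 2.0  # w_in_c
    # total belonging-weighted strength attached to c (internal twice)
    attach = np.asarray(B.T @ np.asarray(A.sum(axis=1)).ravel())
    q = 0.0
    for c in range(K):
        n_c = sizes[c]
        if n_c <= 1:
            continue
        d_c = 2.0 * strength_in[c] / (n_c * (n_c - 1.0))
        q += (2.0 * strength_in[c] / two_w) * d_c
        q -= ((attach[c] / two_w) * d_c) ** 2
        for c2 in range(K):
            if c2 == c:
                continue
            n_c2 = sizes[c2]
            if n_c2 == 0:
                continue
            w_cc2 = M[c, c2]
            q -= (w_cc2 / two_w) * (w_cc2 / (n_c * n_c2))
    return float(q)


def modularity_density(g: WeightedGraph, p: Partition) -> float:
    """Modularity density Qds: per-community modularity weighted by
    internal density, with split penalties over community pairs.

    Rewards communities that are both well separated and internally
    dense, which removes the resolution limit of classic Q (small dense
    cliques are no longer absorbed) and penalizes spurious splits of a
    single dense cluster.  Negative edges are dropped with a warning —
    the density terms are only meaningful on non-negative weight.
    """
    labels = _labels_for_graph(g, p)
    K = labels.max() + 1
    sizes = np.bincount(labels, minlength=K).astype(float)
    if np.any(sizes == 0):
        raise ValueError("partition contains an empty community")
    Ap, An = _split_signs(g)
    if An.nnz:
        warnings.warn("negative edges ignored in modularity density")
    n = g.n_nodes
    B = np.zeros((n, K))
    B[np.arange(n), labels] = 1.0
    return _qds_terms(Ap, B, sizes)


# ---------------------------------------------------------------------------
# cover agreement


def _aligned_membership(c1: Cover, c2: Cover) -> tuple[np.ndarray, np.ndarray]:
    if set(c1.node_ids) != set(c2.node_ids):
        raise ValueError("covers span different node sets")
    order = c1.node_ids
    d2 = c2.as_dict()
    m1 = _membership_matrix(c1.memberships)
    m2 = _membership_matrix(tuple(d2[v] for v in order))
    return m1, m2


def _membership_matrix(memberships: tuple[frozenset[int], ...]) -> np.ndarray:
    labels = sorted(set().union(*memberships))
    idx = {l: k for k, l in enumerate(labels)}
    B = np.zeros((len(memberships), len(labels)), dtype=np.int64)
    for i, mem in enumerate(memberships):
        for l in mem:
            B[i, idx[l]] = 1
    return B


def omega_index(c1: Cover, c2: Cover) -> float:
    """Omega index: chance-adjusted pairwise agreement on the *number* of
    shared communities.  Equals the ARI when both covers are disjoint."""
    B1, B2 = _aligned_membership(c1, c2)
    n = B1.shape[0]
    if n < 2:
        return 1.0
    T1 = (B1 @ B1.T)
    T2 = (B2 @ B2.T)
    iu = np.triu_indices(n, k=1)
    t1, t2 = T1[iu], T2[iu]
    n_pairs = len(t1)
    obs = np.mean(t1 == t2)
    # expected agreement: sum over shared-count j of the product of the
    # two marginal frequencies of j
    exp = 0.0
    for j in set(t1.tolist()) | set(t2.tolist()):
        exp += (np.sum(t1 == j) / n_pairs) * (np.sum(t2 == j) / n_pairs)
    if math.isclose(exp, 1.0):
        return 1.0 if math.isclose(obs, 1.0) else 0.0
    return float((obs - exp) / (1.0 - exp))


def _h(p: float) -> float:
    return -p * math.log(p) if p > 0 else 0.0


def _cond_entropy_sets(x: np.ndarray, y: np.ndarray, n: int) -> float | None:
    """H(X|Y) for two binary community-indicator vectors, subject to the
    standard constraint that the match must beat the mismatch entropy;
    returns None when the constraint fails."""
    a = np.sum((x == 0) & (y == 0)) / n
    b = np.sum((x == 0) & (y == 1)) / n
    c = np.sum((x == 1) & (y == 0)) / n
    d = np.sum((x == 1) & (y == 1)) / n
    if _h(a) + _h(d) < _h(b) + _h(c):
        return None
    h_xy = _h(a) + _h(b) + _h(c) + _h(d)
    h_y = _h(a + c) + _h(b + d)
    return h_xy - h_y


def _cover_cond_entropy(BX: np.ndarray, BY: np.ndarray) -> float:
    """Normalized H(X|Y): per community of X, the best-match conditional
    entropy against any community of Y, normalized by H(X_k)."""
    n = BX.shape[0]
    terms = []
    for k in range(BX.shape[1]):
        x = BX[:, k]
        px = x.sum() / n
        hx = _h(px) + _h(1 - px)
        best = None
        for l in range(BY.shape[1]):
            h = _cond_entropy_sets(x, BY[:, l], n)
            if h is not None and (best is None or h < best):
                best = h
        if best is None:
            best = hx
        terms.append(best / hx if hx > 0 else 0.0)
    return float(np.mean(terms)) if terms else 0.0


def overlapping_nmi(c1: Cover, c2: Cover) -> float:
    """Set-based overlapping NMI (best-match normalized conditional
    entropies): 1 - (H(X|Y)_norm + H(Y|X)_norm) / 2.  Equals 1 for
    identical covers and is invariant to community relabeling."""
    B1, B2 = _aligned_membership(c1, c2)
    hxy = _cover_cond_entropy(B1, B2)
    hyx = _cover_cond_entropy(B2, B1)
    return float(1.0 - 0.5 * (hxy + hyx))


# ---------------------------------------------------------------------------
# overlapping quality


def _belonging_matrix(g: WeightedGraph, c: Cover) -> np.ndarray:
    if set(c.node_ids) != set(g.node_ids):
        raise ValueError("cover does not span the graph's node set")
    d = c.as_dict()
    mems = tuple(d[v] for v in g.node_ids)
    labels = sorted(set().union(*mems))
    idx = {l: k for k, l in enumerate(labels)}
    B = np.zeros((g.n_nodes, len(labels)))
    for i, mem in enumerate(mems):
        for l in mem:
            B[i, idx[l]] = 1.0 / len(mem)
    return B


def _newman_q_belonging(A: sp.csr_array, B: np.ndarray) -> float:
    two_w = A.sum()
    if two_w == 0:
        return 0.0
    s = np.asarray(A.sum(axis=1)).ravel()
    intra = np.einsum("cc->c", B.T @ (A @ B))
    strength = B.T @ s
    return float(np.sum(intra / two_w - (strength / two_w) ** 2))


def overlapping_quality(g: WeightedGraph, c: Cover) -> tuple[float, float]:
    """Overlapping modularity and overlapping modularity density.

    Each node's contribution is split equally over its memberships
    (belonging coefficient 1/|memberships|).  Both reduce exactly to
    :func:`modularity_signed` / :func:`modularity_density` when the
    cover is a partition.
    """
    if len(c.node_ids) == 0:
        raise ValueError("empty cover")
    B = _belonging_matrix(g, c)
    Ap, An = _split_signs(g)
    wp, wn = Ap.sum() / 2.0, An.sum() / 2.0
    qp = _newman_q_belonging(Ap, B) if wp > 0 else 0.0
    qn = _newman_q_belonging(An, B) if wn > 0 else 0.0
    q_ov = float((wp * qp - wn * qn) / (wp + wn)) if wp + wn > 0 else 0.0
    sizes = B.sum(axis=0)
    if An.nnz:
        warnings.warn("negative edges ignored in overlapping modularity density")
    qds_ov = _qds_terms(Ap, B, sizes)
    return q_ov, qds_ov


# ---------------------------------------------------------------------------
# multi-community calls


def multicommunity_f1(
    inferred: Cover, truth: Cover
) -> tuple[float, float, float, ConfusionCounts]:
    """Sensitivity, specificity and F1 of multi-community node calls.

    A node is positive when it belongs to >= 2 communities.  F1 is the
    harmonic mean of precision and sensitivity; zero denominators yield
    0 for the affected rate.
    """
    if set(inferred.node_ids) != set(truth.node_ids):
        raise ValueError("covers span different node sets")
    td = truth.as_dict()
    pred = np.array([len(m) >= 2 for m in inferred.memberships])
    true = np.array([len(td[v]) >= 2 for v in inferred.node_ids])
    tp = int(np.sum(pred & true))
    fp = int(np.sum(pred & ~true))
    fn = int(np.sum(~pred & true))
    tn = int(np.sum(~pred & ~true))
    counts = ConfusionCounts(tp, fp, fn, tn)
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    return sens, spec, f1, counts
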