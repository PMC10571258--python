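"""SpeakEasy 2 (Champagne): popularity-corrected label propagation.

The algorithm clusters a signed weighted network by maximizing *label
specificity*: for node i and label l,

    spec(i, l) = obs(i, l) - p_l * s_i

where obs(i, l) is the total edge weight from i to neighbors currently
carrying l, s_i is i's total strength, and p_l is the global popularity of
l (the strength-weighted fraction of the network holding l).  A label is
attractive to a node when it is more common among the node's neighbors
than its global popularity predicts — this is what keeps large clusters
from swallowing the network simply by being large.

Labels evolve through four stages, looped several times per run:

* **standard** — a random 90% of nodes simultaneously adopt their most
  specific neighborhood label;
* **bubble** — oversized clusters burst: their least-secure members are
  dispersed onto fresh random labels, letting groups of nodes escape
  configurations that single-node updates can never leave;
* **nurture** — only the worst-fitting nodes update, so promising
  proto-clusters formed by the bubble stage survive and organize the
  remainder around them;
* **merge** — whole label classes with above-chance cross-linking are
  fused, the label-level counterpart of a node update.

Several independent runs each contribute one sampled partition to a pool;
the final answer is the pool medoid under pairwise NMI, i.e. the most
typical partition rather than the one maximizing any quality score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .graph import Partition, WeightedGraph

__all__ = [
    "SE2Params",
    "LabelState",
    "PartitionPool",
    "initialize_labels",
    "label_specificity",
    "standard_update",
    "bubble_stage",
    "nurture_stage",
    "merge_stage",
    "run_se2",
    "consensus_select",
]

_TIE_TOL = 1e-12


@dataclass(frozen=True)
class SE2Params:
    """Tunable knobs of the label dynamics.

    Defaults follow the algorithm's published constants where they exist:
    labels are initialized at 1% of the node count, 90% of nodes refresh
    per standard step, a partition is sampled after 5 passes through the
    four stages, and the consensus pool holds 10 independent runs.
    """

    initial_label_fraction: float = 0.01
    update_fraction: float = 0.9
    stage_passes_per_partition: int = 5
    independent_runs: int = 10
    max_steps_per_stage: int = 10
    nurture_steps: int = 5
    bubble_size_quantile: float = 0.9
    bubble_disperse_fraction: float = 0.5
    nurture_fit_quantile: float = 0.3
    convergence_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.initial_label_fraction <= 1:
            raise ValueError("initial_label_fraction must be in (0, 1]")
        if not 0 < self.update_fraction <= 1:
            raise ValueError("update_fraction must be in (0, 1]")
        if self.independent_runs < 1:
            raise ValueError("independent_runs must be >= 1")
        if self.stage_passes_per_partition < 1:
            raise ValueError("stage_passes_per_partition must be >= 1")


class LabelState:
    """Evolving node -> label assignment with cached graph quantities.

    Labels are dense non-negative ints, compacted (no empty label ids)
    after every stage, so ``n_labels`` equals the number of live labels.
    """

    def __init__(self, g: WeightedGraph, labels: np.ndarray, step_count: int = 0):
        self._W = g.adjacency
        self._absW = sp.csr_array(abs(g.adjacency))
        self.labels = np.asarray(labels, dtype=np.int64)
        self.strengths = g.strengths()
        self._abs_strengths = np.abs(self.strengths)
        self._has_negative = np.asarray(
            (g.adjacency.minimum(0)).power(2).sum(axis=1)
        ).ravel() > 0
        self.step_count = step_count
        self.last_changed_fraction = 1.0
        self._compact()

    def _compact(self) -> None:
        _, self.labels = np.unique(self.labels, return_inverse=True)
        self.labels = self.labels.astype(np.int64)

    @property
    def n_labels(self) -> int:
        return int(self.labels.max()) + 1

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def label_popularity(self) -> np.ndarray:
        """p_l = sum of |s_j| over nodes with label l, normalized to 1.

        Absolute strengths keep popularities non-negative on signed
        networks.  Falls back to plain node counts if every strength is
        zero (edgeless graph).
        """
        tot = self._abs_strengths.sum()
        if tot == 0:
            counts = np.bincount(self.labels, minlength=self.n_labels)
            return counts / counts.sum()
        p = np.bincount(
            self.labels, weights=self._abs_strengths, minlength=self.n_labels
        )
        return p / tot

    def _onehot(self) -> sp.csr_array:
        n = self.n_nodes
        return sp.csr_array(
            (np.ones(n), (np.arange(n), self.labels)), shape=(n, self.n_labels)
        )

    def specificity_matrix(self) -> np.ndarray:
        """Dense (n_nodes, n_labels) matrix of spec(i, l)."""
        H = self._onehot()
        obs = np.asarray((self._W @ H).todense())
        p = self.label_popularity()
        return obs - np.outer(self.strengths, p)

    def neighbor_label_mask(self) -> np.ndarray:
        """Candidate labels per node: labels incident through any edge,
        plus the node's own label; nodes touching negative edges scan all
        live labels (an absent label can win argmax there)."""
        H = self._onehot()
        mask = np.asarray((self._absW @ H).todense()) > 0
        mask[np.arange(self.n_nodes), self.labels] = True
        mask[self._has_negative, :] = True
        return mask

    def copy(self) -> "LabelState":
        new = object.__new__(LabelState)
        new._W = self._W
        new._absW = self._absW
        new.labels = self.labels.copy()
        new.strengths = self.strengths
        new._abs_strengths = self._abs_strengths
        new._has_negative = self._has_negative
        new.step_count = self.step_count
        new.last_changed_fraction = self.last_changed_fraction
        return new


@dataclass(frozen=True)
class PartitionPool:
    """Replicate partitions plus per-node label-score records.

    ``scores[k]`` is the dense specificity matrix of run k's final state
    (rows = nodes, columns = that partition's communities); the best and
    second-best entries per row drive both consensus diagnostics and
    multi-community nomination.
    """

    partitions: tuple[Partition, ...]
    scores: tuple[np.ndarray, ...] = field(repr=False)
    run_seeds: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(self.partitions) == 0:
            raise ValueError("partition pool must be non-empty")
        nodesets = {p.node_ids for p in self.partitions}
        if len(nodesets) != 1:
            raise ValueError("pool partitions cover different node sets")

    def __len__(self) -> int:
        return len(self.partitions)

    def best_and_second(self, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(best_label, best_score, second_label, second_score) for run k."""
        S = self.scores[k]
        if S.shape[1] == 1:
            n = S.shape[0]
            return (
                np.zeros(n, dtype=int),
                S[:, 0],
                np.zeros(n, dtype=int),
                np.full(n, -np.inf),
            )
        order = np.argsort(S, axis=1)
        best = order[:, -1]
        second = order[:, -2]
        idx = np.arange(S.shape[0])
        return best, S[idx, best], second, S[idx, second]


# ---------------------------------------------------------------------------
# stages


def initialize_labels(
    g: WeightedGraph, params: SE2Params, rng: np.random.Generator
) -> LabelState:
    """Seed the dynamics with far fewer labels than nodes.

    Each node draws one of ``max(1, round(f * n))`` distinct labels
    uniformly (f = ``initial_label_fraction``, default 1%).  Overloading
    labels this way trades nothing for speed: spurious labels die out
    during the standard stage, and the bubble stage re-creates labels
    wherever clusters need to split.
    """
    n = g.n_nodes
    k = max(1, int(round(params.initial_label_fraction * n)))
    labels = rng.integers(0, k, size=n)
    if len(np.unique(labels)) < min(k, n):
        # guarantee every intended label is in use (matters for small n)
        forced = rng.permutation(n)[: min(k, n)]
        labels[forced] = np.arange(min(k, n))
    return LabelState(g, labels)


def label_specificity(
    state: LabelState, g: WeightedGraph, node: int, label: int
) -> float:
    """spec(node, label) = observed neighbor support minus expected support."""
    if not 0 <= label < state.n_labels:
        raise ValueError(f"label {label} unknown to this state")
    row = g.adjacency[[node], :]
    obs = float(row[:, state.labels == label].sum())
    p = state.label_popularity()[label]
    return obs - p * state.strengths[node]


def _argmax_with_ties(
    scores: np.ndarray, allowed: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Row-wise argmax over allowed entries, ties broken uniformly."""
    masked = np.where(allowed, scores, -np.inf)
    rowmax = masked.max(axis=1)
    ties = masked >= rowmax[:, None] - _TIE_TOL
    noise = rng.random(scores.shape)
    return np.argmax(np.where(ties, noise, -1.0), axis=1)


def standard_update(
    state: LabelState,
    g: WeightedGraph,
    params: SE2Params,
    rng: np.random.Generator,
) -> LabelState:
    """One synchronous step: a random ``update_fraction`` of nodes adopt
    the label most specific to their neighborhood.

    Only the most recent label configuration is consulted — no label
    history is aggregated.  Updating 90% rather than all nodes breaks the
    oscillations that full synchronous updates produce on some small
    binary networks.
    """
    n = state.n_nodes
    m = int(round(params.update_fraction * n))
    selected = rng.permutation(n)[:m]
    spec = state.specificity_matrix()
    allowed = state.neighbor_label_mask()
    choice = _argmax_with_ties(spec, allowed, rng)
    new = state.copy()
    new.labels[selected] = choice[selected]
    new.last_changed_fraction = float(np.mean(new.labels != state.labels))
    new.step_count += 1
    new._compact()
    return new


def bubble_stage(
    state: LabelState,
    g: WeightedGraph,
    params: SE2Params,
    rng: np.random.Generator,
) -> LabelState:
    """Burst oversized clusters by dispersing their least-secure members.

    Clusters above the ``bubble_size_quantile`` of current cluster sizes
    (the largest cluster always qualifies once it has >= 4 members) lose
    their bottom ``bubble_disperse_fraction`` of members, ranked by the
    security margin spec(i, own) - max over other labels of spec(i, l).
    Dispersed members are scattered over fresh random labels, so the
    label count never decreases here.  Random splitting is deliberate:
    structure-aware splits cost more and recover no better.
    """
    labels = state.labels
    sizes = np.bincount(labels, minlength=state.n_labels)
    thr = np.quantile(sizes, params.bubble_size_quantile)
    eligible = np.flatnonzero((sizes > thr) | ((sizes == sizes.max()) & (sizes >= 4)))
    eligible = eligible[sizes[eligible] >= 4]
    if len(eligible) == 0:
        return state
    spec = state.specificity_matrix()
    own = spec[np.arange(state.n_nodes), labels]
    if state.n_labels > 1:
        tmp = spec.copy()
        tmp[np.arange(state.n_nodes), labels] = -np.inf
        margin = own - tmp.max(axis=1)
    else:
        margin = own
    new = state.copy()
    median_size = float(np.median(sizes))
    next_label = state.n_labels
    for c in eligible:
        members = np.flatnonzero(labels == c)
        n_disp = int(len(members) * params.bubble_disperse_fraction)
        if n_disp == 0:
            continue
        order = np.argsort(margin[members], kind="stable")
        insecure = members[order[:n_disp]]
        k_new = max(2, int(np.ceil(sizes[c] / max(median_size, 1.0))))
        fresh = next_label + rng.integers(0, k_new, size=n_disp)
        new.labels[insecure] = fresh
        next_label += k_new
    new._compact()
    return new


def nurture_stage(
    state: LabelState,
    g: WeightedGraph,
    params: SE2Params,
    rng: np.random.Generator,
) -> LabelState:
    """Selective update of only the worst-fitting nodes.

    Nodes in the bottom ``nurture_fit_quantile`` of current-label
    specificity update by the standard rule; everyone else holds still,
    so proto-clusters with good fit persist and recruit the stragglers.
    """
    spec = state.specificity_matrix()
    own = spec[np.arange(state.n_nodes), state.labels]
    thr = np.quantile(own, params.nurture_fit_quantile)
    poor = np.flatnonzero(own <= thr)
    if len(poor) == 0:
        return state
    allowed = state.neighbor_label_mask()
    choice = _argmax_with_ties(spec, allowed, rng)
    new = state.copy()
    new.labels[poor] = choice[poor]
    new.step_count += 1
    new._compact()
    return new


def merge_stage(state: LabelState, g: WeightedGraph) -> LabelState:
    """Fuse label pairs whose cross-linking exceeds the random expectation.

    Observed inter-label weight M_ab is compared with the configuration
    -model expectation S_a * S_b / (2W) (S_x: total strength of label x,
    W: total edge weight, 2W the total strength S); the most above-chance
    pair merges first and the stage repeats until no pair is above
    chance.  Each merge removes one label, so termination is bounded by
    the label count.
    """
    K = state.n_labels
    if K == 1:
        return state
    H = state._onehot()
    M = np.asarray((H.T @ state._W @ H).todense())
    S_lab = np.bincount(state.labels, weights=state.strengths, minlength=K)
    S = state.strengths.sum()
    parent = np.arange(K)
    alive = np.ones(K, dtype=bool)
    while alive.sum() > 1:
        if S != 0:
            E = np.outer(S_lab, S_lab) / S
        else:
            E = np.zeros_like(M)
        D = M - E
        np.fill_diagonal(D, -np.inf)
        D[~alive, :] = -np.inf
        D[:, ~alive] = -np.inf
        a, b = np.unravel_index(np.argmax(D), D.shape)
        if D[a, b] <= 0:
            break
        a, b = min(a, b), max(a, b)
        M[a, :] += M[b, :]
        M[:, a] += M[:, b]
        M[a, a] += 0.0  # row+col add already folds M[b,b] and cross terms
        S_lab[a] += S_lab[b]
        S_lab[b] = 0.0
        alive[b] = False
        parent[parent == b] = a
    new = state.copy()
    new.labels = parent[state.labels]
    new._compact()
    return new


# ---------------------------------------------------------------------------
# driver


def _one_run(
    g: WeightedGraph, params: SE2Params, rng: np.random.Generator
) -> LabelState:
    state = initialize_labels(g, params, rng)
    for _ in range(params.stage_passes_per_partition):
        for _ in range(params.max_steps_per_stage):
            state = standard_update(state, g, params, rng)
            if state.last_changed_fraction < params.convergence_fraction:
                break
        state = bubble_stage(state, g, params, rng)
        for _ in range(params.nurture_steps):
            state = nurture_stage(state, g, params, rng)
        state = merge_stage(state, g)
    return state


def run_se2(
    g: WeightedGraph, params: SE2Params | None = None
) -> tuple[Partition, PartitionPool]:
    """Cluster a preprocessed graph; return the consensus partition and
    the full partition pool it was selected from.

    Each of ``independent_runs`` restarts gets a child seed derived from
    ``params.seed``, initializes fresh labels, loops the stage schedule
    ``stage_passes_per_partition`` times and contributes its final label
    state (plus per-node community scores) to the pool.  The consensus
    partition is the pool medoid under pairwise NMI.
    """
    if params is None:
        params = SE2Params()
    n = g.n_nodes
    if n == 0:
        raise ValueError("cannot cluster an empty graph")
    if n == 1:
        p = Partition(g.node_ids, np.zeros(1, dtype=int))
        pool = PartitionPool((p,), (np.zeros((1, 1)),), (params.seed,))
        return p, pool
    children = np.random.SeedSequence(params.seed).spawn(params.independent_runs)
    partitions: list[Partition] = []
    scores: list[np.ndarray] = []
    seeds: list[int] = []
    for k, child in enumerate(children):
        rng = np.random.default_rng(child)
        state = _one_run(g, params, rng)
        partitions.append(Partition(g.node_ids, state.labels))
        scores.append(state.specificity_matrix())
        seeds.append(int(child.generate_state(1)[0] % (2**31)))
    pool = PartitionPool(tuple(partitions), tuple(scores), tuple(seeds))
    return consensus_select(pool), pool


def consensus_select(pool: PartitionPool) -> Partition:
    """The pool medoid: the member with the highest mean NMI against all
    other members — a 'most typical' partition rather than a score
    optimum.  Ties resolve to the lowest run index."""
    from .metrics import nmi

    m = len(pool)
    if m == 1:
        return pool.partitions[0]
    sim = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            sim[i, j] = sim[j, i] = nmi(pool.partitions[i], pool.partitions[j])
    mean_sim = sim.sum(axis=1) / (m - 1)
    return pool.partitions[int(np.argmax(mean_sim))]
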