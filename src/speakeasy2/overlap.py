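"""Multi-community (overlapping) node nomination from the partition pool.

A node that genuinely sits between communities oscillates between them
across replicate runs: its best and second-best community scores stay
close in partition after partition.  Nomination therefore uses the whole
pool — a node is flagged when the second-best score is within a margin
of the best in enough partitions — and only then are the flagged node's
communities chosen, from the final consensus partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import LabelState, PartitionPool
from .graph import Cover, Partition, WeightedGraph

__all__ = ["OverlapParams", "detect_multicommunity"]


@dataclass(frozen=True)
class OverlapParams:
    """Thresholds for multi-community nomination.

    margin_threshold
        Relative closeness required: second_best >= margin * best (with a
        positive best score) counts as a near-tie.
    consistency_fraction
        Fraction of pool partitions in which the near-tie must hold.
    max_memberships
        Hard cap on how many communities a node may join.
    """

    margin_threshold: float = 0.5
    consistency_fraction: float = 0.5
    max_memberships: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.margin_threshold <= 1:
            raise ValueError("margin_threshold must be in (0, 1]")
        if not 0 < self.consistency_fraction <= 1:
            raise ValueError("consistency_fraction must be in (0, 1]")
        if self.max_memberships < 2:
            raise ValueError("max_memberships must be >= 2")


def detect_multicommunity(
    pool: PartitionPool,
    g: WeightedGraph,
    final: Partition,
    params: OverlapParams | None = None,
) -> Cover:
    """Upgrade the consensus partition to a cover with multi-community
    nodes.

    For every pool partition, each node's specificity scores toward that
    partition's communities are ranked.  A node is flagged when, in at
    least ``consistency_fraction`` of partitions, the second-best score
    reaches ``margin_threshold`` of the (positive) best.  The membership
    count m for a flagged node is the modal number of near-best
    communities across partitions, clipped to [2, max_memberships]; the
    node is then placed into the m communities of the *final* partition
    with the highest scores.  Flagging is thus independent of which
    communities are ultimately assigned.
    """
    if params is None:
        params = OverlapParams()
    n = len(final.node_ids)
    n_parts = len(pool)
    close_votes = np.zeros(n, dtype=int)
    near_counts = np.zeros((n_parts, n), dtype=int)
    for k in range(n_parts):
        S = pool.scores[k]
        if S.shape[1] < 2:
            near_counts[k] = 1
            continue
        best = S.max(axis=1)
        positive = best > 0
        near = S >= params.margin_threshold * best[:, None]
        counts = near.sum(axis=1)
        counts[~positive] = 1
        near_counts[k] = counts
        close_votes += (counts >= 2) & positive
    flagged = close_votes >= params.consistency_fraction * n_parts

    # scores against the final partition's communities, for placement
    final_state = LabelState(g, final.labels)
    S_final = final_state.specificity_matrix()

    memberships: list[frozenset[int]] = []
    for i in range(n):
        if not flagged[i]:
            memberships.append(frozenset((int(final.labels[i]),)))
            continue
        counts_i = near_counts[:, i]
        counts_i = counts_i[counts_i >= 2]
        vals, freq = np.unique(counts_i, return_counts=True)
        m = int(vals[np.argmax(freq)])
        m = min(max(m, 2), params.max_memberships, S_final.shape[1])
        top = np.argsort(S_final[i])[::-1][:m]
        memberships.append(frozenset(int(t) for t in top))
    return Cover(final.node_ids, tuple(memberships))
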