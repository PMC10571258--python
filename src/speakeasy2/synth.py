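"""LFR-style weighted benchmark generation with planted (optionally
overlapping) communities.

Networks are built from perfectly separated planted communities that are
then cross-linked to a controlled extent: each node sends a fraction mu
of its edges outside its own communit(ies).  Degrees, community sizes
and edge weights are drawn from bounded power laws; cross-community edge
weights are scaled according to one of three regimes, so the topological
mixing (mu) and the weight-level mixing (mu_w) can be varied jointly or
independently.  This is an LFR-style generator — stub matching over
power-law draws with planted membership — not a port of any particular
LFR code; its contract is the parameter semantics, not byte-level
agreement with other implementations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .graph import Cover, WeightedGraph

__all__ = [
    "BenchmarkSpec",
    "BenchmarkInstance",
    "sample_powerlaw",
    "truncated_powerlaw_mean",
    "generate_benchmark",
    "benchmark_grid",
    "mixing_summary",
]

REGIMES = ("covary", "constant_proportion", "constant_weight")


@dataclass(frozen=True)
class BenchmarkSpec:
    """Parameters of one benchmark network.

    mu is the fraction of each node's edges that land outside its planted
    communit(ies); mu_w sets the relative weight level of those
    cross-community edges ("match_mu" ties it to mu).  The regime decides
    which of the two is swept:

    - ``covary``: cross-link proportion and weight level move together
      (mu_w := mu);
    - ``constant_proportion``: mu held fixed, mu_w varied;
    - ``constant_weight``: mu varied, weight level pinned at neutral
      (mu_w := 0.5).
    """

    n_nodes: int = 2000
    avg_degree: float = 30.0
    degree_exponent: float = 3.0
    community_size_exponent: float = 1.5
    weight_exponent: float = 1.5
    mu: float = 0.1
    mu_w: float | str = "match_mu"
    regime: str = "covary"
    overlap_fraction: float = 0.0
    memberships: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 10:
            raise ValueError("n_nodes must be >= 10")
        for exp in (
            self.degree_exponent,
            self.community_size_exponent,
            self.weight_exponent,
        ):
            if exp <= 1:
                raise ValueError("power-law exponents must exceed 1")
        if not 0 <= self.mu <= 1:
            raise ValueError("mu must be in [0, 1]")
        if not 0 <= self.overlap_fraction <= 1:
            raise ValueError("overlap_fraction must be in [0, 1]")
        if self.overlap_fraction > 0 and self.memberships < 2:
            raise ValueError("memberships must be >= 2 when overlap_fraction > 0")
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}")

    def effective_mu_w(self) -> float:
        if self.regime == "covary":
            return self.mu
        if self.regime == "constant_weight":
            return 0.5
        if self.mu_w == "match_mu":
            return self.mu
        return float(self.mu_w)


@dataclass(frozen=True)
class BenchmarkInstance:
    graph: WeightedGraph
    truth: Cover
    spec: BenchmarkSpec


# ---------------------------------------------------------------------------
# power-law draws


def sample_powerlaw(
    count: int,
    exponent: float,
    lo: float,
    hi: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """I.i.d. draws from the bounded power law with density ~ x^-exponent
    on [lo, hi], by inverse-CDF sampling."""
    if not lo < hi:
        raise ValueError("require lo < hi")
    if exponent <= 1:
        raise ValueError("exponent must exceed 1")
    u = rng.random(count)
    a = 1.0 - exponent
    return (lo**a + u * (hi**a - lo**a)) ** (1.0 / a)


def truncated_powerlaw_mean(exponent: float, lo: float, hi: float) -> float:
    """Closed-form mean of the bounded power law on [lo, hi]."""
    a = 1.0 - exponent
    b = 2.0 - exponent
    if abs(b) < 1e-12:
        num = np.log(hi / lo)
    else:
        num = (hi**b - lo**b) / b
    den = (hi**a - lo**a) / a
    return float(num / den)


def _solve_degree_lo(exponent: float, hi: float, target_mean: float) -> float:
    """Minimum degree such that the truncated power-law mean hits the
    requested average degree (how LFR pins its degree sequence)."""

    def f(lo: float) -> float:
        return truncated_powerlaw_mean(exponent, lo, hi) - target_mean

    eps = 1e-6
    if f(1.0) >= 0:
        return 1.0
    if f(hi - eps) <= 0:
        return hi - eps
    return float(brentq(f, 1.0, hi - eps))


# ---------------------------------------------------------------------------
# generation


def _draw_community_sizes(
    slots: int, spec: BenchmarkSpec, rng: np.random.Generator
) -> np.ndarray:
    lo = max(2.0, 2.0 * spec.avg_degree)
    hi = max(lo * 1.5, spec.n_nodes / 4.0)
    if lo >= hi:
        lo, hi = 2.0, max(4.0, spec.n_nodes / 4.0)
    sizes: list[int] = []
    for _ in range(10_000):
        s = int(round(sample_powerlaw(1, spec.community_size_exponent, lo, hi, rng)[0]))
        total = sum(sizes) + s
        if total >= slots:
            s = slots - sum(sizes)
            if s >= lo / 2 or not sizes:
                if s > 0:
                    sizes.append(s)
            elif s > 0:
                sizes[-1] += s
            break
        sizes.append(s)
    else:
        raise RuntimeError("community-size sampling failed to fill the network")
    # guarantee enough communities for the requested membership count
    while len(sizes) < max(2, spec.memberships):
        big = int(np.argmax(sizes))
        half = sizes[big] // 2
        sizes.append(half)
        sizes[big] -= half
    return np.asarray(sizes, dtype=int)


def _assign_memberships(
    sizes: np.ndarray, spec: BenchmarkSpec, rng: np.random.Generator
) -> tuple[list[list[int]], np.ndarray]:
    """Random membership assignment honoring community sizes as targets.

    Returns per-community member lists and the membership-count array.
    Exactly round(overlap_fraction * n) nodes receive ``memberships``
    communities; the rest one.
    """
    n = spec.n_nodes
    n_over = int(round(spec.overlap_fraction * n))
    m = spec.memberships if n_over else 1
    counts = np.ones(n, dtype=int)
    over_nodes = rng.permutation(n)[:n_over]
    counts[over_nodes] = m
    capacity = sizes.astype(float).copy()
    members: list[list[int]] = [[] for _ in sizes]
    # overlap nodes first: they need several distinct communities
    order = np.concatenate([over_nodes, np.setdiff1d(rng.permutation(n), over_nodes)])
    for v in order:
        need = counts[v]
        avail = np.flatnonzero(capacity > 0)
        if len(avail) < need:
            avail = np.argsort(-capacity)[:need]  # overflow smallest deficit
        w = np.clip(capacity[avail], 1e-9, None)
        chosen = rng.choice(avail, size=need, replace=False, p=w / w.sum())
        for c in chosen:
            members[c].append(int(v))
            capacity[c] -= 1
    return members, counts


def _pair_stubs(
    stubs: np.ndarray,
    rng: np.random.Generator,
    forbidden: "set[tuple[int,int]] | None" = None,
    same_comm: np.ndarray | None = None,
    max_rounds: int = 30,
) -> list[tuple[int, int]]:
    """Stub matching with rejection of self-loops, duplicates and
    (optionally) pairs that already share a community; residual stubs
    after bounded retries are discarded."""
    edges: set[tuple[int, int]] = set(forbidden) if forbidden else set()
    new_edges: list[tuple[int, int]] = []
    pool = stubs.copy()
    for _ in range(max_rounds):
        if len(pool) < 2:
            break
        rng.shuffle(pool)
        if len(pool) % 2:
            pool = pool[:-1]
        left, right = pool[0::2], pool[1::2]
        rejected: list[int] = []
        for a, b in zip(left, right):
            if a == b:
                rejected.extend((a, b))
                continue
            key = (min(a, b), max(a, b))
            if key in edges or (
                same_comm is not None and same_comm[a, b]
            ):
                rejected.extend((a, b))
                continue
            edges.add(key)
            new_edges.append(key)
        if not rejected:
            break
        pool = np.asarray(rejected)
    return new_edges


def generate_benchmark(spec: BenchmarkSpec) -> BenchmarkInstance:
    """Generate one weighted benchmark network with planted truth.

    Pipeline: draw a degree sequence and community sizes from their power
    laws; assign nodes to communities (multi-community nodes split their
    internal degree budget equally); wire internal edges per community and
    cross-community edges globally by degree-preserving stub matching;
    draw edge weights from the weight power law, scaling cross-community
    weights by mu_w/(1 - mu_w) (neutral at mu_w = 0.5); finally rescale
    so the maximum weight equals one.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_nodes
    hi_deg = min(n - 1.0, np.sqrt(n * spec.avg_degree))
    lo_deg = _solve_degree_lo(spec.degree_exponent, hi_deg, spec.avg_degree)
    degrees = np.clip(
        np.round(sample_powerlaw(n, spec.degree_exponent, lo_deg, hi_deg, rng)),
        1,
        int(hi_deg),
    ).astype(int)

    n_over = int(round(spec.overlap_fraction * n))
    m = spec.memberships if n_over else 1
    slots = n + n_over * (m - 1)
    sizes = _draw_community_sizes(slots, spec, rng)
    members, counts = _assign_memberships(sizes, spec, rng)
    n_comm = len(members)
    node_comms: list[list[int]] = [[] for _ in range(n)]
    for c, mem in enumerate(members):
        for v in mem:
            node_comms[v].append(c)

    d_int = np.round((1.0 - spec.mu) * degrees).astype(int)
    d_ext = degrees - d_int

    # shared-community lookup for external-edge rejection
    comm_mat = np.zeros((n, n_comm), dtype=bool)
    for v, cs in enumerate(node_comms):
        comm_mat[v, cs] = True
    same_comm = comm_mat @ comm_mat.T

    intra_edges: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    for c, mem in enumerate(members):
        mem_arr = np.asarray(mem)
        size_c = len(mem_arr)
        if size_c < 2:
            continue
        stubs: list[int] = []
        for v in mem_arr:
            share = d_int[v] // counts[v]
            stubs.extend([int(v)] * min(share, size_c - 1))
        got = _pair_stubs(np.asarray(stubs, dtype=int), rng, forbidden=seen)
        intra_edges.extend(got)
        seen.update(got)

    ext_stubs = np.repeat(np.arange(n), d_ext)
    inter_edges = _pair_stubs(ext_stubs, rng, forbidden=seen, same_comm=same_comm)

    mu_w = min(max(spec.effective_mu_w(), 0.02), 0.98)
    scale_inter = mu_w / (1.0 - mu_w)
    w_lo, w_hi = 0.1, 1.0
    w_intra = sample_powerlaw(len(intra_edges), spec.weight_exponent, w_lo, w_hi, rng)
    w_inter = (
        sample_powerlaw(len(inter_edges), spec.weight_exponent, w_lo, w_hi, rng)
        * scale_inter
    )
    all_edges = intra_edges + inter_edges
    weights = np.concatenate([w_intra, w_inter]) if all_edges else np.array([])
    if len(weights):
        weights = weights / weights.max()

    node_ids = [f"n{i}" for i in range(n)]
    graph = WeightedGraph.from_edges(
        node_ids,
        [(i, j, w) for (i, j), w in zip(all_edges, weights)],
    )
    truth = Cover(
        tuple(node_ids), tuple(frozenset(cs) for cs in node_comms)
    )
    return BenchmarkInstance(graph, truth, spec)


def mixing_summary(inst: BenchmarkInstance) -> dict[str, float]:
    """Realized mixing of a generated network: the fraction and mean
    weight of edges whose endpoints share no planted community."""
    A = inst.graph.offdiag().tocoo()
    mem = inst.truth.memberships
    inter_w, intra_w = [], []
    for i, j, w in zip(A.row, A.col, A.data):
        if i < j:
            (inter_w if not (mem[i] & mem[j]) else intra_w).append(w)
    n_inter, n_intra = len(inter_w), len(intra_w)
    total = n_inter + n_intra
    return {
        "n_intra": float(n_intra),
        "n_inter": float(n_inter),
        "inter_fraction": n_inter / total if total else 0.0,
        "mean_intra_weight": float(np.mean(intra_w)) if intra_w else 0.0,
        "mean_inter_weight": float(np.mean(inter_w)) if inter_w else 0.0,
        "mean_degree": 2.0 * total / inst.graph.n_nodes,
    }


def benchmark_grid(
    grid: Mapping[str, Sequence], root_seed: int = 0
) -> list[BenchmarkSpec]:
    """Cartesian product of parameter value lists, one spec per cell,
    deterministic ordering, per-cell seeds derived from ``root_seed``."""
    for k, v in grid.items():
        if len(v) == 0:
            raise ValueError(f"empty value list for parameter {k!r}")
    keys = list(grid.keys())
    specs = []
    for idx, combo in enumerate(itertools.product(*(grid[k] for k in keys))):
        kwargs = dict(zip(keys, combo))
        kwargs.setdefault("seed", (root_seed * 1_000_003 + idx) % (2**31))
        specs.append(BenchmarkSpec(**kwargs))
    return specs
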