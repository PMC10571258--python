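"""Graph and partition data model, file I/O, and input preprocessing.

The substrate for everything in this package is an undirected, weighted
graph whose edge weights are finite reals in [-1, 1] (after preprocessing).
Nodes carry arbitrary string identifiers (gene symbols, protein IDs, cell
barcodes, ...) which are mapped to dense 0-based indices internally and
restored on output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.io
import scipy.sparse as sp
from scipy.stats import skew


class GraphFormatError(ValueError):
    """Raised when an input file cannot be parsed or violates symmetry."""


class WeightDomainError(ValueError):
    """Raised when edge weights fall outside [-1, 1] after rescaling."""


@dataclass(frozen=True)
class WeightedGraph:
    """Symmetric signed weighted adjacency over ``n_nodes`` nodes.

    Parameters
    ----------
    node_ids
        Stable external identifiers, one per node, unique.
    adjacency
        Symmetric ``n x n`` sparse matrix (CSR).  The main diagonal holds
        per-node self-connection weights (may be zero).
    """

    node_ids: tuple[str, ...]
    adjacency: sp.csr_array = field(repr=False)

    def __post_init__(self) -> None:
        n = len(self.node_ids)
        if n < 1:
            raise ValueError("graph must have at least one node")
        if len(set(self.node_ids)) != n:
            raise ValueError("node_ids must be unique")
        A = self.adjacency
        if A.shape != (n, n):
            raise ValueError("adjacency shape does not match node count")
        if A.nnz and not np.all(np.isfinite(A.data)):
            raise ValueError("all edge weights must be finite")
        asym = abs(A - A.T)
        if asym.nnz and asym.max() > 1e-12:
            raise GraphFormatError("adjacency matrix is not symmetric")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def self_weights(self) -> np.ndarray:
        return np.asarray(self.adjacency.diagonal())

    def offdiag(self) -> sp.csr_array:
        """Adjacency with the main diagonal removed."""
        A = self.adjacency.tocoo()
        keep = A.row != A.col
        return sp.csr_array(
            (A.data[keep], (A.row[keep], A.col[keep])), shape=A.shape
        )

    def strengths(self) -> np.ndarray:
        """Node strengths s_i = sum_j w_ij (self-connection included)."""
        return np.asarray(self.adjacency.sum(axis=1)).ravel()

    def n_edges(self) -> int:
        """Number of stored undirected off-diagonal edges."""
        return self.offdiag().nnz // 2

    def index_of(self) -> dict[str, int]:
        return {v: i for i, v in enumerate(self.node_ids)}

    @classmethod
    def from_edges(
        cls,
        node_ids: Sequence[str],
        edges: Iterable[tuple[int, int, float]],
        self_weights: np.ndarray | None = None,
    ) -> "WeightedGraph":
        """Build from (i, j, w) index triples; both orientations are stored."""
        n = len(node_ids)
        rows, cols, data = [], [], []
        for i, j, w in edges:
            rows.append(i)
            cols.append(j)
            data.append(w)
            if i != j:
                rows.append(j)
                cols.append(i)
                data.append(w)
        A = sp.csr_array(
            (np.asarray(data, dtype=float), (rows, cols)), shape=(n, n)
        )
        # collapse duplicate entries deterministically
        A.sum_duplicates()
        if self_weights is not None:
            A = A.tolil()
            A.setdiag(self_weights)
            A = sp.csr_array(A.tocsr())
        return cls(tuple(node_ids), A)


@dataclass(frozen=True)
class Partition:
    """Disjoint community assignment: one label per node.

    Labels are canonicalized to a contiguous 0..K-1 range in order of first
    appearance, so two partitions that differ only by a relabeling compare
    equal after construction from the same node order.
    """

    node_ids: tuple[str, ...]
    labels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.shape != (len(self.node_ids),):
            raise ValueError("labels must align with node_ids")
        _, canon = np.unique(lab, return_inverse=True)
        # reindex in order of first appearance for stable output
        order = {}
        out = np.empty(len(lab), dtype=np.int64)
        for k, v in enumerate(canon):
            out[k] = order.setdefault(int(v), len(order))
        object.__setattr__(self, "labels", out)

    @property
    def n_communities(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    def as_dict(self) -> dict[str, int]:
        return {v: int(l) for v, l in zip(self.node_ids, self.labels)}

    def to_cover(self) -> "Cover":
        return Cover(
            self.node_ids, tuple(frozenset((int(l),)) for l in self.labels)
        )

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_communities)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return self.node_ids == other.node_ids and np.array_equal(
            self.labels, other.labels
        )


@dataclass(frozen=True)
class Cover:
    """Overlapping community assignment: a non-empty label set per node."""

    node_ids: tuple[str, ...]
    memberships: tuple[frozenset[int], ...]

    def __post_init__(self) -> None:
        if len(self.memberships) != len(self.node_ids):
            raise ValueError("memberships must align with node_ids")
        if any(len(m) == 0 for m in self.memberships):
            raise ValueError("every node needs at least one community")

    @property
    def labels_used(self) -> tuple[int, ...]:
        return tuple(sorted(set().union(*self.memberships)))

    def is_disjoint(self) -> bool:
        return all(len(m) == 1 for m in self.memberships)

    def to_partition(self) -> Partition:
        if not self.is_disjoint():
            raise ValueError("cover has multi-community nodes")
        return Partition(
            self.node_ids, np.array([next(iter(m)) for m in self.memberships])
        )

    def as_dict(self) -> dict[str, frozenset[int]]:
        return dict(zip(self.node_ids, self.memberships))

    def multicommunity_nodes(self) -> tuple[str, ...]:
        return tuple(
            v for v, m in zip(self.node_ids, self.memberships) if len(m) >= 2
        )


# ---------------------------------------------------------------------------
# readers / writers


def _read_edgelist(path: Path) -> WeightedGraph:
    ids: dict[str, int] = {}
    seen: dict[tuple[int, int], float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (2, 3):
                raise GraphFormatError(
                    f"{path}:{lineno}: expected 'src dst [weight]', got {line!r}"
                )
            try:
                w = float(parts[2]) if len(parts) == 3 else 1.0
            except ValueError as exc:
                raise GraphFormatError(
                    f"{path}:{lineno}: bad weight {parts[2]!r}"
                ) from exc
            if not np.isfinite(w):
                raise GraphFormatError(f"{path}:{lineno}: non-finite weight")
            i = ids.setdefault(parts[0], len(ids))
            j = ids.setdefault(parts[1], len(ids))
            key = (min(i, j), max(i, j))
            if key in seen and seen[key] != w:
                raise GraphFormatError(
                    f"{path}:{lineno}: conflicting weight for edge "
                    f"{parts[0]}--{parts[1]} ({seen[key]} vs {w})"
                )
            seen[key] = w
    if not ids:
        raise GraphFormatError(f"{path}: empty edge list")
    node_ids = [None] * len(ids)
    for v, i in ids.items():
        node_ids[i] = v
    edges = [(i, j, w) for (i, j), w in seen.items() if i != j]
    diag = np.zeros(len(ids))
    for (i, j), w in seen.items():
        if i == j:
            diag[i] = w
    return WeightedGraph.from_edges(node_ids, edges, self_weights=diag)


def _read_matrix_market(path: Path) -> WeightedGraph:
    try:
        M = scipy.io.mmread(path)
    except Exception as exc:  # mmread raises assorted types
        raise GraphFormatError(f"{path}: not a valid Matrix Market file: {exc}")
    A = sp.csr_array(sp.coo_array(M))
    if A.shape[0] != A.shape[1]:
        raise GraphFormatError(f"{path}: matrix is not square")
    asym = abs(A - A.T)
    if asym.nnz and asym.max() > 1e-12:
        raise GraphFormatError(f"{path}: 'general' matrix is not symmetric")
    node_ids = tuple(str(i) for i in range(A.shape[0]))
    return WeightedGraph(node_ids, A)


def read_graph(path: str | Path, format: str = "edgelist") -> WeightedGraph:
    """Read a graph from an edge list or a Matrix Market file.

    Edge lists are whitespace-delimited ``src dst [weight]`` rows with
    optional ``#`` comments; the weight defaults to 1.  Duplicate entries
    for the same unordered pair with different weights are rejected.
    Matrix Market input may be ``symmetric`` or ``general``; general
    matrices are validated for symmetry.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "edgelist":
        return _read_edgelist(path)
    if format == "matrix_market":
        return _read_matrix_market(path)
    raise ValueError(f"unknown graph format {format!r}")


def write_graph(path: str | Path, g: WeightedGraph, format: str = "edgelist") -> None:
    """Write a graph as an edge list (upper triangle) or Matrix Market file."""
    path = Path(path)
    if format == "matrix_market":
        scipy.io.mmwrite(path, sp.coo_matrix(g.adjacency), symmetry="symmetric")
        return
    A = g.adjacency.tocoo()
    with open(path, "w") as fh:
        for i, j, w in zip(A.row, A.col, A.data):
            if i <= j:
                fh.write(f"{g.node_ids[i]}\t{g.node_ids[j]}\t{w:.10g}\n")


def write_outputs(path: str | Path, result: Partition | Cover) -> None:
    """Write a partition or cover as TSV with header ``node\\tcommunity``.

    Covers get one row per membership.  Round-trips losslessly through
    :func:`read_partition` / :func:`read_cover`.
    """
    if len(result.node_ids) == 0:
        raise ValueError("refusing to write an empty assignment")
    rows: list[tuple[str, int]] = []
    if isinstance(result, Partition):
        rows = list(zip(result.node_ids, (int(l) for l in result.labels)))
    else:
        for v, mem in zip(result.node_ids, result.memberships):
            rows.extend((v, c) for c in sorted(mem))
    with open(path, "w") as fh:
        fh.write("node\tcommunity\n")
        for v, c in rows:
            fh.write(f"{v}\t{c}\n")


def _read_assignment_rows(path: Path) -> list[tuple[str, int]]:
    rows = []
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise GraphFormatError(f"{path}: empty assignment file")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.strip()
            if not line:
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise GraphFormatError(f"{path}:{lineno}: expected 2 columns")
            rows.append((parts[0], int(parts[1])))
    if not rows:
        raise GraphFormatError(f"{path}: no assignments")
    return rows


def read_partition(path: str | Path) -> Partition:
    rows = _read_assignment_rows(Path(path))
    ids, labels = zip(*rows)
    if len(set(ids)) != len(ids):
        raise GraphFormatError(f"{path}: duplicate node rows in partition")
    return Partition(tuple(ids), np.asarray(labels))


def read_cover(path: str | Path) -> Cover:
    rows = _read_assignment_rows(Path(path))
    mem: dict[str, set[int]] = {}
    order: list[str] = []
    for v, c in rows:
        if v not in mem:
            order.append(v)
            mem[v] = set()
        mem[v].add(c)
    return Cover(tuple(order), tuple(frozenset(mem[v]) for v in order))


# ---------------------------------------------------------------------------
# preprocessing


SKEW_THRESHOLD = 2.0


def preprocess_graph(g: WeightedGraph) -> WeightedGraph:
    """Normalize edge weights and set self-connection weights.

    Three rules, applied in order:

    1. If the maximum absolute off-diagonal weight is below one, all
       weights are rescaled so the new maximum equals one.
    2. Weights already spanning [-1, 1] with low skew pass through
       unadjusted.
    3. If the positive off-diagonal weight distribution is heavily skewed
       (sample skewness > 2), each node's self-connection weight is
       replaced by its average off-diagonal edge weight.  The ratio of
       self weight to neighbor weight controls how readily a node leaves
       its own label, so heavy-tailed weight distributions need this
       recentering.

    Idempotent; never changes the off-diagonal sparsity pattern.
    """
    off = g.offdiag()
    if off.nnz == 0:
        return g
    w = off.data
    wmax = np.abs(w).max()
    A = sp.csr_array(g.adjacency, copy=True)
    if wmax < 1.0:
        A = A * (1.0 / wmax)
        off = off * (1.0 / wmax)
        w = off.data
    if np.abs(w).max() > 1.0 + 1e-12:
        raise WeightDomainError(
            "edge weights exceed [-1, 1]; normalize the input network "
            "(e.g. divide by the maximum absolute weight) before clustering"
        )
    pos = w[w > 0]
    heavy = len(pos) >= 3 and np.std(pos) > 0 and skew(pos) > SKEW_THRESHOLD
    if heavy:
        deg = np.diff(off.indptr)
        rowsum = np.asarray(off.sum(axis=1)).ravel()
        avg = np.divide(rowsum, deg, out=np.zeros_like(rowsum), where=deg > 0)
        A = A.tolil()
        A.setdiag(avg)
        A = sp.csr_array(A.tocsr())
    return WeightedGraph(g.node_ids, A)


def symmetrize(node_ids: Sequence[str], A: sp.spmatrix) -> WeightedGraph:
    """Average a directed adjacency with its transpose, with a warning."""
    A = sp.csr_array(A)
    asym = abs(A - A.T)
    if asym.nnz and asym.max() > 1e-12:
        warnings.warn("directed input symmetrized by averaging (i,j) and (j,i)")
        A = (A + A.T) * 0.5
    return WeightedGraph(tuple(node_ids), A)
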