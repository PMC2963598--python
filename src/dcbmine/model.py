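"""Profile networks and the densely-connected-bicluster (DCB) predicates.

A *profile network* is an undirected gene interaction graph in which every
node carries an expression profile (log fold-changes) over a shared, ordered
list of experimental conditions. A gene set is a *densely connected
bicluster* with respect to parameters (gamma, epsilon, d_min) when its
induced subgraph is connected, its edge density is at least gamma, and all
member genes lie within epsilon of each other in at least d_min conditions.
The set of qualifying conditions is the module's *profile subspace*.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import DomainError, UnknownGeneError

__all__ = [
    "DCBParams",
    "ProfileNetwork",
    "Module",
    "density",
    "is_connected",
    "coexpression_subspace",
    "is_dcb",
]


@dataclass(frozen=True)
class DCBParams:
    """Constraint triple of the DCB problem.

    Parameters
    ----------
    gamma : float
        Density threshold in [0, 1]: minimum fraction of the C(k, 2)
        possible edges that must be present in a k-gene module.
    epsilon : float
        Homogeneity threshold (same units as the expression values,
        typically log2 fold-change): maximum spread allowed between member
        genes in a condition for it to count as co-expressed.
    d_min : int
        Minimum number of conditions in which the genes must be
        co-expressed.
    """

    gamma: float
    epsilon: float
    d_min: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise DomainError(f"gamma must be in [0, 1], got {self.gamma}")
        if self.epsilon < 0:
            raise DomainError(f"epsilon must be >= 0, got {self.epsilon}")
        if self.d_min < 1:
            raise DomainError(f"d_min must be a positive integer, got {self.d_min}")


class ProfileNetwork:
    """Undirected gene graph plus per-gene expression profiles.

    Parameters
    ----------
    genes : sequence of str
        Ordered gene identifiers (opaque, case-sensitive strings).
    edges : iterable of (str, str)
        Undirected interaction pairs; duplicates are collapsed. Self-loops
        are rejected (drop them at I/O time).
    profiles : mapping gene -> sequence of float, or 2-d array
        Expression values per gene over the shared condition list; NaN
        encodes a missing measurement. An array must be aligned with
        ``genes`` row-wise.
    condition_names : sequence of str
        Ordered condition labels; every profile must have this length.
    """

    def __init__(
        self,
        genes: Sequence[str],
        edges: Iterable[tuple[str, str]],
        profiles: Mapping[str, Sequence[float]] | np.ndarray,
        condition_names: Sequence[str],
    ):
        self.genes: tuple[str, ...] = tuple(genes)
        if len(set(self.genes)) != len(self.genes):
            raise DomainError("duplicate gene identifiers in gene list")
        self.condition_names: tuple[str, ...] = tuple(condition_names)
        self._index: dict[str, int] = {g: i for i, g in enumerate(self.genes)}

        if isinstance(profiles, np.ndarray):
            mat = np.asarray(profiles, dtype=float)
            if mat.shape != (len(self.genes), len(self.condition_names)):
                raise DomainError(
                    f"profile matrix shape {mat.shape} does not match "
                    f"({len(self.genes)} genes, {len(self.condition_names)} conditions)"
                )
        else:
            mat = np.empty((len(self.genes), len(self.condition_names)), dtype=float)
            for g in self.genes:
                if g not in profiles:
                    raise DomainError(f"no profile supplied for gene {g!r}")
                row = np.asarray(profiles[g], dtype=float)
                if row.shape != (len(self.condition_names),):
                    raise DomainError(
                        f"profile for gene {g!r} has length {row.size}, "
                        f"expected {len(self.condition_names)}"
                    )
                mat[self._index[g]] = row
        self.profiles: np.ndarray = mat

        self.graph = nx.Graph()
        self.graph.add_nodes_from(self.genes)
        for u, v in edges:
            if u not in self._index:
                raise UnknownGeneError(u)
            if v not in self._index:
                raise UnknownGeneError(v)
            if u == v:
                raise DomainError(f"self-loop on gene {u!r} is not allowed")
            self.graph.add_edge(u, v)

    # -- basic accessors -------------------------------------------------
    @property
    def n_conditions(self) -> int:
        return len(self.condition_names)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def index(self, gene: str) -> int:
        try:
            return self._index[gene]
        except KeyError:
            raise UnknownGeneError(gene) from None

    def profile(self, gene: str) -> np.ndarray:
        return self.profiles[self.index(gene)]

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def __repr__(self) -> str:
        return (
            f"ProfileNetwork({self.n_genes} genes, {self.n_edges} edges, "
            f"{self.n_conditions} conditions)"
        )


@dataclass(frozen=True, eq=False)
class Module:
    """A gene set with its witnessing co-expression subspace.

    ``subspace`` is the full (maximal) set of condition indices in which the
    member genes are mutually within epsilon. ``density`` is the edge ratio
    of the induced subgraph at creation time (NaN when unknown, e.g. a
    merge performed without the network); modules produced by merging may
    fall below the enumeration threshold gamma.
    """

    genes: frozenset[str]
    subspace: frozenset[int]
    density: float
    provenance: str = "enumerated"  # "enumerated" | "merged"

    def __post_init__(self) -> None:
        if self.provenance not in ("enumerated", "merged"):
            raise DomainError(f"unknown provenance {self.provenance!r}")

    def __eq__(self, other) -> bool:
        if not isinstance(other, Module):
            return NotImplemented
        dens_equal = self.density == other.density or (
            math.isnan(self.density) and math.isnan(other.density)
        )
        return (
            self.genes == other.genes
            and self.subspace == other.subspace
            and dens_equal
            and self.provenance == other.provenance
        )

    def __hash__(self) -> int:
        return hash((self.genes, self.subspace, self.provenance))

    @property
    def size(self) -> int:
        return len(self.genes)

    def sort_key(self) -> tuple[int, tuple[str, ...]]:
        """Stable output ordering: larger first, then lexicographic genes."""
        return (-len(self.genes), tuple(sorted(self.genes)))


# -- predicates ----------------------------------------------------------

def _check_members(net: ProfileNetwork, gene_set: Iterable[str]) -> list[str]:
    members = list(gene_set)
    if not members:
        raise DomainError("gene set must be non-empty")
    for g in members:
        if g not in net:
            raise UnknownGeneError(g)
    return members


def density(net: ProfileNetwork, gene_set: Iterable[str]) -> float:
    """Edge density of the induced subgraph: |edges| / C(k, 2).

    Singletons return 1.0 by convention (the empty-denominator case never
    corresponds to an emitted module).
    """
    members = set(_check_members(net, gene_set))
    k = len(members)
    if k == 1:
        return 1.0
    adj = net.graph.adj
    m = sum(1 for u in members for v in adj[u] if v in members) // 2
    return m / (k * (k - 1) / 2)


def induced_edge_count(net: ProfileNetwork, gene_set: Iterable[str]) -> int:
    """Number of network edges with both endpoints inside ``gene_set``."""
    members = set(_check_members(net, gene_set))
    adj = net.graph.adj
    return sum(1 for u in members for v in adj[u] if v in members) // 2


def is_connected(net: ProfileNetwork, gene_set: Iterable[str]) -> bool:
    """True iff the induced subgraph on ``gene_set`` is connected."""
    members = set(_check_members(net, gene_set))
    adj = net.graph.adj
    start = next(iter(members))
    seen = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v in members and v not in seen:
                seen.add(v)
                stack.append(v)
    return len(seen) == len(members)


def coexpression_subspace(
    net: ProfileNetwork, gene_set: Iterable[str], epsilon: float
) -> frozenset[int]:
    """Conditions in which all genes are mutually within ``epsilon``.

    A condition qualifies when every gene in the set has a non-missing value
    there and the spread (max minus min, equivalent to the all-pairs
    difference bound) does not exceed ``epsilon``. Conditions with any
    missing value among the set are excluded.
    """
    members = _check_members(net, gene_set)
    idx = [net.index(g) for g in members]
    sub = net.profiles[idx]
    valid = ~np.isnan(sub).any(axis=0)
    spread = np.full(sub.shape[1], np.inf)
    if valid.any():
        cols = sub[:, valid]
        spread[valid] = cols.max(axis=0) - cols.min(axis=0)
    return frozenset(int(d) for d in np.flatnonzero(valid & (spread <= epsilon)))


def is_dcb(
    net: ProfileNetwork, gene_set: Iterable[str], params: DCBParams
) -> tuple[bool, frozenset[int] | None]:
    """Test the full DCB predicate; return (verdict, witnessing subspace).

    True iff the induced subgraph is connected, gamma-dense, and the genes
    are co-expressed in at least d_min conditions. On success the full
    (maximal) subspace is returned as the witness; on failure the subspace
    slot is None.
    """
    members = set(_check_members(net, gene_set))
    if len(members) < 2:
        raise DomainError("is_dcb requires a gene set of size >= 2")
    if not is_connected(net, members):
        return False, None
    if density(net, members) < params.gamma:
        return False, None
    subspace = coexpression_subspace(net, members, params.epsilon)
    if len(subspace) < params.d_min:
        return False, None
    return True, subspace
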