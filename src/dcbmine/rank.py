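"""Statistical ranking and redundancy filtering of modules.

Two independent significance criteria are computed per module:

* **Co-expression**: the number of co-expressed conditions of the module is
  compared against an empirical null built by sampling connected
  subnetworks of the same size from the interaction network (default 2000
  draws), whose co-expressed-condition counts are fitted by maximum
  likelihood to a normal distribution truncated to [0, #conditions].
* **Dense connectivity**: the module's induced edge count m among its
  C(k, 2) possible edges is referred to the hypergeometric distribution of
  drawing C(k, 2) gene pairs from the C(n, 2) pairs of the whole network,
  of which |E| are edges.

Modules are ranked on each criterion separately (smaller upper-tail
p-value = better), the two ranks are averaged into an overall rank, and a
top-down filter removes modules whose genes are already covered by
better-ranked ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import networkx as nx
import numpy as np
from scipy import optimize, stats

from .errors import DomainError, SamplingError
from .model import Module, ProfileNetwork, coexpression_subspace, induced_edge_count

__all__ = [
    "CoexpressionNull",
    "RankedModule",
    "sample_connected_subnetworks",
    "fit_coexpression_null",
    "coexpression_pvalue",
    "density_pvalue",
    "rank_modules",
    "filter_ranked",
]


@dataclass(frozen=True)
class CoexpressionNull:
    """Truncated-normal null for co-expressed-condition counts.

    ``lower``/``upper`` are the truncation bounds (0 and the number of
    conditions). A constant sample yields a degenerate point-mass null
    (``degenerate=True``, location at the mass point, scale 0).
    """

    loc: float
    scale: float
    lower: float
    upper: float
    n_samples: int
    degenerate: bool = False

    def _ab(self) -> tuple[float, float]:
        return (self.lower - self.loc) / self.scale, (self.upper - self.loc) / self.scale


def sample_connected_subnetworks(
    net: ProfileNetwork | nx.Graph,
    k: int,
    n_samples: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[frozenset[str]]:
    """Sample connected induced gene sets of exactly ``k`` genes.

    A uniform start node is drawn from the nodes of components with at
    least k members; the set then grows by repeatedly adding a uniformly
    chosen neighbor of the current set until it has k genes (restarting on
    a dead end, which cannot occur inside a component of size >= k).
    Deterministic under ``seed``.
    """
    graph = net.graph if isinstance(net, ProfileNetwork) else net
    if rng is None:
        rng = np.random.default_rng(seed)
    eligible = sorted(
        n for c in nx.connected_components(graph) if len(c) >= k for n in c
    )
    if not eligible:
        raise SamplingError(
            f"no connected component with at least {k} genes to sample from"
        )
    adj = graph.adj
    samples: list[frozenset[str]] = []
    while len(samples) < n_samples:
        current = {eligible[rng.integers(len(eligible))]}
        while len(current) < k:
            frontier = sorted(
                {v for u in current for v in adj[u]} - current
            )
            if not frontier:
                break  # dead end; restart
            current.add(frontier[rng.integers(len(frontier))])
        if len(current) == k:
            samples.append(frozenset(current))
    return samples


def fit_coexpression_null(
    counts: list[int] | np.ndarray, bounds: tuple[float, float]
) -> CoexpressionNull:
    """Maximum-likelihood truncated-normal fit with fixed truncation bounds."""
    arr = np.asarray(counts, dtype=float)
    if arr.size == 0:
        raise DomainError("counts must be non-empty")
    lo, hi = float(bounds[0]), float(bounds[1])
    if np.any(arr < lo) or np.any(arr > hi):
        raise DomainError("counts fall outside the truncation bounds")
    if np.ptp(arr) == 0:
        return CoexpressionNull(
            loc=float(arr[0]), scale=0.0, lower=lo, upper=hi,
            n_samples=arr.size, degenerate=True,
        )

    def nll(theta: np.ndarray) -> float:
        loc, log_scale = theta
        scale = np.exp(log_scale)
        a, b = (lo - loc) / scale, (hi - loc) / scale
        ll = stats.truncnorm.logpdf(arr, a, b, loc=loc, scale=scale)
        if not np.all(np.isfinite(ll)):
            return np.inf
        return -ll.sum()

    x0 = np.array([arr.mean(), np.log(max(arr.std(ddof=1), 1e-6))])
    res = optimize.minimize(nll, x0, method="Nelder-Mead", options={"xatol": 1e-6, "fatol": 1e-8})
    loc, scale = float(res.x[0]), float(np.exp(res.x[1]))
    return CoexpressionNull(
        loc=loc, scale=scale, lower=lo, upper=hi, n_samples=arr.size,
    )


def coexpression_pvalue(null: CoexpressionNull, observed: float) -> float:
    """Upper-tail probability P(X >= observed) under the fitted null."""
    if not null.lower <= observed <= null.upper:
        raise DomainError(
            f"observed count {observed} outside [{null.lower}, {null.upper}]"
        )
    if null.degenerate:
        return 1.0 if observed <= null.loc else 0.0
    a, b = null._ab()
    return float(stats.truncnorm.sf(observed, a, b, loc=null.loc, scale=null.scale))


def density_pvalue(n_nodes: int, n_edges: int, k: int, m: int) -> float:
    """Upper-tail hypergeometric probability of a k-gene module having m edges.

    Population: the C(n_nodes, 2) gene pairs of the whole network, of which
    n_edges are edges; draws: the C(k, 2) pairs inside the module. Returns
    P(X >= m).
    """
    if not 2 <= k <= n_nodes:
        raise DomainError(f"module size k={k} must satisfy 2 <= k <= {n_nodes}")
    pairs_total = comb(n_nodes, 2)
    pairs_module = comb(k, 2)
    if not 0 <= n_edges <= pairs_total:
        raise DomainError(f"n_edges={n_edges} outside [0, {pairs_total}]")
    if not 0 <= m <= pairs_module or m > n_edges:
        raise DomainError(
            f"module edge count m={m} outside [0, min({pairs_module}, {n_edges})]"
        )
    return float(stats.hypergeom.sf(m - 1, pairs_total, n_edges, pairs_module))


@dataclass(frozen=True)
class RankedModule:
    """A module plus its two p-values, per-criterion ranks and overall rank."""

    module: Module
    p_coexpression: float
    p_density: float
    rank_coexpression: int
    rank_density: int
    overall_rank: float = field(default=0.0)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "overall_rank", (self.rank_coexpression + self.rank_density) / 2
        )


def _competition_ranks(pvalues: list[float]) -> list[int]:
    """Competition ("1224") ranking: rank = 1 + number of strictly smaller values."""
    arr = np.asarray(pvalues)
    return [int(1 + np.sum(arr < p)) for p in arr]


def rank_modules(
    modules: list[Module],
    net: ProfileNetwork,
    epsilon: float,
    n_samples: int = 2000,
    seed: int | None = None,
    per_size: bool = True,
) -> list[RankedModule]:
    """Rank modules by co-expression and dense-connectivity significance.

    Co-expression nulls are fitted per module size (size-matched sampling)
    by default, since co-expressed-condition counts depend strongly on set
    size; ``per_size=False`` pools one null over all sampled sizes. The
    returned list is sorted by overall rank, ties broken by (size
    descending, lexicographic gene list).
    """
    if not modules:
        raise DomainError("rank_modules requires a non-empty module list")
    rng = np.random.default_rng(seed)
    bounds = (0.0, float(net.n_conditions))
    sizes = sorted({m.size for m in modules})
    counts_by_size: dict[int, list[int]] = {}
    for k in sizes:
        samples = sample_connected_subnetworks(net, k, n_samples, rng=rng)
        counts_by_size[k] = [
            len(coexpression_subspace(net, s, epsilon)) for s in samples
        ]
    if per_size:
        nulls = {k: fit_coexpression_null(c, bounds) for k, c in counts_by_size.items()}
    else:
        pooled = fit_coexpression_null(
            [x for c in counts_by_size.values() for x in c], bounds
        )
        nulls = {k: pooled for k in sizes}

    p_co = [
        coexpression_pvalue(nulls[m.size], len(m.subspace)) for m in modules
    ]
    p_de = [
        density_pvalue(net.n_genes, net.n_edges, m.size, induced_edge_count(net, m.genes))
        for m in modules
    ]
    r_co = _competition_ranks(p_co)
    r_de = _competition_ranks(p_de)
    ranked = [
        RankedModule(
            module=m,
            p_coexpression=pc,
            p_density=pd,
            rank_coexpression=rc,
            rank_density=rd,
        )
        for m, pc, pd, rc, rd in zip(modules, p_co, p_de, r_co, r_de)
    ]
    ranked.sort(key=lambda r: (r.overall_rank,) + r.module.sort_key())
    return ranked


def filter_ranked(
    ranked: list[RankedModule],
    top_n: int | None = None,
    union_containment: bool = True,
) -> list[RankedModule]:
    """Top-down redundancy filter over an overall-rank-ordered list.

    A module is kept iff its gene set is not contained in the union of the
    gene sets of the modules already kept (``union_containment=False``
    checks containment in any single kept module instead). With ``top_n``
    the traversal stops once that many modules have been kept.
    """
    kept: list[RankedModule] = []
    covered: set[str] = set()
    for r in ranked:
        genes = r.module.genes
        if union_containment:
            redundant = genes <= covered
        else:
            redundant = any(genes <= k.module.genes for k in kept)
        if not redundant:
            kept.append(r)
            covered |= genes
            if top_n is not None and len(kept) >= top_n:
                break
    return kept
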