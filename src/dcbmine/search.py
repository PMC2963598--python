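"""Exhaustive enumeration of maximal densely connected biclusters.

The search organizes connected subnetworks in a lattice where a child is
obtained from its parent by adding one connected gene, and traverses it
breadth-first. For gamma >= 0.5 the DCB constraint is *loosely
anti-monotone*: every satisfying subnetwork of size k+1 contains at least
one satisfying induced subnetwork of size k, so testing only children of
size-k DCBs is exhaustive. Below gamma = 0.5 the property fails and the
brute-force enumerator must be used instead.
"""

from __future__ import annotations

import logging
from itertools import combinations

from .errors import DomainError
from .model import DCBParams, Module, ProfileNetwork, coexpression_subspace, density, is_dcb

logger = logging.getLogger(__name__)

__all__ = ["enumerate_dcbs", "brute_force_dcbs"]


def _maximal(dcbs: dict[frozenset[str], frozenset[int]]) -> list[frozenset[str]]:
    """Gene sets not strictly contained in another DCB's gene set."""
    by_size = sorted(dcbs, key=len, reverse=True)
    kept: list[frozenset[str]] = []
    for s in by_size:
        if not any(s < t for t in kept):
            kept.append(s)
    return kept


def _build_modules(
    net: ProfileNetwork,
    dcbs: dict[frozenset[str], frozenset[int]],
    min_size: int,
) -> list[Module]:
    out = [
        Module(genes=s, subspace=dcbs[s], density=density(net, s))
        for s in _maximal(dcbs)
        if len(s) >= min_size
    ]
    return sorted(out, key=Module.sort_key)


def enumerate_dcbs(
    net: ProfileNetwork,
    params: DCBParams,
    min_size: int = 3,
    max_size: int | None = None,
    candidate_hook=None,
) -> list[Module]:
    """All maximal DCBs of size >= ``min_size`` via breadth-first lattice search.

    Level k = 2 is seeded with every edge whose endpoint pair is
    sufficiently co-expressed; level k+1 candidates are the one-gene
    neighbor extensions of the size-k DCBs, deduplicated by gene set. A
    final pass discards any DCB whose gene set is a strict subset of
    another enumerated DCB's gene set, implementing maximality literally.

    Parameters
    ----------
    net, params :
        Instance and constraint triple; ``params.gamma`` must be >= 0.5 —
        the regime in which loose anti-monotonicity guarantees completeness.
    min_size : int
        Smallest reported module size (size-2 DCBs always seed the search).
    max_size : int or None
        Engineering safety valve; reaching it aborts deeper levels and
        voids the completeness guarantee, which is logged loudly.
    candidate_hook : callable or None
        Called as ``candidate_hook(gene_set, level)`` for every candidate
        tested above the seed level (instrumentation for tests).
    """
    if params.gamma < 0.5:
        raise DomainError(
            "enumerate_dcbs requires gamma >= 0.5 (loose anti-monotonicity); "
            "use brute_force_dcbs for smaller density thresholds"
        )
    if min_size < 2:
        raise DomainError("min_size must be >= 2")

    level: dict[frozenset[str], frozenset[int]] = {}
    for u, v in net.graph.edges:
        sub = coexpression_subspace(net, (u, v), params.epsilon)
        if len(sub) >= params.d_min:
            level[frozenset((u, v))] = sub
    all_dcbs: dict[frozenset[str], frozenset[int]] = dict(level)

    adj = net.graph.adj
    k = 2
    while level:
        if max_size is not None and k >= max_size:
            logger.warning(
                "enumeration stopped at the size cap %d with %d live sets; "
                "the output is no longer guaranteed to be complete",
                max_size,
                len(level),
            )
            break
        nxt: dict[frozenset[str], frozenset[int]] = {}
        tested: set[frozenset[str]] = set()
        for s in level:
            neighbors = set()
            for g in s:
                neighbors.update(adj[g])
            neighbors -= s
            for g in neighbors:
                cand = s | {g}
                if cand in tested:
                    continue
                tested.add(cand)
                if candidate_hook is not None:
                    candidate_hook(cand, k + 1)
                ok, sub = is_dcb(net, cand, params)
                if ok:
                    nxt[cand] = sub
        all_dcbs.update(nxt)
        level = nxt
        k += 1

    return _build_modules(net, all_dcbs, min_size)


def brute_force_dcbs(
    net: ProfileNetwork,
    params: DCBParams,
    min_size: int = 3,
    max_size: int | None = None,
    gene_cap: int = 18,
) -> list[Module]:
    """Reference enumerator: test every gene subset directly.

    Enumerates all subsets of size in [min_size, max_size] (default
    max_size = number of genes), keeps those passing the DCB predicate and
    returns the maximal ones under the same strict-subset criterion as
    :func:`enumerate_dcbs`. Works for any gamma, including gamma < 0.5
    where the lattice search is incomplete, but is exponential in the gene
    count and therefore refuses networks above ``gene_cap`` genes.
    """
    n = net.n_genes
    if n > gene_cap:
        raise DomainError(
            f"brute_force_dcbs caps at {gene_cap} genes, got {n}"
        )
    if min_size < 2:
        raise DomainError("min_size must be >= 2")
    if max_size is None:
        max_size = n

    dcbs: dict[frozenset[str], frozenset[int]] = {}
    for k in range(min_size, max_size + 1):
        for combo in combinations(net.genes, k):
            s = frozenset(combo)
            ok, sub = is_dcb(net, s, params)
            if ok:
                dcbs[s] = sub
    return _build_modules(net, dcbs, min_size)
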