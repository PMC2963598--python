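"""Core-attachment merging of overlapping modules.

Functional subunits in biomolecular networks often consist of a dense core
plus peripheral genes attached to it, and incomplete interaction data tends
to split such units into overlapping fragments. The refinement below
iteratively merges module pairs that share a large fraction of both their
members and their co-expression subspaces. Merging deliberately relaxes the
enumeration constraints: a merged module's density may drop below gamma and
its subspace (the intersection of the parents') may drop below d_min.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .errors import DomainError
from .model import Module, ProfileNetwork, density

logger = logging.getLogger(__name__)

__all__ = ["MergeParams", "merge_modules"]


@dataclass(frozen=True)
class MergeParams:
    """Overlap thresholds for merging, both as fractions in (0, 1].

    ``member_overlap`` / ``subspace_overlap`` are compared against the
    intersection divided by the smaller of the two sets, so a small module
    sitting almost wholly inside a big one merges into it. Set
    ``jaccard=True`` to divide by the union instead.
    """

    member_overlap: float = 0.75
    subspace_overlap: float = 0.75
    jaccard: bool = False

    def __post_init__(self) -> None:
        for name in ("member_overlap", "subspace_overlap"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise DomainError(f"{name} must be in (0, 1], got {v}")


def _overlap(a: frozenset, b: frozenset, jaccard: bool) -> float:
    if not a or not b:
        return 0.0
    inter = len(a & b)
    denom = len(a | b) if jaccard else min(len(a), len(b))
    return inter / denom


def _pair_key(m1: Module, m2: Module):
    k1, k2 = sorted((tuple(sorted(m1.genes)), tuple(sorted(m2.genes))))
    return (k1, k2)


def merge_modules(
    modules: list[Module],
    params: MergeParams,
    net: ProfileNetwork | None = None,
) -> list[Module]:
    """Merge overlapping modules to a fixpoint.

    Exact-duplicate gene sets are always collapsed first. Then, while any
    pair exceeds both overlap thresholds, the pair with the highest member
    overlap (ties broken lexicographically on sorted gene lists) is
    replaced by one module whose gene set is the union and whose subspace
    is the intersection of the parents'. Merged modules carry
    ``provenance="merged"``; their density is recomputed when ``net`` is
    supplied and NaN otherwise.
    """
    # collapse duplicates deterministically
    by_genes: dict[frozenset, Module] = {}
    order = sorted(modules, key=Module.sort_key)
    dup = 0
    for m in order:
        if m.genes in by_genes:
            prev = by_genes[m.genes]
            by_genes[m.genes] = Module(
                genes=m.genes,
                subspace=prev.subspace & m.subspace,
                density=prev.density,
                provenance=prev.provenance,
            )
            dup += 1
        else:
            by_genes[m.genes] = m
    if dup:
        logger.info("merge_modules: collapsed %d duplicate gene set(s)", dup)
    pool = list(by_genes.values())

    def recompute(genes: frozenset, subspace: frozenset) -> Module:
        if net is not None:
            dens = density(net, genes)
            # intersection of parents' subspaces is the witness; keep it
            # rather than recomputing, matching the relaxed semantics
        else:
            dens = float("nan")
        return Module(genes=genes, subspace=subspace, density=dens, provenance="merged")

    while True:
        best = None
        for i in range(len(pool)):
            for j in range(i + 1, len(pool)):
                m1, m2 = pool[i], pool[j]
                ov_g = _overlap(m1.genes, m2.genes, params.jaccard)
                if ov_g < params.member_overlap:
                    continue
                ov_s = _overlap(m1.subspace, m2.subspace, params.jaccard)
                if ov_s < params.subspace_overlap:
                    continue
                cand = (-ov_g, _pair_key(m1, m2), i, j)
                if best is None or cand < best:
                    best = cand
        if best is None:
            break
        _, _, i, j = best
        m1, m2 = pool[i], pool[j]
        merged = recompute(m1.genes | m2.genes, m1.subspace & m2.subspace)
        if len(merged.subspace) == 0 or (
            merged.subspace != m1.subspace or merged.subspace != m2.subspace
        ):
            logger.debug(
                "merge: %s + %s -> %s (subspace %d)",
                sorted(m1.genes),
                sorted(m2.genes),
                sorted(merged.genes),
                len(merged.subspace),
            )
        pool = [m for k, m in enumerate(pool) if k not in (i, j)]
        # a merge can recreate an existing gene set; collapse immediately
        replaced = False
        for k, m in enumerate(pool):
            if m.genes == merged.genes:
                pool[k] = Module(
                    genes=m.genes,
                    subspace=m.subspace & merged.subspace,
                    density=m.density if not math.isnan(m.density) else merged.density,
                    provenance="merged",
                )
                replaced = True
                break
        if not replaced:
            pool.append(merged)

    return sorted(pool, key=Module.sort_key)
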