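"""GO-based assessment of a module collection.

Implements the standard module-quality battery: per-module term enrichment
(one-sided hypergeometric over the analyzed background, with
Benjamini-Hochberg correction across all module/term tests of a run),
plus four summary quantities:

* **ER** (enrichment ratio): percent of modules enriched with at least one
  *deep* term — level >= ``deep_level`` (level 7 or higher by default,
  i.e. 7, 8, 9, ...), where a term's level is the shortest directed path
  from an ontology root.
* **COV** (coverage): percent of the terms associated with any background
  gene that are enriched in at least one module.
* **IC** (individual coverage): the probability that, for a random
  (gene, term) association, the term is enriched in some module containing
  the gene — i.e. the mean over genes of e_g / t_g, with t_g the gene's
  term count and e_g the number of those terms enriched in a module
  containing g. Overlapping module collections can cover several
  functional contexts of the same gene; partitions cannot.
* **OMPSDF**: the count of overlapping module pairs supporting different
  functionalities — pairs sharing genes but no core-level enriched term,
  in which a shared gene carries two deep terms enriched in exactly one
  module each.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
from scipy import stats

from .errors import DomainError, StructureError
from .model import Module, ProfileNetwork, density

__all__ = [
    "AnnotationSet",
    "EnrichmentResult",
    "MetricsReport",
    "term_levels",
    "enrich",
    "enrich_modules",
    "enriched_terms",
    "enrichment_ratio",
    "coverage",
    "individual_coverage",
    "ompsdf",
    "basic_stats",
    "assess",
]


def term_levels(dag_edges: list[tuple[str, str]]) -> dict[str, int]:
    """Shortest-path level of every term from the nearest ontology root.

    ``dag_edges`` are (child, parent) pairs. Roots (terms that never appear
    as a child) have level 0; with several roots the minimum distance
    counts. A cyclic edge table raises :class:`StructureError`.
    """
    down = nx.DiGraph()  # parent -> child
    terms: set[str] = set()
    for child, parent in dag_edges:
        terms.update((child, parent))
        down.add_edge(parent, child)
    down.add_nodes_from(terms)
    if not nx.is_directed_acyclic_graph(down):
        raise StructureError("term edge table contains a cycle")
    children = {c for c, _ in dag_edges}
    roots = sorted(terms - children)
    if not roots:
        raise StructureError("term edge table has no root (every term has a parent)")
    level: dict[str, int] = {r: 0 for r in roots}
    queue = deque(roots)
    while queue:
        t = queue.popleft()
        for c in down.successors(t):
            if c not in level:
                level[c] = level[t] + 1
                queue.append(c)
    return level


@dataclass(frozen=True)
class AnnotationSet:
    """Gene -> term annotations plus term levels.

    ``term_level`` may be supplied directly or derived from a child->parent
    edge table via :meth:`from_tables`. Terms without a known level never
    satisfy a level-based condition (deep or core).
    """

    gene_terms: dict[str, frozenset[str]]
    term_level: dict[str, int]

    @classmethod
    def from_tables(
        cls,
        gene_terms: dict[str, frozenset[str]] | list[tuple[str, str]],
        dag_edges: list[tuple[str, str]] | None = None,
        term_level: dict[str, int] | None = None,
    ) -> "AnnotationSet":
        if not isinstance(gene_terms, dict):
            mapping: dict[str, set[str]] = {}
            for gene, term in gene_terms:
                mapping.setdefault(gene, set()).add(term)
            gene_terms = {g: frozenset(ts) for g, ts in mapping.items()}
        else:
            gene_terms = {g: frozenset(ts) for g, ts in gene_terms.items()}
        if term_level is None:
            term_level = term_levels(dag_edges) if dag_edges else {}
        return cls(gene_terms=gene_terms, term_level=dict(term_level))

    def terms_of(self, gene: str) -> frozenset[str]:
        return self.gene_terms.get(gene, frozenset())

    def dataset_terms(self, genes) -> frozenset[str]:
        """All terms associated with any of the given genes."""
        out: set[str] = set()
        for g in genes:
            out |= self.terms_of(g)
        return frozenset(out)


@dataclass(frozen=True)
class EnrichmentResult:
    module_id: int
    term: str
    p_raw: float
    p_corrected: float
    level: int | None


def enrich(
    module_genes: frozenset[str] | set[str],
    annotations: AnnotationSet,
    background: frozenset[str] | set[str],
) -> list[tuple[str, float]]:
    """Raw one-sided hypergeometric enrichment p-values for one module.

    For each term annotating at least one module gene: population = the
    background, successes = background genes carrying the term, draws =
    module size, observed = module genes carrying the term;
    p = P(X >= observed).
    """
    background = frozenset(background)
    if not background:
        raise DomainError("background gene set is empty")
    module_genes = frozenset(module_genes)
    if not module_genes <= background:
        missing = sorted(module_genes - background)[:3]
        raise DomainError(f"module genes not in background: {missing}")
    n_bg = len(background)
    n_mod = len(module_genes)
    terms = sorted({t for g in module_genes for t in annotations.terms_of(g)})
    out = []
    for term in terms:
        with_term = frozenset(
            g for g in background if term in annotations.terms_of(g)
        )
        observed = len(module_genes & with_term)
        p = float(stats.hypergeom.sf(observed - 1, n_bg, len(with_term), n_mod))
        out.append((term, min(p, 1.0)))
    return out


def enrich_modules(
    modules: list[Module],
    annotations: AnnotationSet,
    background: frozenset[str] | set[str],
    method: str = "bh",
) -> list[EnrichmentResult]:
    """Enrichment for all modules with multiple-testing correction.

    The correction family is all (module, term) tests of the run: one
    global Benjamini-Hochberg (default) or Bonferroni pass.
    """
    if method not in ("bh", "bonferroni"):
        raise DomainError(f"unknown correction method {method!r}")
    raw: list[tuple[int, str, float]] = []
    for i, m in enumerate(modules):
        for term, p in enrich(m.genes, annotations, background):
            raw.append((i, term, p))
    if not raw:
        return []
    pvals = [p for _, _, p in raw]
    if method == "bh":
        corrected = stats.false_discovery_control(pvals, method="bh")
    else:
        corrected = [min(1.0, p * len(pvals)) for p in pvals]
    return [
        EnrichmentResult(
            module_id=i,
            term=term,
            p_raw=p,
            p_corrected=float(q),
            level=annotations.term_level.get(term),
        )
        for (i, term, p), q in zip(raw, corrected)
    ]


def enriched_terms(
    results: list[EnrichmentResult], p_threshold: float
) -> dict[int, frozenset[str]]:
    """Per-module set of terms significant at the corrected threshold."""
    out: dict[int, set[str]] = {}
    for r in results:
        if r.p_corrected < p_threshold:
            out.setdefault(r.module_id, set()).add(r.term)
    return {i: frozenset(ts) for i, ts in out.items()}


def enrichment_ratio(
    modules: list[Module],
    results: list[EnrichmentResult],
    annotations: AnnotationSet,
    p_threshold: float = 0.05,
    deep_level: int = 7,
) -> float:
    """ER: percent of modules enriched with >= 1 term of level >= deep_level."""
    if not modules:
        raise DomainError("no modules to assess")
    per_module = enriched_terms(results, p_threshold)
    hits = 0
    for i in range(len(modules)):
        terms = per_module.get(i, frozenset())
        if any(
            (lvl := annotations.term_level.get(t)) is not None and lvl >= deep_level
            for t in terms
        ):
            hits += 1
    return 100.0 * hits / len(modules)


def coverage(
    results: list[EnrichmentResult],
    annotations: AnnotationSet,
    background: frozenset[str] | set[str],
    p_threshold: float = 0.05,
) -> float:
    """COV: percent of dataset-associated terms enriched in >= 1 module."""
    dataset_terms = annotations.dataset_terms(background)
    if not dataset_terms:
        return 0.0
    enriched = {
        r.term for r in results if r.p_corrected < p_threshold
    } & set(dataset_terms)
    return 100.0 * len(enriched) / len(dataset_terms)


def individual_coverage(
    modules: list[Module],
    results: list[EnrichmentResult],
    annotations: AnnotationSet,
    p_threshold: float = 0.05,
) -> float:
    """IC: mean over genes of the fraction of their terms covered.

    Restricted to genes that appear in at least one module and carry at
    least one term. A term of gene g counts as covered when it is enriched
    in at least one module containing g.
    """
    per_module = enriched_terms(results, p_threshold)
    modules_of: dict[str, list[int]] = {}
    for i, m in enumerate(modules):
        for g in m.genes:
            modules_of.setdefault(g, []).append(i)
    fractions = []
    for g, mod_ids in sorted(modules_of.items()):
        terms = annotations.terms_of(g)
        if not terms:
            continue
        covered_here = set()
        for i in mod_ids:
            covered_here |= per_module.get(i, frozenset())
        e_g = len(terms & covered_here)
        fractions.append(e_g / len(terms))
    if not fractions:
        return 0.0
    return 100.0 * sum(fractions) / len(fractions)


def ompsdf(
    modules: list[Module],
    results: list[EnrichmentResult],
    annotations: AnnotationSet,
    core_level: int = 3,
    deep_level: int = 7,
    p_threshold: float = 0.05,
) -> int:
    """Count overlapping module pairs supporting different functionalities.

    A pair (M1, M2) counts when (i) the gene sets overlap, (ii) M1 and M2
    share no enriched term of level <= core_level (they reflect different
    cellular core processes), and (iii) some shared gene carries two terms
    of level >= deep_level, one enriched in M1 only and the other in M2
    only.
    """
    per_module = enriched_terms(results, p_threshold)
    lvl = annotations.term_level

    def is_core(t: str) -> bool:
        return lvl.get(t) is not None and lvl[t] <= core_level

    def is_deep(t: str) -> bool:
        return lvl.get(t) is not None and lvl[t] >= deep_level

    count = 0
    for i, j in combinations(range(len(modules)), 2):
        shared_genes = modules[i].genes & modules[j].genes
        if not shared_genes:
            continue
        e_i = per_module.get(i, frozenset())
        e_j = per_module.get(j, frozenset())
        if any(is_core(t) for t in e_i & e_j):
            continue
        # only_i and only_j are disjoint, so any hit in both yields two
        # distinct deep terms, one exclusive to each module
        only_i = {t for t in e_i - e_j if is_deep(t)}
        only_j = {t for t in e_j - e_i if is_deep(t)}
        for g in shared_genes:
            terms = annotations.terms_of(g)
            if (terms & only_i) and (terms & only_j):
                count += 1
                break
    return count


@dataclass(frozen=True)
class MetricsReport:
    n_genes: int
    n_modules: int
    average_module_size: float
    average_density: float
    enrichment_ratio: float
    coverage: float
    individual_coverage: float
    ompsdf: int


def basic_stats(
    modules: list[Module], net: ProfileNetwork
) -> tuple[int, int, float, float]:
    """(#genes covered, #modules, average module size, average density)."""
    if not modules:
        raise DomainError("no modules to assess")
    covered = set().union(*(m.genes for m in modules))
    ams = sum(m.size for m in modules) / len(modules)
    dy = sum(density(net, m.genes) for m in modules) / len(modules)
    return len(covered), len(modules), ams, dy


def assess(
    modules: list[Module],
    net: ProfileNetwork,
    annotations: AnnotationSet,
    background: frozenset[str] | set[str],
    p_threshold: float = 0.05,
    deep_level: int = 7,
    core_level: int = 3,
    method: str = "bh",
) -> MetricsReport:
    """Run the full assessment battery on a module collection."""
    results = enrich_modules(modules, annotations, background, method=method)
    n_genes, n_modules, ams, dy = basic_stats(modules, net)
    return MetricsReport(
        n_genes=n_genes,
        n_modules=n_modules,
        average_module_size=ams,
        average_density=dy,
        enrichment_ratio=enrichment_ratio(
            modules, results, annotations, p_threshold, deep_level
        ),
        coverage=coverage(results, annotations, background, p_threshold),
        individual_coverage=individual_coverage(
            modules, results, annotations, p_threshold
        ),
        ompsdf=ompsdf(
            modules, results, annotations, core_level, deep_level, p_threshold
        ),
    )
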