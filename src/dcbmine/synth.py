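"""Synthetic benchmark instances with planted, recoverable modules.

The generator plants gamma-dense connected subgraphs into an
Erdos-Renyi background network and gives each plant's member genes an
epsilon-band expression signature on a chosen set of conditions, so the
planted gene sets are densely connected biclusters by construction. All
other expression values are unstructured draws (log2 fold-change scale),
an optional measurement-noise term jitters every value, and missing
values are masked outside the planted cells. Ground truth is returned
alongside the instance so recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import ceil, comb

import numpy as np

from .errors import PlantSpecError
from .model import Module, ProfileNetwork

__all__ = [
    "Plant",
    "PlantSpec",
    "PlantTruth",
    "RecoveryScore",
    "generate",
    "score_recovery",
    "random_profile_network",
    "default_benchmark_spec",
]


@dataclass(frozen=True)
class Plant:
    """One planted module: size, internal density, subspace size, overlap.

    ``overlap_with`` names an earlier plant (index into the spec's plant
    list) with which ``n_overlap_genes`` member genes are shared.
    """

    size: int
    density: float
    n_planted_conditions: int
    overlap_with: int | None = None
    n_overlap_genes: int = 0


@dataclass(frozen=True)
class PlantSpec:
    """Full description of a synthetic instance.

    ``background_sd`` is the standard deviation of the unstructured
    expression values outside the planted cells (log2 units; always
    present — a real compendium is never flat). ``noise_sd`` is
    measurement noise added to *every* value, including the planted
    epsilon-bands; it is the dial that degrades recovery, and 0 is the
    noise-free setting. ``missing_rate`` masks values outside planted
    cells only, so missingness never destroys a planted witness.
    """

    n_genes: int = 100
    edge_prob: float = 0.05
    n_conditions: int = 10
    epsilon: float = 0.5
    plants: tuple[Plant, ...] = ()
    background_sd: float = 1.0
    noise_sd: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        used = 0
        for i, p in enumerate(self.plants):
            if p.size < 2 or p.size > self.n_genes:
                raise PlantSpecError(f"plant {i}: size {p.size} infeasible")
            min_edges = p.size - 1
            target = ceil(p.density * comb(p.size, 2))
            if target < min_edges:
                raise PlantSpecError(
                    f"plant {i}: density {p.density} yields {target} edges, "
                    f"below the {min_edges} needed for connectivity"
                )
            if p.density > 1.0 or p.density <= 0.0:
                raise PlantSpecError(f"plant {i}: density {p.density} not in (0, 1]")
            if not 1 <= p.n_planted_conditions <= self.n_conditions:
                raise PlantSpecError(
                    f"plant {i}: subspace size {p.n_planted_conditions} "
                    f"outside [1, {self.n_conditions}]"
                )
            if p.overlap_with is not None:
                if not 0 <= p.overlap_with < i:
                    raise PlantSpecError(
                        f"plant {i}: overlap_with must name an earlier plant"
                    )
                if not 0 < p.n_overlap_genes < p.size:
                    raise PlantSpecError(
                        f"plant {i}: n_overlap_genes must be in (0, size)"
                    )
            used += p.size - p.n_overlap_genes
        if used > self.n_genes:
            raise PlantSpecError(
                f"plants need {used} distinct genes, background has {self.n_genes}"
            )
        if not 0 <= self.missing_rate < 1:
            raise PlantSpecError(f"missing_rate {self.missing_rate} not in [0, 1)")
        if self.epsilon < 0 or self.noise_sd < 0 or self.background_sd < 0:
            raise PlantSpecError("epsilon / noise_sd / background_sd must be >= 0")


@dataclass(frozen=True)
class PlantTruth:
    genes: frozenset[str]
    subspace: frozenset[int]


@dataclass(frozen=True)
class RecoveryScore:
    best_jaccard: tuple[float, ...]  # one entry per plant
    n_exact: int  # plants recovered with Jaccard exactly 1.0


def _random_connected_wiring(
    members: list[str], n_edges: int, rng: np.random.Generator
) -> set[tuple[str, str]]:
    """Random connected graph on ``members`` with exactly ``n_edges`` edges."""
    k = len(members)
    order = [members[i] for i in rng.permutation(k)]
    edges: set[tuple[str, str]] = set()
    for i in range(1, k):  # random recursive tree guarantees connectivity
        j = int(rng.integers(i))
        edges.add(tuple(sorted((order[i], order[j]))))
    remaining = [
        p for p in combinations(sorted(members), 2) if p not in edges
    ]
    extra = n_edges - (k - 1)
    if extra > 0:
        picks = rng.choice(len(remaining), size=extra, replace=False)
        edges.update(remaining[i] for i in picks)
    return edges


def generate(spec: PlantSpec) -> tuple[ProfileNetwork, list[PlantTruth]]:
    """Realize a :class:`PlantSpec`; deterministic under its seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = [f"g{i:04d}" for i in range(spec.n_genes)]

    # assign plant memberships
    unused = list(genes)
    plant_genes: list[list[str]] = []
    for p in spec.plants:
        members: list[str] = []
        if p.overlap_with is not None:
            donor = plant_genes[p.overlap_with]
            picks = rng.choice(len(donor), size=p.n_overlap_genes, replace=False)
            members.extend(donor[i] for i in picks)
        n_new = p.size - len(members)
        picks = rng.choice(len(unused), size=n_new, replace=False)
        members.extend(unused[i] for i in sorted(picks, reverse=True))
        for i in sorted(picks, reverse=True):
            del unused[i]
        plant_genes.append(sorted(members))

    in_some_plant = {g for members in plant_genes for g in members}
    plant_pairs = {
        p for members in plant_genes for p in combinations(members, 2)
    }

    # background Erdos-Renyi edges, excluding pairs rewired by plants
    edges: set[tuple[str, str]] = set()
    for i in range(spec.n_genes):
        for j in range(i + 1, spec.n_genes):
            if rng.random() < spec.edge_prob:
                pair = (genes[i], genes[j])
                if pair not in plant_pairs:
                    edges.add(pair)

    # plant wiring: exactly ceil(density * C(k,2)) edges, connected
    for p, members in zip(spec.plants, plant_genes):
        target = ceil(p.density * comb(p.size, 2))
        edges |= _random_connected_wiring(members, target, rng)

    # expression: unstructured background everywhere, then epsilon-bands
    profiles = rng.normal(0.0, spec.background_sd, (spec.n_genes, spec.n_conditions))
    gene_index = {g: i for i, g in enumerate(genes)}
    truth: list[PlantTruth] = []
    planted_cells = np.zeros((spec.n_genes, spec.n_conditions), dtype=bool)
    centers_at: dict[int, list[float]] = {}
    for p, members in zip(spec.plants, plant_genes):
        subspace = sorted(
            int(d)
            for d in rng.choice(
                spec.n_conditions, size=p.n_planted_conditions, replace=False
            )
        )
        rows = [gene_index[g] for g in members]
        for d in subspace:
            # planted signatures are strong differential-expression levels
            # (|log2FC| in [2, 4], random sign) so a band practically never
            # aliases with the near-zero unstructured background; plants
            # sharing a condition draw distinct slots >= 2*epsilon apart so
            # their signatures stay distinguishable
            sep = max(2.0 * spec.epsilon, 1e-6)
            magnitudes = [2.0 + i * sep for i in range(int(2.0 / sep) + 1)]
            slots = [s * m for m in magnitudes for s in (1.0, -1.0)]
            taken = centers_at.setdefault(d, [])
            free = [c for c in slots if all(abs(c - t) >= sep for t in taken)]
            if not free:
                raise PlantSpecError(
                    f"cannot place {len(taken) + 1} separated plant signatures "
                    f"in condition {d}; use more conditions or a smaller epsilon"
                )
            center = float(free[rng.integers(len(free))])
            taken.append(center)
            profiles[rows, d] = center + rng.uniform(
                -spec.epsilon / 2, spec.epsilon / 2, size=len(rows)
            )
            planted_cells[rows, d] = True
        truth.append(
            PlantTruth(genes=frozenset(members), subspace=frozenset(subspace))
        )

    if spec.noise_sd > 0:
        profiles = profiles + rng.normal(
            0.0, spec.noise_sd, profiles.shape
        )
    if spec.missing_rate > 0:
        mask = (rng.random(profiles.shape) < spec.missing_rate) & ~planted_cells
        profiles = np.where(mask, np.nan, profiles)

    net = ProfileNetwork(
        genes=genes,
        edges=sorted(edges),
        profiles=profiles,
        condition_names=[f"cond{d}" for d in range(spec.n_conditions)],
    )
    return net, truth


def score_recovery(
    found: list[Module] | list[frozenset[str]], truth: list[PlantTruth]
) -> RecoveryScore:
    """Best Jaccard index per plant over the found modules."""
    found_sets = [
        m.genes if isinstance(m, Module) else frozenset(m) for m in found
    ]
    best = []
    for plant in truth:
        if not found_sets:
            best.append(0.0)
            continue
        best.append(
            max(
                len(plant.genes & s) / len(plant.genes | s)
                for s in found_sets
            )
        )
    return RecoveryScore(
        best_jaccard=tuple(best), n_exact=sum(1 for j in best if j == 1.0)
    )


def random_profile_network(
    n_genes: int,
    edge_prob: float,
    n_conditions: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    value_low: float = -2.0,
    value_high: float = 2.0,
    missing_rate: float = 0.0,
) -> ProfileNetwork:
    """Unstructured random instance: ER graph + uniform random profiles.

    Used for randomized cross-checks between the lattice search and the
    brute-force enumerator; carries no planted structure.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    genes = [f"g{i:03d}" for i in range(n_genes)]
    edges = [
        (genes[i], genes[j])
        for i in range(n_genes)
        for j in range(i + 1, n_genes)
        if rng.random() < edge_prob
    ]
    profiles = rng.uniform(value_low, value_high, (n_genes, n_conditions))
    if missing_rate > 0:
        mask = rng.random(profiles.shape) < missing_rate
        profiles = np.where(mask, np.nan, profiles)
    return ProfileNetwork(
        genes=genes,
        edges=edges,
        profiles=profiles,
        condition_names=[f"c{d}" for d in range(n_conditions)],
    )


def default_benchmark_spec(seed: int = 0) -> PlantSpec:
    """The standard recovery benchmark: five disjoint plants in a sparse background.

    Sizes 4-8 at internal density 0.7, each with a 3-condition planted
    subspace, inside a 100-gene ER(p=0.05) background over 10 conditions
    at epsilon = 0.5 log2 units; noise-free and fully observed.
    """
    return PlantSpec(
        n_genes=100,
        edge_prob=0.05,
        n_conditions=10,
        epsilon=0.5,
        plants=tuple(
            Plant(size=k, density=0.7, n_planted_conditions=3) for k in range(4, 9)
        ),
        background_sd=1.0,
        noise_sd=0.0,
        missing_rate=0.0,
        seed=seed,
    )
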