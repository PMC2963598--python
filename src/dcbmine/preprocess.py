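"""Data-reduction steps applied before enumeration.

Two expression-based gene filters (a variance-interval filter in the style
used for compendium-type datasets, and a fold-change filter in the style
used for tissue panels) plus a sound edge-pruning step: an edge whose two
endpoint genes are not co-expressed in at least d_min conditions cannot lie
inside any DCB, because the co-expression subspace is anti-monotone under
gene-set growth.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .model import DCBParams, ProfileNetwork, coexpression_subspace

logger = logging.getLogger(__name__)

__all__ = ["variance_filter", "fold_filter", "prune_edges"]


def _row_stats(matrix: pd.DataFrame):
    """Per-gene non-missing count, mean and sample (n-1) std."""
    values = matrix.to_numpy(dtype=float)
    n = np.sum(~np.isnan(values), axis=1)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(np.where(np.isnan(values), np.nan, values), axis=1)
        sd = np.full(len(matrix), np.nan)
        enough = n >= 2
        if enough.any():
            sd[enough] = np.nanstd(values[enough], axis=1, ddof=1)
    return values, n, mean, sd


def variance_filter(matrix: pd.DataFrame, k: float = 1.5) -> list[str]:
    """Genes with at least one value escaping the mean +/- k*sd interval.

    A gene is retained iff some non-missing value x satisfies
    ``|x - mean| > k * sd`` with mean/sd over that gene's non-missing
    values (sample standard deviation). Genes with fewer than two
    non-missing values are excluded with a logged warning; constant
    profiles (sd = 0) are discarded since no value escapes the interval.
    """
    if matrix.empty:
        raise ValueError("expression matrix is empty")
    if k <= 0:
        raise ValueError(f"variance multiplier k must be > 0, got {k}")
    values, n, mean, sd = _row_stats(matrix)
    too_few = n < 2
    if too_few.any():
        logger.warning(
            "variance_filter: excluding %d gene(s) with < 2 non-missing values",
            int(too_few.sum()),
        )
    dev = np.abs(values - mean[:, None])
    escapes = np.where(np.isnan(dev), False, dev > (k * sd)[:, None])
    keep = ~too_few & escapes.any(axis=1)
    return [g for g, ok in zip(matrix.index, keep) if ok]


def fold_filter(
    matrix: pd.DataFrame, min_dev: float = 1.0, min_samples: int = 2
) -> list[str]:
    """Genes deviating from their mean by >= ``min_dev`` in >= ``min_samples`` samples.

    With log2 fold-change input the default min_dev = 1.0 corresponds to a
    2-fold ratio variation from the mean. The comparison is inclusive
    ("at least").
    """
    if matrix.empty:
        raise ValueError("expression matrix is empty")
    if min_dev <= 0:
        raise ValueError(f"min_dev must be > 0, got {min_dev}")
    if min_samples < 1:
        raise ValueError(f"min_samples must be >= 1, got {min_samples}")
    values, n, mean, _ = _row_stats(matrix)
    too_few = n < 2
    if too_few.any():
        logger.warning(
            "fold_filter: excluding %d gene(s) with < 2 non-missing values",
            int(too_few.sum()),
        )
    dev = np.abs(values - mean[:, None])
    hits = np.where(np.isnan(dev), False, dev >= min_dev).sum(axis=1)
    keep = ~too_few & (hits >= min_samples)
    return [g for g, ok in zip(matrix.index, keep) if ok]


def prune_edges(net: ProfileNetwork, params: DCBParams) -> ProfileNetwork:
    """Drop edges whose endpoints fail the pairwise co-expression constraint.

    An edge (u, v) survives iff u and v are within epsilon of each other in
    at least d_min conditions. Since growing a gene set can only shrink its
    co-expression subspace, no removed edge can sit inside any DCB, so the
    set of maximal DCBs is unchanged. Genes isolated by the pruning are
    removed afterwards (logged).
    """
    kept_edges = []
    removed = 0
    for u, v in net.graph.edges:
        if len(coexpression_subspace(net, (u, v), params.epsilon)) >= params.d_min:
            kept_edges.append((u, v))
        else:
            removed += 1
    connected = {g for e in kept_edges for g in e}
    kept_genes = [g for g in net.genes if g in connected]
    dropped_genes = net.n_genes - len(kept_genes)
    if removed or dropped_genes:
        logger.info(
            "prune_edges: removed %d/%d edge(s) and %d isolated gene(s)",
            removed,
            net.n_edges,
            dropped_genes,
        )
    idx = [net.index(g) for g in kept_genes]
    return ProfileNetwork(
        genes=kept_genes,
        edges=kept_edges,
        profiles=net.profiles[idx] if kept_genes else net.profiles[:0],
        condition_names=net.condition_names,
    )
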