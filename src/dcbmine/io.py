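"""Readers and writers for the package's tab-separated file formats.

Formats
-------
Network
    Two tab-separated gene-identifier columns per line; undirected,
    deduplicated on read, self-loops dropped with a logged count.
Expression
    TSV matrix, first column gene identifiers, header row of condition
    names; ``NA`` or an empty cell denotes a missing value.
Modules
    One module per row: ``module_id  provenance  n_genes  genes  subspace
    density`` plus, when ranked, ``p_coexpression  p_density
    rank_coexpression  rank_density  overall_rank``. ``genes`` and
    ``subspace`` are comma-joined lists inside one field. Writing is
    deterministic (modules sorted by size descending, then lexicographic
    gene list) and round-trips exactly.
Annotations
    2-column gene<TAB>term table; term DAG as 2-column child<TAB>parent.

All readers reject malformed input with the offending line/record in the
error message rather than silently coercing it.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputFormatError
from .model import Module, ProfileNetwork
from .rank import RankedModule

logger = logging.getLogger(__name__)

__all__ = [
    "read_network",
    "read_expression",
    "read_pairs",
    "build_profile_network",
    "write_modules",
    "read_modules",
    "write_metrics",
]

_MISSING_TOKENS = {"", "NA", "NaN", "nan"}


def read_network(path: str | Path, header: bool = False) -> list[tuple[str, str]]:
    """Read a two-column tab-separated edge list.

    Returns deduplicated undirected edges; self-loops are dropped with a
    logged count. ``header=True`` skips the first line (no auto-detection).
    """
    path = Path(path)
    edges: set[tuple[str, str]] = set()
    self_loops = 0
    n_lines = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0] or not fields[1]:
                raise InputFormatError(
                    f"{path}:{lineno}: expected two tab-separated identifiers, "
                    f"got {line!r}"
                )
            n_lines += 1
            u, v = fields
            if u == v:
                self_loops += 1
                continue
            edges.add((u, v) if u <= v else (v, u))
    if n_lines == 0:
        raise InputFormatError(f"{path}: empty network file")
    if self_loops:
        logger.info("read_network: dropped %d self-loop(s)", self_loops)
    return sorted(edges)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x conditions TSV matrix with NA/empty missing values."""
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if raw.index.has_duplicates:
        dupes = sorted(raw.index[raw.index.duplicated()].unique())[:3]
        raise InputFormatError(f"{path}: duplicate gene row(s): {dupes}")
    values = np.empty(raw.shape, dtype=float)
    for i, gene in enumerate(raw.index):
        for j, cond in enumerate(raw.columns):
            cell = raw.iat[i, j].strip()
            if cell in _MISSING_TOKENS:
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise InputFormatError(
                    f"{path}: non-numeric cell {cell!r} at gene {gene!r}, "
                    f"condition {cond!r}"
                ) from None
    return pd.DataFrame(values, index=raw.index, columns=raw.columns)


def read_pairs(path: str | Path, header: bool = False) -> list[tuple[str, str]]:
    """Read any 2-column TSV pair table (gene->term, child->parent)."""
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0] or not fields[1]:
                raise InputFormatError(
                    f"{path}:{lineno}: expected two tab-separated fields, got {line!r}"
                )
            pairs.append((fields[0], fields[1]))
    return pairs


def build_profile_network(
    edges: list[tuple[str, str]], expression: pd.DataFrame
) -> ProfileNetwork:
    """Join an edge list with an expression matrix on shared gene identifiers.

    Identifier matching is exact and case-sensitive; genes present in only
    one of the two inputs are dropped with a logged report.
    """
    net_genes = {g for e in edges for g in e}
    expr_genes = set(expression.index)
    shared = net_genes & expr_genes
    only_net = sorted(net_genes - expr_genes)
    only_expr = sorted(expr_genes - net_genes)
    if only_net:
        logger.info(
            "build_profile_network: %d gene(s) only in the network (dropped): %s%s",
            len(only_net), only_net[:5], "..." if len(only_net) > 5 else "",
        )
    if only_expr:
        logger.info(
            "build_profile_network: %d gene(s) only in the expression matrix "
            "(dropped): %s%s",
            len(only_expr), only_expr[:5], "..." if len(only_expr) > 5 else "",
        )
    genes = sorted(shared)
    kept_edges = [(u, v) for u, v in edges if u in shared and v in shared]
    profiles = expression.loc[genes].to_numpy(dtype=float)
    return ProfileNetwork(
        genes=genes,
        edges=kept_edges,
        profiles=profiles,
        condition_names=list(expression.columns),
    )


_MODULE_COLUMNS = [
    "module_id", "provenance", "n_genes", "genes", "subspace", "density",
    "p_coexpression", "p_density", "rank_coexpression", "rank_density",
    "overall_rank",
]


def write_modules(
    modules: list[Module] | list[RankedModule], path: str | Path
) -> None:
    """Write modules (plain or ranked) to the TSV dialect above."""
    path = Path(path)
    rows = []
    plain = [m.module if isinstance(m, RankedModule) else m for m in modules]
    ranked = [m if isinstance(m, RankedModule) else None for m in modules]
    # ranked lists keep their rank order; plain lists get the canonical order
    if all(r is None for r in ranked):
        order = sorted(range(len(plain)), key=lambda i: plain[i].sort_key())
    else:
        order = list(range(len(plain)))
    for out_id, i in enumerate(order):
        m, r = plain[i], ranked[i]
        row = [
            str(out_id),
            m.provenance,
            str(len(m.genes)),
            ",".join(sorted(m.genes)),
            ",".join(str(d) for d in sorted(m.subspace)),
            repr(m.density),
        ]
        if r is not None:
            row += [
                repr(r.p_coexpression),
                repr(r.p_density),
                str(r.rank_coexpression),
                str(r.rank_density),
                repr(r.overall_rank),
            ]
        else:
            row += [""] * 5
        rows.append(row)
    with path.open("w") as fh:
        fh.write("\t".join(_MODULE_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def read_modules(path: str | Path) -> list[Module] | list[RankedModule]:
    """Read a module TSV; returns RankedModules iff rank fields are present."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _MODULE_COLUMNS:
            raise InputFormatError(f"{path}: unexpected module file header")
        out: list = []
        for record, line in enumerate(fh):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(_MODULE_COLUMNS):
                raise InputFormatError(
                    f"{path}: record {record}: expected "
                    f"{len(_MODULE_COLUMNS)} fields, got {len(fields)}"
                )
            try:
                module = Module(
                    genes=frozenset(fields[3].split(",")) if fields[3] else frozenset(),
                    subspace=frozenset(
                        int(d) for d in fields[4].split(",") if d != ""
                    ),
                    density=float(fields[5]),
                    provenance=fields[1],
                )
                if int(fields[2]) != len(module.genes):
                    raise ValueError("gene count mismatch")
                if fields[6]:
                    out.append(
                        RankedModule(
                            module=module,
                            p_coexpression=float(fields[6]),
                            p_density=float(fields[7]),
                            rank_coexpression=int(fields[8]),
                            rank_density=int(fields[9]),
                        )
                    )
                else:
                    out.append(module)
            except (ValueError, KeyError) as exc:
                raise InputFormatError(
                    f"{path}: record {record}: {exc}"
                ) from None
    return out


def write_metrics(report, path: str | Path) -> None:
    """Write a MetricsReport as a two-column key<TAB>value file."""
    path = Path(path)
    with path.open("w") as fh:
        for name, value in vars(report).items():
            if isinstance(value, float) and not math.isnan(value):
                fh.write(f"{name}\t{value:.4f}\n")
            else:
                fh.write(f"{name}\t{value}\n")
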