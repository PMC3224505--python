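"""Readers and writers for the tab-delimited exchange formats.

Expression files are self-contained: row 1 carries sample labels, row 2 the
sampling times in seconds (``#time_s``), row 3 steady-state flags
(``#steady``), then one gene per row.  Duplicate steady-state columns sharing
a sampling time (replicates) are averaged into one column at load time; the
raw columns are kept on ``ExpressionSeries.raw`` for inspection.

Networks are 3-column edge lists (source, target, kind in {PPI, PDI});
annotations are 2-column (gene, term) with an optional third term-name
column.  Every writer emits the dialect its reader consumes, bit-exactly.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    EDGE_KINDS,
    PPI,
    AnnotationTable,
    ExpressionSeries,
    FormatError,
    InteractionNetwork,
    TimeGrid,
)

__all__ = [
    "read_expression",
    "write_expression",
    "read_network",
    "write_network",
    "read_annotations",
    "write_annotations",
]

_TIME_ROW = "#time_s"
_STEADY_ROW = "#steady"


def _fmt(x: float) -> str:
    """Shortest decimal string that round-trips the float exactly."""
    if float(x) == int(x):
        return str(int(x))
    return repr(float(x))


def read_expression(path) -> ExpressionSeries:
    """Read a log2 expression matrix with embedded time metadata.

    Steady-state replicate columns that share a sampling time are averaged
    into a single column; the unaveraged matrix is retained in ``.raw``.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if len(lines) < 4:
        raise FormatError(f"{path}: expected header + {_TIME_ROW} + {_STEADY_ROW} + data rows")
    header = lines[0].split("\t")
    labels = header[1:]
    n = len(labels)
    time_row = lines[1].split("\t")
    steady_row = lines[2].split("\t")
    if time_row[0] != _TIME_ROW or steady_row[0] != _STEADY_ROW:
        raise FormatError(
            f"{path}: time metadata missing (rows 2-3 must start with "
            f"{_TIME_ROW!r} and {_STEADY_ROW!r})"
        )
    if len(time_row) != n + 1 or len(steady_row) != n + 1:
        raise FormatError(f"{path}: metadata rows must match the {n} sample columns")
    try:
        times = np.array([float(x) for x in time_row[1:]])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric time in {_TIME_ROW} row: {exc}") from None
    try:
        steady = np.array([int(x) for x in steady_row[1:]], dtype=bool)
    except ValueError as exc:
        raise FormatError(f"{path}: non-0/1 flag in {_STEADY_ROW} row: {exc}") from None

    gene_ids: list[str] = []
    rows: list[list[float]] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[3:], start=4):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != n + 1:
            raise FormatError(f"{path}:{lineno}: expected {n + 1} columns, got {len(parts)}")
        gid = parts[0]
        if gid in seen:
            raise FormatError(f"{path}:{lineno}: duplicate gene ID: {gid}")
        seen.add(gid)
        vals = []
        for col, cell in enumerate(parts[1:], start=2):
            try:
                vals.append(float(cell))
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric value {cell!r} in column {col}"
                ) from None
        gene_ids.append(gid)
        rows.append(vals)
    if not gene_ids:
        raise FormatError(f"{path}: no gene rows")
    values = np.array(rows)

    raw = None
    uniq, inverse, counts = np.unique(times, return_inverse=True, return_counts=True)
    if np.any(counts > 1):
        raw = pd.DataFrame(values, index=gene_ids, columns=labels)
        raw.attrs["time_s"] = times.tolist()
        raw.attrs["steady"] = steady.astype(int).tolist()
        merged = np.empty((values.shape[0], len(uniq)))
        new_labels, new_steady = [], []
        for j in range(len(uniq)):
            cols = np.flatnonzero(inverse == j)
            merged[:, j] = values[:, cols].mean(axis=1)
            new_labels.append(labels[cols[0]])
            new_steady.append(bool(steady[cols].any()))
        values, labels, times, steady = merged, new_labels, uniq, np.array(new_steady)

    steady_idx = np.flatnonzero(steady)
    if len(steady_idx) == 0:
        raise FormatError(f"{path}: no steady-state sample flagged")
    grid = TimeGrid(times, tuple(labels), steady, reference_index=int(steady_idx[0]))
    return ExpressionSeries(tuple(gene_ids), values, grid, raw=raw)


def write_expression(expr: ExpressionSeries, path) -> None:
    path = Path(path)
    grid = expr.grid
    out = ["gene_id\t" + "\t".join(grid.labels)]
    out.append(_TIME_ROW + "\t" + "\t".join(_fmt(t) for t in grid.times))
    out.append(_STEADY_ROW + "\t" + "\t".join(str(int(s)) for s in grid.is_steady))
    for gid, row in zip(expr.gene_ids, expr.values):
        out.append(gid + "\t" + "\t".join(_fmt(v) for v in row))
    path.write_text("\n".join(out) + "\n", encoding="utf-8")


def read_network(path) -> InteractionNetwork:
    """Read a 3-column edge list; PPI edges are deduplicated regardless of
    orientation, self-loops are dropped and counted in ``load_report``."""
    path = Path(path)
    edges: list[tuple[str, str, str]] = []
    seen: set[tuple[str, str, str]] = set()
    nodes: dict[str, None] = {}
    tf: set[str] = set()
    n_self = n_dup = 0
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise FormatError(f"{path}:{lineno}: expected 3 tab-separated columns")
        u, v, kind = parts
        if kind not in EDGE_KINDS:
            raise FormatError(f"{path}:{lineno}: unknown edge kind {kind!r}")
        if u == v:
            n_self += 1
            continue
        nodes.setdefault(u)
        nodes.setdefault(v)
        if kind != PPI:
            tf.add(u)
        key = (min(u, v), max(u, v), kind) if kind == PPI else (u, v, kind)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        edges.append(key)
    if n_self:
        warnings.warn(f"{path}: dropped {n_self} self-loop(s)", stacklevel=2)
    net = InteractionNetwork(tuple(nodes), tuple(edges), frozenset(tf))
    net.load_report = {"self_loops": n_self, "duplicate_edges": n_dup}
    return net


def write_network(net: InteractionNetwork, path) -> None:
    path = Path(path)
    out = [f"{u}\t{v}\t{kind}" for u, v, kind in net.edges]
    path.write_text("\n".join(out) + ("\n" if out else ""), encoding="utf-8")


def read_annotations(path) -> AnnotationTable:
    """Read gene->term pairs; duplicates are collapsed with a warning."""
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    names: dict[str, str] = {}
    n_dup = 0
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) not in (2, 3):
            raise FormatError(f"{path}:{lineno}: expected 2 or 3 tab-separated columns")
        gene, term = parts[0], parts[1]
        if len(parts) == 3 and parts[2]:
            names[term] = parts[2]
        if (gene, term) in seen:
            n_dup += 1
            continue
        seen.add((gene, term))
        pairs.append((gene, term))
    if n_dup:
        warnings.warn(f"{path}: collapsed {n_dup} duplicate annotation pair(s)", stacklevel=2)
    return AnnotationTable(tuple(pairs), names)


def write_annotations(table: AnnotationTable, path) -> None:
    path = Path(path)
    out = []
    for gene, term in table.pairs:
        name = table.term_names.get(term)
        out.append(f"{gene}\t{term}\t{name}" if name else f"{gene}\t{term}")
    path.write_text("\n".join(out) + ("\n" if out else ""), encoding="utf-8")
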