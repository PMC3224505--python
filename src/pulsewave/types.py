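"""Shared domain containers for impulse-chemostat transcriptome analysis.

The central object is :class:`ExpressionSeries`: a genes x samples matrix of
log2 intensities over an ordered, irregular time grid that spans seconds to
hours around a nutrient impulse, with the pre-impulse steady state serving as
the reference condition for every downstream statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TimeGrid",
    "ExpressionSeries",
    "PulseModel",
    "InteractionNetwork",
    "AnnotationTable",
    "FormatError",
]


class FormatError(ValueError):
    """Raised when an input file violates the documented dialect."""


@dataclass(frozen=True)
class TimeGrid:
    """Ordered sampling grid around a nutrient impulse.

    Times are seconds since the impulse; the pre-impulse steady state sits at
    a negative time (-1 s by convention) so the grid stays strictly
    increasing.  Exactly one sample, a steady-state one, is the reference
    against which correlation profiles are computed.
    """

    times: np.ndarray
    labels: tuple[str, ...]
    is_steady: np.ndarray
    reference_index: int = 0

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        steady = np.asarray(self.is_steady, dtype=bool)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "is_steady", steady)
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        if times.ndim != 1 or len(times) < 3:
            raise ValueError("a time grid needs at least 3 samples")
        if not (len(times) == len(self.labels) == len(steady)):
            raise ValueError("times, labels and is_steady must have equal length")
        if not np.all(np.diff(times) > 0):
            raise ValueError("sampling times must be strictly increasing")
        if not (0 <= self.reference_index < len(times)):
            raise ValueError("reference_index out of range")
        if not steady[self.reference_index]:
            raise ValueError("the reference sample must be a steady-state sample")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def hours(self) -> np.ndarray:
        return self.times / 3600.0


@dataclass
class ExpressionSeries:
    """Genes x samples matrix of log2 intensities on a :class:`TimeGrid`.

    ``raw`` optionally keeps the unaveraged replicate columns when the loader
    collapsed steady-state replicates into one reference column.
    """

    gene_ids: tuple[str, ...]
    values: np.ndarray
    grid: TimeGrid
    raw: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.gene_ids = tuple(str(g) for g in self.gene_ids)
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            seen: set[str] = set()
            dup = next(g for g in self.gene_ids if g in seen or seen.add(g))
            raise ValueError(f"duplicate gene ID: {dup}")
        if self.values.ndim != 2 or self.values.shape != (len(self.gene_ids), len(self.grid)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.grid)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must all be finite")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]

    def subset(self, gene_ids) -> "ExpressionSeries":
        """Row-subset preserving the requested order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise KeyError(f"genes not in series: {missing[:5]}")
        rows = [index[g] for g in gene_ids]
        return ExpressionSeries(tuple(gene_ids), self.values[rows], self.grid)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids), columns=list(self.grid.labels))


@dataclass(frozen=True)
class PulseModel:
    """Chemostat and dosing parameters for a nutrient impulse.

    Parameters
    ----------
    D : dilution rate, h^-1 (medium flow / working volume).
    V : working volume, L.
    v_inj : injected stock volume, L.
    stock_conc : stock concentration, % w/v (g per 100 mL).
    C_base : residual pre-impulse concentration of the limiting nutrient,
        % w/v.  Zero for a fully limiting nutrient.

    The concentration step at t = 0 follows from the dose identity
    ``delta_C0 = stock_conc * v_inj / V`` and is exposed as a property so the
    identity holds by construction.
    """

    D: float
    V: float
    v_inj: float
    stock_conc: float
    C_base: float = 0.0

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError("dilution rate D must be positive")
        if self.V <= 0:
            raise ValueError("working volume V must be positive")
        if not (0 < self.v_inj <= self.V):
            raise ValueError("injected volume must satisfy 0 < v_inj <= V")
        if self.stock_conc <= 0:
            raise ValueError("stock concentration must be positive")
        if self.C_base < 0:
            raise ValueError("C_base must be non-negative")

    @property
    def delta_C0(self) -> float:
        """Concentration increment at t = 0, % w/v (dose identity)."""
        return self.stock_conc * self.v_inj / self.V


PPI = "PPI"
PDI = "PDI"
EDGE_KINDS = (PPI, PDI)


@dataclass
class InteractionNetwork:
    """Interactome: undirected protein-protein plus directed protein-DNA edges.

    PPI edges are stored as canonically ordered pairs with no duplicates and
    no self-loops; PDI edges keep their TF -> target direction.  ``tf_set``
    flags the nodes acting as transcription factors.
    """

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str, str], ...]
    tf_set: frozenset[str] = frozenset()
    load_report: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        self.nodes = tuple(str(n) for n in self.nodes)
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate node IDs")
        canon = []
        seen = set()
        for u, v, kind in self.edges:
            if kind not in EDGE_KINDS:
                raise ValueError(f"unknown edge kind: {kind!r}")
            if u == v:
                raise ValueError(f"self-loop on node {u!r}")
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge endpoint not in node set: ({u!r}, {v!r})")
            key = (min(u, v), max(u, v), kind) if kind == PPI else (u, v, kind)
            if key in seen:
                raise ValueError(f"duplicate edge: {key}")
            seen.add(key)
            canon.append(key)
        self.edges = tuple(canon)
        self.tf_set = frozenset(self.tf_set)
        if not self.tf_set <= node_set:
            raise ValueError("tf_set contains unknown nodes")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def ppi_edges(self) -> list[tuple[str, str]]:
        return [(u, v) for u, v, k in self.edges if k == PPI]

    def pdi_edges(self) -> list[tuple[str, str]]:
        return [(u, v) for u, v, k in self.edges if k == PDI]

    def to_networkx(self):
        """Directed multigraph view (PPI edges appear in both directions)."""
        import networkx as nx

        g = nx.MultiDiGraph()
        g.add_nodes_from(self.nodes)
        for u, v, kind in self.edges:
            g.add_edge(u, v, kind=kind)
            if kind == PPI:
                g.add_edge(v, u, kind=kind)
        return g


@dataclass
class AnnotationTable:
    """Gene -> term annotation pairs with optional term labels."""

    pairs: tuple[tuple[str, str], ...]
    term_names: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pairs = tuple((str(g), str(t)) for g, t in self.pairs)
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (gene, term) pairs")
        self.pairs = pairs

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def terms(self) -> list[str]:
        return sorted({t for _, t in self.pairs})

    def genes_for_term(self, term: str) -> set[str]:
        return {g for g, t in self.pairs if t == term}

    def terms_for_gene(self, gene: str) -> set[str]:
        return {t for g, t in self.pairs if g == gene}

    def term_to_genes(self) -> dict:
        out: dict[str, set] = {}
        for g, t in self.pairs:
            out.setdefault(t, set()).add(g)
        return out

    def mapped(self, slim_map: dict) -> "AnnotationTable":
        """Roll annotations up through a term -> slim-term mapping.

        Terms absent from the map are kept as-is; duplicates created by the
        roll-up are collapsed.
        """
        pairs = sorted({(g, slim_map.get(t, t)) for g, t in self.pairs})
        names = {slim_map.get(t, t): n for t, n in self.term_names.items()}
        return AnnotationTable(tuple(pairs), names)
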