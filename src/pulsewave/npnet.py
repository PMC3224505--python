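"""Negative-Positive (NP) network analysis.

The interactome is reduced to the edges whose endpoint expression profiles
are strongly correlated or anti-correlated over the impulse time course
(|PCC| >= 0.7 by default); retained edges are labelled co-regulated
(PCC > 0) or anti-regulated (PCC < 0).  The reduced network is then
dissected into modules: the largest clusters of co-expressed nodes that
contain fewer than 1% anti-regulated internal links, found by walking a
correlation-distance dendrogram from coarse to fine.  Downstream summaries
cover inter-module mean correlations, interface/core membership, and
date/party hub classification by the mean correlation of a node with its
network neighbours.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist

from .types import ExpressionSeries, InteractionNetwork

__all__ = [
    "ReducedNetwork",
    "ModulePartition",
    "reduce_network",
    "find_modules",
    "inter_module_summary",
    "classify_hubs",
    "interface_core",
]

CO = "coregulated"
ANTI = "antiregulated"


@dataclass
class ReducedNetwork:
    """NP network: interactome edges surviving the |PCC| threshold.

    ``nodes`` is the expression/interactome intersection (the candidate
    universe); ``active_nodes`` are the nodes incident to at least one
    retained edge — the node count reported for the NP network itself.
    Each edge carries its PCC and a co/anti label.
    """

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str, str, float, str], ...]  # (u, v, kind, pcc, label)
    threshold: float
    tf_set: frozenset = frozenset()
    n_skipped_constant: int = 0

    @property
    def active_nodes(self) -> tuple[str, ...]:
        touched = {n for u, v, *_ in self.edges for n in (u, v)}
        return tuple(n for n in self.nodes if n in touched)

    @property
    def n_nodes(self) -> int:
        return len(self.active_nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_co(self) -> int:
        return sum(1 for e in self.edges if e[4] == CO)

    @property
    def n_anti(self) -> int:
        return sum(1 for e in self.edges if e[4] == ANTI)

    def counts(self) -> dict:
        """Four-field summary: nodes, edges, co- and anti-regulated edges."""
        return {
            "Nodes": self.n_nodes,
            "Edges": self.n_edges,
            "Co-regulated edges": self.n_co,
            "Anti-regulated edges": self.n_anti,
        }

    def edges_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["source", "target", "kind", "pcc", "label"])

    def degree_table(self) -> dict:
        deg: dict[str, list[float]] = {}
        for u, v, _k, pcc, _l in self.edges:
            deg.setdefault(u, []).append(pcc)
            deg.setdefault(v, []).append(pcc)
        return deg


def _zscore_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    constant = sd[:, 0] == 0
    sd[constant] = 1.0
    return (x - mu) / sd, constant


def reduce_network(
    network: InteractionNetwork,
    expr: ExpressionSeries,
    threshold: float = 0.7,
) -> ReducedNetwork:
    """Keep interactome edges whose endpoint profiles satisfy |PCC| >= threshold.

    PCC is computed over the full dynamic profile (reference steady state
    included).  Edges touching a constant profile are skipped and counted,
    not fatal.  ``threshold`` must lie in (0, 1]; 0 is tolerated only for
    degenerate diagnostic use.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    index = {g: i for i, g in enumerate(expr.gene_ids)}
    common = [n for n in network.nodes if n in index]
    if len(common) < 2:
        raise ValueError("need expression for at least 2 network nodes")
    common_set = set(common)
    z, constant = _zscore_rows(expr.values)
    n_samples = z.shape[1]

    edges: list[tuple[str, str, str, float, str]] = []
    skipped = 0
    for u, v, kind in network.edges:
        if u not in common_set or v not in common_set:
            continue
        iu, iv = index[u], index[v]
        if constant[iu] or constant[iv]:
            skipped += 1
            continue
        pcc = float(np.dot(z[iu], z[iv]) / n_samples)
        pcc = max(-1.0, min(1.0, pcc))
        if abs(pcc) >= threshold:
            edges.append((u, v, kind, pcc, CO if pcc > 0 else ANTI))
    return ReducedNetwork(
        nodes=tuple(common),
        edges=tuple(edges),
        threshold=threshold,
        tf_set=frozenset(network.tf_set & common_set),
        n_skipped_constant=skipped,
    )


@dataclass
class ModulePartition:
    """Node -> module assignment with per-module link statistics."""

    assignment: dict
    modules: pd.DataFrame  # module, size, n_edges_within, n_anti_within, anti_frac
    unclustered: tuple[str, ...] = ()
    max_anti_frac: float = 0.01

    def members(self, module: str) -> list[str]:
        return [n for n, m in self.assignment.items() if m == module]

    @property
    def module_labels(self) -> list[str]:
        return list(self.modules["module"])


def _intra_edge_stats(members: set, edge_list) -> tuple[int, int]:
    n_edges = n_anti = 0
    for u, v, label in edge_list:
        if u in members and v in members:
            n_edges += 1
            n_anti += label == ANTI
    return n_edges, n_anti


def find_modules(
    reduced: ReducedNetwork,
    expr: ExpressionSeries,
    max_anti_frac: float = 0.01,
    min_module_size: int = 2,
    require_connected: bool = True,
) -> ModulePartition:
    """Dissect the NP network into the largest admissible co-expression modules.

    Nodes (those incident to retained edges) are hierarchically clustered on
    their expression profiles (d = 1 - PCC, average linkage) and the
    dendrogram is walked from the root down.  A candidate cluster is
    accepted as a module when (a) its intra-cluster anti-regulated link
    fraction — anti edges over retained edges inside the cluster, 0 when
    edgeless — is below ``max_anti_frac``, and (b) it induces a connected
    subgraph of the reduced network (a network module should be one
    component; without this, co-expressed but network-disjoint clusters
    would merge).  Rejected candidates are split into their two dendrogram
    children and the walk recurses; clusters smaller than
    ``min_module_size`` end up unclustered.

    If the root itself is accepted the whole network is one global module —
    a legitimate outcome for a highly co-expressed network — and a warning
    is emitted because inter-module analyses are then undefined.
    """
    if not (0.0 < max_anti_frac < 1.0):
        raise ValueError("max_anti_frac must lie in (0, 1)")
    nodes = list(reduced.active_nodes)
    if not nodes:
        raise ValueError("reduced network has no retained edges")
    sub = expr.subset(nodes)
    edge_list = [(u, v, label) for u, v, _k, _p, label in reduced.edges]

    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    graph.add_edges_from((u, v) for u, v, _ in edge_list)

    accepted: list[list[str]] = []
    unclustered: list[str] = []

    def admissible(members: list[str]) -> bool:
        mset = set(members)
        n_edges, n_anti = _intra_edge_stats(mset, edge_list)
        frac = (n_anti / n_edges) if n_edges else 0.0
        if frac >= max_anti_frac:
            return False
        if require_connected and not nx.is_connected(graph.subgraph(mset)):
            return False
        return True

    if len(nodes) == 1:
        unclustered = nodes
    else:
        d = np.clip(pdist(sub.values, metric="correlation"), 0.0, None)
        tree = to_tree(linkage(d, method="average"))
        stack = [tree]
        while stack:
            node = stack.pop()
            members = [nodes[i] for i in node.pre_order()]
            if len(members) < min_module_size:
                unclustered.extend(members)
                continue
            if admissible(members):
                accepted.append(members)
            else:
                if node.is_leaf():
                    unclustered.append(members[0])
                else:
                    stack.append(node.right)
                    stack.append(node.left)

    if len(accepted) == 1 and len(accepted[0]) == len(nodes):
        warnings.warn(
            "the whole network forms a single global module; "
            "inter-module analyses are not applicable",
            stacklevel=2,
        )

    accepted.sort(key=lambda m: (-len(m), m[0]))
    assignment: dict[str, str] = {}
    rows = []
    for i, members in enumerate(accepted, start=1):
        label = f"M{i}"
        mset = set(members)
        n_edges, n_anti = _intra_edge_stats(mset, edge_list)
        frac = (n_anti / n_edges) if n_edges else 0.0
        assert frac < max_anti_frac, "emitted module violates the anti-link bound"
        for m in members:
            assignment[m] = label
        rows.append((label, len(members), n_edges, n_anti, frac))
    modules = pd.DataFrame(
        rows, columns=["module", "size", "n_edges_within", "n_anti_within", "anti_frac"]
    )
    return ModulePartition(
        assignment=assignment,
        modules=modules,
        unclustered=tuple(unclustered),
        max_anti_frac=max_anti_frac,
    )


def inter_module_summary(partition: ModulePartition, expr: ExpressionSeries) -> pd.DataFrame:
    """Mean pairwise PCC between every pair of distinct modules.

    Entry (A, B) averages PCC(a, b) over all cross pairs a in A, b in B and
    is labelled correlated/anti-correlated by its sign.
    """
    labels = partition.module_labels
    if len(labels) < 2:
        raise ValueError("inter-module summary needs at least 2 modules")
    z_by_mod = {}
    for m in labels:
        sub = expr.subset(partition.members(m))
        z, constant = _zscore_rows(sub.values)
        z_by_mod[m] = z[~constant]
    n_samples = len(expr.grid)
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            cross = z_by_mod[a] @ z_by_mod[b].T / n_samples
            mean_pcc = float(cross.mean())
            rows.append((a, b, mean_pcc, "correlated" if mean_pcc > 0 else "anti-correlated"))
    return pd.DataFrame(rows, columns=["module_a", "module_b", "mean_pcc", "label"])


def classify_hubs(
    reduced: ReducedNetwork,
    min_degree: int = 5,
    partition: ModulePartition | None = None,
) -> pd.DataFrame:
    """Date/party classification of hubs by average neighbour correlation.

    AvgPCC of a node is the arithmetic mean of the PCC values on its
    retained incident edges; |AvgPCC| > 0.1 makes a party hub (neighbours
    co-expressed with it, interactions presumed simultaneous), otherwise a
    date hub (equality falls to date).  Only nodes with degree >=
    ``min_degree`` are classified.  When a partition is supplied, an
    ``is_interface`` column marks hubs with at least one inter-module edge.
    """
    if min_degree < 1:
        raise ValueError("min_degree must be >= 1")
    incident = reduced.degree_table()
    inter_nodes: set[str] = set()
    if partition is not None:
        assign = partition.assignment
        for u, v, *_ in reduced.edges:
            mu, mv = assign.get(u), assign.get(v)
            if mu is not None and mv is not None and mu != mv:
                inter_nodes.update((u, v))
    rows = []
    for node in reduced.active_nodes:
        pccs = incident.get(node, [])
        if len(pccs) < min_degree:
            continue
        avg = float(np.mean(pccs))
        rows.append(
            (
                node,
                len(pccs),
                avg,
                "party" if abs(avg) > 0.1 else "date",
                node in reduced.tf_set,
                node in inter_nodes if partition is not None else False,
            )
        )
    return pd.DataFrame(
        rows, columns=["node", "degree", "avg_pcc", "hub_class", "is_tf", "is_interface"]
    )


def interface_core(
    partition: ModulePartition,
    reduced: ReducedNetwork,
    tf_set=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Interface/core flags per clustered node and TF interface counts.

    A node is *interface* when it has at least one retained edge to a
    different module, *core* otherwise.  The second table counts, for each
    ordered module pair (A, B), the transcription factors of A that
    interface with B.
    """
    tf_set = frozenset(reduced.tf_set if tf_set is None else tf_set)
    assign = partition.assignment
    partners: dict[str, set[str]] = {n: set() for n in assign}
    for u, v, *_ in reduced.edges:
        mu, mv = assign.get(u), assign.get(v)
        if mu is None or mv is None or mu == mv:
            continue
        partners[u].add(mv)
        partners[v].add(mu)
    rows = [
        (n, assign[n], bool(partners[n]), n in tf_set)
        for n in assign
    ]
    nodes_df = pd.DataFrame(rows, columns=["node", "module", "is_interface", "is_tf"])

    pair_counts: dict[tuple[str, str], int] = {}
    for n, module in assign.items():
        if n not in tf_set:
            continue
        for other in partners[n]:
            pair_counts[(module, other)] = pair_counts.get((module, other), 0) + 1
    pairs_df = pd.DataFrame(
        [(a, b, c) for (a, b), c in sorted(pair_counts.items())],
        columns=["module", "partner_module", "n_tf_interface"],
    )
    return nodes_df, pairs_df
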