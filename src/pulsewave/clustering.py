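"""Temporal clustering: hierarchical (correlation distance) and batch SOM.

Hierarchical clustering uses the correlation distance d = 1 - PCC with
average linkage; a flat cut at d = 0.5 (i.e. PCC = 0.5) reproduces the
similarity-threshold partitioning used for sample- and gene-axis heatmaps.

The self-organizing map arranges prototype profiles ("imaginary points") on
a small grid (2x4 or 3x3 presets), trains them by batch updates with a
linearly shrinking Gaussian neighbourhood on per-gene standardized
profiles, and reports per-cell centroids with normal-approximation
confidence bands; genes falling outside their cell's band at too many time
points are reported unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import norm
from sklearn.cluster import kmeans_plusplus

from .types import ExpressionSeries

__all__ = ["Dendrogram", "SomClusterSet", "hier_cluster", "som_cluster"]


@dataclass
class Dendrogram:
    """Agglomerative merge tree over items under d = 1 - PCC."""

    ids: tuple[str, ...]
    linkage_matrix: np.ndarray
    method: str

    def cut(self, similarity: float = 0.5) -> dict:
        """Flat partition at correlation-distance threshold d = similarity.

        With d = 1 - PCC, a cut at 0.5 groups items correlated above
        PCC = 0.5.  Returns item -> 1-based cluster label.
        """
        labels = fcluster(self.linkage_matrix, t=similarity, criterion="distance")
        return dict(zip(self.ids, (int(x) for x in labels)))

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]


def hier_cluster(expr: ExpressionSeries, axis: str = "genes", method: str = "average") -> Dendrogram:
    """Hierarchical clustering of genes or samples under d = 1 - PCC.

    A constant row/column has no defined correlation and raises an error
    naming the offender.
    """
    if axis == "genes":
        x = expr.values
        ids = expr.gene_ids
    elif axis == "samples":
        x = expr.values.T
        ids = expr.grid.labels
    else:
        raise ValueError("axis must be 'genes' or 'samples'")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    spans = np.ptp(x, axis=1)
    if np.any(spans == 0):
        bad = ids[int(np.flatnonzero(spans == 0)[0])]
        raise ValueError(f"constant profile (correlation undefined): {bad!r}")
    d = np.clip(pdist(x, metric="correlation"), 0.0, None)
    z = linkage(d, method=method)
    return Dendrogram(tuple(ids), z, method)


@dataclass
class SomClusterSet:
    """Trained SOM: grid of centroids with member lists and confidence bands.

    Centroids and bands live on the per-gene standardized scale.  Bands are
    ``centroid +/- z(ci_level) * spread`` per time point, where the spread
    is the member-profile SD (prediction band, the membership gate) or the
    SD/sqrt(m) centroid confidence band, per the ``band`` argument of
    :func:`som_cluster`.  ``members`` maps flat cell index (row-major) to
    gene IDs; genes whose profile leaves the band at more than
    ``max_outside_frac`` of the time points are listed in ``unassigned``.
    """

    shape: tuple[int, int]
    centroids: np.ndarray
    band_lower: np.ndarray
    band_upper: np.ndarray
    members: dict = field(default_factory=dict)
    unassigned: tuple[str, ...] = ()
    assignments: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return self.shape[0] * self.shape[1]


def _standardize(x: np.ndarray, ids) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    flat = np.flatnonzero(sd[:, 0] == 0)
    if len(flat):
        raise ValueError(f"constant profile cannot be standardized: {ids[int(flat[0])]!r}")
    return (x - mu) / sd


def som_cluster(
    expr: ExpressionSeries,
    rows: int = 2,
    cols: int = 4,
    n_iter: int = 500,
    seed: int = 0,
    ci_level: float = 0.95,
    max_outside_frac: float = 0.2,
    sigma0: float = 0.5,
    band: str = "sd",
) -> SomClusterSet:
    """Batch self-organizing map over standardized temporal profiles.

    Prototypes are seeded with kmeans++ and refined by batch updates with a
    Gaussian neighbourhood shrinking linearly from ``sigma0`` to ~0 over
    ``n_iter`` sweeps, then polished with plain k-means steps until the
    assignment is stable.  The default neighbourhood is deliberately narrow:
    the grids used here are tiny (8-9 cells) and the seeding is already
    close to optimal, so the neighbourhood only orders similar prototypes
    onto adjacent cells; wide radii blur well-separated temporal archetypes
    into each other.  Deterministic for a fixed seed.
    """
    k = rows * cols
    if k < 1:
        raise ValueError("grid must have at least one cell")
    if expr.n_genes < k:
        raise ValueError(f"need at least {k} genes for a {rows}x{cols} grid")
    if not (0.0 < ci_level < 1.0):
        raise ValueError("ci_level must be in (0, 1)")
    if not (0.0 <= max_outside_frac <= 1.0):
        raise ValueError("max_outside_frac must be in [0, 1]")
    if band not in ("sd", "se"):
        raise ValueError("band must be 'sd' (member prediction band) or 'se' (centroid CI)")

    x = _standardize(expr.values, expr.gene_ids)
    rng = np.random.default_rng(seed)
    centroids, _ = kmeans_plusplus(x, n_clusters=k, random_state=int(rng.integers(2**31)))

    grid_pos = np.array([(r, c) for r in range(rows) for c in range(cols)], dtype=float)
    grid_d2 = ((grid_pos[:, None, :] - grid_pos[None, :, :]) ** 2).sum(axis=2)
    sigma_end = 0.05

    def assign(c: np.ndarray) -> np.ndarray:
        d2 = ((x[:, None, :] - c[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d2, axis=1)

    for it in range(n_iter):
        sigma = sigma0 + (sigma_end - sigma0) * (it / max(n_iter - 1, 1))
        bmu = assign(centroids)
        h = np.exp(-grid_d2 / (2.0 * sigma * sigma))  # cells x cells
        w = h[:, bmu]  # cells x genes
        totals = w.sum(axis=1)
        new = w @ x
        nonzero = totals > 1e-12
        centroids[nonzero] = new[nonzero] / totals[nonzero, None]

    # k-means polish: hard assignments, neighbourhood off
    bmu = assign(centroids)
    for _ in range(100):
        for c in range(k):
            idx = np.flatnonzero(bmu == c)
            if len(idx):
                centroids[c] = x[idx].mean(axis=0)
        new_bmu = assign(centroids)
        if np.array_equal(new_bmu, bmu):
            break
        bmu = new_bmu

    n_t = x.shape[1]
    lower = np.empty((k, n_t))
    upper = np.empty((k, n_t))
    members: dict[int, list[str]] = {c: [] for c in range(k)}
    z = norm.ppf(0.5 + ci_level / 2.0)
    for c in range(k):
        idx = np.flatnonzero(bmu == c)
        if len(idx) == 0:
            lower[c] = upper[c] = centroids[c]
            continue
        prof = x[idx]
        mean = prof.mean(axis=0)
        if len(idx) > 1:
            spread = prof.std(axis=0, ddof=1)
            if band == "se":
                spread = spread / np.sqrt(len(idx))
        else:
            spread = np.zeros(n_t)
        centroids[c] = mean
        lower[c] = mean - z * spread
        upper[c] = mean + z * spread

    tol = 1e-9
    unassigned: list[str] = []
    assignments: dict[str, int] = {}
    for i, gid in enumerate(expr.gene_ids):
        c = int(bmu[i])
        outside = np.mean((x[i] < lower[c] - tol) | (x[i] > upper[c] + tol))
        if outside > max_outside_frac:
            unassigned.append(gid)
        else:
            members[c].append(gid)
            assignments[gid] = c
    return SomClusterSet(
        shape=(rows, cols),
        centroids=centroids,
        band_lower=lower,
        band_upper=upper,
        members=members,
        unassigned=tuple(unassigned),
        assignments=assignments,
    )
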