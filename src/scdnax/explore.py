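"""Clone exploration: VAF-matrix construction, clustering, PCA, and
per-cluster genotype/VAF summaries.

Cells are clustered in VAF space over a user-selected set of variants.
K-means (the default), DBSCAN and Leiden community detection on a kNN graph
are provided; the elbow curve (within-cluster sum of squares versus k)
supports the user's choice of k.  Missing calls are handled complete-case:
a cell missing any selected variant is dropped from the matrix — imputation
would manufacture signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN, KMeans
from sklearn.metrics import adjusted_rand_score
from sklearn.neighbors import NearestNeighbors

from .dataset import ScdnaDataset


@dataclass
class VafMatrix:
    """Complete-case cells x selected-variants VAF matrix (percent)."""

    values: np.ndarray
    cell_index: np.ndarray  # indices into the (filtered) dataset
    variant_keys: list[tuple[str, int, str, str]]
    n_dropped_cells: int = 0

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]


@dataclass
class ClusteringResult:
    labels: np.ndarray  # -1 allowed for DBSCAN noise
    method: str
    params: dict
    centroids: Optional[np.ndarray] = None
    wss_curve: Optional[list[tuple[int, float]]] = None
    pca: Optional[tuple[np.ndarray, np.ndarray]] = None  # (projection, evr)
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.tolist()) - {-1})


class EmptyMatrixError(ValueError):
    pass


def build_vaf_matrix(
    dataset: ScdnaDataset, variant_keys: Sequence[tuple[str, int, str, str]]
) -> VafMatrix:
    """Select AF columns for the given variant keys, complete-case on cells."""
    key_to_col = {k: j for j, k in enumerate(dataset.variant_keys)}
    cols = []
    for key in variant_keys:
        if key not in key_to_col:
            raise KeyError(f"variant {key} not present in dataset")
        cols.append(key_to_col[key])
    cols = np.asarray(cols, dtype=np.intp)
    complete = (dataset.ngt[:, cols] != 3).all(axis=1)
    keep = np.flatnonzero(complete)
    if keep.size == 0:
        raise EmptyMatrixError(
            "no cell is genotyped in every selected variant"
        )
    return VafMatrix(
        values=dataset.af[np.ix_(keep, cols)].astype(float),
        cell_index=keep,
        variant_keys=[dataset.variants[j].key for j in cols],
        n_dropped_cells=int(dataset.n_cells - keep.size),
    )


def _canonicalize_labels(
    labels: np.ndarray, centroids: Optional[np.ndarray] = None
) -> tuple[np.ndarray, Optional[np.ndarray]]:
    """Relabel clusters by descending size; ties by centroid lexicographic
    order (falling back to old label order).  Noise (-1) is untouched."""
    old = [int(l) for l in sorted(set(labels.tolist()) - {-1})]
    sizes = {l: int((labels == l).sum()) for l in old}

    def sort_key(l: int):
        if centroids is not None:
            return (-sizes[l], tuple(centroids[l]))
        return (-sizes[l], l)

    order = sorted(old, key=sort_key)
    mapping = {l: i for i, l in enumerate(order)}
    new_labels = np.array([mapping.get(int(l), -1) for l in labels], dtype=int)
    new_centroids = None
    if centroids is not None:
        new_centroids = np.vstack([centroids[l] for l in order]) if order else centroids
    return new_labels, new_centroids


def _pca_for_result(x: np.ndarray) -> Optional[tuple[np.ndarray, np.ndarray]]:
    n_comp = min(2, x.shape[0], x.shape[1])
    if x.shape[0] < 2 or n_comp < 1:
        return None
    return pca_project(x, n_components=n_comp)


def _best_kmeans(
    x: np.ndarray,
    k: int,
    seed: int,
    n_init: int,
    warm_start_centroids: Optional[np.ndarray] = None,
) -> KMeans:
    """Best-of-n_init Lloyd runs from k-means++; optionally also try the
    previous k's centroids plus the point farthest from them."""
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, init="k-means++")
    km.fit(x)
    if warm_start_centroids is not None and warm_start_centroids.shape[0] == k - 1:
        d = np.linalg.norm(x[:, None, :] - warm_start_centroids[None], axis=2)
        farthest = x[int(d.min(axis=1).argmax())]
        init = np.vstack([warm_start_centroids, farthest[None, :]])
        km2 = KMeans(n_clusters=k, n_init=1, random_state=seed, init=init)
        km2.fit(x)
        if km2.inertia_ < km.inertia_:
            return km2
    return km


def cluster_kmeans(
    vaf: VafMatrix, k: int, seed: int = 0, n_init: int = 10
) -> ClusteringResult:
    """K-means in VAF space, best of ``n_init`` k-means++ restarts by WSS."""
    x = vaf.values
    if not 1 <= k <= x.shape[0]:
        raise ValueError(f"k = {k} outside [1, {x.shape[0]} rows]")
    km = _best_kmeans(x, k, seed, n_init)
    labels, centroids = _canonicalize_labels(km.labels_, km.cluster_centers_)
    return ClusteringResult(
        labels=labels,
        method="kmeans",
        params={"k": k, "seed": seed, "n_init": n_init},
        centroids=centroids,
        pca=_pca_for_result(x),
        diagnostics={"wss": float(km.inertia_)},
    )


def elbow_curve(
    vaf: VafMatrix, k_max: int, seed: int = 0, n_init: int = 10
) -> list[tuple[int, float]]:
    """WSS of the best k-means fit for k = 1..k_max, sorted by k.

    Each k also tries a warm start built from the previous k's centroids
    plus the farthest remaining point, which guarantees the curve is
    non-increasing in k.
    """
    x = vaf.values
    if k_max > x.shape[0]:
        raise ValueError(f"k_max = {k_max} exceeds {x.shape[0]} rows")
    curve: list[tuple[int, float]] = []
    prev_centroids = None
    for k in range(1, k_max + 1):
        km = _best_kmeans(x, k, seed, n_init, warm_start_centroids=prev_centroids)
        curve.append((k, float(km.inertia_)))
        prev_centroids = km.cluster_centers_
    return curve


def cluster_dbscan(vaf: VafMatrix, eps: float, min_pts: int) -> ClusteringResult:
    """Density clustering (Euclidean); noise points get label -1."""
    if eps <= 0:
        raise ValueError("eps must be > 0")
    if min_pts < 1:
        raise ValueError("min_pts must be >= 1")
    x = vaf.values
    db = DBSCAN(eps=eps, min_samples=min_pts).fit(x)
    labels, _ = _canonicalize_labels(db.labels_)
    return ClusteringResult(
        labels=labels,
        method="dbscan",
        params={"eps": eps, "min_pts": min_pts},
        pca=_pca_for_result(x),
        diagnostics={"n_noise": int((labels == -1).sum())},
    )


def knn_graph(x: np.ndarray, n_neighbors: int) -> list[tuple[int, int]]:
    """Symmetric (union) unweighted kNN edge list, Euclidean metric."""
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(x)
    _, idx = nn.kneighbors(x)
    edges = set()
    for i in range(x.shape[0]):
        for j in idx[i, 1:]:  # skip self
            a, b = (i, int(j)) if i < j else (int(j), i)
            if a != b:
                edges.add((a, b))
    return sorted(edges)


def cluster_leiden(
    vaf: VafMatrix, n_neighbors: int = 15, resolution: float = 1.0, seed: int = 0
) -> ClusteringResult:
    """Leiden modularity communities on a symmetric unweighted kNN graph."""
    import igraph
    import leidenalg

    x = vaf.values
    n = x.shape[0]
    if n_neighbors >= n:
        raise ValueError(f"n_neighbors = {n_neighbors} must be < {n} rows")
    edges = knn_graph(x, n_neighbors)
    if not edges:
        raise ValueError("kNN graph has zero edges")
    g = igraph.Graph(n=n, edges=edges)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    labels, _ = _canonicalize_labels(np.asarray(part.membership, dtype=int))
    return ClusteringResult(
        labels=labels,
        method="leiden",
        params={"n_neighbors": n_neighbors, "resolution": resolution, "seed": seed},
        pca=_pca_for_result(x),
        diagnostics={"n_edges": len(edges), "modularity": float(part.modularity)},
    )


def pca_project(
    vaf: VafMatrix | np.ndarray, n_components: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Column-centred SVD projection onto the top principal components.

    Sign convention: each component's largest-magnitude loading is made
    positive.  Returns (projection, explained-variance fractions); the
    fractions are relative to total variance and sum to <= 1.
    """
    x = vaf.values if isinstance(vaf, VafMatrix) else np.asarray(vaf, dtype=float)
    n, p = x.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 rows")
    if n_components > min(n, p):
        raise ValueError(
            f"n_components = {n_components} exceeds min(rows, cols) = {min(n, p)}"
        )
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    # flip so each component's largest-|loading| is positive
    for i in range(vt.shape[0]):
        j = int(np.abs(vt[i]).argmax())
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    proj = (u[:, :n_components] * s[:n_components])
    total_var = float((s**2).sum())
    if total_var == 0:
        evr = np.zeros(n_components)
    else:
        evr = (s[:n_components] ** 2) / total_var
    return proj, evr


def genotype_abundance(
    dataset: ScdnaDataset,
    labels: Sequence[int],
    variant_keys: Sequence[tuple[str, int, str, str]],
    cell_index: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Counts of NGT codes {0,1,2,3} per (cluster, variant).

    ``labels`` must align with ``cell_index`` (or with all cells when
    ``cell_index`` is omitted); per (cluster, variant) the genotype
    marginal equals the cluster size.
    """
    labels = np.asarray(labels, dtype=int)
    if cell_index is None:
        cell_index = np.arange(dataset.n_cells)
    cell_index = np.asarray(cell_index, dtype=np.intp)
    if labels.shape[0] != cell_index.shape[0]:
        raise ValueError(
            f"labels ({labels.shape[0]}) misaligned with cells ({cell_index.shape[0]})"
        )
    key_to_col = {k: j for j, k in enumerate(dataset.variant_keys)}
    rows = []
    for key in variant_keys:
        if key not in key_to_col:
            raise KeyError(f"variant {key} not present in dataset")
        col = dataset.ngt[cell_index, key_to_col[key]]
        vid = dataset.variants[key_to_col[key]].id
        for cl in sorted(set(labels.tolist())):
            in_cl = col[labels == cl]
            for code, name in ((0, "WT"), (1, "Het"), (2, "Hom"), (3, "Missing")):
                rows.append(
                    {
                        "cluster": cl,
                        "variant": vid,
                        "genotype": name,
                        "ngt": code,
                        "count": int((in_cl == code).sum()),
                    }
                )
    return pd.DataFrame(rows)


def cluster_vaf_summary(vaf: VafMatrix, labels: Sequence[int]) -> pd.DataFrame:
    """Per (cluster, variant) order statistics of VAF (midpoint quartiles)."""
    labels = np.asarray(labels, dtype=int)
    if labels.shape[0] != vaf.n_cells:
        raise ValueError("labels misaligned with VAF matrix rows")
    rows = []
    for cl in sorted(set(labels.tolist())):
        vals = vaf.values[labels == cl]
        for j, key in enumerate(vaf.variant_keys):
            col = vals[:, j]
            entry = {
                "cluster": cl,
                "variant": f"{key[0]}:{key[1]}:{key[2]}/{key[3]}",
                "n": int(col.size),
            }
            if col.size:
                entry.update(
                    median=float(np.median(col)),
                    q1=float(np.percentile(col, 25, method="midpoint")),
                    q3=float(np.percentile(col, 75, method="midpoint")),
                    mean=float(col.mean()),
                )
            else:
                entry.update(median=np.nan, q1=np.nan, q3=np.nan, mean=np.nan)
            rows.append(entry)
    return pd.DataFrame(rows)


def adjusted_rand_index(a: Sequence[int], b: Sequence[int]) -> float:
    """Chance-corrected partition agreement (pair-counting ARI) in [-1, 1]."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape[0] != b.shape[0]:
        raise ValueError(f"label lengths differ: {a.shape[0]} vs {b.shape[0]}")
    return float(adjusted_rand_score(a, b))
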