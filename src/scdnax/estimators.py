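"""Scikit-learn-compatible estimator façades over the workflow stages.

These compose with sklearn pipelines and model selection; the module-level
functions in :mod:`scdnax.panel`, :mod:`scdnax.filtering` and
:mod:`scdnax.explore` remain the functional core each estimator delegates
to.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from . import explore, filtering, panel
from .dataset import ScdnaDataset
from .explore import VafMatrix


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, VafMatrix):
        return X.values
    return check_array(X, dtype=float)


class ReadCountNormalizer(TransformerMixin, BaseEstimator):
    """Diploid-centred amplicon read-count normalization.

    ``fit`` learns per-amplicon medians from the row-normalized training
    cells; ``transform`` row-normalizes new cells and applies those medians.
    ``fit_transform`` on one matrix reproduces the three-step normalization
    exactly (per-amplicon median of the output is 2).

    Attributes
    ----------
    median_ : ndarray of shape (n_amplicons,)
        Per-amplicon medians of row-normalized counts over included cells.
    excluded_cells_ : list of int
        Zero-total training cells excluded from the median.
    degenerate_amplicons_ : list of int
        Amplicons with zero median (their normalized values are 0).
    """

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        nc = panel.normalize_read_counts(X)
        totals = X.sum(axis=1)
        included = totals > 0
        row_norm = X[included] / totals[included, None]
        self.median_ = np.median(row_norm, axis=0)
        self.excluded_cells_ = nc.excluded_cells
        self.degenerate_amplicons_ = nc.degenerate_amplicons
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "median_")
        X = check_array(X, dtype=float)
        totals = X.sum(axis=1)
        out = np.zeros_like(X, dtype=float)
        ok = totals > 0
        out[ok] = X[ok] / totals[ok, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(self.median_ > 0, out / self.median_, 0.0)
        return 2.0 * out


class VariantCallFilter(BaseEstimator):
    """Mask/drop filter over a :class:`ScdnaDataset` (stateless transform).

    Parameters mirror :class:`scdnax.filtering.FilterConfig`; ``transform``
    returns the filtered dataset and stores the :class:`FilterReport` as
    ``report_``.
    """

    def __init__(
        self,
        min_dp: int = 10,
        min_gq: int = 30,
        min_vaf_mut: float = 20.0,
        min_genotyped_cells_frac: float = 0.5,
        min_mutated_cells_frac: float = 0.01,
        max_mutated_cells_frac: float = 1.0,
        min_cell_genotyped_frac: float = 0.5,
    ):
        self.min_dp = min_dp
        self.min_gq = min_gq
        self.min_vaf_mut = min_vaf_mut
        self.min_genotyped_cells_frac = min_genotyped_cells_frac
        self.min_mutated_cells_frac = min_mutated_cells_frac
        self.max_mutated_cells_frac = max_mutated_cells_frac
        self.min_cell_genotyped_frac = min_cell_genotyped_frac

    def _config(self) -> filtering.FilterConfig:
        return filtering.FilterConfig(**self.get_params())

    def fit(self, X: ScdnaDataset, y=None):
        if not isinstance(X, ScdnaDataset):
            raise TypeError("VariantCallFilter operates on ScdnaDataset objects")
        self.n_features_in_ = X.n_variants
        return self

    def transform(self, X: ScdnaDataset) -> ScdnaDataset:
        out, report = filtering.filter_variants(X, self._config())
        self.report_ = report
        return out

    def fit_transform(self, X: ScdnaDataset, y=None) -> ScdnaDataset:
        return self.fit(X).transform(X)


class VAFKMeans(ClusterMixin, BaseEstimator):
    """K-means clone clustering in VAF space (size-canonicalized labels)."""

    def __init__(self, k: int = 4, seed: int = 0, n_init: int = 10):
        self.k = k
        self.seed = seed
        self.n_init = n_init

    def fit(self, X, y=None):
        x = _as_matrix(X)
        res = explore.cluster_kmeans(
            _wrap(x), k=self.k, seed=self.seed, n_init=self.n_init
        )
        self.labels_ = res.labels
        self.cluster_centers_ = res.centroids
        self.inertia_ = res.diagnostics["wss"]
        self.result_ = res
        self.n_features_in_ = x.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "cluster_centers_")
        x = _as_matrix(X)
        d = np.linalg.norm(x[:, None, :] - self.cluster_centers_[None], axis=2)
        return d.argmin(axis=1)


class VAFDBSCAN(ClusterMixin, BaseEstimator):
    """Density-based clone clustering; noise labeled -1."""

    def __init__(self, eps: float = 10.0, min_pts: int = 5):
        self.eps = eps
        self.min_pts = min_pts

    def fit(self, X, y=None):
        x = _as_matrix(X)
        res = explore.cluster_dbscan(_wrap(x), eps=self.eps, min_pts=self.min_pts)
        self.labels_ = res.labels
        self.result_ = res
        self.n_features_in_ = x.shape[1]
        return self


class VAFLeiden(ClusterMixin, BaseEstimator):
    """Leiden communities on a symmetric unweighted kNN graph of cells."""

    def __init__(self, n_neighbors: int = 15, resolution: float = 1.0, seed: int = 0):
        self.n_neighbors = n_neighbors
        self.resolution = resolution
        self.seed = seed

    def fit(self, X, y=None):
        x = _as_matrix(X)
        res = explore.cluster_leiden(
            _wrap(x),
            n_neighbors=self.n_neighbors,
            resolution=self.resolution,
            seed=self.seed,
        )
        self.labels_ = res.labels
        self.result_ = res
        self.n_features_in_ = x.shape[1]
        return self


def _wrap(x: np.ndarray) -> VafMatrix:
    return VafMatrix(
        values=np.asarray(x, dtype=float),
        cell_index=np.arange(x.shape[0]),
        variant_keys=[("", j, "N", "A") for j in range(x.shape[1])],
    )
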