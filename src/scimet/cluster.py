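"""Dimensionality reduction, graph clustering and embedding.

The filtered window matrix is imputed (missing entries get the window's
mean fraction across covered cells), optionally centered per window,
reduced by truncated SVD to 50 components, and clustered by Louvain
community detection on a k-nearest-neighbor graph of the component
scores.  Per-window centering is on by default: without it the first
component is dominated by each cell's global methylation level rather
than by regional differences (switch it off to process raw fractions).
The 2-D embedding is decorative and pluggable; the default projects the
first two components, and a UMAP embedder is available when umap-learn
is installed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.decomposition import TruncatedSVD
from sklearn.neighbors import NearestNeighbors

from .matrix import WindowMatrix


@dataclass
class ClusterResult:
    barcodes: np.ndarray
    labels: np.ndarray  # contiguous ints, 0 = largest cluster
    scores: np.ndarray  # cells x components
    embedding: np.ndarray  # cells x 2
    params: dict

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "barcode": self.barcodes,
                "cluster": self.labels,
                "umap1": self.embedding[:, 0],
                "umap2": self.embedding[:, 1],
            }
        )


def impute(m: WindowMatrix, method: str = "window_mean") -> np.ndarray:
    """Fill missing fractions: per-window mean or per-cell global level."""
    X = m.frac.copy()
    missing = np.isnan(X)
    if not missing.any():
        return X
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        if method == "window_mean":
            fill = np.nanmean(X, axis=0)
            fill = np.where(np.isnan(fill), np.nanmean(X), fill)
            X[missing] = np.broadcast_to(fill, X.shape)[missing]
        elif method == "cell_mean":
            fill = np.nanmean(X, axis=1)
            fill = np.where(np.isnan(fill), np.nanmean(X), fill)
            X[missing] = np.broadcast_to(fill[:, None], X.shape)[missing]
        else:
            raise ValueError(f"unknown imputation method {method!r}")
    return X


def _embed_svd(scores: np.ndarray, seed: int) -> np.ndarray:
    if scores.shape[1] >= 2:
        return scores[:, :2].copy()
    return np.column_stack([scores[:, 0], np.zeros(len(scores))])


def _embed_umap(scores: np.ndarray, seed: int) -> np.ndarray:
    import umap

    return umap.UMAP(n_components=2, random_state=seed).fit_transform(scores)


EMBEDDERS: dict[str, Callable[[np.ndarray, int], np.ndarray]] = {
    "svd": _embed_svd,
    "umap": _embed_umap,
}


def reduce_and_cluster(
    m: WindowMatrix,
    n_components: int = 50,
    knn_k: int = 30,
    seed: int = 0,
    center: bool = True,
    impute_method: str = "window_mean",
    embedder: str | Callable[[np.ndarray, int], np.ndarray] = "svd",
) -> ClusterResult:
    """SVD -> kNN graph -> Louvain on a filtered window matrix.

    Labels are deterministic for a fixed seed: the SVD uses a seeded
    randomized solver, neighbor lists are exact, and the Louvain run is
    seeded.  Cluster ids are relabeled by decreasing size.  If the
    matrix has fewer cells than ``knn_k`` the neighbor count is reduced
    with a warning.
    """
    if m.is_empty:
        raise ValueError("cannot cluster an empty matrix")
    n_cells = m.shape[0]
    X = impute(m, impute_method)
    if center:
        X = X - X.mean(axis=0, keepdims=True)

    k_comp = int(min(n_components, n_cells - 1, m.shape[1] - 1))
    k_comp = max(k_comp, 1)
    if float(X.std()) == 0.0:
        scores = np.zeros((n_cells, k_comp))
    else:
        svd = TruncatedSVD(n_components=k_comp, random_state=seed)
        scores = svd.fit_transform(X)

    if knn_k >= n_cells:
        warnings.warn(
            f"knn_k={knn_k} >= {n_cells} cells; reducing to {n_cells - 1}",
            stacklevel=2,
        )
        knn_k = n_cells - 1
    knn_k = max(knn_k, 1)

    if float(scores.std()) == 0.0:
        # degenerate geometry (e.g. identical rows): one cluster
        labels = np.zeros(n_cells, dtype=int)
    else:
        nn = NearestNeighbors(n_neighbors=knn_k + 1).fit(scores)
        _, idx = nn.kneighbors(scores)
        graph = nx.Graph()
        graph.add_nodes_from(range(n_cells))
        for i in range(n_cells):
            for j in idx[i, 1:]:
                graph.add_edge(i, int(j))
        communities = nx.community.louvain_communities(graph, seed=seed)
        communities = sorted(communities, key=lambda c: (-len(c), min(c)))
        labels = np.empty(n_cells, dtype=int)
        for lab, members in enumerate(communities):
            labels[list(members)] = lab

    embed_fn = EMBEDDERS[embedder] if isinstance(embedder, str) else embedder
    embedding = embed_fn(scores, seed)
    params = {
        "n_components": k_comp,
        "knn_k": knn_k,
        "seed": seed,
        "center": center,
        "impute": impute_method,
        "embedder": embedder if isinstance(embedder, str) else getattr(embedder, "__name__", "custom"),
    }
    return ClusterResult(m.barcodes.copy(), labels, scores, embedding, params)
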