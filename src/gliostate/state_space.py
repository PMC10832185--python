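"""Dimensionality reduction, driver-gene selection and state clustering.

PCA treats samples as observations and genes as features, centering but (by
default) not variance-scaling the genes.  Each component's sign is fixed by
forcing its largest-magnitude loading positive, which makes eigenvector
"waterfall" plots and the driver sets derived from them reproducible.

Driver genes for a component are those whose differential — by default the
absolute loading — falls in the extreme tail of all differentials.  With the
default ``tail_fraction`` of 0.05 the threshold is the 95th percentile
(linear interpolation) and selection uses strict inequality, so at most 5% of
genes are returned.  Alternative readings of the rule are available via
``mode``: ``"literal"`` thresholds at the 5th percentile (selecting ~95% of
genes), and ``"gap"`` uses the difference between consecutive ranked
loadings in the waterfall instead of the loading itself.

State assignment is confirmed with seeded k-means on the sample scores and
with agglomerative clustering (Manhattan distance, Ward linkage).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .errors import ClusteringError, InvalidParameterError
from .normalize import NormalizedMatrix

__all__ = [
    "PCAResult",
    "DriverGeneSet",
    "HierarchicalClustering",
    "fit_pca",
    "select_driver_genes",
    "kmeans_states",
    "hierarchical_cluster",
]


@dataclass
class PCAResult:
    loadings: pd.DataFrame                # genes x components, unit-norm columns
    scores: pd.DataFrame                  # samples x components
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


@dataclass
class DriverGeneSet:
    component: int
    genes: list                           # ordered by decreasing differential
    differentials: pd.Series              # for the selected genes, same order
    threshold: float
    mode: str = "absolute"


@dataclass
class HierarchicalClustering:
    linkage: np.ndarray                   # scipy linkage matrix
    leaf_order: list                      # item labels in dendrogram order
    labels: list                          # item labels in input order


def _as_feature_frame(data: NormalizedMatrix | pd.DataFrame) -> pd.DataFrame:
    """Genes-by-samples frame from either container."""
    return data.values if isinstance(data, NormalizedMatrix) else data


def fit_pca(
    data: NormalizedMatrix | pd.DataFrame,
    n_components: int,
    scale: bool = False,
) -> PCAResult:
    """Principal components of log2 expression, samples as observations.

    Genes are centered; set ``scale=True`` to also divide by the per-gene
    standard deviation.  Deterministic: the full SVD solver is used and each
    component's largest-magnitude loading is made positive.
    """
    frame = _as_feature_frame(data)
    X = frame.to_numpy(dtype=float).T          # samples x genes
    n_samples, n_genes = X.shape
    if n_samples < 2:
        raise InvalidParameterError("PCA needs at least 2 samples")
    max_comp = min(n_genes, n_samples - 1)
    if not (1 <= n_components <= max_comp):
        raise InvalidParameterError(
            f"n_components must be in [1, {max_comp}], got {n_components}"
        )
    if scale:
        sd = X.std(axis=0, ddof=0)
        X = (X - X.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_.T             # genes x components
    for j in range(n_components):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    comp_labels = [f"PC{j + 1}" for j in range(n_components)]
    return PCAResult(
        loadings=pd.DataFrame(loadings, index=frame.index, columns=comp_labels),
        scores=pd.DataFrame(scores, index=frame.columns, columns=comp_labels),
        explained_variance_ratio=model.explained_variance_ratio_,
    )


def select_driver_genes(
    pca: PCAResult,
    component: int = 0,
    tail_fraction: float = 0.05,
    mode: str = "absolute",
) -> DriverGeneSet:
    """Genes whose loading differential exceeds the extreme-tail threshold.

    ``component`` is 0-based.  ``mode`` picks the differential and threshold:

    - ``"absolute"`` (default): differential = |loading|, threshold at the
      (1 - tail_fraction) quantile, strict inequality — the top tail.
    - ``"literal"``: same differential but thresholded at the
      ``tail_fraction`` quantile, i.e. "greater than the 5th percentile".
    - ``"gap"``: differential = drop to the next gene in the descending
      waterfall of loadings (last gene gets 0), top-tail threshold.
    """
    if not (0 <= component < pca.n_components):
        raise InvalidParameterError(f"component {component} out of range")
    if not (0 < tail_fraction < 1):
        raise InvalidParameterError("tail_fraction must lie in (0, 1)")
    load = pca.loadings.iloc[:, component]
    if mode in ("absolute", "literal"):
        diff = load.abs()
    elif mode == "gap":
        ranked = load.sort_values(ascending=False)
        gaps = -np.diff(ranked.to_numpy(), append=ranked.iloc[-1])
        diff = pd.Series(gaps, index=ranked.index).reindex(load.index)
    else:
        raise InvalidParameterError(f"unknown driver-selection mode: {mode!r}")
    quantile = tail_fraction if mode == "literal" else 1.0 - tail_fraction
    threshold = float(np.quantile(diff.to_numpy(), quantile))
    selected = diff[diff > threshold].sort_values(ascending=False, kind="stable")
    return DriverGeneSet(
        component=component,
        genes=list(selected.index),
        differentials=selected,
        threshold=threshold,
        mode=mode,
    )


def kmeans_states(
    scores: pd.DataFrame,
    k: int = 3,
    seed: int = 0,
    n_restarts: int = 10,
) -> tuple[pd.Series, float]:
    """Seeded k-means on sample scores; returns (labels, inertia)."""
    X = scores.to_numpy(dtype=float)
    if not (1 <= k <= X.shape[0]):
        raise InvalidParameterError(f"k must be in [1, {X.shape[0]}], got {k}")
    model = KMeans(
        n_clusters=k, n_init=n_restarts, random_state=seed, algorithm="lloyd"
    )
    labels = model.fit_predict(X)
    return pd.Series(labels, index=scores.index, name="state"), float(model.inertia_)


def hierarchical_cluster(
    matrix: pd.DataFrame,
    axis: str = "rows",
) -> HierarchicalClustering:
    """Agglomerative clustering with Manhattan distances and Ward linkage.

    Returns the scipy merge tree and a deterministic leaf order (scipy breaks
    distance ties by input index).
    """
    if axis not in ("rows", "columns"):
        raise InvalidParameterError("axis must be 'rows' or 'columns'")
    frame = matrix if axis == "rows" else matrix.T
    X = frame.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ClusteringError("need at least 2 items to cluster")
    if np.isnan(X).any():
        raise ClusteringError("missing values present; impute or drop first")
    Z = hierarchy.linkage(pdist(X, metric="cityblock"), method="ward")
    order = hierarchy.leaves_list(Z)
    labels = list(frame.index)
    return HierarchicalClustering(
        linkage=Z,
        leaf_order=[labels[i] for i in order],
        labels=labels,
    )
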