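"""Dietary-pattern clustering: UMAP embedding, K-means, cluster-number
selection, and clustering-comparison utilities.

The pipeline encodes the ordinal questionnaire as 1-based integer scale
positions (no standardization), embeds the matrix in 2D with UMAP
(Chebyshev metric, n_neighbors 10, min_dist 0.1), partitions the embedding
with K-means, and selects the number of clusters by three diagnostics
reported jointly: the within-cluster-sum-of-squares elbow, the mean
silhouette, and the number of modes of a 2D Gaussian kernel density
estimate over the embedding (the contour-map peak count).

The default KDE bandwidth adapts to the finest data scale: 2.5 times
the median distance to the 10th nearest neighbour.  Normal-reference
rules (Scott) are derived for unimodal targets; on the multi-island
geometry UMAP produces they oversmooth and merge adjacent density modes,
while fixed fractions of them undersmooth flat unimodal clouds.  Both
Scott variants remain selectable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from sklearn.neighbors import KernelDensity

from .cohort import Cohort
from .schema import CATEGORIES


@dataclass
class ClusteringConfig:
    """Parameters of the embedding / clustering / selection stage.

    UMAP defaults are the tuned study values; KDE defaults are the
    adaptive nearest-neighbour bandwidth ("knn") on a 200x200 evaluation
    grid with peaks counted above 5% of the maximum density.
    """

    n_neighbors: int = 10
    min_dist: float = 0.1
    n_components: int = 2
    metric: str = "chebyshev"
    seed: int = 0
    k: int | None = None              # fixed k; None = select automatically
    k_range: tuple[int, int] = (2, 10)
    kmeans_n_init: int = 10
    kde_bandwidth: float | str = "knn"
    kde_grid_size: int = 200
    kde_peak_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.n_neighbors < 2:
            raise ValueError("n_neighbors must be >= 2")
        if self.n_components != 2:
            raise ValueError("the pattern pipeline is defined for a 2D "
                             "embedding (n_components = 2)")

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        doc["k_range"] = list(self.k_range)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ClusteringConfig":
        doc = yaml.safe_load(open(path))
        if "k_range" in doc:
            doc["k_range"] = tuple(doc["k_range"])
        return cls(**doc)


@dataclass
class Embedding2D:
    coordinates: pd.DataFrame          # columns D1, D2
    config: ClusteringConfig

    def __post_init__(self) -> None:
        if not np.isfinite(self.coordinates.to_numpy()).all():
            raise ValueError("embedding contains non-finite coordinates")

    @property
    def values(self) -> np.ndarray:
        return self.coordinates.to_numpy()


@dataclass
class SelectionDiagnostics:
    wcss: dict[int, float]
    silhouette: dict[int, float]
    kde_peak_count: int
    elbow_k: int
    silhouette_k: int
    selected_k: int
    agreed: bool                       # KDE count confirmed elbow/silhouette

    def to_dict(self) -> dict:
        return {
            "wcss": {int(k): float(v) for k, v in self.wcss.items()},
            "silhouette": {int(k): float(v) for k, v in self.silhouette.items()},
            "kde_peak_count": int(self.kde_peak_count),
            "elbow_k": int(self.elbow_k),
            "silhouette_k": int(self.silhouette_k),
            "selected_k": int(self.selected_k),
            "agreed": bool(self.agreed),
        }


@dataclass
class ClusterAssignment:
    labels: pd.Series                  # cluster id per participant, 0..k-1
    k: int
    diagnostics: SelectionDiagnostics | None = None

    def __post_init__(self) -> None:
        vals = self.labels.to_numpy()
        if vals.min() < 0 or vals.max() >= self.k:
            raise ValueError("labels must lie in 0..k-1")


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------

def encode_matrix(cohort: Cohort,
                  categories: Sequence[str] = CATEGORIES,
                  grouping: Mapping[str, Sequence[str]] | None = None,
                  ) -> pd.DataFrame:
    """Numeric design matrix from a cohort.

    Columns are the selected variables' 1-based integer scale positions
    ("raw data", unstandardized).  With ``grouping``, each group column is
    the mean of its member columns and ungrouped variables are dropped.
    """
    if not categories:
        raise ValueError("at least one variable category must be selected")
    variables = cohort.schema.by_category(categories)
    cols = {}
    for var in variables:
        codes = cohort.data[var.id].cat.codes.to_numpy()
        if (codes < 0).any():
            raise ValueError(f"missing responses in variable {var.id!r}")
        cols[var.id] = codes + 1
    mat = pd.DataFrame(cols, index=cohort.data.index, dtype=float)
    if grouping is not None:
        grouped = {}
        for group, members in grouping.items():
            missing = [m for m in members if m not in mat.columns]
            if missing:
                raise ValueError(f"group {group!r} references unselected or "
                                 f"unknown variables {missing}")
            grouped[group] = mat[list(members)].mean(axis=1)
        mat = pd.DataFrame(grouped, index=mat.index)
    return mat


# ---------------------------------------------------------------------------
# UMAP embedding
# ---------------------------------------------------------------------------

def embed_umap(matrix: pd.DataFrame | np.ndarray,
               config: ClusteringConfig | None = None) -> Embedding2D:
    """2D UMAP embedding of an encoded matrix, deterministic per seed."""
    import umap  # deferred: numba compilation is slow at import time

    config = config or ClusteringConfig()
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < config.n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors+1 = {config.n_neighbors + 1} rows, "
            f"got {X.shape[0]}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_neighbors=config.n_neighbors,
            min_dist=config.min_dist,
            n_components=config.n_components,
            metric=config.metric,
            random_state=config.seed,
        )
        coords = reducer.fit_transform(X)
    index = (matrix.index if isinstance(matrix, pd.DataFrame)
             else pd.RangeIndex(X.shape[0]))
    df = pd.DataFrame(coords, index=index, columns=["D1", "D2"])
    return Embedding2D(df, config)


# ---------------------------------------------------------------------------
# KDE peak counting (contour-map mode count)
# ---------------------------------------------------------------------------

def _scott_bandwidth(X: np.ndarray) -> float:
    # Scott's rule for d=2: n^(-1/(d+4)) times the mean marginal spread
    n = X.shape[0]
    sigma = X.std(axis=0, ddof=1).mean()
    if sigma == 0:
        return 1.0  # degenerate cloud; any positive bandwidth gives one mode
    return float(sigma * n ** (-1.0 / 6.0))


def _knn_bandwidth(X: np.ndarray, k: int = 10, scale: float = 2.5) -> float:
    """Adaptive bandwidth: ``scale`` times the median distance to the
    k-th nearest neighbour (falls back to 1.0 for coincident points)."""
    from sklearn.neighbors import NearestNeighbors

    k = min(k, X.shape[0] - 1)
    dist, _ = NearestNeighbors(n_neighbors=k + 1).fit(X).kneighbors(X)
    med = float(np.median(dist[:, -1]))
    return scale * med if med > 0 else 1.0


def _resolve_bandwidth(X: np.ndarray, bandwidth: float | str) -> float:
    if bandwidth == "knn":
        return _knn_bandwidth(X)
    if bandwidth == "scott":
        return _scott_bandwidth(X)
    if bandwidth == "half-scott":
        return 0.5 * _scott_bandwidth(X)
    return float(bandwidth)


def kde_peak_count(embedding: Embedding2D | np.ndarray,
                   bandwidth: float | str = "knn",
                   grid_size: int = 200,
                   threshold: float = 0.05,
                   pad: float = 3.0) -> int:
    """Number of modes of the 2D Gaussian KDE of the embedding.

    The density is evaluated on a ``grid_size`` x ``grid_size`` grid padded
    by ``pad`` bandwidths around the data range; a mode is a strict local
    maximum over its 8 neighbours whose density exceeds
    ``threshold * max(density)``.
    """
    X = embedding.values if isinstance(embedding, Embedding2D) else \
        np.asarray(embedding, dtype=float)
    if X.shape[0] < 10:
        raise ValueError("need at least 10 points for a density estimate")
    bw = _resolve_bandwidth(X, bandwidth)
    if bw <= 0:
        raise ValueError("bandwidth must be positive")
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")

    kde = KernelDensity(bandwidth=bw, kernel="gaussian").fit(X)
    lo = X.min(axis=0) - pad * bw
    hi = X.max(axis=0) + pad * bw
    gx = np.linspace(lo[0], hi[0], grid_size)
    gy = np.linspace(lo[1], hi[1], grid_size)
    GX, GY = np.meshgrid(gx, gy)
    grid = np.column_stack([GX.ravel(), GY.ravel()])
    density = np.exp(kde.score_samples(grid)).reshape(grid_size, grid_size)

    return _count_grid_modes(density, threshold)


def _count_grid_modes(density: np.ndarray, threshold: float) -> int:
    """Local maxima of a density grid, merging flat plateaus.

    A cell is a candidate if it equals the 3x3 neighbourhood maximum;
    connected candidate plateaus count once (so a symmetric mode split
    across two equal grid cells is one mode, while two distant equal
    maxima are two).  The inclusive cutoff keeps exactly the global
    maximum at threshold = 1.0.
    """
    from scipy import ndimage

    local_max = density == ndimage.maximum_filter(density, size=3,
                                                  mode="constant", cval=-1.0)
    local_max &= density >= threshold * density.max()
    _, n_modes = ndimage.label(local_max)
    return int(n_modes)


def kde_density_grid(embedding: Embedding2D | np.ndarray,
                     bandwidth: float | str = "knn",
                     grid_size: int = 200,
                     pad: float = 3.0):
    """(gx, gy, density) of the embedding KDE, for contour plotting."""
    X = embedding.values if isinstance(embedding, Embedding2D) else \
        np.asarray(embedding, dtype=float)
    bw = _resolve_bandwidth(X, bandwidth)
    kde = KernelDensity(bandwidth=bw, kernel="gaussian").fit(X)
    lo = X.min(axis=0) - pad * bw
    hi = X.max(axis=0) + pad * bw
    gx = np.linspace(lo[0], hi[0], grid_size)
    gy = np.linspace(lo[1], hi[1], grid_size)
    GX, GY = np.meshgrid(gx, gy)
    density = np.exp(
        kde.score_samples(np.column_stack([GX.ravel(), GY.ravel()]))
    ).reshape(grid_size, grid_size)
    return gx, gy, density


def scatter_contour_plot(embedding: Embedding2D | np.ndarray,
                         labels=None, bandwidth: float | str = "knn",
                         path=None):
    """Embedding scatter with overlaid KDE contours (the contour map)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    X = embedding.values if isinstance(embedding, Embedding2D) else \
        np.asarray(embedding, dtype=float)
    gx, gy, density = kde_density_grid(X, bandwidth)
    fig, ax = plt.subplots(figsize=(6, 5))
    if labels is None:
        ax.plot(X[:, 0], X[:, 1], "o", ms=3, alpha=0.6)
    else:
        labels = np.asarray(labels)
        for lab in np.unique(labels):
            pts = X[labels == lab]
            ax.plot(pts[:, 0], pts[:, 1], "o", ms=3, alpha=0.7,
                    label=str(lab))
        ax.legend(title="cluster", fontsize=8)
    ax.contour(gx, gy, density, levels=8, colors="k", linewidths=0.6,
               alpha=0.6)
    ax.set_xlabel("D1")
    ax.set_ylabel("D2")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


# ---------------------------------------------------------------------------
# Cluster-number selection
# ---------------------------------------------------------------------------

def _kmeans(X: np.ndarray, k: int, seed: int, n_init: int) -> KMeans:
    return KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)


def select_k(embedding: Embedding2D | np.ndarray,
             config: ClusteringConfig | None = None) -> SelectionDiagnostics:
    """Cluster-number diagnostics and selection over ``config.k_range``.

    Reports the WCSS curve (elbow at the maximum second difference), the
    mean silhouette per k, and the KDE mode count.  The selected k is the
    KDE mode count when it coincides with the elbow or the silhouette
    optimum (the density map confirms a distance-based criterion);
    otherwise the silhouette optimum is returned with ``agreed=False`` as
    the flag for user override.
    """
    config = config or ClusteringConfig()
    X = embedding.values if isinstance(embedding, Embedding2D) else \
        np.asarray(embedding, dtype=float)
    if np.allclose(X, X[0]):
        raise ValueError("degenerate embedding: all points identical")
    kmin, kmax = config.k_range
    kmax = min(kmax, X.shape[0] - 1)
    if kmin < 2 or kmin > kmax:
        raise ValueError(f"invalid k range ({kmin}, {kmax}) for n={X.shape[0]}")

    ks = list(range(kmin, kmax + 1))
    wcss, sil = {}, {}
    for k in ks:
        km = _kmeans(X, k, config.seed, config.kmeans_n_init)
        wcss[k] = float(km.inertia_)
        sil[k] = float(silhouette_score(X, km.labels_))

    # elbow: maximum second difference of the WCSS curve (interior ks)
    w = np.array([wcss[k] for k in ks])
    if len(ks) >= 3:
        second_diff = w[:-2] - 2 * w[1:-1] + w[2:]
        elbow_k = ks[1 + int(np.argmax(second_diff))]
    else:
        elbow_k = ks[int(np.argmin(w))]
    silhouette_k = max(sil, key=sil.get)
    peaks = kde_peak_count(X, config.kde_bandwidth, config.kde_grid_size,
                           config.kde_peak_threshold)

    agreed = peaks in (elbow_k, silhouette_k)
    selected = peaks if agreed else silhouette_k
    selected = int(np.clip(selected, kmin, kmax))
    return SelectionDiagnostics(wcss=wcss, silhouette=sil,
                                kde_peak_count=peaks, elbow_k=elbow_k,
                                silhouette_k=silhouette_k,
                                selected_k=selected, agreed=agreed)


def kmeans_assign(embedding: Embedding2D | np.ndarray, k: int,
                  config: ClusteringConfig | None = None,
                  diagnostics: SelectionDiagnostics | None = None,
                  ) -> ClusterAssignment:
    """K-means labels (k-means++ with restarts) on the 2D embedding."""
    config = config or ClusteringConfig()
    X = embedding.values if isinstance(embedding, Embedding2D) else \
        np.asarray(embedding, dtype=float)
    km = _kmeans(X, k, config.seed, config.kmeans_n_init)
    index = (embedding.coordinates.index if isinstance(embedding, Embedding2D)
             else pd.RangeIndex(X.shape[0]))
    return ClusterAssignment(pd.Series(km.labels_, index=index, name="cluster"),
                             k=k, diagnostics=diagnostics)


# ---------------------------------------------------------------------------
# Clustering comparison
# ---------------------------------------------------------------------------

def cluster_overlap(a: ClusterAssignment | pd.Series,
                    b: ClusterAssignment | pd.Series) -> pd.Series:
    """Per-cluster agreement (%) after optimal one-to-one label matching.

    Labels of ``b`` are matched to labels of ``a`` by maximizing total
    agreement (Hungarian assignment on the contingency matrix; ties break
    toward the lowest label index).  Returns, for each cluster of ``a``,
    the percentage of its members whose ``b`` label is the matched one.
    """
    sa = a.labels if isinstance(a, ClusterAssignment) else pd.Series(a)
    sb = b.labels if isinstance(b, ClusterAssignment) else pd.Series(b)
    if not sa.index.equals(sb.index):
        if set(sa.index) != set(sb.index):
            raise ValueError("assignments cover different participants")
        sb = sb.loc[sa.index]
    ct = pd.crosstab(sa, sb)
    cost = -ct.to_numpy(dtype=float)
    row_ind, col_ind = linear_sum_assignment(cost)
    matched = {ct.index[i]: ct.columns[j] for i, j in zip(row_ind, col_ind)}
    out = {}
    for label_a in ct.index:
        members = sa == label_a
        if label_a in matched:
            agree = (sb[members] == matched[label_a]).mean()
        else:  # more clusters in a than in b: nothing to match against
            agree = 0.0
        out[label_a] = 100.0 * float(agree)
    return pd.Series(out, name="overlap_pct")


# ---------------------------------------------------------------------------
# sklearn-style estimator
# ---------------------------------------------------------------------------

class DietaryPatternClusterer(BaseEstimator, ClusterMixin):
    """UMAP + K-means dietary-pattern clusterer with automatic k selection.

    A scikit-learn-compatible wrapper over the functional stage:
    ``fit(X)`` embeds the encoded ordinal matrix in 2D, selects the number
    of clusters (unless ``k`` is fixed), and partitions with K-means.

    Parameters mirror :class:`ClusteringConfig`.

    Attributes
    ----------
    embedding_ : ndarray of shape (n, 2)
    labels_ : ndarray of shape (n,)
    k_ : int
    diagnostics_ : SelectionDiagnostics
    """

    def __init__(self, n_neighbors: int = 10, min_dist: float = 0.1,
                 metric: str = "chebyshev", k: int | None = None,
                 k_range: tuple[int, int] = (2, 10),
                 kmeans_n_init: int = 10,
                 kde_bandwidth: float | str = "knn",
                 kde_grid_size: int = 200,
                 kde_peak_threshold: float = 0.05,
                 random_state: int = 0):
        self.n_neighbors = n_neighbors
        self.min_dist = min_dist
        self.metric = metric
        self.k = k
        self.k_range = k_range
        self.kmeans_n_init = kmeans_n_init
        self.kde_bandwidth = kde_bandwidth
        self.kde_grid_size = kde_grid_size
        self.kde_peak_threshold = kde_peak_threshold
        self.random_state = random_state

    def _config(self) -> ClusteringConfig:
        return ClusteringConfig(
            n_neighbors=self.n_neighbors, min_dist=self.min_dist,
            metric=self.metric, seed=self.random_state, k=self.k,
            k_range=self.k_range, kmeans_n_init=self.kmeans_n_init,
            kde_bandwidth=self.kde_bandwidth,
            kde_grid_size=self.kde_grid_size,
            kde_peak_threshold=self.kde_peak_threshold,
        )

    def fit(self, X, y=None):
        config = self._config()
        embedding = embed_umap(X, config)
        diagnostics = select_k(embedding, config)
        k = self.k if self.k is not None else diagnostics.selected_k
        assignment = kmeans_assign(embedding, k, config, diagnostics)
        self.embedding_ = embedding.values
        self.labels_ = assignment.labels.to_numpy()
        self.k_ = k
        self.diagnostics_ = diagnostics
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
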