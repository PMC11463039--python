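"""Weighted similarity network fusion (WSNF) and spectral clustering of samples.

Per-kingdom Bray-Curtis similarity matrices are fused by SNF cross-diffusion;
the kingdoms are weighted by taxonomic richness (number of retained taxa).
Unlike the generic SNF recipe we do not rebuild affinities from Euclidean
distances with a scaled-exponential kernel: the Bray-Curtis similarity is the
affinity. Cluster number comes from the eigengap of the normalized graph
Laplacian; the k-nearest-neighbour size is chosen by silhouette width.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import SpectralClustering
from sklearn.metrics import silhouette_score

from .profiles import AbundanceTable

__all__ = [
    "SimilarityMatrix",
    "FusionConfig",
    "ClusterAssignment",
    "similarity_from_profile",
    "richness_weights",
    "snf_fuse",
    "eigengap_n_clusters",
    "select_k_neighbors",
    "spectral_cluster",
]


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric sample-by-sample similarity with id bookkeeping."""

    matrix: np.ndarray
    sample_ids: list[str]
    kind: str = "bray_curtis_similarity"
    domain: str | None = None

    def __post_init__(self) -> None:
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("similarity matrix must be square")
        if m.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids must match matrix dimension")
        if not np.allclose(m, m.T, atol=1e-9):
            raise ValueError("similarity matrix must be symmetric")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class FusionConfig:
    k_neighbors: int = 20
    iterations: int = 20
    domain_weights: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass(frozen=True)
class ClusterAssignment:
    """Spectral-clustering result; labels are 1-based."""

    labels: np.ndarray
    sample_ids: list[str]
    n_clusters: int
    eigengap_values: np.ndarray | None = None
    silhouette_by_k: dict[int, float] = field(default_factory=dict)


def similarity_from_profile(table: AbundanceTable) -> SimilarityMatrix:
    """1 - Bray-Curtis dissimilarity between sample columns; diagonal 1."""
    if table.mode != "relative":
        raise ValueError("similarity_from_profile requires a relative-mode table")
    if table.n_samples < 2:
        raise ValueError("need at least two samples")
    x = table.values.T  # samples x taxa
    if (x.sum(axis=1) <= 0).any():
        bad = [s for s, tot in zip(table.sample_ids, x.sum(axis=1)) if tot <= 0]
        raise ValueError(f"all-zero sample profile(s): {bad}")
    sim = 1.0 - squareform(pdist(x, metric="braycurtis"))
    np.fill_diagonal(sim, 1.0)
    doms = set(table.domain)
    domain = doms.pop() if len(doms) == 1 else None
    return SimilarityMatrix(sim, table.sample_ids, "bray_curtis_similarity", domain)


def richness_weights(tables: list[AbundanceTable]) -> dict[str, float]:
    """Per-kingdom fusion weights proportional to retained-taxon counts."""
    counts = {}
    for t in tables:
        doms = set(t.domain)
        if len(doms) != 1:
            raise ValueError("each table must hold a single domain")
        counts[doms.pop()] = t.n_taxa
    total = sum(counts.values())
    if total == 0:
        raise ValueError("all tables are empty; weights undefined")
    return {d: c / total for d, c in counts.items()}


def _row_normalize(w: np.ndarray) -> np.ndarray:
    """SNF full-kernel normalization: off-diagonal mass 1/2 per row, diag 1/2."""
    p = np.array(w, dtype=float)
    np.fill_diagonal(p, 0.0)
    rowsum = p.sum(axis=1, keepdims=True)
    rowsum[rowsum == 0] = 1.0
    p = p / (2.0 * rowsum)
    np.fill_diagonal(p, 0.5)
    return p


def _knn_kernel(w: np.ndarray, k: int) -> np.ndarray:
    """Sparse local kernel: keep each row's k strongest neighbours, row-normalize."""
    n = w.shape[0]
    s = np.array(w, dtype=float)
    np.fill_diagonal(s, -np.inf)
    keep = np.zeros_like(s, dtype=bool)
    idx = np.argpartition(-s, kth=k - 1, axis=1)[:, :k]
    rows = np.repeat(np.arange(n), k)
    keep[rows, idx.ravel()] = True
    s = np.where(keep, w, 0.0)
    rowsum = s.sum(axis=1, keepdims=True)
    rowsum[rowsum == 0] = 1.0
    return s / rowsum


def snf_fuse(
    similarities: list[SimilarityMatrix], config: FusionConfig
) -> SimilarityMatrix:
    """Fuse per-kingdom similarities by weighted SNF cross-diffusion.

    Each kingdom's status matrix is diffused through its k-NN kernel against
    the richness-weighted average of the other kingdoms' matrices, then the
    fused result is the richness-weighted average of the final status
    matrices, symmetrized. A single input is returned unchanged.
    """
    if not similarities:
        raise ValueError("need at least one similarity matrix")
    ref = similarities[0]
    for s in similarities[1:]:
        if s.sample_ids != ref.sample_ids:
            raise ValueError("sample sets/order differ across similarity matrices")

    if config.domain_weights is None:
        weights = np.full(len(similarities), 1.0 / len(similarities))
    else:
        weights = np.array(
            [config.domain_weights[s.domain] for s in similarities], dtype=float
        )
        if (weights < 0).any() or weights.sum() <= 0:
            raise ValueError("domain weights must be nonnegative and not all zero")
        weights = weights / weights.sum()
    # zero-weight kingdoms contribute nothing to the fusion; drop them up front
    active = weights > 0
    similarities = [s for s, a in zip(similarities, active) if a]
    weights = weights[active]

    if len(similarities) == 1:
        return SimilarityMatrix(similarities[0].matrix.copy(), ref.sample_ids, "fused")
    n = ref.n
    if config.k_neighbors >= n:
        raise ValueError(f"k_neighbors ({config.k_neighbors}) must be < n ({n})")

    status = [_row_normalize(s.matrix) for s in similarities]
    status = [(p + p.T) / 2.0 for p in status]
    kernels = [_knn_kernel(s.matrix, config.k_neighbors) for s in similarities]

    for _ in range(config.iterations):
        updated = []
        for d, (s_d, p_d) in enumerate(zip(kernels, status)):
            other_w = np.array([w for e, w in enumerate(weights) if e != d])
            other_w = other_w / other_w.sum()
            mean_other = sum(
                w * status[e]
                for w, e in zip(other_w, [e for e in range(len(status)) if e != d])
            )
            p_new = s_d @ mean_other @ s_d.T
            p_new = _row_normalize(p_new)
            updated.append((p_new + p_new.T) / 2.0)
        status = updated

    fused = sum(w * p for w, p in zip(weights, status))
    fused = (fused + fused.T) / 2.0
    return SimilarityMatrix(fused, ref.sample_ids, "fused")


def _normalized_laplacian_eigs(matrix: np.ndarray) -> np.ndarray:
    w = np.maximum(matrix, 0.0)
    d = w.sum(axis=1)
    d_inv_sqrt = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 0.0)
    lap = np.eye(w.shape[0]) - (d_inv_sqrt[:, None] * w) * d_inv_sqrt[None, :]
    return np.sort(np.linalg.eigvalsh(lap))


def eigengap_n_clusters(fused: SimilarityMatrix, k_max: int = 10) -> int:
    """Cluster count = argmax over k in [2, k_max] of the Laplacian eigengap."""
    n = fused.n
    if not 2 <= k_max < n:
        raise ValueError("need 2 <= k_max < n")
    eigs = _normalized_laplacian_eigs(fused.matrix)
    gaps = eigs[2 : k_max + 1] - eigs[1:k_max]  # gap after k-th smallest, k=2..k_max
    if np.allclose(gaps, 0.0, atol=1e-12):
        warnings.warn(
            "degenerate spectrum (no eigengap); returning k_max", stacklevel=2
        )
        return k_max
    return int(np.argmax(gaps)) + 2


def spectral_cluster(
    fused: SimilarityMatrix, n_clusters: int, seed: int = 0
) -> ClusterAssignment:
    """Normalized spectral clustering on the fused similarity (1-based labels)."""
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    if n_clusters > fused.n:
        raise ValueError("n_clusters cannot exceed the number of samples")
    if n_clusters == fused.n:
        labels = np.arange(1, fused.n + 1)
        return ClusterAssignment(labels, fused.sample_ids, n_clusters)
    model = SpectralClustering(
        n_clusters=n_clusters,
        affinity="precomputed",
        assign_labels="kmeans",
        random_state=seed,
        n_init=10,
    )
    labels = model.fit_predict(np.maximum(fused.matrix, 0.0)) + 1
    return ClusterAssignment(labels, fused.sample_ids, n_clusters)


def _silhouette_distance(fused: SimilarityMatrix) -> np.ndarray:
    """Distance for silhouette: 1 - similarity rescaled to unit off-diag max."""
    m = fused.matrix.copy()
    np.fill_diagonal(m, 0.0)
    top = m.max()
    if top <= 0:
        top = 1.0
    d = 1.0 - m / top
    np.fill_diagonal(d, 0.0)
    return np.maximum(d, 0.0)


def select_k_neighbors(
    similarities: list[SimilarityMatrix],
    k_grid: list[int],
    config: FusionConfig | None = None,
    k_max_clusters: int = 10,
    seed: int = 0,
) -> tuple[int, dict[int, float]]:
    """Pick the k-NN size maximizing mean silhouette width of the clustering.

    For each candidate k: fuse, choose the cluster count by eigengap, cluster
    spectrally, and score silhouette on the (1 - fused similarity) distance.
    Ties go to the smallest k. Returns (best_k, silhouette_by_k).
    """
    if not k_grid:
        raise ValueError("k_grid must be non-empty")
    config = config or FusionConfig()
    scores: dict[int, float] = {}
    for k in sorted(k_grid):
        cfg = FusionConfig(
            k_neighbors=k,
            iterations=config.iterations,
            domain_weights=config.domain_weights,
        )
        fused = snf_fuse(similarities, cfg)
        n_clusters = eigengap_n_clusters(fused, k_max=min(k_max_clusters, fused.n - 1))
        assign = spectral_cluster(fused, n_clusters, seed=seed)
        scores[k] = float(
            silhouette_score(
                _silhouette_distance(fused), assign.labels, metric="precomputed"
            )
        )
    best = max(sorted(scores), key=lambda k: scores[k])  # ties -> smallest k
    return best, scores
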