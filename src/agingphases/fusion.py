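"""Similarity network fusion (SNF) and spectral clustering of subjects.

Each omics layer is turned into a subjects × subjects Euclidean
distance matrix, converted to a scaled-exponential affinity kernel, and
the per-layer affinities are fused by cross-diffusion: each view's full
"status" matrix is repeatedly propagated through its own k-nearest-
neighbour "local" matrix while being averaged against the other views,
which strengthens edges supported by several data views.  The number
of clusters is chosen with the eigen-gap statistic of the normalized
graph Laplacian (rotation cost reported as tie-breaker) and subjects
are clustered with normalized-Laplacian spectral clustering.

Conventions (diagonal 1/2 status normalization, eta = 1/n diagonal
regularization, 1e-12 kernel floor) follow the original fusion method's
reference implementation; only k, t and alpha are exposed as the
parameters of record.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from .io import OmicsMatrix

logger = logging.getLogger("agingphases")

_EPS_FLOOR = 1e-12


@dataclass
class SNFParams:
    """Fusion hyperparameters: k nearest neighbours, t diffusion
    iterations, and the kernel width multiplier alpha (mu)."""

    k: int = 10
    t: int = 20
    alpha: float = 0.5

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.t < 0:
            raise ValueError("t must be >= 0")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")


@dataclass
class SimilarityNetwork:
    """A subjects × subjects network (distance, affinity, or fused)."""

    matrix: np.ndarray
    subject_ids: list[str]
    role: str  # distance | affinity | status | local | fused

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("network matrix must be square")
        if m.shape[0] != len(self.subject_ids):
            raise ValueError("subject id count does not match matrix size")
        self.matrix = m

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.subject_ids,
                            columns=self.subject_ids)


@dataclass
class ClusterSelection:
    """Eigen-gap / rotation-cost table over a candidate K range."""

    table: pd.DataFrame  # columns: k, eigengap, rotation_cost
    best_k: int


def pairwise_distance(matrix: OmicsMatrix, standardize: bool = True) -> SimilarityNetwork:
    """Euclidean distance between subject profiles.

    With ``standardize`` each feature is scaled to mean 0, SD 1 across
    subjects first; zero-variance features are dropped with a warning.
    """
    if matrix.n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    vals = matrix.values.to_numpy(float)
    if standardize:
        mu = vals.mean(axis=1, keepdims=True)
        sd = vals.std(axis=1, keepdims=True)
        flat = (sd == 0).ravel()
        if flat.any():
            warnings.warn(f"dropping {int(flat.sum())} zero-variance feature(s) "
                          "before distance computation")
            vals, mu, sd = vals[~flat], mu[~flat], sd[~flat]
        vals = (vals - mu) / sd
    dist = squareform(pdist(vals.T, metric="euclidean"))
    return SimilarityNetwork(dist, matrix.subject_ids, role="distance")


def affinity_matrix(dist: SimilarityNetwork, params: SNFParams | None = None) -> SimilarityNetwork:
    """Scaled-exponential affinity kernel.

    ``W(i,j) = exp(-d(i,j)^2 / (alpha * eps(i,j)))`` where
    ``eps(i,j) = (mean kNN-dist of i + mean kNN-dist of j + d(i,j)) / 3``,
    floored at a small positive constant so the kernel is defined even
    for all-zero distances.
    """
    params = params or SNFParams()
    d = dist.matrix
    n = d.shape[0]
    if params.k >= n:
        raise ValueError("k must be smaller than the number of subjects")
    # mean distance to the k nearest other subjects
    sorted_d = np.sort(d + np.diag(np.full(n, np.inf)), axis=1)
    knn_mean = sorted_d[:, :params.k].mean(axis=1)
    eps = (knn_mean[:, None] + knn_mean[None, :] + d) / 3.0
    eps = np.maximum(eps, _EPS_FLOOR)
    w = np.exp(-(d ** 2) / (params.alpha * eps))
    w = (w + w.T) / 2.0
    return SimilarityNetwork(w, dist.subject_ids, role="affinity")


def _status_matrix(w: np.ndarray) -> np.ndarray:
    """Full-kernel status matrix P: off-diagonal rows sum to 1/2,
    diagonal entries are 1/2 (so every row sums to 1)."""
    p = w.copy().astype(float)
    np.fill_diagonal(p, 0.0)
    rs = p.sum(axis=1)
    rs[rs == 0] = 1.0
    p = p / (2.0 * rs[:, None])
    np.fill_diagonal(p, 0.5)
    return p


def _local_matrix(w: np.ndarray, k: int) -> np.ndarray:
    """k-NN-masked row-stochastic local matrix S (self excluded from
    the neighbourhood)."""
    n = w.shape[0]
    masked = w.copy().astype(float)
    np.fill_diagonal(masked, -np.inf)
    idx = np.argsort(masked, axis=1)[:, ::-1][:, :k]
    s = np.zeros_like(w, dtype=float)
    rows = np.repeat(np.arange(n), k)
    s[rows, idx.ravel()] = w[rows, idx.ravel()]
    rs = s.sum(axis=1)
    rs[rs == 0] = 1.0
    return s / rs[:, None]


def snf_fuse(affinities: list[SimilarityNetwork], params: SNFParams | None = None,
             record_history: bool = False) -> SimilarityNetwork:
    """Fuse affinity networks by iterative cross-diffusion.

    For each view v: ``P_v <- S_v · mean(P_other) · S_v^T``, followed by
    symmetrization with an ``I/n`` diagonal regularizer and re-(half-)
    normalization, for t iterations; the output is the symmetrized
    view average.  With ``t = 0`` the result is exactly the average of
    the initial status matrices.

    When ``record_history`` is set, every intermediate status matrix is
    kept on the returned network as ``.history`` (list of per-iteration
    lists) for diagnostics.
    """
    params = params or SNFParams()
    if not affinities:
        raise ValueError("need at least one affinity network")
    ids = affinities[0].subject_ids
    for a in affinities[1:]:
        if a.subject_ids != ids:
            raise ValueError("affinity networks must share an identical subject set")
    n = len(ids)
    eta = 1.0 / n

    ps = [_status_matrix(a.matrix) for a in affinities]
    ss = [_local_matrix(a.matrix, params.k) for a in affinities]
    m = len(ps)
    history: list[list[np.ndarray]] = [[p.copy() for p in ps]] if record_history else []

    for _ in range(params.t):
        new_ps = []
        for v in range(m):
            if m > 1:
                other = sum(ps[u] for u in range(m) if u != v) / (m - 1)
            else:
                other = ps[0]
            q = ss[v] @ other @ ss[v].T
            q = (q + q.T) / 2.0 + eta * np.eye(n)
            new_ps.append(_status_matrix(q))
        ps = new_ps
        if record_history:
            history.append([p.copy() for p in ps])

    fused = sum(ps) / m
    if params.t > 0:
        fused = _status_matrix(fused)
        fused = (fused + fused.T) / 2.0
    network = SimilarityNetwork(fused, ids, role="fused")
    if record_history:
        network.history = history  # type: ignore[attr-defined]
    return network


def _normalized_laplacian(w: np.ndarray) -> np.ndarray:
    a = w.copy().astype(float)
    np.fill_diagonal(a, 0.0)
    a = np.maximum((a + a.T) / 2.0, 0.0)
    deg = a.sum(axis=1)
    deg[deg == 0] = np.finfo(float).eps
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    lap = -a * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]
    np.fill_diagonal(lap, 1.0)
    return (lap + lap.T) / 2.0


def spectral_cluster(fused: SimilarityNetwork, n_clusters: int,
                     seed: int = 0, n_init: int = 50) -> pd.Series:
    """Normalized-Laplacian spectral clustering of the fused network.

    Takes the eigenvectors of the K smallest Laplacian eigenvalues,
    row-normalizes them, and runs k-means with ``n_init`` restarts and
    a fixed seed.  Returns raw labels 0..K-1 indexed by subject id.
    """
    n = fused.n
    if not 2 <= n_clusters < n:
        raise ValueError("need 2 <= n_clusters < n_subjects")
    lap = _normalized_laplacian(fused.matrix)
    vals, vecs = eigh(lap)
    n_components = int(np.sum(vals < 1e-10))
    if n_components > n_clusters:
        warnings.warn(f"graph has {n_components} connected components but "
                      f"{n_clusters} clusters requested")
    u = vecs[:, :n_clusters]
    norms = np.linalg.norm(u, axis=1)
    norms[norms == 0] = 1.0
    u = u / norms[:, None]
    km = KMeans(n_clusters=n_clusters, n_init=n_init, random_state=seed)
    labels = km.fit_predict(u)
    return pd.Series(labels, index=fused.subject_ids, name="cluster")


def _rotation_cost(vecs: np.ndarray, k: int) -> float:
    """Alignment cost of the first k Laplacian eigenvectors.

    Rows of the row-normalized eigenvector matrix are compared to the
    ideal one-indicator-per-row structure; cost 1 means perfectly
    cluster-aligned rows, larger means diffuse.  Evaluated at the
    identity rotation (no Givens search), which is sufficient for its
    role as a reported tie-breaker.
    """
    u = vecs[:, :k]
    norms = np.linalg.norm(u, axis=1)
    norms[norms == 0] = 1.0
    u = u / norms[:, None]
    row_max = np.max(u ** 2, axis=1)
    row_max[row_max == 0] = 1.0
    return float(np.mean(1.0 / row_max))


def select_cluster_number(fused: SimilarityNetwork,
                          k_range: tuple[int, int] = (2, 8),
                          ) -> ClusterSelection:
    """Choose the number of clusters by the eigen-gap statistic.

    ``eigengap(K) = lambda_{K+1} - lambda_K`` of the normalized
    Laplacian spectrum (ascending); the chosen K maximizes the gap over
    the candidate range, with smaller rotation cost breaking ties.
    """
    lo, hi = k_range
    n = fused.n
    if not (2 <= lo <= hi <= n - 1):
        raise ValueError("k_range must lie within [2, n_subjects - 1]")
    lap = _normalized_laplacian(fused.matrix)
    vals, vecs = eigh(lap)
    rows = []
    for k in range(lo, hi + 1):
        gap = float(vals[k] - vals[k - 1])
        rows.append({"k": k, "eigengap": gap,
                     "rotation_cost": _rotation_cost(vecs, k)})
    table = pd.DataFrame(rows)
    best = table.sort_values(["eigengap", "rotation_cost", "k"],
                             ascending=[False, True, True]).iloc[0]
    return ClusterSelection(table=table, best_k=int(best["k"]))
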