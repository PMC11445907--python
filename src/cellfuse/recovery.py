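"""Discriminative dropout recovery via confidence-masked, graph-regularized NMF.

The recovery pipeline for one modality X (N cells x D features):

1.  *Recovery confidence.*  For gene j within cluster k, with zero rate
    a, mean expression b and (population) variance v2 over the cluster's
    cells,

        c = (1 - a) * b / ((1 - a) * b + a * v2),

    broadcast to every cell of the cluster.  High c means a zero is
    likely a technical dropout worth imputing.

2.  *Guidance matrix.*  G_ij = 1 for observed entries (X_ij > 0) and for
    zeros whose confidence falls below the threshold T (trusted
    biological zeros); G_ij = 0 marks the entries to recover.

3.  *Adaptive similarity.*  Each cell receives a probability
    distribution over its k nearest neighbours (closed-form simplex
    solution of the probabilistic-neighbours objective), giving a
    cell-cell similarity S, degrees D and normalized Laplacian
    L = I - D^{-1/2} S D^{-1/2}.

4.  *Masked NMF.*  Minimize

        ||G o (X - P Q^T)||_F^2 + l1 (||P||_F^2 + ||Q||_F^2)
                                + l2 Tr(P^T L P)

    by multiplicative updates that keep P, Q non-negative; the
    similarity is optionally re-estimated from the current P on a fixed
    schedule, coupling the neighbour graph to the evolving cell factors.

5.  *Recovery.*  X_tilde = (1 - G) o (P Q^T) + X: only entries flagged
    for recovery change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans

from .io import MultiModalDataset

__all__ = [
    "GuidanceArtifacts",
    "SimilarityGraph",
    "FactorizationState",
    "initial_clusters",
    "recovery_confidence",
    "guidance_matrix",
    "adaptive_similarity",
    "fit_masked_nmf",
    "recover_matrix",
    "missing_rate",
    "DropoutRecovery",
]

_EPS = 1e-10


@dataclass
class GuidanceArtifacts:
    """Confidence matrix, guidance mask and the per-cluster statistics behind them."""

    confidence: np.ndarray  # N x D, entries in [0, 1]
    guidance: np.ndarray  # N x D binary; 0 = recover this entry
    threshold: float
    cluster_labels: np.ndarray
    zero_rate: np.ndarray  # K x D  (a)
    mean_expression: np.ndarray  # K x D  (b)
    variance: np.ndarray  # K x D  (v2)


@dataclass
class SimilarityGraph:
    """Symmetrized neighbour similarity with degrees and normalized Laplacian."""

    S: np.ndarray  # symmetrized similarity, zero diagonal
    degrees: np.ndarray  # row sums of S
    laplacian: np.ndarray  # I - D^{-1/2} S D^{-1/2}
    row_stochastic: np.ndarray  # pre-symmetrization rows (each sums to 1)

    @property
    def normalized_affinity(self) -> np.ndarray:
        d = 1.0 / np.sqrt(np.maximum(self.degrees, _EPS))
        return d[:, None] * self.S * d[None, :]


@dataclass
class FactorizationState:
    """Fitted masked-NMF state for one modality."""

    P: np.ndarray  # N x r cell factors
    Q: np.ndarray  # D x r feature factors
    graph: SimilarityGraph
    rank: int
    lambda1: float
    lambda2: float
    objective_trace: list = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False


def initial_clusters(dataset: MultiModalDataset, n_clusters: int, seed: int) -> np.ndarray:
    """Seed clustering for the confidence statistics.

    K-means on the per-feature standardized concatenation of all
    modalities; deterministic given the seed, every cluster non-empty.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be positive")
    if n_clusters > dataset.n_cells:
        raise ValueError("n_clusters cannot exceed the number of cells")
    X = np.hstack(dataset.matrices())
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd < 1e-12] = 1.0
    Xs = (X - mu) / sd
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=int(seed))
    return km.fit_predict(Xs)


def recovery_confidence(X: np.ndarray, labels: np.ndarray) -> GuidanceArtifacts:
    """Per-entry recovery confidence from per-cluster gene statistics.

    A gene silent in an entire cluster (a=1, b=0, v2=0) gets confidence
    0: uniform silence is treated as biological, never recovered.
    Returns artifacts without a guidance matrix (threshold NaN) —
    combine with :func:`guidance_matrix`.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (X.shape[0],):
        raise ValueError("labels must have one entry per cell")
    ks = np.unique(labels)
    K = int(ks.max()) + 1
    D = X.shape[1]
    a = np.zeros((K, D))
    b = np.zeros((K, D))
    v2 = np.zeros((K, D))
    c = np.zeros((K, D))
    for k in range(K):
        members = labels == k
        if not members.any():
            raise ValueError(f"cluster {k} is empty")
        sub = X[members]
        a[k] = (sub == 0).mean(axis=0)
        b[k] = sub.mean(axis=0)
        v2[k] = sub.var(axis=0)  # population (1/n) variance over all cells
        num = (1.0 - a[k]) * b[k]
        den = num + a[k] * v2[k]
        nz = den > 0
        c[k, nz] = num[nz] / den[nz]  # den == 0 leaves c = 0 (trusted zero)
    confidence = c[labels]
    return GuidanceArtifacts(
        confidence=confidence,
        guidance=np.ones_like(confidence, dtype=int),
        threshold=float("nan"),
        cluster_labels=labels,
        zero_rate=a,
        mean_expression=b,
        variance=v2,
    )


def guidance_matrix(X: np.ndarray, confidence: np.ndarray, threshold: float) -> np.ndarray:
    """Binary guidance mask: 1 = trust the entry, 0 = recover it.

    Observed entries (X > 0) are always trusted; zeros are trusted only
    when their confidence falls below the threshold.
    """
    X = np.asarray(X, dtype=float)
    confidence = np.asarray(confidence, dtype=float)
    if X.shape != confidence.shape:
        raise ValueError(f"shape mismatch: X {X.shape} vs confidence {confidence.shape}")
    G = np.where((X > 0) | (confidence < threshold), 1, 0)
    return G


def adaptive_similarity(P: np.ndarray, k_neighbors: int) -> SimilarityGraph:
    """Probabilistic-neighbour similarity from cell factor rows.

    Each row of the pre-symmetrization matrix is the closed-form simplex
    solution supported on the k nearest neighbours (squared Euclidean
    distances d_(1) <= ... ):

        s_(j) = (d_(k+1) - d_(j)) / (k d_(k+1) - sum_{l<=k} d_(l)),

    uniform 1/k over the neighbours when the denominator degenerates
    (all k+1 nearest distances equal).  Ties broken by index.
    """
    P = np.asarray(P, dtype=float)
    n = P.shape[0]
    if k_neighbors >= n:
        raise ValueError("k_neighbors must be smaller than the number of cells")
    k = k_neighbors
    d2 = cdist(P, P, metric="sqeuclidean")
    np.fill_diagonal(d2, np.inf)
    order = np.argsort(d2, axis=1, kind="stable")
    W = np.zeros((n, n))
    rows = np.arange(n)
    nbrs = order[:, :k]  # k nearest
    d_near = np.take_along_axis(d2, nbrs, axis=1)
    if k < n - 1:
        d_top = np.take_along_axis(d2, order[:, k : k + 1], axis=1)
    else:
        d_top = d_near[:, -1:]
    denom = k * d_top[:, 0] - d_near.sum(axis=1)
    w = np.empty_like(d_near)
    good = denom > 1e-12
    w[good] = np.clip(d_top[good] - d_near[good], 0.0, None) / denom[good, None]
    w[~good] = 1.0 / k
    # numerical safety: renormalize rows to exactly 1
    w /= w.sum(axis=1, keepdims=True)
    W[rows[:, None], nbrs] = w
    S = 0.5 * (W + W.T)
    degrees = S.sum(axis=1)
    dinv = 1.0 / np.sqrt(np.maximum(degrees, _EPS))
    L = np.eye(n) - dinv[:, None] * S * dinv[None, :]
    return SimilarityGraph(S=S, degrees=degrees, laplacian=L, row_stochastic=W)


def masked_nmf_objective(
    X: np.ndarray,
    G: np.ndarray,
    P: np.ndarray,
    Q: np.ndarray,
    lambda1: float,
    lambda2: float,
    L: np.ndarray,
) -> float:
    """The full recovery objective for the current factors."""
    R = G * (X - P @ Q.T)
    obj = float(np.sum(R * R))
    obj += lambda1 * (float(np.sum(P * P)) + float(np.sum(Q * Q)))
    obj += lambda2 * float(np.trace(P.T @ L @ P))
    return obj


def fit_masked_nmf(
    X: np.ndarray,
    G: np.ndarray,
    S: SimilarityGraph,
    rank: int,
    lambda1: float = 0.1,
    lambda2: float = 0.1,
    max_iter: int = 500,
    tol: float = 1e-4,
    sim_update_every: Optional[int] = 10,
    k_neighbors: int = 15,
    seed: int = 0,
) -> FactorizationState:
    """Alternating multiplicative updates for the masked, graph-regularized NMF.

    Updates (eps added to denominators)::

        P <- P o [(G o X) Q + l2 A P] / [(G o (P Q^T)) Q + l1 P + l2 P]
        Q <- Q o [(G o X)^T P]        / [(G o (P Q^T))^T P + l1 Q]

    where A = D^{-1/2} S D^{-1/2}.  Both iterates stay entrywise
    non-negative and the objective is non-increasing between similarity
    refreshes.  When ``sim_update_every`` is set, the neighbour graph is
    re-estimated from the current P every that many iterations.
    Stops when the relative objective change drops below ``tol``.
    """
    X = np.asarray(X, dtype=float)
    G = np.asarray(G, dtype=float)
    if X.shape != G.shape:
        raise ValueError("X and G must have the same shape")
    if not np.any(X > 0):
        raise ValueError("cannot factorize an all-zero matrix")
    n, d = X.shape
    if rank > min(n, d):
        raise ValueError(f"rank {rank} exceeds min(N, D) = {min(n, d)}")

    rng = np.random.default_rng(seed)
    scale = np.sqrt(X.mean() / rank)
    P = rng.uniform(0.0, 1.0, size=(n, rank)) * scale
    Q = rng.uniform(0.0, 1.0, size=(d, rank)) * scale

    GX = G * X
    graph = S
    A = graph.normalized_affinity
    L = graph.laplacian
    trace = []
    prev = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if sim_update_every and it > 1 and (it - 1) % sim_update_every == 0:
            graph = adaptive_similarity(P, k_neighbors)
            A = graph.normalized_affinity
            L = graph.laplacian
            prev = None  # objective basis changed with the new Laplacian
        PQt = P @ Q.T
        num_p = GX @ Q + lambda2 * (A @ P)
        den_p = (G * PQt) @ Q + lambda1 * P + lambda2 * P + _EPS
        P = P * (num_p / den_p)
        PQt = P @ Q.T
        num_q = GX.T @ P
        den_q = (G * PQt).T @ P + lambda1 * Q + _EPS
        Q = Q * (num_q / den_q)
        if not (np.all(np.isfinite(P)) and np.all(np.isfinite(Q))):
            raise FloatingPointError(f"non-finite NMF iterate at iteration {it}")
        obj = masked_nmf_objective(X, G, P, Q, lambda1, lambda2, L)
        trace.append(obj)
        if prev is not None and abs(prev - obj) < tol * (1.0 + abs(prev)):
            converged = True
            break
        prev = obj
    return FactorizationState(
        P=P,
        Q=Q,
        graph=graph,
        rank=rank,
        lambda1=lambda1,
        lambda2=lambda2,
        objective_trace=trace,
        n_iter=it,
        converged=converged,
    )


def recover_matrix(X: np.ndarray, G: np.ndarray, P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Impute the flagged entries: X_tilde = (1 - G) o (P Q^T) + X."""
    X = np.asarray(X, dtype=float)
    G = np.asarray(G, dtype=float)
    if X.shape != G.shape:
        raise ValueError("X and G must have the same shape")
    low = P @ Q.T
    if low.shape != X.shape:
        raise ValueError("P Q^T shape does not match X")
    return (1.0 - G) * low + X


def missing_rate(X: np.ndarray) -> float:
    """Fraction of zero entries — the missing-value rate statistic."""
    X = np.asarray(X)
    if X.size == 0:
        raise ValueError("empty matrix")
    return float(np.mean(X == 0))


class DropoutRecovery(BaseEstimator, TransformerMixin):
    """Confidence-masked graph-regularized NMF imputation for one modality.

    Transductive: :meth:`fit` consumes a single cells x features matrix
    together with cluster labels (pass via ``y``; required for the
    confidence statistics) and :meth:`fit_transform` returns the
    recovered matrix.  Fitted attributes carry the guidance artifacts
    and factorization state.

    Parameters
    ----------
    threshold : float, default 0.1
        Recovery-confidence threshold T; zeros with confidence >= T are
        imputed.  Larger T recovers fewer entries.
    rank : int, default 50
        NMF rank, capped at min(N, D) - 1.
    lambda1, lambda2 : float, default 0.1
        Ridge and Laplacian-smoothness weights.
    k_neighbors : int, default 15
        Neighbourhood size of the adaptive similarity.
    sim_update_every : int or None, default 10
        Re-estimate the similarity from the current cell factors every
        this many NMF iterations (None: keep the initial graph).
    """

    def __init__(
        self,
        threshold: float = 0.1,
        rank: int = 50,
        lambda1: float = 0.1,
        lambda2: float = 0.1,
        k_neighbors: int = 15,
        max_iter: int = 500,
        tol: float = 1e-4,
        sim_update_every: Optional[int] = 10,
        random_state: int = 0,
    ):
        self.threshold = threshold
        self.rank = rank
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.k_neighbors = k_neighbors
        self.max_iter = max_iter
        self.tol = tol
        self.sim_update_every = sim_update_every
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if y is None:
            raise ValueError(
                "DropoutRecovery needs cluster labels in y (see initial_clusters)"
            )
        labels = np.asarray(y, dtype=int)
        n, d = X.shape
        art = recovery_confidence(X, labels)
        G = guidance_matrix(X, art.confidence, self.threshold)
        art.guidance = G
        art.threshold = float(self.threshold)
        k = min(self.k_neighbors, n - 1)
        rank = min(self.rank, min(n, d) - 1)
        graph0 = adaptive_similarity(X, k)  # initial graph from the observed data
        state = fit_masked_nmf(
            X,
            G,
            graph0,
            rank=rank,
            lambda1=self.lambda1,
            lambda2=self.lambda2,
            max_iter=self.max_iter,
            tol=self.tol,
            sim_update_every=self.sim_update_every,
            k_neighbors=k,
            seed=self.random_state,
        )
        self.artifacts_ = art
        self.guidance_ = G
        self.confidence_ = art.confidence
        self.state_ = state
        self.recovered_ = recover_matrix(X, G, state.P, state.Q)
        self.missing_rate_before_ = missing_rate(X)
        self.missing_rate_after_ = missing_rate(self.recovered_)
        return self

    def transform(self, X=None):
        """Return the recovered matrix of the fitted input (transductive)."""
        if not hasattr(self, "recovered_"):
            raise RuntimeError("DropoutRecovery is not fitted")
        return self.recovered_

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, y).recovered_
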