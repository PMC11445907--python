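"""Losses and the pretrain -> joint-train loop of the fusion model.

Training runs full batch with Adam (learning rate 5e-4, gradient norm
clipped at 5).  The pretraining phase fits the per-view autoencoders on
the reconstruction loss alone; the joint phase then optimizes

    L = L_r + lambda * L_c

over encoders, decoders and attention parameters, where L_r is the sum
of squared reconstruction errors over all views and L_c the
structure-guided contrastive loss: positives are (consensus, view)
pairs of the same cell, negatives are other cells down-weighted by the
global structural affinity (1 - S_ij),

    L_c = -(1/(M N)) sum_i sum_m log
          e^{D(H_hat_i, H^m_i)/tau} / sum_{j != i} e^{(1 - S_ij) D(H_hat_i, H^m_j)/tau}

with D the cosine similarity and tau the temperature.  The denominator
above is the default ``self_exclude`` reading of the loss; the
``literal`` variant instead sums over all j and subtracts e^{1/tau}.
Either way the denominator is clamped below at 1e-12.  The prefactor
generalizes the two-view 1/(2N) to M views.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from . import _autodiff as ad
from ._autodiff import Adam, Tensor
from .fusion import AttentionAggregator, ViewAutoencoder

__all__ = [
    "LossWeights",
    "TrainingState",
    "ClusteringResult",
    "reconstruction_loss",
    "cosine_similarity",
    "contrastive_loss",
    "total_loss",
    "assign_clusters",
    "ConsensusFusionClusterer",
]

_DENOM_FLOOR = 1e-12


@dataclass
class LossWeights:
    temperature: float = 0.5
    balance: float = 1.0

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.balance < 0:
            raise ValueError("balance must be non-negative")


@dataclass
class TrainingState:
    epochs_pretrain: int
    epochs_train: int
    learning_rate: float
    seed: int
    history: dict = field(default_factory=dict)


@dataclass
class ClusteringResult:
    labels: np.ndarray
    n_clusters: int
    embedding: np.ndarray
    metrics: Optional[dict] = None


# ---------------------------------------------------------------------------
# losses


def _row_normalize(H: Tensor) -> Tensor:
    norm = ad.sqrt((H * H).sum(axis=1, keepdims=True) + 1e-24)
    return H / norm


def _reconstruction_loss_t(X_views: Sequence[Tensor], Xhat_views: Sequence[Tensor]) -> Tensor:
    total = None
    for X, Xhat in zip(X_views, Xhat_views):
        diff = X - Xhat
        term = (diff * diff).sum()
        total = term if total is None else total + term
    return total


def reconstruction_loss(X_views, decoders, Z_views) -> float:
    """Sum of squared errors sum_m ||X^m - g^m(Z^m)||^2 (no averaging)."""
    total = 0.0
    for X, dec, Z in zip(X_views, decoders, Z_views):
        Xhat = dec.decode(Tensor(np.asarray(Z, dtype=float))).data
        total += float(np.sum((np.asarray(X, dtype=float) - Xhat) ** 2))
    return total


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """u.v / (|u||v|); defined as 0 with a warning for a zero vector."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        warnings.warn("cosine similarity of a zero vector defined as 0", RuntimeWarning)
        return 0.0
    return float(u @ v / (nu * nv))


def _contrastive_loss_t(
    H_hat: Tensor,
    H_views: Sequence[Tensor],
    S: Tensor,
    temperature: float,
    mode: str = "self_exclude",
) -> Tensor:
    n = H_hat.shape[0]
    m_views = len(H_views)
    inv_t = 1.0 / temperature
    Hn = _row_normalize(H_hat)
    off_diag = 1.0 - np.eye(n)
    total = None
    for Hm in H_views:
        Hmn = _row_normalize(Hm)
        Dm = Hn @ Hmn.T  # N x N cosine similarities
        pos = (Hn * Hmn).sum(axis=1)  # D(H_hat_i, H^m_i)
        E = ad.exp((1.0 - S) * Dm * inv_t)
        if mode == "self_exclude":
            denom = (E * off_diag).sum(axis=1)
        elif mode == "literal":
            denom = E.sum(axis=1) - float(np.exp(inv_t))
        else:
            raise ValueError(f"unknown contrastive mode {mode!r}")
        denom = ad.clamp_min(denom, _DENOM_FLOOR)
        term = pos * inv_t - ad.log(denom)
        total = term.sum() if total is None else total + term.sum()
    return total * (-1.0 / (m_views * n))


def contrastive_loss(
    H_hat: np.ndarray,
    H_views: Sequence[np.ndarray],
    S: np.ndarray,
    temperature: float = 0.5,
    mode: str = "self_exclude",
) -> float:
    """Structure-guided contrastive loss (functional, no gradients)."""
    S = np.asarray(S, dtype=float)
    rs = S.sum(axis=1)
    if not np.allclose(rs, 1.0, atol=1e-6):
        raise ValueError("S must be row-stochastic")
    t = _contrastive_loss_t(
        Tensor(np.asarray(H_hat, dtype=float)),
        [Tensor(np.asarray(H, dtype=float)) for H in H_views],
        Tensor(S),
        temperature,
        mode,
    )
    return t.item()


def total_loss(recon: float, contrast: float, balance: float) -> float:
    """L = L_r + lambda * L_c."""
    return recon + balance * contrast


def assign_clusters(H: np.ndarray, n_clusters: int, seed: int) -> ClusteringResult:
    """K-means (20 restarts, seeded) on the consensus embedding rows."""
    H = np.asarray(H, dtype=float)
    if n_clusters < 1:
        raise ValueError("n_clusters must be positive")
    if n_clusters > H.shape[0]:
        raise ValueError("n_clusters cannot exceed the number of cells")
    km = KMeans(n_clusters=n_clusters, n_init=20, random_state=int(seed))
    labels = km.fit_predict(H)
    return ClusteringResult(labels=labels, n_clusters=n_clusters, embedding=H)


# ---------------------------------------------------------------------------
# trainer


class ConsensusFusionClusterer(BaseEstimator, ClusterMixin):
    """Attention-fused deep clustering of recovered multi-modal matrices.

    ``fit`` takes a list of cells x features arrays (one per view),
    pretrains the autoencoders on reconstruction, jointly optimizes
    reconstruction plus the structure-guided contrastive loss, and
    k-means-partitions the consensus embedding.

    Parameters
    ----------
    n_clusters : int
        Number of clusters K.
    encoder_dims : sequence of int, default (512, 64)
        Hidden widths and bottleneck of every view autoencoder.
    epochs_pretrain, epochs_train : int, default 200, 200
        Full-batch epochs of the two phases.
    learning_rate : float, default 5e-4
    temperature : float, default 0.5
        Contrastive temperature tau.
    balance : float, default 1.0
        Weight lambda of the contrastive loss; 0 disables it.
    use_attention : bool, default True
        False replaces attention aggregation by the plain mean of view
        bottlenecks with a uniform structure matrix (ablation arm).
    contrastive_mode : {"self_exclude", "literal"}
    random_state : int

    Attributes
    ----------
    labels_ : ndarray of shape (n_cells,)
    embedding_ : ndarray of shape (n_cells, d)
        Consensus representation H_hat.
    structure_ : ndarray of shape (n_cells, n_cells)
        Final global structural relationship matrix S.
    training_state_ : TrainingState with per-epoch loss history.
    """

    def __init__(
        self,
        n_clusters: int = 4,
        encoder_dims=(512, 64),
        epochs_pretrain: int = 200,
        epochs_train: int = 200,
        learning_rate: float = 5e-4,
        temperature: float = 0.5,
        balance: float = 1.0,
        use_attention: bool = True,
        contrastive_mode: str = "self_exclude",
        clip_norm: float = 5.0,
        random_state: int = 0,
    ):
        self.n_clusters = n_clusters
        self.encoder_dims = encoder_dims
        self.epochs_pretrain = epochs_pretrain
        self.epochs_train = epochs_train
        self.learning_rate = learning_rate
        self.temperature = temperature
        self.balance = balance
        self.use_attention = use_attention
        self.contrastive_mode = contrastive_mode
        self.clip_norm = clip_norm
        self.random_state = random_state

    # -- phases ------------------------------------------------------------
    def _init_model(self, views: List[np.ndarray]) -> None:
        rng = np.random.default_rng(int(self.random_state))
        dims = list(self.encoder_dims)
        self.encoders_ = [ViewAutoencoder(v.shape[1], dims, rng) for v in views]
        self.attention_ = AttentionAggregator(len(views), dims[-1], rng)

    def _encode_all(self, X_t: List[Tensor]) -> List[Tensor]:
        return [enc.encode(x) for enc, x in zip(self.encoders_, X_t)]

    def _consensus(self, Z_views: List[Tensor]):
        """Return (S, H_hat) tensors for the current parameters."""
        n = Z_views[0].shape[0]
        if self.use_attention:
            Z = ad.concat(Z_views, axis=1)
            S, _, H_hat = self.attention_.forward(Z)
        else:
            H_hat = Z_views[0]
            for Zm in Z_views[1:]:
                H_hat = H_hat + Zm
            H_hat = H_hat * (1.0 / len(Z_views))
            S = Tensor(np.full((n, n), 1.0 / n))
        return S, H_hat

    def pretrain(self, views: List[np.ndarray]) -> List[float]:
        """Reconstruction-only training of the autoencoders."""
        X_t = [Tensor(v) for v in views]
        params = [p for enc in self.encoders_ for p in enc.parameters()]
        opt = Adam(params, lr=self.learning_rate, clip_norm=self.clip_norm)
        history = []
        for epoch in range(self.epochs_pretrain):
            Z = self._encode_all(X_t)
            Xhat = [enc.decode(z) for enc, z in zip(self.encoders_, Z)]
            loss = _reconstruction_loss_t(X_t, Xhat)
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"non-finite pretraining loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            history.append(loss.item())
        return history

    def train_joint(self, views: List[np.ndarray]):
        """Joint optimization of L_r + lambda * L_c over all parameters."""
        X_t = [Tensor(v) for v in views]
        params = [p for enc in self.encoders_ for p in enc.parameters()]
        params += self.attention_.parameters()
        opt = Adam(params, lr=self.learning_rate, clip_norm=self.clip_norm)
        recon_h, contrast_h, total_h = [], [], []
        use_contrastive = self.balance > 0
        for epoch in range(self.epochs_train):
            Z = self._encode_all(X_t)
            Xhat = [enc.decode(z) for enc, z in zip(self.encoders_, Z)]
            recon = _reconstruction_loss_t(X_t, Xhat)
            if use_contrastive:
                S, H_hat = self._consensus(Z)
                contrast = _contrastive_loss_t(
                    H_hat, Z, S, self.temperature, self.contrastive_mode
                )
                loss = recon + contrast * self.balance
                contrast_h.append(contrast.item())
            else:
                loss = recon
                contrast_h.append(0.0)
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"non-finite joint loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            recon_h.append(recon.item())
            total_h.append(loss.item())
        return recon_h, contrast_h, total_h

    # -- estimator surface ---------------------------------------------------
    def fit(self, X, y=None):
        views = [np.asarray(v, dtype=float) for v in X]
        if len(views) < 1:
            raise ValueError("need at least one view")
        n = views[0].shape[0]
        if any(v.shape[0] != n for v in views):
            raise ValueError("all views must cover the same cells")
        if self.n_clusters > n:
            raise ValueError("n_clusters cannot exceed the number of cells")
        LossWeights(temperature=self.temperature, balance=self.balance)  # validate

        self._init_model(views)
        pre_h = self.pretrain(views)
        recon_h, contrast_h, total_h = self.train_joint(views)

        # final forward with trained parameters
        Z = self._encode_all([Tensor(v) for v in views])
        S, H_hat = self._consensus(Z)
        self.view_embeddings_ = [z.data for z in Z]
        self.embedding_ = H_hat.data
        self.structure_ = S.data
        self.training_state_ = TrainingState(
            epochs_pretrain=self.epochs_pretrain,
            epochs_train=self.epochs_train,
            learning_rate=self.learning_rate,
            seed=int(self.random_state),
            history={
                "pretrain_reconstruction": pre_h,
                "joint_reconstruction": recon_h,
                "joint_contrastive": contrast_h,
                "joint_total": total_h,
            },
        )
        result = assign_clusters(self.embedding_, self.n_clusters, int(self.random_state))
        self.labels_ = result.labels
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X, y).labels_
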