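"""Cross-modal fusion: per-view autoencoders and attention aggregation.

Each recovered modality is compressed by its own autoencoder
(ReLU hidden layers, linear bottleneck of width d).  The bottlenecks are
concatenated into Z (N x M*d) and aggregated through a scaled
dot-product attention block:

    R  = Z W_R            B1 = Z W_1        B2 = Z W_2
    S  = row-softmax(B1 B2^T / sqrt(d_a))   (global structural relationships)
    z_hat_i = sum_j S_ij R_j                (Z_hat = S R)
    H_hat = (Z + Z_hat) W_3 + b_3           (residual consensus, N x d)

S is row-stochastic; its rows express pairwise cell affinity in the
fused latent space and later re-weight contrastive negatives.  The
view-specific representation entering the contrastive loss is the raw
bottleneck Z^m, so consensus and views share the dimension d.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor

__all__ = [
    "ViewAutoencoder",
    "AttentionAggregator",
    "GlobalStructure",
    "encode_view",
    "concat_views",
    "global_structure",
    "aggregate",
]


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=(fan_in, fan_out))


class ViewAutoencoder:
    """Autoencoder for one modality: D -> hidden... -> d and mirrored back.

    ``encoder_dims`` lists the hidden widths followed by the bottleneck,
    e.g. (512, 64); hidden layers are ReLU, the bottleneck and the
    decoder output are linear.
    """

    def __init__(self, input_dim: int, encoder_dims=(512, 64), rng: np.random.Generator = None):
        rng = rng or np.random.default_rng(0)
        dims = [int(input_dim)] + [int(d) for d in encoder_dims]
        self.input_dim = int(input_dim)
        self.bottleneck = dims[-1]
        self.enc_W = [Tensor(_xavier(rng, a, b), requires_grad=True) for a, b in zip(dims[:-1], dims[1:])]
        self.enc_b = [Tensor(np.zeros(b), requires_grad=True) for b in dims[1:]]
        rdims = dims[::-1]
        self.dec_W = [Tensor(_xavier(rng, a, b), requires_grad=True) for a, b in zip(rdims[:-1], rdims[1:])]
        self.dec_b = [Tensor(np.zeros(b), requires_grad=True) for b in rdims[1:]]

    def encode(self, x: Tensor) -> Tensor:
        h = x if isinstance(x, Tensor) else Tensor(x)
        last = len(self.enc_W) - 1
        for i, (W, b) in enumerate(zip(self.enc_W, self.enc_b)):
            h = h @ W + b
            if i < last:
                h = ad.relu(h)
        return h

    def decode(self, z: Tensor) -> Tensor:
        h = z if isinstance(z, Tensor) else Tensor(z)
        last = len(self.dec_W) - 1
        for i, (W, b) in enumerate(zip(self.dec_W, self.dec_b)):
            h = h @ W + b
            if i < last:
                h = ad.relu(h)
        return h

    def parameters(self) -> list:
        return self.enc_W + self.enc_b + self.dec_W + self.dec_b


class AttentionAggregator:
    """Scaled dot-product attention over concatenated view bottlenecks.

    W_R is one dense (M*d) x (M*d) map (the per-view block form is its
    special case); W_1, W_2 map to the attention width d_a (= d), and
    W_3, b_3 project the residual sum back to the consensus width d.
    """

    def __init__(self, n_views: int, d: int, rng: np.random.Generator = None, d_attn: int = None):
        rng = rng or np.random.default_rng(0)
        total = int(n_views) * int(d)
        d_attn = int(d_attn or d)
        self.n_views = int(n_views)
        self.d = int(d)
        self.d_attn = d_attn
        self.W_R = Tensor(_xavier(rng, total, total), requires_grad=True)
        self.W_1 = Tensor(_xavier(rng, total, d_attn), requires_grad=True)
        self.W_2 = Tensor(_xavier(rng, total, d_attn), requires_grad=True)
        self.W_3 = Tensor(_xavier(rng, total, d), requires_grad=True)
        self.b_3 = Tensor(np.zeros(d), requires_grad=True)

    def forward(self, Z: Tensor):
        """Return (S, Z_hat, H_hat) as tensors."""
        Z = Z if isinstance(Z, Tensor) else Tensor(Z)
        R = Z @ self.W_R
        B1 = Z @ self.W_1
        B2 = Z @ self.W_2
        logits = (B1 @ B2.T) / np.sqrt(self.d_attn)
        if not np.all(np.isfinite(logits.data)):
            raise FloatingPointError("non-finite attention logits")
        S = ad.softmax_rows(logits)
        Z_hat = S @ R
        H_hat = (Z + Z_hat) @ self.W_3 + self.b_3
        return S, Z_hat, H_hat

    def parameters(self) -> list:
        return [self.W_R, self.W_1, self.W_2, self.W_3, self.b_3]


@dataclass
class GlobalStructure:
    """Row-stochastic structure matrix S and the aggregated representation."""

    S: np.ndarray
    Z_hat: np.ndarray


# ---------------------------------------------------------------------------
# functional surface (NumPy in / NumPy out)


def encode_view(encoder: ViewAutoencoder, X: np.ndarray) -> np.ndarray:
    """Deterministic bottleneck representation Z^m of one recovered view."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != encoder.input_dim:
        raise ValueError(f"input has {X.shape[1]} features, encoder expects {encoder.input_dim}")
    return encoder.encode(Tensor(X)).data


def concat_views(*Zs: np.ndarray) -> np.ndarray:
    """Column-wise concatenation [Z^1, ..., Z^M] in modality order."""
    Zs = [np.asarray(Z, dtype=float) for Z in Zs]
    n = Zs[0].shape[0]
    if any(Z.shape[0] != n for Z in Zs):
        raise ValueError("all views must cover the same cells")
    return np.concatenate(Zs, axis=1)


def global_structure(Z: np.ndarray, params: AttentionAggregator) -> GlobalStructure:
    """Attention pass producing S and Z_hat = S R."""
    S, Z_hat, _ = params.forward(Tensor(np.asarray(Z, dtype=float)))
    return GlobalStructure(S=S.data, Z_hat=Z_hat.data)


def aggregate(Z: np.ndarray, Z_hat: np.ndarray, params: AttentionAggregator) -> np.ndarray:
    """Residual consensus H_hat = (Z + Z_hat) W_3 + b_3."""
    Z = np.asarray(Z, dtype=float)
    Z_hat = np.asarray(Z_hat, dtype=float)
    if Z.shape != Z_hat.shape:
        raise ValueError("Z and Z_hat must share a shape")
    return (Tensor(Z + Z_hat) @ params.W_3 + params.b_3).data
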