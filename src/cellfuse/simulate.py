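"""Synthetic multi-modal single-cell data with known clusters and dropout.

The generator produces, for each of M modalities, cluster-specific
non-negative mean expression profiles (log-normal draws, rescaled so the
minimum pairwise distance between cluster means equals
``separation * noise_sd * sqrt(D_m)``), adds truncated Gaussian noise
clipped at zero, and then zeroes each strictly positive entry
independently with probability ``dropout_rate`` — the technical-dropout
process layered on top of true expression.  Biological zeros (entries
already zero before dropout) are never masked, so the recorded mask
identifies exactly the entries a recovery method should restore.

Every downstream stage can therefore be scored against a ground-truth
oracle: labels, pre-dropout matrices, and the dropout masks themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .io import ModalityMatrix, MultiModalDataset

__all__ = ["SimulationParams", "SyntheticGroundTruth", "apply_dropout", "simulate_multimodal"]


@dataclass
class SimulationParams:
    """Study conditions for the generator.

    separation is the minimum distance between cluster mean profiles in
    units of the within-cluster standard deviation (per feature,
    aggregated over the modality as sd * sqrt(D_m)).
    """

    n_cells: int = 500
    n_clusters: int = 4
    dims: Sequence[int] = (200, 60)
    separation: float = 4.0
    dropout_rate: float = 0.3
    noise_sd: Sequence[float] = None
    seed: int = 0

    def __post_init__(self):
        if self.n_clusters < 2:
            raise ValueError("need at least 2 clusters")
        if self.n_cells < self.n_clusters:
            raise ValueError("n_cells must be >= n_clusters")
        self.dims = [int(d) for d in self.dims]
        if any(d < 2 for d in self.dims):
            raise ValueError("every modality needs at least 2 features")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.noise_sd is None:
            self.noise_sd = [1.0] * len(self.dims)
        else:
            self.noise_sd = [float(s) for s in self.noise_sd]
        if len(self.noise_sd) != len(self.dims):
            raise ValueError("noise_sd must have one entry per modality")
        if any(s <= 0 for s in self.noise_sd):
            raise ValueError("noise_sd must be positive")


@dataclass
class SyntheticGroundTruth:
    """Pre-dropout truth: matrices, dropout masks (1 = zeroed), labels."""

    true_matrices: list
    dropout_masks: list
    labels: np.ndarray


def apply_dropout(true_matrix: np.ndarray, rate: float, seed) -> Tuple[np.ndarray, np.ndarray]:
    """Zero each strictly positive entry independently with probability ``rate``.

    ``seed`` may be an integer or a ``numpy.random.Generator``.  Entries
    that are already zero (biological non-expression) are never masked.
    """
    if not (0.0 <= rate <= 1.0):
        raise ValueError("dropout rate must lie in [0, 1]")
    true_matrix = np.asarray(true_matrix, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mask = ((true_matrix > 0) & (rng.random(true_matrix.shape) < rate)).astype(int)
    observed = true_matrix * (1 - mask)
    return observed, mask


def _cluster_profiles(rng, n_clusters, dim, separation, noise_sd):
    """Log-normal mean profiles rescaled to the requested separation."""
    mu = rng.lognormal(mean=0.0, sigma=1.0, size=(n_clusters, dim))
    center = mu.mean(axis=0)
    dists = [
        np.linalg.norm(mu[a] - mu[b])
        for a in range(n_clusters)
        for b in range(a + 1, n_clusters)
    ]
    min_dist = max(min(dists), 1e-12)
    target = separation * noise_sd * np.sqrt(dim)
    mu = center + (mu - center) * (target / min_dist)
    # negative values can appear after rescaling; profiles must stay non-negative
    return np.clip(mu, 0.0, None)


def simulate_multimodal(
    params: SimulationParams,
) -> Tuple[MultiModalDataset, SyntheticGroundTruth]:
    """Draw a multi-modal dataset plus its ground truth.

    All modalities share one cluster assignment; profiles and dropout
    are drawn independently per modality.  Deterministic given
    ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    n, k = params.n_cells, params.n_clusters
    # balanced assignment, shuffled: guarantees every cluster non-empty
    labels = rng.permutation(np.arange(n) % k)

    modalities, true_mats, masks = [], [], []
    cell_ids = [f"cell{i:05d}" for i in range(n)]
    for m, (dim, sd) in enumerate(zip(params.dims, params.noise_sd)):
        mu = _cluster_profiles(rng, k, dim, params.separation, sd)
        true = np.clip(mu[labels] + rng.normal(0.0, sd, size=(n, dim)), 0.0, None)
        observed, mask = apply_dropout(true, params.dropout_rate, rng)
        true_mats.append(true)
        masks.append(mask)
        modalities.append(
            ModalityMatrix(
                values=observed,
                feature_ids=[f"mod{m}_feat{j:05d}" for j in range(dim)],
                cell_ids=cell_ids,
                name=f"modality{m}",
            )
        )
    dataset = MultiModalDataset(modalities=modalities, labels=labels, n_clusters=k)
    truth = SyntheticGroundTruth(true_matrices=true_mats, dropout_masks=masks, labels=labels)
    return dataset, truth
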