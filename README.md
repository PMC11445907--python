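# cellfuse

Recover-then-aggregate clustering for multi-modal single-cell data.

Single-cell multi-omics matrices (paired RNA/protein, RNA/ATAC, ...) are
riddled with zeros from two very different sources: genuine biological
non-expression and technical dropout, where the assay simply missed the
signal. Clustering pipelines that treat every zero as signal conflate the
two and degrade. `cellfuse` addresses this for joint clustering of M
aligned views `X^m ∈ R^(N×D_m)` over the same N cells, in two stages:

**1. Discriminative dropout recovery.** For gene *j* in cluster *k*
(clusters seeded by k-means), with zero rate *a*, mean expression *b* and
variance *v²* over the cluster's cells, the recovery confidence is

    c = (1 − a)·b / ((1 − a)·b + a·v²)

A binary guidance matrix G trusts all observed entries and all zeros with
c below a threshold 𝒯 (default 0.1); the remaining zeros are imputed by a
masked, graph-regularized NMF

    min_{P,Q ≥ 0}  ‖G ⊙ (X − PQᵀ)‖²_F + λ₁(‖P‖²_F + ‖Q‖²_F) + λ₂ Tr(Pᵀ L P)

solved by multiplicative updates, where L is the normalized Laplacian of
an adaptive k-nearest-neighbour similarity re-estimated from the cell
factors P as they evolve. Recovery is `X̃ = (1 − G) ⊙ (PQᵀ) + X`.

**2. Attention fusion with structure-guided contrastive training.** Each
recovered view is compressed by its own autoencoder (512 → 64); the
concatenated bottlenecks Z pass through scaled dot-product attention,
`S = softmax(ZW₁ (ZW₂)ᵀ/√d)`, producing a row-stochastic global structure
matrix S and a residual consensus embedding `Ĥ = (Z + SZW_R)W₃ + b₃`.
Training minimizes `L = L_r + λ·L_c`: reconstruction plus an
InfoNCE-style loss whose negatives are down-weighted by (1 − S_ij), so
cells the attention already considers related are not pushed apart.
Clusters come from k-means on Ĥ and are scored by Hungarian-matched
accuracy (ACC), normalized mutual information (NMI, max-entropy
denominator) and the adjusted Rand index (ARI).

## Worked example

```python
from cellfuse import (SimulationParams, simulate_multimodal,
                      RecoverAggregateClustering, evaluate_clustering)

params = SimulationParams(n_cells=300, n_clusters=3, seed=0)  # 30% dropout
dataset, truth = simulate_multimodal(params)

model = RecoverAggregateClustering(
    n_clusters=3, epochs_pretrain=100, epochs_train=100, random_state=0,
).fit(dataset)

print("missing rate before:", [round(r, 3) for r in model.missing_rate_before_])
print("missing rate after: ", [round(r, 3) for r in model.missing_rate_after_])
print(evaluate_clustering(truth.labels, model.labels_))
```

Output:

```
missing rate before: [0.463, 0.455]
missing rate after:  [0.0, 0.0]
{'ACC': 1.0, 'NMI': 1.0, 'ARI': 1.0}
```

The two views start with ~46% zeros (biological zeros plus the 30%
simulated dropout); every zero judged recoverable is imputed, and the
fused embedding separates the three generating clusters perfectly
(ACC/NMI/ARI all 1.0 against the ground-truth labels).

The same pipeline is available from the shell:

```bash
cellfuse simulate --n-cells 300 --n-clusters 3 --seed 0 --outdir data
cellfuse run data/modality0 data/modality1 --labels data/labels.tsv \
    --clusters 3 --outdir out
cellfuse ablate data/modality0 data/modality1 --labels data/labels.tsv \
    --arms no_recovery,no_contrastive --n-seeds 3
```

Inputs are 10x-style Matrix Market triplets (`matrix.mtx` +
`features.tsv` + `barcodes.tsv`, feature-major on disk) or dense CSV/TSV
(header = feature ids, first column = cell ids), assumed preprocessed and
non-negative.

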