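# Methods

## Problem and model

`cellfuse` clusters N cells measured in M aligned modalities
`X^m ∈ R^(N×D_m)` (all entries non-negative; raw counts or normalized
values are both accepted and the loader records which was given). The
method is a two-stage "recover then aggregate" design: impute technical
dropout zeros first, then learn one consensus embedding across
modalities and cluster it.

## Stage 1 — discriminative dropout recovery

**Seed clustering.** The confidence statistics are defined per cluster,
but nothing upstream provides clusters; we obtain them once by k-means
(10 restarts, seeded) on the per-feature standardized concatenation of
all modalities, and do not recompute them during recovery.

**Recovery confidence.** For gene *j* within cluster *k*, let *a* be the
zero rate, *b* the mean and *v²* the population (1/n) variance over all
the cluster's cells — zeros included; both conventions are plausible
readings and the all-cells mean is the plainer one, so we use it and
document it here for auditability. The confidence
`c = (1−a)b / ((1−a)b + a v²)` lies in [0, 1]; when the denominator is
exactly zero (a gene silent in the entire cluster: a = 1, v² = 0) we
define c = 0 — uniform silence carries no evidence of dropout, so the
zero is trusted as biological.

**Guidance.** `G_ij = 1` for every observed entry and for every zero
whose confidence is below the threshold 𝒯 (trusted zeros); `G_ij = 0`
flags the entries to impute. Raising 𝒯 trusts more zeros, so the number
of recovered entries is non-increasing in 𝒯; 𝒯 = 0.1 is the default.

**Adaptive similarity.** Cell neighbourhoods come from the
probabilistic-neighbours problem: each cell's row of the similarity is
the simplex-constrained minimizer of `Σ_j s_ij d_ij + γ_i Σ_j s²_ij`
with squared Euclidean distances d and the regularity weight chosen so
the solution is supported on exactly k neighbours (k = 15 by default).
This has the closed form
`s_(j) = (d_(k+1) − d_(j)) / (k d_(k+1) − Σ_{l≤k} d_(l))` over the k
nearest points (uniform 1/k when the leading k+1 distances tie; index
order breaks remaining ties), verified in the tests against a generic
QP solver. Rows are then symmetrized, `S ← (S + Sᵀ)/2`, giving degrees
D and the normalized Laplacian `L = I − D^{−1/2} S D^{−1/2}`.

**Masked NMF.** The objective

`‖G ⊙ (X − PQᵀ)‖²_F + λ₁(‖P‖² + ‖Q‖²) + λ₂ Tr(Pᵀ L P)`

is minimized by multiplicative updates

```
P ← P ⊙ [(G⊙X)Q + λ₂ A P] / [(G⊙(PQᵀ))Q + λ₁P + λ₂P + ε]
Q ← Q ⊙ [(G⊙X)ᵀP]         / [(G⊙(PQᵀ))ᵀP + λ₁Q + ε]
```

with `A = D^{−1/2} S D^{−1/2}` and ε = 1e-10. This is the standard
graph-regularized NMF rule and the unique multiplicative form whose
fixed points satisfy the stationarity condition of the objective above
(note `Tr(PᵀLP) = Tr(PᵀP) − Tr(PᵀAP)`, which splits into the λ₂ terms
of numerator and denominator). Iterates stay entrywise non-negative and
the objective is non-increasing, which the test suite verifies against
an independent recomputation of the formula on random instances.

The neighbour graph is re-estimated from the current cell factors P
every 10 iterations (`sim_update_every`), coupling the similarity to
the factorization as it improves; the initial graph is built from the
observed matrix rows, which carry more neighbourhood signal than a
random initialization of P. The recorded objective is only guaranteed
monotone between refreshes, since a refresh changes the Laplacian the
objective is measured against. P and Q are initialized
`Uniform(0,1)·sqrt(mean(X)/r)` with the stage seed; rank r = 50 (capped
at min(N, D) − 1), λ₁ = λ₂ = 0.1, at most 500 iterations, stopping at a
relative objective change below 1e-4.

**Recovery.** `X̃ = (1 − G) ⊙ (PQᵀ) + X`; entries with G = 1 are
bit-exact copies of the input. Each modality is recovered independently
with the same threshold and the same seed clustering.

## Stage 2 — fusion and training

Each view has its own autoencoder, `D_m → 512 → 64` with a ReLU hidden
layer and linear bottleneck, mirrored by the decoder (ReLU hidden,
linear output). The view representation entering the contrastive loss
is the raw bottleneck `Z^m` itself — no extra projection head — so the
consensus and the views share the dimension d = 64 and the cosine in
the loss is well-defined.

The concatenated bottlenecks `Z = [Z^1, …, Z^M]` feed a scaled
dot-product attention block: `R = Z W_R` (one dense (Md)×(Md) map; a
per-view block-diagonal W_R is its special case), `B₁ = Z W₁`,
`B₂ = Z W₂` with attention width d_a = d, the global structure
`S = row-softmax(B₁B₂ᵀ/√d_a)`, the aggregate `Ẑ = S R`, and the
residual consensus `Ĥ = (Z + Ẑ) W₃ + b₃`. All attention weights are
Xavier-uniform initialized from the stage seed. Attention runs full
batch (S is N×N), which is the regime the method targets (thousands of
cells, not millions).

**Losses.** The reconstruction loss is the plain sum of squared errors
over all views (no averaging); λ rescales accordingly and defaults to
1. The contrastive loss treats the (consensus, view) pair of the same
cell as the positive and every other cell as a structure-weighted
negative:

`L_c = −1/(MN) Σ_i Σ_m log [ e^{D(Ĥ_i, H^m_i)/𝓜} / Σ_{j≠i} e^{(1−S_ij) D(Ĥ_i, H^m_j)/𝓜} ]`

with cosine similarity D and temperature 𝓜 = 0.5. Two denominator
conventions are implemented: the default (`self_exclude`) drops the
j = i term, which is how we read the subtraction of `e^{1/𝓜}` in the
loss's usual statement — a literal subtraction can drive the
denominator non-positive whenever all similarities and structure
weights are moderate. The literal form is available as
`contrastive_mode="literal"`. Both clamp the denominator at 1e-12
(gradient blocked at the clamp). The prefactor 1/(MN) generalizes the
two-view 1/(2N) to M views. The vectorized implementation is tested to
1e-8 against a double-loop recomputation.

**Optimization.** Pretraining runs 200 epochs of reconstruction-only
Adam (lr 5e-4, global gradient-norm clip at 5) on the autoencoders;
joint training runs a further 200 epochs of `L_r + λL_c` over all
parameters, with S recomputed each forward pass. Attention parameters
are frozen during pretraining (they receive no reconstruction
gradient). With λ = 0 the joint phase degenerates exactly to
reconstruction-only training. Gradients come from the package's small
reverse-mode autodiff engine (`_autodiff.py`), validated against
central finite differences. Everything is NumPy; runs are deterministic
given the seed.

**Assignment.** k-means with 20 restarts (seeded) on the rows of Ĥ.

## Evaluation

ACC is computed after an optimal one-to-one mapping of predicted to
true labels (Hungarian assignment on the contingency table) — raw-label
matching is meaningless for cluster labels. NMI uses the max-entropy
denominator and ARI the standard pair-counting adjustment; both
delegate to scikit-learn, with the degenerate
single-cluster-on-both-sides case equal to 1 by convention. The test
suite checks all three against brute-force oracles (exhaustive label
mappings, direct entropy sums, explicit pair counting) on complete
enumerations of small partitions.

## Synthetic data: what it emulates and what it does not

The generator draws K cluster mean profiles per modality from a
log-normal, rescales their deviations so the minimum pairwise distance
between cluster means equals `separation · noise_sd · √D_m`, adds
truncated Gaussian noise clipped at zero, and then zeroes each strictly
positive entry independently with probability `dropout_rate` — the
dropout mask is recorded, and biological zeros are never masked. All
modalities share one balanced cluster assignment; profiles, dimensions
and dropout draws are independent per modality.

Defaults are the package's standard study conditions: N = 500 cells,
K = 4 clusters, two modalities of 200 and 60 features (a wide RNA-like
view and a narrow protein-like view, scaled to sizes that keep the full
test suite at minutes on one CPU), separation 4, dropout 0.3,
noise_sd 1. At these settings k-means on the pre-dropout data recovers
the labels essentially perfectly, so the benchmark isolates what the
pipeline must preserve and repair rather than testing the frontier of
cluster detectability.

What the generator does **not** emulate: negative-binomial count noise
and mean–variance coupling, value-dependent dropout (real dropout hits
low-expressed genes harder; here it is uniform Bernoulli on positive
entries), batch effects, library-size variation, and correlated
features. Passing tests therefore demonstrate that the algebra and the
optimization behave as specified and that recovery genuinely
reconstructs masked signal under clean cluster structure — not that the
pipeline outperforms alternatives on real tissue atlases.

## Numerical choices and degenerate inputs

- ε = 1e-10 in every multiplicative-update denominator; contrastive
  denominator clamp 1e-12; cosine row norms stabilized with 1e-24
  inside the square root.
- An all-zero input matrix to the NMF is an error; non-finite iterates
  or losses abort with the iteration/epoch index.
- A cosine of a zero vector is defined as 0 with a warning.
- Duplicate cells are allowed in the similarity (a zero distance simply
  dominates its row); k_neighbors must be < N and is capped at N − 1 by
  the estimator.
- Labels are re-encoded to 0..K−1 by first appearance; the mapping is
  persisted in the output manifest.
- One global seed fans out to stage seeds by fixed offsets (clustering
  +1, NMF +2, fusion model +3), so stages can be re-run in isolation.

## Known limitations

- Recovery confidence uses one formula for every modality; heavily
  non-Gaussian views (e.g. near-binary ATAC) may warrant per-modality
  confidence models.
- Full-batch attention is O(N²) memory; desk-scale N (≤ ~6000) is the
  intended regime.
- The seed clustering feeds the confidence statistics once; a poor seed
  clustering propagates into which zeros are recovered.
- The ablation arm without attention replaces the consensus by the
  plain mean of view bottlenecks with a uniform structure matrix — the
  minimal change that keeps the contrastive loss well-defined.
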