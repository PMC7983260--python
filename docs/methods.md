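# Methods

## Model

Let `Y ∈ {0,1}^{m×n}` be the association matrix (rows: lncRNAs, columns:
diseases; 1 = known association, 0 = unknown), `X_l ∈ R^{m×d_l}`
continuous per-lncRNA features and `X_d ∈ {0,1}^{n×d_d}` binary
per-disease features. The method treats link prediction as
graph semi-supervised learning under two assumptions: the completed
score matrix is low-rank, and predictions vary smoothly along the
feature manifolds of each entity set.

### Graphs

Each side gets its own graph from its features. For node *i*, the k
nearest other nodes by Euclidean distance form `N(i)`; the selection
matrix `C` (`C_ij = 1 iff j ∈ N(i)`) is symmetrised by the mutual rule

    Ã = Cᵀ ⊙ C + I,

so an edge survives only when both endpoints selected each other, and
every node keeps a self-loop. Graph convolutions use the symmetric
normalisation `Â = D̃^{-1/2} Ã D̃^{-1/2}` with `D̃_ii = Σ_j Ã_ij`; its
spectrum lies in [−1, 1], which keeps stacked propagation stable. Exact
distance ties are broken by ascending node index so graphs are identical
across platforms; because the selection uses squared distances computed
with a fixed operation order, tie sets are exact. The mutual rule can
isolate a node (self-loop only); that is legal and the normalisation
stays well defined.

### Networks

All layers are graph convolutions `H' = ρ(Â H W)` without bias. Per
side:

- GNNq (variational, feature inference): encoder GCN `d_in→h` (relu),
  parallel GCN heads `h→h` for `μ` and `log σ` (linear; `σ = exp(log σ)`
  guarantees positivity), sample `Z = μ + σ⊙ε`, decoder GCN `h→h` (relu)
  then GCN `h→d_in` (sigmoid) reconstructing the features.
- GNNp (plain, label propagation): GCN `n_labels→h` (relu) giving `Z'`,
  GCN `h→n_labels` (sigmoid) giving the prediction block `F`.

Hidden width `h = 256` by default. Dropout 0.5 is applied to every
hidden activation during training only; evaluation passes use ε = 0 and
no dropout and are bit-deterministic. Weights are Glorot-uniform from
the run seed. Decoder outputs pass through sigmoids, which is why
continuous features are globally min-max scaled to [0, 1] before
training (a constant matrix maps to zeros); `μ` and `log σ` are left
unsquashed.

### Losses

All losses are elementwise sums (no averaging; the learning rate
absorbs scale):

- Gaussian reconstruction `½‖X − X'‖²_F` (continuous features),
- Bernoulli reconstruction: full binary cross-entropy
  `−Σ[X log X' + (1−X) log(1−X')]` (binary features and labels). A
  positive-term-only cross-entropy would be minimised by the constant
  all-ones output, so the complement term is required for a well-posed
  objective. Logs are guarded by a 1e-10 clamp.
- KL to the standard normal `−½ Σ (1 + 2 log σ − μ² − σ²)`,
- manifold loss `L_m = ½‖Z − Z'‖²_F` coupling the two autoencoders,
- co-training loss `L_c = ½‖Z_l Z_dᵀ − Y‖²_F` coupling the two spaces.

Totals: `L_q = α L_ql + (1−α) L_qd + β L_c` and
`L_p = α L_pl + (1−α) L_pd` with `L_p• = BCE + γ L_m`.

### Training

One epoch = one E-step followed by one M-step, each a single Adam
update (lr 0.01, weight decay 1e-5, separate optimizer state for the
q-group and the p-group). The E-step draws fresh ε and dropout masks and
updates only the two GNNq; the M-step recomputes the posterior means
`μ_l, μ_d` in eval mode, treats them as constants, and updates only the
two GNNp — so the manifold target is the low-variance posterior mean
rather than a sample. Coupling weights ramp linearly, `β = γ = e/e_n`
with `e_n = 500`: early epochs let each network fit its own objective
before the couplings bind them. Each of the four networks consumes an
independent child stream of the run seed, which makes runs reproducible
and makes the two spaces exactly decouple when `β = γ = 0` (verified
bit-exactly in the tests). After training,
`F = α F_l + (1−α) F_dᵀ` is min-max rescaled to [0, 1]; both `F_l` and
`F_d` pass through a width-`h` bottleneck, so by the rank-sum inequality
the fused matrix is low-rank as well.

### Sequence features

When lncRNA features are not given numerically they are computed from
sequences: uppercase, U→T, overlapping k-mers (k = 3, stride 1),
dropping k-mers with characters outside ACGT; a skip-gram model with
negative sampling (5 negatives, unigram^0.75 noise, 5 epochs, linearly
decaying lr from 0.025) is trained on the corpus of all input
sequences, and each sequence's vector (300-dim by default) is the sum
of its k-mer vectors. The corpus is sorted before training, so the
embeddings are invariant to record order. The autodiff core, the Adam
optimizer and this embedder are part of the package; they are validated
against finite differences, closed forms and lookup-and-sum oracles in
the test suite.

## Evaluation protocol

5-fold cross-validation partitions the *known positives* only (unknown
pairs are already 0 and are never masked). Per fold, the model trains
on the masked matrix; the evaluation set is the held-out positives
(label 1) plus every pair that is 0 in the full matrix (label 0), with
training positives excluded. Metrics are reported per fold and on
scores pooled across folds (each unknown pair therefore contributes one
score per fold).

- AUROC: tie-aware rank-sum (Mann–Whitney; ties count ½).
- AUPR: non-interpolated average precision; tied scores form a single
  operating point, so uniform scores give exactly the prevalence.
- Thresholded metrics (sensitivity, specificity, accuracy, precision,
  F1, MCC) use the rule "positive iff score ≥ t" and define any 0/0 as
  0. At fixed specificity (0.95, 0.99 by default) the threshold is the
  smallest observed score achieving the level.
- Top-k true-positive counts (k ∈ {20, 40, 60, 80, 100}) use stable
  descending order.

## Synthetic benchmark

The generator plants the structure the model assumes. Row factors
`U ∈ R^{m×r}` and column factors `V ∈ R^{n×r}` are i.i.d. standard
normal; ground-truth scores are `sigmoid(U Vᵀ/√r)` (the `√r` keeps
logits O(1) at any rank) and `Y` marks the `n_positives` highest-truth
cells — top-cell selection rather than Bernoulli draws makes the
positive count exact and runs comparable across seeds. Features carry
the same factors: `X_l = U W_l + noise` (Gaussian, sd 0.3, then min-max
scaled) and `X_d ~ Bernoulli(sigmoid(V W_d + logit(0.05)))`. The fixed
benchmark is m = 60, n = 80, r = 4, 300 positives (prevalence 0.0625),
64 lncRNA features, 120 disease features. A Bernoulli row that comes
out all-zero is repaired deterministically by setting its
highest-probability entry, preserving the no-empty-rows invariant at
any seed.

What it does *not* emulate: real k-mer composition statistics, disease
ontology structure, curation biases (popular diseases are studied
more), or feature families whose informativeness differs between sides
in uncontrolled ways. Passing the benchmark shows the machinery
recovers planted low-rank structure from informative features; it does
not certify performance on curated catalogues.

## Problem sizes and numerical choices

Tests and the acceptance script run the full 60×80 benchmark with the
reference defaults (500 epochs, 256-dim hiddens); one fit takes roughly
12 s on a single CPU and the complete three-seed cross-validation about
three minutes. Numerical rank uses singular values above `1e-6·σ_max`.
Degenerate cases are defined explicitly: constant fused matrices
rescale to all zeros (with a warning), empty gene columns are dropped
before training, and an all-zero association matrix is rejected.

## Known limitations

- The disease-side mutual k-NN graph over sparse binary features is
  much sparser than the lncRNA-side graph (ties resolve to low indices;
  the AND rule then isolates ~15% of disease nodes on the benchmark),
  so the disease-space prediction `F_d` has markedly weaker early
  precision than `F_l`; the fixed `α = 0.5` fusion averages that
  weakness in. Pooled AUPR sits near 5× prevalence rather than far
  above it for exactly this reason.
- Single-threaded dense linear algebra; graphs beyond a few thousand
  nodes would need a sparse path.
- No cold-start evaluation (new lncRNA/disease with no known links) and
  no class-weighted loss variants.
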