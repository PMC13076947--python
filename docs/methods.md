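# Methods

## Model

A study is a set of triplets *(drug i, drug j, cell line r)* with continuous
synergy scores. Per metric, published cut-offs partition scores into three
classes; per cell line these classes define a heterogeneous drug–drug graph
whose typed adjacencies stack into an interaction tensor
𝒜_r ∈ ℝ^{n×n×3}. Two assumptions drive the architecture:

1. **Low-rank relational structure.** Interaction profiles across partners
   and edge types are approximately low-rank, so the Tucker mode-1 factor
   U_r (top-R₁ left singular vectors of the mode-1 unfolding) is an
   informative global drug embedding.
2. **Compositional local structure.** Useful relations also arise from
   *paths* through typed edges (e.g. "synergistic with an antagonist of").
   The graph transformer learns these as soft meta-paths: per channel, a
   softmax over the three edge types mixes the adjacencies into a convex
   combination Q_c; L successive degree-normalized products of L+1 mixtures
   compose relations of length up to L+1; graph convolution with self-loops
   over the composed adjacency projects drug fingerprints into per-channel
   embeddings; channel attention pools them into Z_r.

The per-drug interaction feature is the row of H_r = [U_r; Z_r]. The
predictor projects four modalities (expression g_r, molecular-GCN
embeddings s_i/s_j, fingerprints x_i/x_j, interaction features h_{r,i}/h_{r,j})
through shared-per-modality two-layer MLPs with batch normalization into a
common latent size, concatenates them in a fixed order, and maps the result
to a scalar with a three-layer MLP. Training minimizes MSE with Adam. The
molecular encoder applies symmetric-normalized graph convolutions with
self-loops over the heavy-atom graph and mean-pools atom embeddings.

### Undirected pairs

Pairs are unordered. Records are stored canonically (smaller drug index
first); training augments each triplet with the swapped ordering and
evaluation averages both orderings, making predictions order-invariant in
practice without constraining the network.

### Leakage policy

Graphs, tensors and U_r are rebuilt per cross-validation fold from
**training records only**. Building them from all records would leak
held-out labels into the features; the leakage guard is asserted by test.

## Parameters

| parameter | default | notes |
|---|---|---|
| d (GTN embedding) | 32 | reference value; sensitivity optimum |
| C (channels) | 2 | reference value |
| L (compositions) | 1 | meta-paths up to length L+1 = 2; L counts products, not mixtures |
| h (attention hidden) | = d | not published; tied to d |
| R₁ (Tucker rank) | min(n, d) | commensurate with d so global and local blocks are comparable; R₂ = R₁, R₃ = 3 |
| learning rate | 0.001 | Adam, reference value |
| dropout / epochs | presets | `oneil`/`cloud`: 0.2 / 200; `almanac`: 0.0 / 500 |
| batch size | 256 | not published; `None` = full batch |
| modality latent / hidden | 64 / 128 | desk-scale; the published width optimum (8192) is available by override |
| interaction classes | Loewe ≥30/≤0; Bliss ≥3.68/≤−3.37; ZIP ≥3.87/≤−3.37; HSA ≥2.64/≤−4.48 | synergy cut inclusive, antagonism cut inclusive, additive open |

The printed ZIP rule leaves [3.68, 3.87) unassigned; the additive interval
is extended to the synergy cut so the three classes partition the line.

Targets are standardized by the training-fold mean/sd inside the trainer
and predictions un-standardized on output; this keeps Adam at lr 0.001
well-scaled regardless of the metric's numeric range.

## Numerical choices

* **Tucker.** Truncated SVD of the mode-1 unfolding for U_r; full HOSVD
  when all factors are needed; optional HOOI refinement (off by default).
  Unfolding layout is Fortran-ordered (element (i,j,k) → row i, column
  j + n·k). Each singular vector is sign-fixed so its largest-magnitude
  entry is positive, making factors deterministic across platforms. A zero
  unfolding returns canonical identity columns.
* **Degree normalization.** D is the row-degree matrix of the unnormalized
  product being normalized at that step; degrees use absolute values (safe
  under score-weighted edges) and zero rows keep degree 1. With binary
  symmetric slices this keeps composed rows sub-stochastic and isolated
  drugs well-defined.
* **Edge weights.** Binary adjacencies by default (matching the formal
  graph definitions and the degree normalization); a score-weighted mode is
  available behind a flag.
* **Autodiff.** All trainable components run on a minimal reverse-mode tape
  over float64 numpy arrays; gradients of every parameter group are checked
  against central finite differences at relative error < 1e-4 in the test
  suite. Batch normalization uses batch statistics in training and running
  estimates in evaluation; dropout masks come from the seeded generator, so
  loss histories are bit-reproducible for a given seed.
* **Degenerate inputs.** Constant vectors make the Pearson correlation
  undefined — it is reported as NaN with a warning, never silently zero;
  single-class folds flag AUC/AUPR as undefined. Strata smaller than k are
  merged into the largest stratum with a warning.

## Synthetic studies

`make_synthetic_study` emulates the statistical structure the model
assumes: each drug carries a latent vector (with a constant coordinate, so
scores decompose into per-drug main effects plus pure pairwise interaction),
each cell line a symmetric loading matrix; scores are the bilinear form plus
Gaussian noise, affinely rescaled so the published Loewe cut-offs yield the
requested class proportions (defaults 10/50/40%, synergy rare). Drugs are
common small molecules from a packaged SMILES list; fingerprints come from
the deterministic hashed-substructure featurizer; expression rows are
Gaussian with a per-cell-line mean shift. `make_planted_tensor` plants an
exact Tucker structure (symmetric in the first two modes, so slices are
valid undirected adjacencies while the mode-1 row space stays span(U*)) for
factor-recovery oracles.

The reference desk-scale study is 20 drugs × 2 cell lines at 80% pair
density (~300 triplets), noise sd 0.1 on a unit-variance signal — small
enough that the entire cross-validated pipeline runs in seconds while
leaving held-out prediction non-trivial.

What the generator does **not** emulate: real dose–response structure,
chemistry-correlated synergy (latents are independent of the molecules), 
assay noise heteroscedasticity, or the marginals of any public screen.
Passing tests therefore demonstrate that the machinery recovers planted
structure under the model's own assumptions, not performance on real
screens.

### Where each component matters

On dense desk-scale studies the fallback fingerprints act as unique drug
identifiers in a transductive setting: the fusion MLP can learn each drug's
latent from fingerprints alone, making the relational components
informationally redundant (they still carry the signal — with deliberately
uninformative fingerprints the Tucker pathway alone reaches held-out
PCC ≈ 0.8 where the fingerprint baseline is at chance). The component
ablation is therefore evaluated on a drug-rich, sparsely covered study
(56 drugs, one cell line, 15% of pairs observed): with few training pairs
per drug, composing latents from fingerprints is sample-starved while the
training graph exposes interaction structure directly, and the full model
consistently beats the no-component baseline — the regime, and the
direction, the architecture is designed for. That run uses dropout 0.2 (the
published regularization for moderate-size data) and R₁ = 6, close to the
planted latent rank.

## Known limitations

* Dense tensors and dense composed adjacencies: memory and time scale as
  O(n²)–O(n³) per cell line; very large drug panels would need sparse
  backends (out of scope).
* Tensor ranks are fixed configuration, not selected adaptively.
* The fallback fingerprint featurizer preserves substructure identity and
  determinism but not the geometry of pretrained graph-infomax embeddings;
  results with it are not comparable to runs using pretrained fingerprints
  (which take precedence when supplied).
* Unseen drugs or cell lines (cold start) are out of scope: every drug must
  appear in the training graphs.
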