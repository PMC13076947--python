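# synergraph

Cell line-specific prediction of drug-combination synergy from heterogeneous
drug–drug interaction graphs.

## The problem

Combination therapy works when two drugs act synergistically in a given
cellular context. Measured combinations are triplets *(drug i, drug j, cell
line r)* with one or more continuous synergy scores (Loewe additivity, Bliss
independence, ZIP, HSA); published cut-offs discretize each score into
synergistic / additive / antagonistic classes (e.g. Loewe: synergy if
score ≥ 30, antagonism if ≤ 0). Screening every pair in every cell line is
infeasible, so the practical task is to regress the synergy score of unseen
pairs — and, through the class cut-off, to rank candidate synergistic
combinations.

## The model

For each cell line *r* the labeled pairs form a heterogeneous graph with
three edge types. Its typed adjacencies **A**<sub>r|1</sub>,
**A**<sub>r|2</sub>, **A**<sub>r|3</sub> (synergistic, additive,
antagonistic) stack into an interaction tensor
𝒜<sub>r</sub> ∈ ℝ<sup>n×n×3</sup>, from which two drug representations are
derived:

* **Global feature U<sub>r</sub>** — the mode-1 factor of the Tucker
  factorization 𝒜<sub>r</sub> ≈ G<sub>r</sub> ×₁ U<sub>r</sub> ×₂
  V<sub>r</sub> ×₃ J<sub>r</sub>, computed as the top-R₁ left singular
  vectors of the mode-1 unfolding. Each drug's row summarizes its whole
  interaction profile across partners and interaction types.
* **Local feature Z<sub>r</sub>** — a graph-transformer embedding: per
  channel, a softmax over edge types mixes the three adjacencies into a
  convex combination; chaining L+1 such mixtures with degree-normalized
  products composes soft meta-paths; graph convolution over the composed
  adjacency (with self-loops) projects drug fingerprints **X** to
  per-channel embeddings, pooled by channel attention into Z<sub>r</sub>.

Rows of H<sub>r</sub> = [U<sub>r</sub>; Z<sub>r</sub>] give the per-drug
interaction feature h<sub>r,i</sub>. A triplet is scored by projecting four
modalities — gene expression g<sub>r</sub>, molecular-graph GCN embeddings
(s<sub>i</sub>, s<sub>j</sub>), fingerprints (x<sub>i</sub>, x<sub>j</sub>),
and (h<sub>r,i</sub>, h<sub>r,j</sub>) — through per-modality two-layer
MLPs with batch normalization, concatenating, and applying a three-layer
prediction MLP, trained end-to-end with MSE loss (Adam, lr 0.001; U<sub>r</sub>
is computed once per fit and held fixed). Evaluation is stratified 10-fold
cross-validation with MSE/RMSE/PCC (+95% CI over fold MSEs) and, after
thresholding predictions at the published synergy cut,
AUC/AUPR/ACC/F1/Cohen's κ.

Training networks run on a small self-contained reverse-mode autodiff core
(`synergraph.autodiff`), in float64 throughout.

## Worked example

No external data is needed: the package generates complete synthetic studies
whose scores follow a bilinear latent-factor surface (the low-rank structure
the tensor model assumes), rescaled so the published Loewe cut-offs give
realistic class proportions.

```python
import synergraph as sg

spec = sg.SyntheticSpec(seed=0)            # 20 drugs, 2 cell lines, ~300 triplets
dataset, truth = sg.make_synthetic_study(spec)

cfg = sg.ModelConfig(d=16, latent=32, modality_hidden=64, pred_hidden=(64,),
                     mol_layers=(32, 32), epochs=30, batch_size=None)
model = sg.SynergyModel(dataset, metric="loewe", config=cfg)
cv = model.fit_cv(k=10, seed=0)
print(cv.summary())
```

prints

```
10-fold cross-validation (loewe metric, 304 predictions)
  MSE:   154.682 +/- 55.989   CI95 [114.63, 194.73]
  RMSE:   12.255 +/- 2.235
  PCC:     0.814 +/- 0.068
  AUC:     0.887   AUPR: 0.622   ACC: 0.911   F1: 0.386   kappa: 0.355
```

A held-out Pearson correlation of 0.81 means the model recovers most of the
planted interaction surface from training pairs alone; the classification
row is the same prediction read through the Loewe ≥ 30 cut (synergistic
pairs are rare, hence the low F1 relative to accuracy).
`cv.per_cell_line()` breaks the same metrics down by cell line, and
`model.fit(...)` / `fit.predict(...)` give direct control over single fits.

The same pipeline is scriptable from the shell:

```bash
synergraph simulate --out study/ --n-drugs 20 --seed 0
synergraph train --synergy study/synergy.csv --drugs study/drugs.csv \
    --expr study/expression.csv --fingerprints study/fingerprints.csv \
    --metric loewe --preset desk --folds 10 --seed 0 --out run/
synergraph ablate --synergy study/synergy.csv --drugs study/drugs.csv \
    --expr study/expression.csv --out ablation/
```

Every run directory receives a manifest and the fully resolved
configuration; re-running with the same manifest reproduces the reports
byte-for-byte.

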