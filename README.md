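# crossfuse

Cross-modal single-cell integration under **weak feature linkage**.

Single-cell and spatial assays increasingly measure *different* feature sets
on *disjoint* sets of cells: a CODEX or CITE-seq antibody panel of 30–200
proteins on one side, the whole transcriptome or genome-wide chromatin
accessibility on the other. Integrating such data ("diagonal" integration)
requires matching cells across modalities using only a handful of linked
features — e.g. a protein and its coding gene — whose cross-modal
correlation is often weak. Methods built for strongly linked modalities
degrade badly in this regime.

`crossfuse` is for computational biologists who need to (1) match cells
between two such datasets, (2) place both datasets in a common embedding,
and (3) quantify how well the integration worked. It also supports
tri-modal integration (e.g. protein + RNA + ATAC) by chaining two pairwise
matchings through the shared middle modality.

## The algorithm

Let `Y ∈ R^{N_y×p_y}` and `Z ∈ R^{N_z×p_z}` be the all-feature matrices of
the two modalities and `Y°, Z° ∈ R^{·×s}` their linked-feature matrices
with column correspondence. Cells may first be aggregated into *meta-cells*
(small Leiden clusters, rows averaged) to denoise and shrink the problem.

1. **Fuzzy smoothing.** Within each modality, build a self-inclusive k-NN
   graph `G` on all features and shrink each row of the linked features
   toward its neighborhood mean: `S(A; w) = wA + (1−w)K⁻¹GA`, where `K` is
   the diagonal matrix of row degrees. This transfers information from all
   features into the weakly linked ones.
2. **Initial matching.** Denoise each smoothed linked matrix by projection
   onto its leading singular subspace, compute the `n_y×n_z` cross-modal
   distance matrix `D°` (1 − Pearson by default), and solve the linear
   assignment problem `min⟨Π, D°⟩` over partial permutation matrices with
   exactly `n_min = min(n_y, n_z)` ones (shortest-augmenting-path solver).
   The matched pairs are the *initial pivots*.
3. **Iterative refinement.** For `t = 1…T`: fit CCA on the current pivot
   pairs of the PCA-reduced all-feature matrices, score **all** cells with
   the canonical loadings, fuzzy-smooth the scores, and re-solve the
   assignment on their cross-distances. Each cycle pulls in more of the
   all-feature information.
4. **Filtering, embedding, propagation.** Keep the `⌈(1−α)·n_min⌉` best
   (smallest-distance) pairs as *refined pivots*; fit a final CCA on their
   all-feature rows to embed every single cell (`Yᵉ = YĈᵧᵉ`, `Zᵉ = ZĈ_zᵉ`);
   match every leftover meta-cell by inheriting the partner of its nearest
   pivot member; expand meta-cell matches to single cells; score each pair
   by the Pearson correlation of its embedding rows and optionally keep
   only the best pair per cell of one modality.

For three modalities, refined pivots of runs 1↔2 and 2↔3 are chained on
the shared modality and a generalized (multiset) CCA on the chained pivot
triples yields one joint embedding for all three datasets.

Evaluation metrics included: cell-type matching accuracy, FOSCTTM (fraction
of cells closer than the true match; 0 is perfect), FOSKNN, silhouette F1
and ARI F1 (harmonic means of modality mixing and cell-type separation).

## Worked example

The synthetic generator draws a shared latent cell state per cell, observes
it through modality-specific linear maps, and controls the number `s` of
linked features and their cross-modal correlation `rho`; the true cell
pairing is recorded, then masked by shuffling.

```python
from crossfuse import PipelineConfig, integrate, matching_accuracy, foscttm
from crossfuse.synthetic import SyntheticSpec, generate

# a CITE-seq-like benchmark: 1,000 cells, 6 cell types, a 100-feature
# "protein" panel weakly linked (rho = 0.5) to 20 of 300 "RNA" features
data = generate(SyntheticSpec(n_cells=1000, n_clusters=6, p_y=300, p_z=100,
                              s_linked=20, linkage_rho=0.5, seed=0))

result = integrate(data.dataset_y, data.dataset_z, data.linkage_yz,
                   PipelineConfig(metacell_size1="off", n_iter=3))

acc = matching_accuracy(result.matching, data.truth.clusters_y, data.truth.clusters_z)
pairs = data.truth.pairing_yz
fos = foscttm(result.embedding.emb_y[pairs[:, 0], :15],
              result.embedding.emb_z[pairs[:, 1], :15])
print(f"matched pairs:          {len(result.matching)}")
print(f"cell-type accuracy:     {acc:.3f}")
print(f"FOSCTTM (0 = perfect):  {fos:.3f}")
```

Output:

```
matched pairs:          1000
cell-type accuracy:     0.977
FOSCTTM (0 = perfect):  0.139
```

With only 20 weakly correlated linked features, 97.7% of matched pairs join
cells of the same type, and on average only ~14% of opposite-modality cells
sit closer than a cell's true partner in the joint embedding — matching
once on the raw linked features alone reaches ~53% accuracy on the same
data (see the ablation in `scripts/acceptance.py`).

The same pipeline is available from the shell: `crossfuse simulate`,
`crossfuse run`, `crossfuse run3` and `crossfuse evaluate` (see `--help`).

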