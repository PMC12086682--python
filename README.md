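# mdmflow

Multimodal diffusion maps for developmental single-cell data.

Joint single-cell assays (SHARE-seq, DOGMA-seq, CITE-seq, ...) measure
several *modalities* — transcriptome, chromatin accessibility, surface
proteins — in the same cells. During differentiation the modalities are
not equally informative everywhere: a lineage decision may play out in
chromatin before it is visible in RNA. `mdmflow` embeds such data by
weighting each modality *per cell* according to how much developmental
signal its local geometry carries, merging the modalities into a single
Markov chain, and eigendecomposing it into a low-dimensional latent
space that preserves trajectories.

## The method

**Cell-specific modality weights.** Let $\mathbf d_c^{m,l}$ be the
distances, measured in the latent space of modality $m$, from cell $c$
to its nearest neighbors found in modality $l$. Distances are
rank-normalized by the modality's empirical CDF of pairwise distances
(estimated from $P = 1000$ sampled cell pairs), and each modality is
scored

$$s_c^m = \sum_{l \ne m} \operatorname{median}\bigl(\mathrm{ECDF}^m(\mathbf d_c^{m,l})\bigr),$$

i.e. a modality scores high for a cell whose cross-modality neighborhood
is expanding in that modality — the signature of an active developmental
process. Scores are smoothed over the neighborhood of the
highest-scoring modality and softmax-normalized with temperature
$\alpha = 10$ into weights $w_c^m$ that sum to 1 per cell.

**Multimodal diffusion maps (MDM).** Per modality, affinities come from
a density-adjusted Gaussian kernel
$\kappa(c_1,c_2)=\exp(-d(c_1,c_2)^2/\varepsilon_{c_1}\varepsilon_{c_2})$
with $\varepsilon_c$ the distance to the $N$-th neighbor (default
$N=20$). Affinities are weighted pairwise,
$K^m_{c_1 c_2} = \tfrac12 (w_{c_1}^m + w_{c_2}^m)\,\kappa^m(c_1,c_2)$,
row-normalized, summed over modalities into the multimodal Markov chain
$K$, and symmetrized, $\hat K = DK + (DK)^\top$. The embedding takes the
top eigenpairs of $\hat K$, scales each eigenvector by its eigenvalue,
and drops the non-informative first pair ($E = 10$ extra pairs are
computed and discarded to guard eigenvector quality).

Around this core the package provides:

- **layout graphs** — fixed-out-degree nearest-neighbor graphs in MDM
  space, optionally re-ranked by externally supplied developmental
  transition probabilities and/or restricted to the next timestamp, for
  ForceAtlas2/UMAP layout engines;
- **diffusion imputation** — $G_{\text{imputed}} = Q\Lambda^t Q^\top G$
  in the retained eigenbasis, with cost independent of $t$, plus
  indicator diffusion for expanding a seed cell set along a
  subtrajectory;
- **topic-based latent modalities** — LDA splits a unimodal count matrix
  into pseudo-modalities (features grouped by most probable topic) so
  the multimodal workflow applies to unimodal data;
- **simulated benchmarks** — the binary-tree (6000 cells, 6 types,
  3 modalities) and rare-transitions (4500 cells, 9 types, 2 modalities)
  developmental datasets with density-based downsampling, ground-truth
  pseudotime and per-type target weights;
- **embedding-quality scores** — signature cohesiveness, velocity
  vector-field alignment, terminal-state separation, and cell-type
  correlation scores.

See `docs/methods.md` for assumptions, parameter defaults, and known
limitations.

## Worked example

```python
import numpy as np
from mdmflow import (make_rare_transitions, compute_weights, run_mdm,
                     target_weights, weight_mse, WeightMatrix, nn_graph)
from mdmflow.benchmarks import knn_label_purity

ds = make_rare_transitions(seed=1)
print(f"dataset: {ds.n_cells} cells, {ds.n_modalities} modalities, "
      f"{len(set(ds.type_labels))} types")

w = compute_weights(ds.modalities, k=60, P=1000, alpha=10.0, seed=1)
targets = target_weights(ds)
print(f"weight MSE vs targets: {weight_mse(w, targets):.4f} "
      f"(uniform: {weight_mse(WeightMatrix(np.full_like(targets, 0.5)), targets):.4f})")

embedding, eig, chain, _ = run_mdm(ds.modalities, weights=w,
                                   n_components=20, n_kernel_neighbor=60, seed=1)
print(f"top eigenvalues: {np.round(eig.eigenvalues[:4], 3)}")
purity = knn_label_purity(embedding.coords, ds.type_labels, k=20)
raw = max(knn_label_purity(m, ds.type_labels, k=20) for m in ds.modalities)
print(f"kNN type purity: MDM {purity:.3f} vs best single modality {raw:.3f}")

graph = nn_graph(embedding, out_degree=60)
print(f"layout graph: {graph.n_edges} edges, 60 per cell")
```

prints

```
dataset: 4500 cells, 2 modalities, 9 types
weight MSE vs targets: 0.1017 (uniform: 0.2500)
top eigenvalues: [2.053 1.63  1.11  1.103]
kNN type purity: MDM 0.689 vs best single modality 0.444
layout graph: 270000 edges, 60 per cell
```

The computed weights recover which modality introduces each lineage
(mean squared error 0.10 against the one-hot ground truth, versus 0.25
for uninformative uniform weights), and the joint embedding separates
the nine cell types better than either modality alone (20-nearest-
neighbor majority-vote purity 0.69 vs 0.44).

The same workflow is available from the shell:

```sh
mdmflow simulate --dataset rare-transitions --seed 1 --out-dir sim/
mdmflow weights --modality sim/modality0.tsv --modality sim/modality1.tsv \
    --k 60 --alpha 10 --seed 1 --out weights.tsv
mdmflow mdm --modality sim/modality0.tsv --modality sim/modality1.tsv \
    --weights weights.tsv --dims 20 --kernel-nn 60 --out embedding.tsv
mdmflow graph --embedding embedding.tsv --variant nn --out-degree 60 --out edges.tsv
```

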