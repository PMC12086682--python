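# Methods

This note documents the models implemented in `mdmflow`, the choices
made where the design was genuinely open, and what the built-in
simulations do and do not establish about real data.

## Model and assumptions

`mdmflow` treats differentiation as a diffusion process on a cell-cell
graph. The core assumptions are:

1. Cells close in a modality's latent space are phenotypically related,
   and local directions in that space trace differentiation.
2. A modality is *informative* for a cell when the cell's neighborhood
   is expanding there: the cell's neighbors found in *other* modalities
   sit unusually far away in this modality's space. The per-modality
   score sums, over the other modalities, the median rank-normalized
   (ECDF-scaled) cross-neighbor distance; the sum never includes the
   modality's own neighbors (a same-modality term would measure nothing
   but the neighbor search itself).
3. A single Markov chain built from per-cell-pair weighted, row-
   normalized, summed modality kernels captures the joint process. The
   chain is symmetrized as `K_hat = DK + (DK)^T` before
   eigendecomposition.

The symmetrization yields a real symmetric operator but *not*
necessarily a positive semi-definite one: nothing in the construction
forbids negative trailing eigenvalues. The eigensolver therefore sorts
by decreasing algebraic value and simply never retains the tail when
`n_components + n_extra + 1 << C`; no spectral correction is applied.
Note `K_hat` is also not stochastic — its leading eigenvalue is close
to 2 rather than 1 — which matters for imputation (below).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `k` (weights) | 20 | neighbors per modality for cross-modality scoring and smoothing |
| `P` | 1000 | sampled cell pairs per modality for the distance ECDF |
| `alpha` | 10 | softmax temperature; must be >= 1 |
| `n_kernel_neighbor` (N) | 20 | neighbor index defining the local kernel bandwidth eps_c |
| `n_graph_neighbors` | max(k, N) | neighbors kept per cell in the sparse affinity graph |
| `n_components` (N dims) | 10 | embedding dimensions |
| `n_extra` (E) | 10 | extra eigenpairs computed and discarded |
| `out_degree` | 30 | edges per node in layout graphs |
| `candidate_pool` | 10 x out_degree | MDM neighborhood searched for high-transition targets |
| LDA iterations | 30 | batch variational inference steps |
| downsampling neighbor | 25 | neighbor index in the cubic density-downsampling law |
| `top_fraction` | 0.05 | cells selected for the cohesiveness score |
| `n_psi` | 3 | neighbors averaged into psi_c and into the vector-field score |

Distances are Euclidean throughout. The ECDF is rank-based, so weights
are invariant to positively rescaling any single modality — modalities
with incomparable units need no prior variance harmonization.

## Numerical and tie-break conventions

- ECDF pair sampling is uniform over distinct ordered pairs, with
  replacement across pairs. The same seed drives every modality's pair
  sample, so byte-identical modalities receive exactly equal scores and
  hence exactly 0.5/0.5 weights.
- Score smoothing is a single pass, averaging over the cell itself plus
  its `k` neighbors from the argmax-score modality. Self-inclusion keeps
  isolated cells stable. Argmax ties break toward the lower modality
  index; consequently, permutation equivariance of the weights holds
  exactly only for cells whose raw scores are untied (ties are measure-
  zero for continuous data but can occur through the discretized ECDF).
- The softmax subtracts the row maximum before exponentiating.
- The kernel kNN graph excludes self-affinities and symmetrizes by
  union; because kappa is symmetric in its arguments, the union assigns
  the same value in both directions. Duplicate cells can give
  eps_c = 0; bandwidths are floored at a machine-epsilon-scaled positive
  value with a warning.
- Cells isolated in every modality keep zero chain rows and land at the
  embedding origin with a warning rather than an error.
- Eigenvectors are unit-norm with the largest-magnitude entry made
  positive (deterministic signs). The dense symmetric solver is used for
  C <= 500, ARPACK with a fixed starting vector above; both paths are
  deterministic and agree to solver precision.
- Layout-graph ranking uses (transition probability descending, distance
  ascending, cell index ascending) everywhere.
- Imputation keeps the full retained basis *including the first
  eigenpair* (the embedding drops it; imputation must not, or mass
  structure is destroyed). Truncation can produce small negative
  imputed values; they are kept unless `clip_nonnegative` is requested.
  Because the leading eigenvalue of `K_hat` exceeds 1, repeated
  application amplifies rather than preserves total signal — imputation
  with small t (1-3) is the intended regime.
- Indicator diffusion zeroes reconstruction noise below
  `1e-10 * max|value|` so a threshold of exactly 0 selects only cells
  genuinely carrying diffused mass. The default selection threshold is
  the 90th percentile of non-seed diffused values (strict inequality);
  a permissive `> 0` rule is available by passing `threshold=0`.
- LDA runs on raw counts (it is a count model); latent modality matrices
  are log-normalized (`ln(1 + count scaled to 10,000 per cell)`) before
  entering MDM. The default "top features" rule keeps features whose
  within-topic probability exceeds the uniform 1/F; a top-k rule is
  available.
- Count downsampling removes exactly `round(p * total)` units via
  multivariate hypergeometric thinning, conserving the total.
- The cohesiveness score's eps-connectivity uses DBSCAN with
  `min_samples = 1`, so every selected cell belongs to a component and
  none silently vanish from the component sum. The psi neighbors are
  searched among all cells, not only selected ones. The vector-field
  embedding score medians over transition-bearing cells only; cells
  without transitions have no defined score.
- The cross-method score rescaling used when comparing multiple
  embeddings (divide by the maximum) is a reporting step, not part of
  the scorers.

## Simulated datasets

The generators fix a documented default geometry; means, covariances and
segment endpoints are overridable.

- **Binary tree** — 6 types A-F, 1000 observations each, 3 modalities.
  Lineage pairs A-B, C-D, E-F are introduced by modalities 1, 2, 3
  respectively: two unit-spaced isotropic Gaussians (sd 0.5) along the
  lineage axis in the introducing modality, and a single common Gaussian
  blob in every other modality (no separating structure), so the
  introducing modality is uniquely informative and one-hot target
  weights are well-defined. Topology: A -> B, then B branches to C -> D
  and E -> F.
- **Rare transitions** — 9 types A-I, 500 observations each,
  2 modalities. The trunk A -> B -> C lies on unit segments laid
  head-to-tail in modality 1 (uniform sampling, no off-axis noise);
  modality 2 introduces three Gaussian branch pairs D-E, F-G, H-I
  leaving the trunk at A, B and C.

Each type is oversampled threefold and downsampled to its target count
with retention probability proportional to the cubed distance to the
25th nearest neighbor. "Probability of being downsampled" is read as
probability of being *retained*: keeping sparse-region points flattens
density, which is what makes downstream kNN structure stable; the
opposite reading would concentrate points and defeat the benchmark's
purpose. Pseudotime orders cells by lineage depth plus normalized
position along the lineage axis; noise shuffles the pseudotime-sorted
order within consecutive blocks of 100 cells, bounding each cell's rank
displacement below 100.

What the simulations emulate: multimodal data where different lineage
segments are visible in different modalities, with realistic type
overlap (adjacent Gaussians at unit spacing with sd 0.5 overlap
heavily). What they do not emulate: count noise (coordinates are
Gaussian/uniform, not sampled counts), dropout, batch effects, doublets,
or modality-specific technical variance. Passing the recovery tests
therefore shows the pipeline extracts cross-modality lineage structure
from geometry; it does not certify performance under count-level noise.

A note on trajectory resolution: the non-introducing modality places a
lineage's cells in one blob, whose kernel inevitably adds "shortcut"
edges between developmentally distant cells. The computed weights
suppress these (trunk cells weight modality 1 at ~0.9) but cannot remove
them, so the fine within-lineage ordering is spread across several
embedding components rather than concentrated in the first. Recovering
the trunk ordering therefore requires a principal-curve readout (the
tests use the one-dimensional diffusion coordinate of the trunk cells'
embedding coordinates), which attains rank correlation > 0.99 with the
generator pseudotime at the published settings (20 dimensions, 60
neighbors).

## Problem sizes in tests

Unit and property tests run on 5-120-cell instances against dense
brute-force oracles (full pairwise-distance kernels, explicit matrix
powers, loop evaluations of the scoring formula). Oracle-equivalence
checks use 40-100 cells; the recovery tests run the full simulated
datasets (4500 and 6000 cells, seconds each on one CPU). The whole suite
completes in well under a minute.

## Known limitations

- Exact (scikit-learn) nearest neighbors only; the backend is a single
  function (`weights._knn_exclude_self`) and could host an approximate
  index for very large C, which would trade the determinism guarantees.
- Layout itself (ForceAtlas2, UMAP) is delegated to external engines via
  the exported edge lists; this package only constructs graphs.
- Velocity fields, optimal-transport couplings, absorption
  probabilities, motif scores and gene signatures are consumed as
  inputs, never computed.
- `fit_topics` is deterministic per seed but, like all variational LDA,
  only locally optimal; topic identity is exchangeable across seeds.
- The eigenvalue-scaled embedding inherits the non-PSD caveat above: on
  pathological graphs the retained spectrum could reach negative values,
  which are reported, not corrected.
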