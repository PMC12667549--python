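# Methods

## Problem and model

Spatial transcriptomics assays measure a gene expression vector at each of N
spatially indexed spots (or cells).  The goal of this package is spatial
domain detection: partitioning the spots into tissue regions with coherent
expression programs (e.g. cortical layers).  The method combines three
ingredients:

1. **Multiscale topological PCA (tPCA)** of the expression matrix
   X ∈ R^{M×N} (M genes × N spots).  For loadings U (M×m) and a
   column-orthonormal spot embedding Q (N×m) it minimizes

       ‖X − U Qᵀ‖₂,₁ + β ‖Q‖₂,₁ + γ Tr(Qᵀ L_P Q),   QᵀQ = I_m,

   where ‖A‖₂,₁ = Σ_i ‖row_i(A)‖₂ promotes row sparsity (genes that cannot
   be reconstructed anywhere are down-weighted instead of dominating the
   fit), and L_P is an *accumulated persistent Laplacian*: the spots are a
   point cloud in expression space, a k-nearest-neighbor graph is built at
   each scale of a strictly decreasing schedule k = 15, 12, 9, 6, and

       L_P = Σ_k ζ_k L^k,    ζ_k ∈ {0, 1},

   sums the unweighted graph Laplacians of the nested snapshots that are
   "switched on".  Shrinking k yields a filtration (edge sets are nested by
   construction: neighbor lists are computed once at the largest k and
   truncated), and the zero-eigenvalue multiplicity of each L^k is the
   Betti-0 number — the component count — of that snapshot.  The trace
   penalty pulls spots that stay kNN-adjacent across scales toward nearby
   embedding rows.

2. **Alignment with a spatial embedding.**  Each of the 2^4 − 1 = 15
   scale-combination embeddings Q_ζ is paired with a spatial embedding Z
   (from any spatially informed encoder, loaded from file; a built-in
   baseline encoder — spatial-kNN neighbor-mean smoothing followed by PCA —
   serves for testing and as a simple default).  The cross-product
   eigenproblem (Zᵀ Q_ζ)(Q_ζᵀ Z) q = λ q is solved by SVD of M = Zᵀ Q_ζ
   after column centering and unit-norm column scaling: q are left singular
   vectors, λ the squared singular values, and the paired direction
   p = Mᵀq/λ re-normalized.  The aligned feature matrix concatenates both
   views' canonical scores, F = [Z q₁..q_c | Q p₁..p_c], ordered by
   descending λ.

3. **Consensus clustering.**  Each aligned F is clustered into the
   requested number of domains (Gaussian mixture or Leiden); the ensemble
   is summarized by the co-association matrix C (fraction of members
   co-clustering each spot pair) and average-linkage agglomerative
   clustering of 1 − C cut at the requested domain count gives the final
   domains.  Alternatively (`mode='rsi_select'`) the partition of the
   single member maximizing the Residue-Similarity Index is adopted.

## Preprocessing

Standard count preprocessing: genes detected (value > 0) in fewer than 3
spots are removed first, then spots expressing fewer than 100 remaining
genes; each spot column is scaled to a common total of 1e4 and
log1p-transformed; the top 3000 genes by normalized dispersion
(variance/mean of the expm1 values, z-scored within 20 mean-quantile bins,
ties to the higher mean then input order) are kept.  The gene-before-cell
filter order matters and is fixed.  The dispersion recipe is the de-facto
standard for this pipeline sentence; it is implemented directly (≈25
lines) and is swappable.

## Numerical choices

- **tPCA solver.**  Alternating IRLS: each L2,1 term is majorized by a
  weighted quadratic ‖a‖ ≤ ‖a‖²/(2c) + c/2 with c the current row norm
  floored at `eps` (1e-8).  Under QᵀQ = I the U-update is exact (U = XQ)
  and eliminating U turns the Q-update into an exact eigenproblem: the m
  smallest eigenvectors of β D₂ + γ L_P − Xᵀ D₁ X.  Both steps minimize
  the majorizer, so the objective trace is non-increasing (slack 1e-9 in
  tests; the `eps` floor can in principle produce O(eps) violations on
  exactly reconstructed rows, not observed in practice).  In Frobenius
  mode D₁ = I, which makes the profiled Q-step exact for the squared-norm
  objective.  Q is initialized from the top-m right singular subspace of
  X; each column's largest-magnitude entry is made positive (sign
  determinism).  Convergence is declared on relative objective change
  (tol 1e-6, max 100 iterations); defaults m = 50, β = γ = 1.
- **Eigensolver.**  Dense LAPACK (`scipy.linalg.eigh`, index subset) for
  N ≤ 2000; above that a seeded ARPACK `eigsh` on a matvec operator
  (sparse L_P plus a rank-M term, never forming the N×N matrix).  The two
  agree to ~1e-6 on overlapping sizes (tested).
- **kNN ties** are broken toward the lower spot index via a stable argsort
  with exact floating-point distance comparison; graphs are therefore
  deterministic and permutation-equivariant.
- **Union symmetrization.**  Neighbor relations are asymmetric; an edge
  exists when either endpoint lists the other.  This keeps every L^k
  symmetric PSD, which the trace regularizer requires.  (An intersection
  rule would also be symmetric; union matches the edge-set definition used
  for the weighted graph.)
- **Gaussian affinities** W_ij = exp(−‖x_i − x_j‖²/η) are available for
  the weighted Laplacian variant; η defaults to the median of squared edge
  distances (median heuristic).  The filtration Laplacians that enter L_P
  are unweighted (−1 off-diagonal entries).
- **Alignment scaling.**  The cross-product is taken after centering and
  unit-norm column scaling, so its entries are correlations and λ is a
  squared correlation in [0, 1] whenever each view's columns are mutually
  orthogonal (always true for the tPCA view).  There is no within-view
  whitening by default — the eigenproblem is solved as printed above,
  which is a partial-least-squares flavor of CCA; `whiten=True` gives the
  classical variant.  Without the column scaling the two views' score
  scales differ by orders of magnitude and downstream mixture clustering
  degrades markedly.  The cost of per-column scaling is that λ is no
  longer exactly invariant to orthogonal rotations of a view's columns
  (it is with `scale=False`).
- **`c='auto'`** keeps every canonical pair with λ > 1e-10 (a rank guard);
  a rank-0 cross-product is an error.
- **GMM clustering** (the Mclust stand-in): full covariance, k-means
  initialization, 10 restarts keeping the best likelihood, `reg_covar`
  1e-6, seeded.  **Leiden**: shared-nearest-neighbor graph (k = 15,
  weights 1 + shared-neighbor count), RB-configuration partition,
  resolution bisected (≤ 30 steps, geometric midpoint) to hit the
  requested cluster count; closest achievable with a warning otherwise.
- **Consensus tie-breaking.**  Co-association entries are multiples of
  1/n_members, so tied merge decisions are common.  scipy's deterministic
  merge order is used; consensus is reproducible exactly, and
  permutation-equivariant whenever no merges are tied.  No index-based
  rule can be both deterministic and permutation-equivariant under ties.
- **RSI.**  With D the pairwise distance matrix of the features and
  d_max its maximum: residue_i = Σ_{j∉class(i)} D_ij scaled by its
  maximum over i; similarity_i = mean_{j∈class(i), j≠i} (1 − D_ij/d_max)
  (singletons score 1); RSI = mean_i (residue_i + similarity_i)/2.  This
  operationalizes "between-class separation vs within-class similarity";
  the combination and normalizations are this package's documented
  choice — the originally proposed score may differ in constants.
- **LR edge enrichment.**  Observed score = mean over graph edges of the
  symmetric product (x_{l,i}x_{r,j} + x_{l,j}x_{r,i})/2 of log
  expression; the null permutes whole spot profiles (preserving gene-gene
  correlation within a spot) with the graph fixed, n_perm ≥ 100 draws;
  z = (obs − null mean)/null sd, flagged degenerate (z = 0) when the null
  is constant.  Permutations are drawn in spot-id-sorted canonical order,
  making z exactly invariant to joint relabeling of spots.

## Synthetic data

The generator emulates a sectioned layered tissue: spots on a rows × cols
lattice; `strips` layout slices the lattice into horizontal bands (one per
domain, as even as possible), `voronoi` assigns domains by nearest seeded
center.  Counts are negative binomial (gamma-Poisson) with variance
μ + μ²/θ; baseline gene means are log-normal; each domain's marker block
multiplies μ by 2^log2fc inside the domain; independent dropout zeroes
entries with fixed probability.  Defaults (the layered preset): 20 × 75
lattice, 5 strips of 300 spots, 300 genes, 40 markers per domain,
log2fc 1.5, baseline log-mean (1.0, 0.5), θ = 10, dropout 0.1.

What the generator does **not** emulate: spatially smooth within-domain
expression gradients, cell-type mixtures within a spot, platform-specific
noise (optical crowding, segmentation error), histology.  Passing the
recovery tests therefore shows the machinery is correct and well
calibrated on planted block structure, not that any particular real-tissue
accuracy will be reached.

## Problem sizes used in tests and the acceptance script

The end-to-end recovery check runs the full layered preset (1500 spots,
300 genes, all 15 scale combinations) once; the ten-seed sweeps (no-signal
control, RSI-accuracy concordance) use a reduced preset (12 × 30 lattice,
150 genes, 20 markers per domain) chosen so a sweep completes in a few
minutes on one core.  Solver and spectral oracles run at N ≤ 200.

## Known limitations

- Only the order-0 (graph) persistent Laplacian is implemented; higher
  simplicial orders and distance-threshold (Vietoris-Rips) filtrations are
  out of scope.
- No re-implementation of deep spatial encoders (STAGATE, SpaceFlow,
  GraphST); their embeddings are consumed from file, and the baseline
  encoder is a deliberately simple linear stand-in.
- Leiden's resolution bisection cannot always reach an exact cluster
  count (cluster number is not monotone in resolution in pathological
  cases); the closest count is returned with a warning.
- The ζ-ensemble costs one tPCA solve per combination (15 by default);
  at ~2×10⁴ spots a partial eigensolver keeps each iteration tractable
  but the ensemble remains the dominant cost.
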