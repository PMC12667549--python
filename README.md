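# mcist

Multiscale cell–cell interactive spatial transcriptomics analysis: spatial
domain detection from spot × gene count matrices by persistent-Laplacian-
regularized sparse PCA, alignment with a spatial embedding, and consensus
clustering — plus unsupervised embedding selection (RSI) and ligand–receptor
edge enrichment.

## Who this is for

Analysts of spatially resolved transcriptomics data (Visium, StereoSeq,
MERFISH, BaristaSeq, STARmap, …) who want to segment a tissue section into
spatial domains by combining *transcriptional* neighborhood structure at
several scales with a *spatial* representation from any spatially informed
encoder.

## The model

For an expression matrix **X** ∈ R^{M×N} (M genes, N spots), topological PCA
finds loadings **U** (M×m) and an orthonormal spot embedding **Q** (N×m)
minimizing

```
‖X − U Qᵀ‖₂,₁ + β ‖Q‖₂,₁ + γ Tr(Qᵀ L_P Q),    s.t. QᵀQ = I_m
```

where ‖·‖₂,₁ is the sum of row-wise Euclidean norms (row sparsity) and

```
L_P = Σ_k ζ_k L^k,   ζ_k ∈ {0,1},   k = 15, 12, 9, 6
```

accumulates the unweighted graph Laplacians of a *kNN-induced filtration*:
nested k-nearest-neighbor graphs of the spots in expression space, from
community scale (k = 15) down to immediate transcriptional neighbors
(k = 6).  The zero-eigenvalue multiplicity of each L^k counts the connected
components (Betti-0) of that snapshot, so L_P encodes multiscale
connectivity in a single PSD regularizer.

Each of the 15 scale-combination embeddings is aligned with a spatial
embedding **Z** through the cross-product eigenproblem
(Zᵀ Q)(Qᵀ Z) q = λ q (solved by SVD; λ = squared canonical correlation),
clustered (Gaussian mixture or Leiden), and the ensemble is merged through
a co-association matrix and agglomerative consensus.  A label-free quality
score, the Residue-Similarity Index, can instead select the single best
scale combination.  See `docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
from mcist import MCIST, io_prep, synth

# synthetic layered tissue: 12x30 lattice, 5 strip domains, planted markers
ds = synth.dlpfc_like(seed=0, grid=(12, 30), n_genes=150, n_markers_per_domain=20)
X = io_prep.qc_filter(ds.expression, min_cells_per_gene=3, min_genes_per_cell=20)
X = io_prep.normalize_log(X)       # per-spot total to 1e4, log1p
X = io_prep.select_hvg(X)          # top genes by normalized dispersion

model = MCIST(X, coords=ds.coords, n_domains=5)
results = model.fit(seed=0)
print(results.summary())
nmi, ari = synth.evaluate_recovery(results.consensus, ds.truth)
print(f"NMI vs planted truth: {nmi:.3f}   ARI: {ari:.3f}")
```

Output:

```
MCIST spatial domain detection
==============================================
spots                 360
genes                 150
filtration scales k   (15, 12, 9, 6)
scale combinations    15
member clustering     gmm
mode                  ensemble
domains requested     5
domains found         5
domain sizes          0:91, 1:91, 2:60, 3:60, 4:58
RSI per member        min=0.497 max=0.577

NMI vs planted truth: 0.933   ARI: 0.948
```

The five consensus domains recover the planted strips almost exactly
(NMI 0.93); the per-member RSI range shows which scale combinations
produced tighter, better-separated embeddings.  `results.plot_domains()`
draws the spots colored by domain; `results.domains_frame()` gives a tidy
spot → domain table.

With real data, load counts and coordinates instead of generating them:

```python
model = MCIST.from_files("filtered_feature_bc_matrix/", "coords.csv",
                         n_domains=7)
results = model.fit(seed=0)
```

and pass `spatial_embedding=mcist.align.load_embedding("stagate.tsv", ids)`
to use a deep spatial encoder's output in place of the baseline encoder.

## Command line

```bash
mcist synth --preset dlpfc-like --seed 0 --out ds/
mcist preprocess --input ds/ --format mtx_dir --out prep/
mcist run --expr ds/ --coords ds/coords.tsv --n-domains 5 --seed 0 --out run/
mcist lr-enrich --expr ds/ --coords ds/coords.tsv --pairs pairs.tsv \
      --graphs spatial,k15,k6 --out enrichment.tsv
```

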