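# Methods

## Model

A single-cell expression matrix (genes × cells), after suitable
preprocessing, is treated as a random matrix perturbed by a low-rank
signal:

    X̃ = X + P

`X` holds within-phenotype biological variability plus technical noise
(i.i.d. entries, mean 0, variance 1 after preprocessing); `P` holds the
noise-free expression profiles, identical for cells of the same
phenotype, so its rank equals the number of distinct phenotypes minus
the shared trend. Random-matrix theory says the singular values of `X`
(divided by √n_genes) fill the Marchenko-Pastur (MP) bulk
[1 − √c, 1 + √c], where c = n_cells / n_genes, whatever the noise
distribution. Structure shows up as singular values above the bulk.

Low-rank perturbation theory connects an outlying scaled singular value
γ of `X̃` to the signal singular value θ of `P` through

    γ² = (θ² + 1)(θ² + c) / θ²,      θ > c^(1/4),

and gives the squared cosine of the angle between the measured and
signal cell-singular vectors,

    φ = 1 − c(1 + θ²) / (θ²(θ² + c)),

with the gene-side conjugate φ_g = 1 − (c + θ²)/(θ²(θ² + 1)). The
clusterability score is phiclust = max_i φ_i over the significant
components (g-phiclust analogously). φ = 0 at the detection threshold
θ = c^(1/4): weaker signal leaves no spectral trace at all, which is
why subclusters of a phiclust-0 cluster also score 0 and over-clustering
of noise is prevented. A multiplicative-noise variant
(X̃ = (I+P)^(1/2) X) is provided with its own θ(λ) inverse and φ
formula; that φ saturates at 1/(c+1) rather than 1, which is
implemented as printed and not renormalized.

## Gating

A component is significant only if

1. its eigenvalue λ = γ² exceeds a Tracy-Widom threshold
   λ* = μ + σ·q_TW1(1 − α_tw), with Johnstone's centering and scaling
   μ = (√(n_genes−1) + √n_cells)²/n_genes and
   σ = (√(n_genes−1)+√n_cells)(1/√(n_genes−1)+1/√n_cells)^(1/3)/n_genes
   (default α_tw = 0.01); and
2. its cell-singular vector deviates from normality (Shapiro-Wilk,
   Benjamini-Hochberg adjusted across the threshold-passing set,
   default α_sw = 0.05; vectors longer than 5000 entries are
   subsampled, inside the W-test's validity range). Singular vectors of
   a pure noise matrix are normal, so a normal-looking vector above the
   threshold is treated as noise.

TW(β=1) quantiles come from the Chiani shifted-gamma approximation
(Gamma(k=46.446, θ=0.18605) − 9.84801), which matches the first three
moments of TW1 and whose 95th/99th quantiles agree with published
values to < 0.001; the analytic threshold is verified in the test suite
against the empirical 99th percentile of 1000 simulated null matrices
(within 2%).

The bulk itself is tested: singular values at or below λ*, excluding
the transcriptome mode, are compared to 1000 draws from the MP law
(inverse-CDF sampling on a numerically integrated density) with a
two-sample Kolmogorov-Smirnov test; p-values are BH-adjusted across
clusters. A failing bulk means the null model does not apply and the
score should not be trusted.

## Preprocessing

Per cluster: every cell is scaled to the median total count, log1p is
applied, zero-variance genes are dropped (no expression floor — all
genes are kept in the analysis), and the matrix is standardized
gene-wise then cell-wise, iterating the two sweeps to a fixed point
(ending on the cell step). Population (1/n) standard deviations keep
the Frobenius norm at exactly n_genes·n_cells, the MP scaling
convention. The exact column constraint annihilates the all-ones gene
direction, pinning the transcriptome mode — the expression trend shared
by all cells — at singular value 0, where it is excluded from the KS
bulk and never a significance candidate. The original normalizations
behind the published datasets (scran pooling, Seurat LogNormalize) are
deliberately replaced by this single default: the double
standardization dominates, and the MP fit of the resulting bulk is the
acceptance check.

## Confounder correction

Depth, mitochondrial/ribosomal load, cell-cycle or stress scores, and
pseudotime drive variance that looks like structure. Each significant
cell-singular vector is regressed (OLS, intercept + all covariates) on
the covariate table; the squared singular value is shrunk by
(1 − adjusted R²) (negative adjusted R² clamped to 0), and θ and φ are
recomputed from the corrected value. A corrected eigenvalue at or below
the TW threshold contributes φ = 0 — θ(γ) is undefined inside the bulk,
and a corrected value there is indistinguishable from noise.
Per-covariate attribution uses single-covariate regressions; the
correction itself always uses the joint fit. The cell-cycle/stress
scores are z-scored gene-set means, not Seurat's control-bin scheme —
the regression only needs a covariate correlated with the nuisance
process.

## Uncertainty

The signal is approximated as P̂ = √n_genes Σ θ_i U_i V_iᵀ over the
significant components (perturbation-theory θ, not the measured γ, so
the sampled matrices reproduce the measured spectrum once noise is
added). Each of n_boot ≥ 50 draws adds a fresh i.i.d. standard-normal
matrix and reruns SVD plus both gates — no re-preprocessing, no
confounder step — and draws where no component survives contribute
phiclust = 0, so the error bar reflects detection failure near the
threshold. σ₊/σ₋ are RMS deviations of draws above/below the point
estimate.

## Ground-truth validation

On simulated data with known labels, the ceiling for any clustering
algorithm is the Bayes error of the label-conditional distributions of
the informative coordinates. An approximate Bayes classifier (one
full-covariance Gaussian per true cluster on the singular vectors above
the MP edge, maximum-likelihood fit, diagonal fallback for tiny
clusters, assignment by highest density with ties toward the larger
cluster) yields the theoretically achievable ARI (tARI) and silhouette
(tSIL). The MP edge, not the TW threshold, gates the classifier here:
near-threshold signal the outlier test would reject still carries
usable separation, and gating it away would let empirical methods beat
the "ceiling". The validation grid checks that seeded k-means never
exceeds tARI beyond noise and that phiclust tracks tARI (Pearson
r ≥ 0.9 across the grid). tARI is defined for ≥ 2 clusters; behavior
beyond two is exposed but experimental.

## Synthetic data

- **planted_rank_one** — X + √n_genes·θ·uvᵀ at 350 genes × 201 cells;
  u, v two-block vectors (200 positive genes, 67 positive cells, entries
  ±1/√n); noise standard normal or Poisson(1) centered/scaled, so θ is
  exactly the scaled signal singular value. The Poisson variant checks
  universality of the MP bulk.
- **splatter_lite** — gamma-Poisson groups: gene means Gamma(0.6,
  rate 0.3), per-group DE with probability de_prob and LogNormal(0.1,
  0.4) factors (inverted w.p. ½), library sizes LogNormal(9.5, 0.2)
  (≈13k counts — a typical droplet depth; the generator has no extra
  biological CV, so this depth also sets the merge-sensitivity crossing
  measured in the acceptance study at a DE fraction of 0.03), counts
  Poisson. No BCV trend, no dropout logistic, no batch effects: the
  claims validated here are random-matrix-level, and passing tests
  speak to group-structured overdispersed counts, not to every
  moment of real droplet data.
- **weighted_mixture** — two synthetic clusters c₁ = α·a + (1−α)·b,
  c₂ with flipped weights, from two cleaned source clusters; each
  synthetic cell consumes a distinct source cell. Clean-up flattens the
  source spectra: outliers to the bulk upper edge, transcriptome mode
  restored at 1.5× the edge. α = 0.5 gives identically distributed
  clusters (phiclust 0); α → 0 or 1 maximal separation.
- **differentiation_path** — noise plus a rank-1 term linear in a
  latent ordering (recorded as true pseudotime); the pseudotime
  covariate should zero the score.
- **multiplicative_planted** — (I+P)^(1/2)X with the spike scaled so
  the planted θ is in MP units: the outlier sits at
  λ = (θ+1)(θ+c)/θ, the forward map inverted by the multiplicative
  θ(λ).

All generators draw from named substreams of a single seed and are
bit-reproducible.

## Numerical choices

θ(γ) uses the rationalized branch (d + √(d²−4c))/2, d = γ² − (c+1),
algebraically identical to 2c/(d − √(d²−4c)) but stable for strong
signal; a forward-identity check to 1e-10 guards it. MP sampling
integrates the density on a 20001-point grid. SVD signs are fixed by
making the largest-magnitude entry of each cell-singular vector
positive. Matrices with more cells than genes are transposed internally
(c ≤ 1 always), with vector roles swapped. When two components tie on
φ, the one with larger γ is reported. Clusters below 10 cells are
rejected; below 50, a warning notes that the asymptotic null is
unreliable.

## Study sizes

The standard studies (phiclust.studies, also run by
scripts/acceptance.py) use: pure-noise null 2000 genes × 500 cells,
50 seeds; merge sensitivity 2000 × 600 (three equal groups, two
merged), DE grid 0.01–0.10, 10 seeds per point; differentiation path
1000 × 300, gradient θ = 5, 20 seeds; k-means split 2000 × 600,
20 seeds. The Monte-Carlo overlap oracle runs at 2000 × 1200 over
20 seeds, and TW calibration uses 1000 null 350 × 201 matrices.

## Limitations

Scores concern detectability of *linear* low-rank structure after
double standardization; strongly nonlinear manifolds may be
under-scored. The confounder step is linear OLS: a nuisance process
nonlinearly related to its covariate is only partially removed (the
differentiation-path study uses a pattern linear in pseudotime). Small
clusters (< 50 cells) sit far from the asymptotic regime. The
multiplicative φ is not on the same [0, 1) scale as the additive one.
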