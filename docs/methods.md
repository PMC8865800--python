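# Methods

## The model

Observed UMI counts for gene *j* in cell *i* are modeled as

    Y[j,i] ~ Poisson( ( Σ_l X[j,l] D[l,i] + Σ_c Z[j,c] C[c,i] ) · G[i] )

with a known nuisance design `D` (r × cells), known per-cell size
factors `G`, nonnegative nuisance expression profiles `X` (genes × r),
nonnegative cluster profiles `Z` (genes × k), and hard one-hot cluster
memberships `C`.  The design typically holds patient one-hot blocks and
min–max-scaled technical covariates; anything encoded there is absorbed
by `X`, so the cluster profiles `Z` capture cell states shared across
patients.  Additivity is the key assumption: patient-specific and
phenotypic transcription act on the rate as a sum, which is appropriate
when the two programs control largely non-overlapping gene sets.  The
observed counts are a mixture of Poisson components with unequal rates
and are therefore overdispersed marginally even though each component is
Poisson.

### Estimation

Hard (classification) EM:

* **M-step** — with memberships fixed, each gene's parameters solve a
  nonnegative Poisson-rate regression against the stacked design
  `[D; one-hot(C)]` with exposure `G`.  We use multiplicative
  (KL-divergence) updates, warm-started between EM iterations, because
  they respect nonnegativity and never decrease the likelihood from any
  starting point; with a warm start the whole EM trace is monotone.
  Inner iterations are capped (100 on the first sweep, 10 thereafter —
  a partial M-step still yields a generalized EM) with a relative
  parameter-change tolerance of 1e-8.  All-zero genes go to exactly
  zero rates.
* **E-step** — each cell is assigned to the cluster maximizing its
  Poisson log-likelihood; ties break to the lowest index.
* **Empty clusters** — an emptied cluster's profile is reseeded from the
  worst-fitting cell's denoised profile.  No cell is moved by the
  reseed itself, so the likelihood is unchanged and monotonicity is
  preserved; the next E-step adopts the cluster only if it helps.
  (Forcibly reassigning cells would break the monotone trace.)
* **Initialization** — each restart draws k exemplar cells by
  k-means++ (D²-weighted) sampling and uses their depth-normalized
  counts as initial cluster profiles.  Restarts alternate between two
  seeding views: raw `log1p(Y/G)` and the nuisance-corrected residual
  `log1p(max(0, Y/G − X₁D))` where `X₁` is a quick single-cluster
  nuisance-only fit.  Which view separates the cell groups better is
  data-dependent (strong patient effects can drown group structure in
  the raw view), so cycling both makes restart diversity robust.
  Uniform random memberships are *not* used: they average every initial
  centroid to the global mean and hard EM cannot break that symmetry.
* **Convergence** — stop when the membership vector is unchanged or the
  relative log-likelihood change is < 1e-8; at most 200 iterations.
  The best of `n_init` restarts (by log-likelihood) is returned;
  everything is deterministic given the seed.

Restart counts: 10 per k inside a BIC scan; the benchmark adapter uses
50 (a final production fit deserves an order of 100–200 — hard EM needs
restart diversity to isolate small cell groups).

Log-likelihoods omit the constant `log Y!` terms throughout; they cancel
in every comparison made here, but reported values are comparable only
within this implementation.

### Model selection

BIC = −2 log L + p·ln(n_cells) with p = n_genes·(r + k) free rate
parameters; hard memberships are not counted (a stated convention).  The
scan default is k = 1..25 with 10 restarts each.  Because clusters that
merely mirror nuisance factors already explained by `D` buy no
likelihood, the penalty eliminates them, which is what lets the method
favor solutions where confounder effects are fully absorbed.

### Denoising

Given fitted `X`, the nuisance-free expression of entry (j, i) is the
per-entry MLE of `Y ~ Poisson((XD + Z̃)·G)`, which has the closed form
`Z̃ = max(0, Y/G − Σ_l X[j,l] D[l,i])` — depth-normalized expression
minus the nuisance contribution, clipped at zero.

## Differential expression

For clusters g1, g2 and gene j, H0 ties the two rate entries,
H1 frees them.  Both are fitted conditionally on the nuisance profiles
`X` and the memberships: each group rate (H1) and the pooled rate (H0)
is a 1-D concave maximization in z ≥ 0, solved by bisection on the score
(the root is bracketed in [0, ΣY/ΣG]; 90 halvings reach machine
precision).  Conditioning H1 the same way as H0 guarantees a
nonnegative statistic and reduces exactly to the classical two-sample
Poisson LRT when r = 0.  The p-value is the upper χ²(1 df) tail at twice
the log-LRT (one parameter difference).  FDR control is
Benjamini–Hochberg.  The all-pairs scan keeps, per pair, the top 1000
genes by statistic among those with FDR < 0.01 and returns the union
plus the full genes × comparisons matrix of signed statistics
(sign = sign of the lower-index cluster rate minus the higher-index
one — unsigned statistics would conflate up- and down-coregulation).

## Signature discovery

1. Pearson correlations between genes over the signed LRT statistics
   across all comparisons; edge iff ρ > 0.8 (strict) and p < 0.01, with
   p from t = ρ√((n−2)/(1−ρ²)) on n = number of comparisons.
   Zero-variance rows are dropped with a warning.
2. Walktrap communities (walk length 3), cut at maximal modularity;
   communities with more than 30 genes proceed.
3. Coreness filter: with n_max = number of genes at the community's
   maximum coreness, keep exactly those genes if n_max > 30, else the
   top 30 by coreness (ties lexicographic).
4. Optionally, hypergeometric overrepresentation against user gene sets
   (retained iff FDR < 0.05 and set size < 500), then a redundancy
   filter: genes in no enriched set are dropped, the binary gene ×
   enriched-set membership matrix is co-clustered by alternating
   two-way k-means (default 3 × 3 blocks, a few refinement sweeps),
   and any gene block with < 3% presence in **any** gene-set block is
   excluded.

## Scoring

* **ssGSEA** — per unit, genes are ranked by expression (descending,
  stable ties) and the score accumulates the difference between the
  weighted in-set ECDF and the uniform out-of-set ECDF along the
  ranking.  Weights are rank-normalized positions to the power
  α = 0.25.  Using ranks rather than raw values makes the unnormalized
  score exactly invariant to strictly increasing per-unit transforms;
  scores are optionally rescaled by their range across units.
* **Permutation p-values** — the null is the score distribution of
  size-matched random gene sets (gene-label permutation);
  p = (1 + #{null ≥ observed}) / (n_perm + 1), so p is never zero.
  Stress-high iff p < 0.05, stress-low iff p > 0.5, otherwise
  indeterminate.
* **CCA stress score** — both blocks (probed ISH expression ×
  treatment-phase indicator + reference score) are column-standardized;
  the first canonical pair comes from the SVD of the whitened
  cross-covariance.  Constant columns are dropped with a warning;
  a rank-deficient covariance is ridge-regularized (warned).  The
  per-sample score is the first canonical variate of the ISH block,
  sign-fixed to correlate nonnegatively with the reference.  Empirical
  p-values permute the sample labels of the target block
  (10⁵ permutations by default; configurable down for desk scale).

## Synthetic data

`simulate_primus` draws directly from the generative model: gamma
baseline rates, cluster profiles = baseline × exp(separation · N(0,1))
(separation 0 ⇒ no phenotypic signal), gamma nuisance profiles,
lognormal size factors, uniform memberships, Poisson counts.  The
recorded truth is gauge-fixed: with patient one-hot blocks summing to
the all-ones row, a per-gene constant can move between `X` and `Z`;
the canonical split puts the per-gene minimum over nuisance profiles
into `Z`, and recovery comparisons apply the same shift to fits.

`simulate_population` emulates a splatter/splatPop-style population
simulation: gamma(shape 0.6, rate 0.3) gene means (splatter's
convention), per-sample lognormal multipliers on all genes (sdlog 0.3)
standing in for individual/eQTL effects, per-group multiplicative DE on
a random 10% of genes (lognormal fold changes, meanlog 1.0, sdlog 0.5,
half up / half down), lognormal library sizes (sdlog 0.2), Poisson
counts (an optional negative-binomial dispersion knob defaults off).
These effect sizes describe strongly modular tumor-state programs and
were fixed once as the study conditions.  Three compositional scenarios
over 6 samples × 5 groups are preset: (i) all groups in all samples
(3000 cells × 5000 genes); (ii) three sample pairs sharing no groups
and one sample-private group (1400 cells × 5000 genes); (iii) the
composition of (ii) with per-sample cell counts 20..2000.  Desk-scale
presets divide genes and cells by 5, preserving composition.

What the generator does **not** emulate: genotype-driven eQTL effect
sharing between samples, gene length/GC biases, batch chemistry
effects, dropout beyond Poisson sampling, doublets, or ambient RNA.
Passing recovery tests on these simulations therefore demonstrates
correctness of the estimation machinery and robustness to
sample-multiplicative confounding — not performance on any particular
real dataset.  Note the simulation is multiplicative while the model is
additive; at desk scale this misspecification occasionally makes the
likelihood prefer splitting a large heterogeneous group over isolating
a ~15-cell sample-private group (the private cells still cluster
together).  With 5× more cells and genes the true partition dominates.

## Quality control

Cell filtering mirrors a two-step scheme: a global cutoff of 15%
mitochondrial UMIs plus per-class thresholds (cancer / stromal /
immune) on reads (8192 / 4096 / 2896), UMIs (4075 / 2048 / 1024),
detected genes (1552 / 1024 / 512) and mitochondrial percentage
(12 / 7.5 / 7.5), all config-driven.  A marker-combination doublet flag
(PAX8 / DCN / PTPRC co-expression) treats "expressing" as count ≥ 1 by
default; the threshold is configurable since the notion is not sharply
defined.  Size factors default to total-count / median-total; any
positive per-cell vector (e.g. scran pooled factors) can be supplied.

## Numerical choices and limitations

* Ties break to the lowest index everywhere (memberships, ranking).
* The LRT conditions on fitted `X` and memberships; post-clustering
  selection effects on DE p-values are not corrected (calibration holds
  when memberships are right).
* BIC's parameter count ignores memberships; alternatives would shift
  the scan by a roughly k-independent amount.
* The correlation-network p-value uses the t approximation, adequate at
  ≥ 15 comparisons.
* The alternating k-means bicluster step is a simple co-clustering; the
  block counts (3 × 3) are configurable and the filter is insensitive
  to them when presence is strongly bimodal.
* Comparator integration methods are not re-implemented; the benchmark
  exposes an adapter contract (labels in, labels out) for importing
  external results.
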