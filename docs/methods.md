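# Methods

## Model

Each biological process is modelled as a 1-dimensional manifold in the
expression space of its gene set: samples differ along a single latent
progression coordinate (e.g. tumor progression), and the process's genes are
smooth functions of that coordinate.  The method estimates the manifold as a
**local principal curve** and reads each sample's score off the curve's
arc-length parameterization.  Two assumptions matter:

- the manifold is connected and unbranched (one strand; branching is out of
  scope), and
- reference (normal) samples cluster near one end, which defines both the
  normalization baseline and the curve's origin.

### Preprocessing

With references, each gene is centered on the reference mean and divided by
the reference **variance** (the literal method description; `scale: sd`
selects the conventional standard-deviation scaling).  The variance
estimator is unbiased (n−1) throughout.  Genes with zero reference variance
are dropped — imputation or fallback scaling would silently distort a
variance-sensitive method.  Without references every gene is z-scored across
all samples; this path is also what makes strictly-noise-free simulations
usable (noise-free references have zero variance by construction).

Genes whose variance falls strictly below the 25% variance quantile are
removed.  The threshold is the order statistic `sorted_vars[floor(q·G)]`,
chosen so that with all-distinct variances exactly `floor(q·G)` genes are
removed and ties at the threshold survive.

### Mapping space

PCA is fitted per gene set over all samples (tumor + normal).  The retained
dimension k counts leading components whose tumor-score variance exceeds 10%
of the normals' **total** variance, scanned in decreasing-eigenvalue order
until the first failure, floored at 1.  The alternative per-component
reading (tumor variance > 1.1 × normal variance on the same component) is
exposed via `component_compare="per_component"` but is not the default: PCA
noise components are selected to maximize (mostly tumor) variance, so their
tumor/normal variance ratios concentrate *above* 1.1 and the per-component
rule systematically over-selects.  Without references, k is the smallest
number of components explaining 80% of total variance.

k is additionally capped (`max_components`, default 4).  Trailing components
carry sampling noise, and the kernel-weighted curve search degrades quickly
with dimension: with h = 10% of range per dimension the effective
neighborhood shrinks by roughly e^{−1/(2·0.16)} ≈ 2.7× per added dimension,
so beyond ~4 dimensions the local center of mass collapses onto single
points.  Omitting redundant components for curve stability is part of the
method's design.

### Curve fitting

Gaussian product kernel, H = diag(h_j²), h_j = `bandwidth_fraction` (default
0.10) × range of dimension j; a zero-range dimension falls back to the
pooled SD.  The traversal alternates local center of mass, local first
eigenvector (sign-continuous with the previous direction; the first
direction is oriented toward the global data centroid so a boundary start
walks *into* the cloud), and a step of size

  t₀(γ) = 1 / ‖γ / h‖₂,

i.e. one bandwidth in the kernel's metric along the travel direction.  This
equals h_j for axis-aligned travel and shrinks for directions with
components in narrow dimensions; a fixed scalar step either stalls against
dense reference clusters (too small) or jumps many bandwidths in narrow
dimensions (too large).  A fixed `step_size` can still be configured.

Stopping rules, per direction:

- **converged** — center-of-mass movement below `tol` (default 10⁻³·mean h);
- **boundary** — kernel mass at the stepped point below `boundary_frac`
  (default 0.01) of the *median* kernel mass over the data points, or an
  empty neighborhood.  The median reference deliberately ignores how dense
  the visited points were: a reference cluster can be orders of magnitude
  denser than the interior;
- **max_iter** (default 10·n).

Two guards against oversteering, the classic failure mode of local
principal curves: a traversal stops when a new center lands within half a
step of a part of the path at least two steps behind along the walked
length (a U-turn at the data edge would otherwise re-walk the curve and
fold its parameterization), and the near-coincident centers recorded while
converging against a boundary are pruned to their final point (their jitter
would corrupt the spline's end tangent).  Angle penalization
(`angle_penalty` < 1 blends the new direction with the previous one) is
exposed but off by default.

With a reference start the curve grows one-sided from the normals into the
tumors; a mean-shift start (no references) grows two-sided and the backward
traversal is prepended in reverse.

### Parameterization and projection

Centers get a cumulative chord-length parameter s; each coordinate is
interpolated by a natural cubic spline over s (linear/quadratic for fewer
than 4 centers); the projection index is the arc length
t(s) = ∫₀ˢ ‖μ′(u)‖ du, tabulated by 5-point Gauss–Legendre quadrature on
`grid_per_interval` (default 50) subdivisions per knot interval.  Beyond
the first and last center the curve continues along the endpoint tangent
rays (`extension_fraction`, default 0.25 of the arc length, per side):
the traversal's centers necessarily stop ~0.7 bandwidths short of the data
edge (the boundary pull of the truncated kernel mean balances the step
there), and without the extension all samples past the last center would
project onto a single endpoint and tie.

Projection minimizes Euclidean distance over the dense grid, refined by
bounded scalar minimization within the best grid cell; ties break toward
smaller t.  The origin t = 0 is the projection of the starting point, so
normals score near zero; indices behind the origin are negative.

### Scores

Projection indices are min–max normalized per process (default); the
`clamp_minmax` mode zeroes negative indices first, encoding "deviation from
the reference" strictly.  Constant index vectors normalize to all zeros and
are flagged.  The per-process metadata records k, the number of centers,
stop reasons, and genes used.  The whole pipeline is deterministic: there
is no random number generation anywhere between input and BPS matrix.

## Survival evaluation

L1-penalized Cox regression is delegated to scikit-survival's coordinate
descent (`CoxnetSurvivalAnalysis`, l1_ratio = 1).  The penalty is chosen by
5-fold cross-validated concordance on the coxnet path (deterministic fold
seed; ties favor the sparser penalty), or fixed.  PI = βᵀX; the risk cutoff
is the (1 − d) quantile of training PI where d is the training event
fraction, so the high-risk fraction matches d within 1/n.  Log-rank tests
delegate to lifelines; "Wilcoxon" weighting is the Gehan–Breslow variant.
LOOCV refits the model per fold and pools held-out PI values into a single
AUC (per-fold AUCs are undefined for singleton folds).  Cluster association
uses Euclidean average-linkage hierarchical clustering cut at 2 groups and
per-factor chi-square tests, with a seeded permutation fallback when an
expected cell count is zero.

## Synthetic cohorts

`generate_cohort` draws, per process, a latent u ~ Uniform(0,1) per tumor
sample and embeds each gene as a(u)-style smooth curves: affine (`line`),
a·cos(πu) + b·sin(πu) (`arc` — a genuinely curved 2-D manifold that a single
linear PC cannot parameterize), or a sigmoid plus trend (`s-curve`), with
per-gene coefficients drawn once from the seed, plus N(0, noise_sd²) noise.
Normals sit at u = 0 with the same noise.  Survival times are exponential
with log-hazard = `hazard_coef` × mean latent of `n_drivers` randomly chosen
driver processes; censoring comes from an independent exponential censoring
time whose rate is calibrated so the expected censored fraction equals
`censor_rate`.  Coin-flip censoring was rejected: it makes observed event
status independent of risk, so AUC-of-PI-vs-status would be 0.5 for any
scorer by construction.

Defaults (n_tumor = 200, n_normal = 40, 20 processes × 50 genes, 3 drivers,
noise_sd = 0.05, hazard_coef = 2, censor_rate = 0.3) describe a mid-sized
tumor/normal cohort with MSigDB-sized gene sets.  The generator does **not**
model batch effects, platform noise, subtype mixtures, correlated gene
sets, or branched trajectories — so a green test establishes correct
recovery of clean single-strand latent structure, not robustness to
real-data artifacts.

Note an intrinsic ceiling of the survival simulation: the specified
log-hazard (coefficient 2 on the *mean* of 3 independent uniform latents)
has SD ≈ 0.33, so even the true risk score discriminates observed event
status only to AUC ≈ 0.59 under calibrated random censoring.  Cross-
validated AUCs near 0.55 are therefore the expected outcome of a correct
implementation at these settings, not a defect.

## Numerical choices

- Unbiased (n−1) variance estimators everywhere.
- Natural spline boundary conditions (second derivative zero at the ends).
- Eigenvector sign convention: continuity with the previous direction;
  first-nonzero-coordinate-positive when there is none.
- Degenerate inputs: empty kernel neighborhoods, zero local covariance and
  collapsed curves raise typed errors; unsalvageable gene sets are skipped
  with the reason recorded in `BPSMatrix.skipped`.
- Curve direction without references is mathematically unidentifiable (both
  orientations fit equally well); scores are then defined up to the
  orientation of the min–max map.  With references the origin anchors the
  direction.

## Known limitations

- Single connected curves only; no branch detection.
- The 10%-of-range bandwidth is fixed, not data-adaptive; very uneven
  sampling along the manifold trades off coverage against detail.
- The mapping-space dimension rule depends on having ≥ ~20 reference
  samples for stable normal-variance estimates; with very few normals k is
  noisy (the cap bounds the damage).
- Gene-set overlap with the filtered expression matrix below
  `min_genes_per_set` (default 2) skips the set rather than scoring it.
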