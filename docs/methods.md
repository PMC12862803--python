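# Methods

## The modelling problem

Given structures x with scalar labels y (extensive quantum-chemical
energies, kcal/mol), we want predictors that are cheap at scale and
interpretable.  The package centres on weighted k-nearest-neighbour
regression; its quality is governed by the distance metric, so the
package provides three metrics (Euclidean, MLKR-learned Mahalanobis,
kernel-induced) plus a KRR accuracy baseline and Δ-learning on the
residual between two label levels.

## Models and numerical choices

**KRR.** α = (K + λI)⁻¹y solved by Cholesky factorisation with one
jitter retry (1e-10·tr(K)/n) and up to 12 steps of iterative
refinement; the fit is rejected if the relative residual stays above
1e-8.  Refinement matters because the extensive atomic kernel is
ill-conditioned at small λ (condition numbers ~1e12 already at n=250).
Default λ = 1e-8; the tuning grid is λ ∈ {1e-2 … 1e-10} by decades and
σ ∈ {0.5, 1, 2, 5, 10, 20, 50} × median pairwise descriptor distance,
searched on a seeded 4000/1000 train/validation split (kept at a 4:1
ratio on smaller data).  Ties prefer the more regularised model.

**Extensive atomic kernel.** K_ij = Σ_{α∈i} Σ_{β∈j} [Z_α = Z_β] ·
exp(−‖q_α − q_β‖²/2σ²) over local descriptor rows.  Restricting to
same-element pairs is the standard choice for atomic-decomposition
kernels and is switchable (`element_matched=False`).  Evaluation is
blocked (default 1024 atom rows) with results independent of block
size; the self-similarity of an n-atom structure is ≥ n, which is what
makes the kernel extensive — and what distorts the kernel-induced
distance relative to the kernel's own similarity ranking.
`normalize_kernel` (cosine normalisation to unit diagonal) exists to
study that trade-off; it sacrifices extensivity.

**MLKR.**  Loss L(A) = Σᵢ (yᵢ − f_LOO(xᵢ))² with
f_LOO(xᵢ) = Σ_{j≠i} yⱼ kᵢⱼ / Σ_{j≠i} kᵢⱼ and
kᵢⱼ = exp(−‖A(xᵢ−xⱼ)‖²/σ²).  The Gaussian normalisation prefactor
cancels in the ratio and is omitted.  Decisions:

* *Exponent convention.*  The kernel is sometimes written with an
  unsquared distance in the exponent; since the distance itself carries
  a square root while the weighting is called a standard RBF kernel, we
  take the squared form as the default and keep the unsquared variant
  behind `exponent="literal"` (its gradient picks up a 1/(2d) factor
  per pair, with zero contribution from coincident pairs).
* *σ is fixed to 1* after standardising features to zero mean and unit
  variance — σ is absorbable into the scale of A, so fitting it would
  only create an identifiability ridge.  The standardisation is folded
  into the returned A, which therefore applies to raw features.
* *Initialisation* is the top-p principal directions of the
  standardised data, each scaled to unit projected variance — a
  deterministic, PCA-like starting point.  p (the rank limit, rows of
  A) defaults to 50: in practice the loss is insensitive beyond that,
  and p caps the optimisation cost at O(n²p).
* *Optimiser*: L-BFGS-B with strong-Wolfe line search, maxiter 200,
  relative loss tolerance 1e-6.  The loss trajectory of accepted
  iterates is recorded and is non-increasing; if line search ever ends
  above the initial loss the initialisation is returned instead.
* *Stabilisation*: per row, the smallest off-diagonal exponent argument
  is subtracted before exponentiation.  The LOO ratio is invariant to
  row scaling, the nearest neighbour's kernel entry becomes exp(0)=1,
  and the normalising sums can no longer underflow; if they still do
  (infinite distances), the point falls back to its nearest
  neighbour's label with a logged warning — never NaN.
* *Subsampling*: metric learning can be capped to a seeded random
  subsample (default 25 000) without replacement; the learned metric is
  then used with all training data.
* The analytic gradient is derived from the implemented loss,
  ∂L/∂A = (4/σ²) A Σ_{i≠j} Pᵢⱼ (xᵢ−xⱼ)(xᵢ−xⱼ)ᵀ with
  Pᵢⱼ = (ŷᵢ−yᵢ)(ŷᵢ−yⱼ) kᵢⱼ/Sᵢ, evaluated as A·Xᵀ(diag(r)+diag(c)−P−Pᵀ)X.
  Finite-difference agreement (relative error ≤ 1e-5) is asserted in
  the test suite and is the binding definition of correctness.

**k-NN.**  Brute-force search uses a stable argsort so exact distance
ties break toward the smaller training index; the KD-tree backend
(scikit-learn) is available for Euclidean/Mahalanobis coordinates and
normalises tie order within the returned neighbour set.  The
kernel-induced mode has no explicit coordinates, so train–test
distances are computed densely and only the brute backend applies.
Reciprocal weighting with zero distances takes the limit: the
prediction is the mean over the zero-distance neighbours.  Default
k = 10 when tuning is skipped; the tuning grid is 1–30.

**Leave-one-out tuning of k.**  For uniform weights the LOO prediction
at k is an exact rescaling of the self-including (k+1)-NN mean,
f_LOO,k(xᵢ) = ((k+1)·f_{k+1}(xᵢ) − yᵢ)/k, so one distance pass prices
every k.  For reciprocal weights the self neighbour (distance 0) would
degenerate the weights, so it is dropped and the next k neighbours are
used — a convention, matched exactly by an explicit re-query oracle in
the tests.  MAE ties prefer the smaller k.

**Uncertainty.**  Prediction quantiles are empirical quantiles of the
*unweighted* neighbour label set, even when the point estimate is
reciprocal-weighted.  `neighbor_quantiles` defaults to the classic
linear-interpolation quantile; the calibration workflow uses the
Weibull plotting positions ((k+1)p) instead, because with finite k the
classic definition has a systematic coverage bias at the outer deciles
(for k=31 the 10th-percentile estimate is the 4th order statistic,
whose coverage is 4/32 = 0.125, a bias larger than the sampling noise
at n=2000), while the (k+1)p positions make observed coverage match the
nominal level.  Calibration curves report, per nominal percentile, the
fraction of test labels at or below the estimated percentile.

## Synthetic data: what it emulates and what it does not

The generator stands in for databases of acid–base molecular clusters
evaluated at two levels of theory.  Clusters are assembled from rigid,
stylised units — an S-centred 5-atom "SA" unit, a 3-atom "W" (water-
like) unit, a 4-atom "AM" (ammonia-like) unit; shapes are schematic,
not chemically accurate — placed with random positions/orientations in
a 10 Å box under a 2.4 Å minimum inter-unit atomic distance (rejection
sampling, ≤1000 attempts per unit), then jittered atom-wise
(σ = 0.05 Å).  The default composition mix spans (SA)1(W)1 … (SA)3(W)3
so an extrapolation holdout of the largest composition exists.

Labels: y_high = Σ_a ε(Z_a) + Σ_{a<b, r<12Å} Morse(r_ab) with
per-element-pair Morse wells (D_e ∈ [2, 8] kcal/mol, r_e ∈ [1.5, 3] Å;
Morse rather than Lennard-Jones for a bounded, smooth well).
ε(Z) = −25·Z kcal/mol is set clearly below the per-atom interaction
scale so total energies are negative and componentwise-larger
compositions have lower mean energy, as binding energies of growing
clusters do.  The low level re-evaluates the same functional with
5% seeded relative perturbations of (D_e, α, r_e), adds a smooth
per-composition offset and Gaussian noise (σ = 0.1 kcal/mol).  The
residual y_high − y_low is therefore structured and learnable — the
Δ-learning premise — and its variance is verified to be below the label
variance (the noise is redrawn if not).

What passing tests on this data do **not** show: anything about real
quantum-chemical accuracy.  The synthetic labels are smooth two-body
functions of exactly the geometric information the descriptors encode,
so absolute MAEs are not comparable to real-database numbers; only the
relative, qualitative behaviour (metric learning helps, Δ-learning
helps, more data helps, extrapolation hurts) transfers.

## Benchmark experiment sizes

The bundled experiments (`molknn.benchmarks`) use desk-scale sizes
chosen so the full suite runs on one core in minutes: noisy-subspace
recovery n = 500/10 features; Δ-benefit n = 1000 clusters; calibration
2000 items at k = 31; k-plateau n = 2000 (x ~ U(0, 100), y = sin x +
N(0, 0.1²) — the window/noise scale puts the bias–variance optimum near
k ≈ 12, inside the recommended 5–15 plateau); learning curves n = 625
with train sizes {125, 500}; extrapolation holdout (SA)3(W)3 at train
size 400.  Cluster benchmarks use a reduced descriptor (6 Å cutoff,
12 radial, 8 angular bins).  Learning-curve subsamples are drawn
independently per train size (not nested).

## Known limitations

* The local descriptor is a simplified 2-/3-body form, not an exact
  reproduction of published discretised many-body representations;
  externally computed descriptor tables can be imported instead.
* No descriptor gradients, hence no force learning.
* No approximate nearest-neighbour backends; the kernel-induced mode is
  O(n·m) dense per prediction batch.
* Bootstrap/jackknife uncertainty variants are out of scope; quantiles
  come from the single neighbour set.
* Kernel matrices are materialised densely; memory is bounded by
  blocking, not by sparse or low-rank approximation.
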