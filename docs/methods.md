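# Methods

## Model

Two groups of observations on the same p features are modelled by
latent Gaussian copulas.  Group g has a latent vector
**Z**⁽ᵍ⁾ ~ N(0, Σ⁽ᵍ⁾) with Σ⁽ᵍ⁾ a correlation matrix; observed
continuous coordinates are strictly increasing transforms of latent
coordinates, and observed binary coordinates arise by thresholding,
`B_j = I(X_j > C_j)`.  Only the transformed cutoffs Λ_j = f_j(C_j) are
identifiable from binary margins.  The estimand is the difference of
latent precision matrices Δ₀ = (Σ⁽²⁾)⁻¹ − (Σ⁽¹⁾)⁻¹; its off-diagonal
support is the set of feature pairs whose conditional dependence
changes between groups.  Sparsity is assumed only of Δ₀, never of the
individual precision matrices, so each group's network may contain
dense hubs.

## Rank-based latent correlation

All correlation estimation goes through Kendall's tau in the tau-a
form, τ̂ = 2/(n(n−1)) Σ_{i<i'} sign(Δx)·sign(Δy): ties contribute zero
and no tie correction is applied, because the population bridges below
are derived for exactly this statistic.

* continuous–continuous: Σ̂_jk = sin(π τ̂_jk / 2);
* binary–binary: τ = F(t; Λ_j, Λ_k) = 2{Φ₂(Λ_j, Λ_k, t) − Φ(Λ_j)Φ(Λ_k)},
  inverted in t;
* binary–continuous: τ = H(t; Λ_j) = 4Φ₂(Λ_j, 0, t/√2) − 2Φ(Λ_j),
  inverted in t;

with Λ̂_j = Φ⁻¹(1 − B̄_j) and the column mean clamped to
[1/(2n), 1 − 1/(2n)] so constant binary columns give finite cutoffs.

The bivariate normal CDF is evaluated through its smooth
trigonometric integral form, Φ₂(h,k,ρ) = Φ(h)Φ(k) +
(2π)⁻¹∫₀^{asin ρ} exp(−(h²+k²−2hk sin t)/(2cos²t)) dt, with a 64-node
Gauss–Legendre rule (error ≈ 1e−14, far below the inversion tolerance,
and exactly zero at ρ = 0 so F(0) = H(0) = 0 without cancellation).
Bridge inversion is by 60 bisection steps on t ∈ [−1+1e−6, 1−1e−6]
(bracket below 1e−17, well past the 1e−8 target); a τ̂ outside the
attainable range of the bridge — common at small n when cutoffs are
extreme, since the range of tau-a shrinks with the cutoffs — is clipped
to the nearest endpoint.  Estimated matrices are exactly symmetric with
unit diagonal and off-diagonals clipped to [−1+1e−6, 1−1e−6].

Degenerate regimes matter here: when both cutoffs of a binary pair are
far from zero the F bridge is nearly flat on one side, so the inversion
amplifies sampling noise in τ̂ and occasionally returns an entry
clipped near ±1 even though the true correlation is moderate.  Raw
bridge-inverted matrices at n ≈ 100 are consequently severely
indefinite (minimum eigenvalue around −1 at p = 80), and plugging them
into the difference estimator both misleads it — the ℓ1-cheapest
feasible solution starts routing through aliased false coordinates —
and wrecks the solver's conditioning.  The estimator therefore projects
bridge-inverted estimates (any binary column present) to the nearest
positive semidefinite correlation matrix by default (eigenvalue floor
1e−4, then rescaled to unit diagonal), the standard plug-in
regularization for latent-copula correlation estimates; `psd=False`
restores the raw matrices.  The all-continuous sine-transform estimate
has no inversion blow-ups and is left as computed.

## Direct difference estimation

Δ is estimated by min |Δ|₁ subject to
|Ŝ⁽¹⁾ Δ Ŝ⁽²⁾ − Ŝ⁽¹⁾ + Ŝ⁽²⁾|∞ ≤ λ.  Symmetry is enforced
structurally: θ collects the p(p+1)/2 upper-triangle entries and the
duplication map Γ (never materialized; index arithmetic only) carries
θ to vec(Δ).  In vectorized coordinates the constraint splits into a
box: off-diagonal coordinates of Γᵀ(Ŝ⁽¹⁾⊗Ŝ⁽²⁾)Γθ − Γᵀvec(Ŝ⁽¹⁾−Ŝ⁽²⁾)
bounded by λ, diagonal coordinates by λ/2 (Γ doubles off-diagonal
coordinates, so both amount to the same per-entry level).  The
Kronecker product is never formed: each operator application is the
sandwich vec(Ŝ⁽²⁾ Δ Ŝ⁽¹⁾) followed by the Γᵀ projection, O(p³) time
and O(p²) memory.

ADMM alternates a box projection (z), an ℓ1-penalized least-squares
step (θ), and an unscaled dual ascent (u), with ρ = 1:

    z ← clip(u/ρ + c − Aθ;  ±λ off-diagonal, ±λ/2 diagonal)
    θ ← argmin |Aθ − (u/ρ + c − z)|₂² + (2/ρ)|θ|₁
    u ← u + ρ(c − Aθ − z)

The θ subproblem is solved *inexactly* by warm-started FISTA (step
1/L, L = 2‖A‖₂² from a cached power iteration), capped at 100 steps per
sweep with inner change tolerance 1e−8 (40 steps and 1e−6 in the
replication harness); the inexactness vanishes as the outer iteration
converges, and a generous inner budget pays for itself — hard sparse
instances converge in a few hundred outer sweeps instead of thousands.  Stopping uses infinity-norm primal and dual
residuals with combined absolute + relative tolerances (defaults
1e−7 + 1e−5·scale for one-off solves; the model interface uses a
relative 1e−4 and the replication harness 1e−3, at which the support
and the entries at the support-threshold scale are long stable).  The
dual residual is ρ·A(θ_new − θ_old), θ being the second-updated block.
These choices were driven by conditioning: rank-based correlation
estimates at n ≈ 100 are strongly indefinite (eigenvalues in [−6, 8]
at p = 50), the operator norm of A reaches ~70, and an absolute
1e−5 stopping rule does not terminate in practical time, while against
a linear-programming oracle (the problem is an LP) the solver agrees to
~1e−6 on small instances.  ρ = 1 was kept after measuring ρ ∈
{10, 50, 200}, over-relaxation and residual-balancing to be slower on
the hard instances.

### The λ path and tuning

λ_max = |Γᵀvec(Ŝ⁽¹⁾−Ŝ⁽²⁾)|∞ is the smallest λ whose solution is
exactly zero.  As in lasso-path software, the default grid excludes
this trivial point and log-spaces n_λ points (default 50; 30 in the
replication harness) from one step inside it down to 0.01·λ_max, so
every path point carries a nonzero estimate and a defined discovery
rate.  Warm starts carry both θ and the dual u down the path.

λ is chosen to minimize AIC(λ) = (n₁+n₂)·L(λ) + 2k, with L the
sup-norm, Frobenius, spectral, or elementwise-ℓ1 norm of
Ŝ⁽¹⁾Δ̂(λ)Ŝ⁽²⁾ − Ŝ⁽¹⁾ + Ŝ⁽²⁾, and k = |θ̂|₀ counted on the
vectorized parameters above numerical zero (1e−5); non-converged path
points are excluded and ties break toward larger λ.  Because the
estimator minimizes |θ|₁ rather than the loss, L(λ) is typically flat
or increasing along the path head, so the AIC minimum sits at or near
the sparsest grid point at large p; the path search stops once the
criterion has failed to improve for several consecutive points
(patience 6, harness 3; non-converged points count, since selection
excludes them), skipping the dense tail.

Support recovery uses a final hardening threshold on |δ̂| (default
1e−5, i.e. numerical zero).  A theoretically-motivated larger constant
can be supplied; it is deliberately not defaulted because its constant
is instance-dependent.

## Synthetic data

The generator builds the study conditions used throughout the tests:

* **Graph pair.**  p features (p divisible by 5) in 5 equal blocks;
  each block's smallest index is a hub connected to all block members;
  hub-edge weights uniform on ±[0.25, 0.75]; diagonal shifted by
  0.2 + |λ_min| so the precision matrix is positive definite.  Two of
  the five hubs are chosen at random and all their edges flip sign in
  group 2 — a ±1 diagonal similarity, so positive definiteness is
  automatic.  Both inverses are rescaled to correlation matrices and
  Δ₀ is recomputed from those, so its support is exactly the flipped
  hubs' edges.  At the degenerate minimum p = 5 a single block (one
  hub, four spokes) replaces the five singleton blocks.  The graph pair
  is generated once per (p, master seed) and held fixed across
  replications; only data are redrawn (replication r uses data seed
  master + r).  This fixed-graph convention is what makes the sup-norm
  error of near-empty tuned estimates constant across replications.
* **Sampling.**  Z ~ N(0, Σ) by Cholesky; the copula transform is the
  moment-normalized Gaussian CDF, g(z) = √12(Φ(z) − ½), which has mean
  0 and variance 1.  Any strictly increasing g leaves every rank-based
  quantity unchanged; the normalization matters because the binary
  designs threshold the *observed* scale at C ~ Unif[0, 1], and with a
  standardized observed scale those cutoffs are moderate — the same
  regime as the outlier design, which thresholds the Gaussian latent
  scale at Unif[0, 1] directly.  n₁ = n₂ = 100 unless stated.
* **Designs.**  `copula`: all coordinates continuous.  `s1_binary`:
  all dichotomized.  `s2_mixed`: first half continuous, second half
  dichotomized.  `s3_outlier`: Gaussian latent data (no copula
  transform) with 10 entries per row replaced by ±5 before
  dichotomizing everything — a misclassification stress test.  One
  cutoff vector is shared between groups.
* What this emulates / does not: hub-structured differential signal
  with clean two-group sampling.  It has no batch effects, no missing
  data, no library-size or count structure, and the dichotomization is
  exactly the model's own thresholding mechanism — so passing tests
  demonstrate correct estimation under the model, not robustness to
  real-array artifacts.

## Evaluation conventions

Support sets are ordered off-diagonal pairs (each undirected edge
counted twice), so TNR's denominator is p(p−1) − |S₀|.  TD (precision)
is undefined on an empty estimated support: reported as NaN and
excluded from replication averages.  ROC curves take one point per
path λ at the numerical-zero support threshold, sorted by false
positive rate.  The harness compares four estimator variants: RDN
(rank-based, observed data), DDN (Pearson, observed data), ZP-DDN
(Pearson on the unobserved latent Gaussians) and ZR-RDN (rank on the
latent Gaussians); the latter two are information-loss benchmarks
available only in simulation.

## Problem sizes used in the shipped checks

The acceptance script runs the mixed-data study at p = 120, n = 100,
20 replications.  The test suite runs the other cells at their
original dimensions and sample sizes with replication counts reduced
to 3–20 per cell (stated per test), chosen to keep the full suite
within a practical single-CPU runtime.

## Known limitations

* Ordinal variables with more than two levels are out of scope.
* Missing values are rejected, not imputed.
* The bridge-inversion noise amplification at extreme cutoffs (above)
  makes binary-data estimates at n ≲ 100 heavy-tailed; the reported
  discovery rates rely on tuned sparsity, and per-replication TD at
  p ≥ 100 on mixed data varies when a spurious clipped entry enters
  the path head.
* AIC is the only tuning rule shipped (no cross-validation or BIC).
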