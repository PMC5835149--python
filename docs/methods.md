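# Methods

This note records the model, the numerical choices, and the reasoning
behind the places where the design was genuinely open.  Empirical numbers
quoted here are the ones the test suite and `scripts/acceptance.py`
actually compute.

## Dynamics and temperature convention

All dynamics is the overdamped Langevin diffusion
dX = −∇V(X) dt + √(2β⁻¹) dW with inverse temperature β, integrated by
Euler–Maruyama; the per-step noise amplitude is √(2·dt/β) per coordinate.
The stationary law is the Boltzmann density ϱ ∝ exp(−βV), the dynamics is
reversible, and the transfer operator at lag t is self-adjoint in L²_μ
with real spectrum 1 = λ₀ > λ₁ ≥ …; implied timescales are
tᵢ = −t/ln λᵢ.

The worked examples and tests run at **β = 2** (temperature ½).  At this
temperature the example landscapes have the kinetic structure the method
needs: the curved double well has one slow timescale t₁ ≈ 5.9 well
separated from t₂ ≈ 0.8, so the lag t = 2 sits inside the gap; the
seven-well circular potential keeps six hopping timescales ≥ 1.7
separated from the intra-well relaxation ≈ 0.05, so lag 0.1 sits inside
that gap.  At β = 0.5 neither separation exists (double-well t₁ ≈ 0.69)
and burst embeddings at these lags would collapse toward the stationary
mean.

## Integrator and RNG

* `dt` defaults to 10⁻³ for burst sampling (stability margin against the
  stiffest example curvature, ≈ 20–50); long sampling trajectories use
  dt = stride = 10⁻², matching the output resolution — at that step the
  integrator bias is part of the reported estimate (see the Ulam section).
* One root seed; every start point draws noise from a substream keyed by
  (seed, blake2b hash of its own coordinates).  Realization m always
  consumes column m of each step's (M, n) Gaussian block.  Consequences:
  results are bit-reproducible, independent of how start points are
  chunked or ordered, and permuting start points permutes outputs
  exactly.  Duplicate start points would share a stream; they do not
  occur in grid or subsample generation.
* Any coordinate beyond 10⁶ aborts with the offending step index rather
  than propagating non-finite states.

## Observable embedding

Linear observables ηⱼ(x) = aⱼᵀx with aⱼ ~ U[−1,1]ⁿ are the default
(2r+1 of them for manifold dimension r; draws are rejected until the
coefficient matrix has full row rank, or pairwise non-collinearity when
2r+1 > n).  Linear functionals are unbounded, but the transition
densities of the confining example potentials decay fast enough for the
pairings to exist; bounded custom observables are accepted.  The
Monte-Carlo standard error of every embedded component is stored so that
downstream kernel scales can be compared against the noise floor (at
M = 10³ on the double-well grid the mean stderr is ≈ 0.01 against a cloud
extent of ≈ 1).

The embedded cloud is itself exposed as the (2r+1)-dimensional fallback
coordinate (no manifold-learning step), which is what one would use when
isolated points must be evaluated independently.

## Diffusion map

Kernel h(u) = exp(−u)·1_{u≤R} on squared distances over σ.

* σ "auto" = median of nonzero squared pairwise distances / ln 2 (kernel
  value ½ at the median distance): scale-free and reproducible;
  overridable.  The embedded coordinates are *not* rescaled or whitened
  before kernel construction — whitening would amplify the transverse
  noise of thin clouds, destroying exactly the thickness information the
  dimension diagnostic needs.
* Cutoff: none (dense kernel) up to 5000 points; above that an automatic
  radius keeping ≥ 32 neighbors per point sparsifies the kernel.  A row
  left without off-diagonal neighbors makes the chain reducible; this is
  reported as an error naming the isolated points instead of returning a
  meaningless map.
* Two-stage normalization W̃ = D⁻¹WD⁻¹, P = D̃⁻¹W̃; eigenpairs through
  the symmetric similar matrix D̃^(−1/2)W̃D̃^(−1/2), so the spectrum is
  real by construction.  Eigenvector signs are fixed (largest-magnitude
  entry positive) and exact eigenvalue ties are ordered lexicographically
  by eigenvector entries, so results are deterministic.
* Out-of-sample evaluation is Nyström: kernel row against the training
  cloud, normalized consistently with training, projected onto ψⱼ.  For
  extending ξ̄ to trajectory points, nearest-neighbor copying is the
  default (cheap, and exact on evaluation points); Nyström re-embedding
  (fresh bursts at the queries) is the alternative when smooth values are
  needed off the training set.

## Intrinsic-dimension diagnostic

The diagnostic estimates how many directions of variation the embedded
cloud has.  A single "largest spectral drop" rule is not reliable here:
on a one-dimensional cloud the eigenvalues decay like harmonics
(γ_k ≈ γ₁^(k²)), so *later* drops are always larger, and closed
one-dimensional clouds (loops) produce near-degenerate pairs rather than
one dominant eigenvalue.  The implemented rule therefore has two stages:

1. **Closed-curve detection.**  Project the cloud on its leading-2 PCA
   plane; if every angular sector around the centroid is occupied and the
   mean per-sector radial coefficient of variation is below 0.2, the
   cloud is a thin closed curve → dimension 1, flagged as closed (the
   quadruple-well "hilly" cloud has thickness ≈ 0.06, the "flat" cloud
   ≈ 0.32).
2. **Weyl-law slope.**  Otherwise fit log(−log γ_k) against log k over
   the significant modes (γ_k ≥ 0.05 γ₁): for a d-dimensional manifold
   the k-th Laplacian eigenvalue grows like k^(2/d), so the slope s gives
   d = 2/s, rounded (segment ≈ 1.03, filled square ≈ 2.4 → 2, flat
   quadruple well ≈ 1.9 → 2).

The near-degenerate-pair caveat (γ₁ ≈ γ₂ within 10%) is always reported:
circle-like level-set topology needs one more *component* than the
intrinsic dimension (the seven-well examples use r_out = 2 for a
one-dimensional circular coordinate for exactly this reason).

## Ulam discretization and spectra

Transition counting uses every sliding-window pair of a strided
trajectory; cells are restricted to those actually visited, and a row
left empty (a cell seen only as an endpoint) receives a self-loop and is
flagged — this keeps the matrix stochastic without inventing transitions.
Count symmetrization (C + Cᵀ)/2 is optional and off by default: the
dynamics is reversible, so finite-sample non-reversibility is noise, and
tests enable symmetrization wherever real sorted spectra are required.
Reaction-coordinate bins are uniform per component over the observed
range (a product grid for r ≥ 2, empty cells dropped).  The number of
dominant eigenvalues is reported as the position of the largest
consecutive gap.

A deterministic reference route discretizes the generator
L = −∇V·∇ + β⁻¹Δ as a nearest-neighbor jump chain with rates
exp(−β(Vⱼ−Vᵢ)/2)/(βh²) and no-flux boundaries; the chain is reversible
for the Boltzmann weights and its rate matrix is similar to a symmetric
matrix, so the spectrum is real and λᵢ = exp(κᵢt) is exact in t.  On the
double well the two routes agree on t₁ within 15% (the difference is the
Euler-step and box-projection bias of the trajectory route, both of which
shrink the slow timescale).

### Bias anatomy of the seven-well timescales

The exact (generator, fine grid) sixth implied timescale of the
seven-well system at β = 2, lag 0.1 is t₆ ≈ 2.03.  The practitioner's
estimate — Ulam counting on a 10⁶-step Euler–Maruyama trajectory at
τ = 10⁻², 40×40 boxes — gives t₆ ≈ 1.71–1.76 (and ≈ 1.73 on average over
replicates): the Euler step distorts the wells (dt×curvature ≈ 0.2–0.5),
the 0.1-wide boxes add projection loss, and the finite count statistics
of ~10³ rare hops bias metastable eigenvalues downward.  These biases are
properties of the stated procedure, not defects to be removed: longer
trajectories drift the estimate up toward the asymptotic Ulam+Euler value
(≈ 1.78).  `scripts/acceptance.py` therefore runs the 10⁶-step procedure
six times independently and averages the per-replicate timescales, which
keeps the estimator and its bias while reducing the rare-event scatter by
√6.  The seventh timescale (≈ 0.044–0.057) is fixed by the radial
confinement curvature (V'' = 20 → t = 1/20) and is insensitive to all of
the above.

## MSM cores, projection error, perturbation bound

Core-matrix entries are conditional transition frequencies between
disjoint user-supplied core sets, with pairs leaving the cores excluded;
the caller is responsible for equilibration.  The empirical level-set
projection P_ξ is realized by within-bin weighted means; its residual rms
is the ε entering the bound |λ − λ_Q| < ε/√(1−ε²), which the
`lemma_oracle` verifies on explicit matrices (validated on 1000 random
symmetric-contraction/projection/eigenvector triples; observed
distance-to-bound ratios reach 0.95, so the bound is nearly sharp).

## Synthetic data scope

All inputs are synthesized from analytic potentials; the generator
emulates burst ensembles and equilibrium trajectories of reversible
overdamped diffusions in up to 10 dimensions.  It does not emulate
molecular force fields, inertia/underdamped effects, non-reversible
drifts, or sampling error from enhanced-sampling reweighting — passing
tests therefore demonstrate the identification machinery, not robustness
to force-field or thermostat artifacts.  Problem sizes in the tests are
chosen for minutes-scale runs (grids up to 40×40, M = 300–1000,
trajectories of 10⁶ steps); the pipeline itself is size-agnostic and its
cost is dominated by M·ℓ short integrations, independent of the ambient
dimension beyond the per-step gradient cost.

## Known limitations

* The closed-curve detector assumes the loop projects to a roughly convex
  planar curve; a strongly twisted closed 1-D cloud in ℝ^(2r+1) could be
  missed (it would then be reported with the dimension of its projection).
* Nearest-neighbor ξ̄ extension is piecewise constant; spectral
  comparisons with fewer bins than evaluation points are insensitive to
  this, but gradient-based uses of ξ̄ would need the Nyström route.
* The Ulam reference requires a trajectory that visits all relevant
  cells; the package reports dropped out-of-domain pairs and empty-row
  flags but does not attempt adaptive domain selection.
* r must be supplied a priori; the dimension diagnostic revises it after
  one embedding pass, and r_out may legitimately exceed r for closed
  level-set topology.
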