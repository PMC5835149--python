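# tmrc — transition-manifold reaction coordinates

`tmrc` identifies low-dimensional **reaction coordinates** of metastable
stochastic dynamics using only short, local simulation bursts — no long
equilibrium trajectory is needed for the identification itself.  It is
aimed at molecular-modelling and stochastic-dynamics practitioners who
work with overdamped Langevin models

```
dX_t = -∇V(X_t) dt + √(2 β⁻¹) dW_t
```

and want a coordinate ξ : ℝⁿ → ℝʳ whose level-set projection preserves the
dominant transfer-operator spectrum (the slow, rare-event kinetics).

## The method

For a lag time *t* inside the slow–fast gap, the transition densities
p^t(x,·) of a metastable system concentrate near an *r*-dimensional
manifold in density space (the *transition manifold*).  The pipeline:

1. choose evaluation points x₁,…,x_ℓ (a grid, or a subsample of a
   trajectory);
2. choose 2r+1 generic linear observables ηⱼ(x) = aⱼᵀx, aⱼ ~ U[-1,1]ⁿ;
3. from each xᵢ launch M short bursts of length t and form the
   Monte-Carlo Koopman averages
   ẑᵢⱼ = (1/M) Σₘ ηⱼ(Φₜ⁽ᵐ⁾(xᵢ)) ≈ E[ηⱼ(X_t) | X₀ = xᵢ],
   embedding p^t(xᵢ,·) into ℝ^(2r+1);
4. parametrize the embedded cloud {ẑᵢ} with a diffusion map
   (kernel W = exp(−‖ẑᵢ−ẑⱼ‖²/σ), two-stage normalization
   W̃ = D⁻¹WD⁻¹, P = D̃⁻¹W̃, eigenpairs γⱼ, ψⱼ);
5. define ξ̄(xᵢ) = (γ₁ψ₁(ẑᵢ), …, γ_r ψ_r(ẑᵢ)).

Validation is spectral: project the dynamics onto bins of ξ̄ (Ulam
transition counting on a long trajectory) and compare the dominant
eigenvalues λᵢ and implied timescales tᵢ = −t/ln λᵢ with the full-space
operator.  The quantitative backbone is the perturbation bound
|λ − λ_Q| < ε/√(1−ε²), with ε the level-set projection residual of the
eigenfunction.

## Worked example

`examples/double_well_rc.py` runs the pipeline on the curved double well
V = (x₁²−1)² + 2(x₁²+x₂−1)² at β = 2 (a reduced 24×18 grid, M = 300,
about 30 s) and compares ξ̄ with the analytic reference coordinate
ξ*(x) = x₁e^(−2x₂):

```
embedded cloud: 432 points in R^3, mean MC stderr 0.0104
diffusion-map eigenvalues: [1.    0.764]
Spearman(xi_bar, x1*exp(-2 x2)) = -0.9887
```

The single nontrivial diffusion-map eigenvalue says the embedded cloud is
effectively one-dimensional; the rank correlation of −0.99 (sign is
arbitrary) says ξ̄ and ξ* share their level sets, i.e. the pipeline
recovered the known reaction coordinate without being told anything about
it.  `examples/projected_spectrum.py` then shows the spectral validation:
projecting onto ξ̄ keeps the slow eigenvalue λ₁ = 0.83 to within 0.01,
while the skewed coordinate x₁+x₂ loses 0.12 of it.

Other examples: `seven_well_spectrum.py` (seven-well circular potential,
implied timescales by deterministic generator discretization and by
trajectory Ulam counting), `quad_well_dimension.py` (intrinsic-dimension
diagnostic separating a 1-D from a 2-D transition region),
`perturbation_bound.py` (the eigenvalue bound on random matrices).

A thin CLI mirrors the stages (`tmrc simulate | embed | rc | spectrum |
compare | oracle`); see `tmrc --help`.

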