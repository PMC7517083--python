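# stochpop

Spectral uncertainty quantification for the stochastic Verhulst (logistic)
population model with a random growth rate.

## The problem

Population growth under environmental fluctuation is commonly modeled by the
Itô SDE

```
dX = (a X − ε X²) dt + λ X dW,        X(0) = x₀,
```

with growth rate `a` (birth minus death rate), nonlinear loss `ε` (carrying
capacity `L = a/ε`), and multiplicative noise of amplitude `λ`.  For
`a > λ²/2` the population persists and settles into a stationary gamma law
`γ(2a/λ² − 1, λ²/2ε)`; for `a < λ²/2` it goes extinct almost surely.  In
practice the growth rate itself is uncertain, `a(ω) = a₀ + a₁ψ₁` with `ψ₁`
uniform — so the state carries **two** kinds of randomness: driving noise
and a random parameter.

`stochpop` computes the moments of `X` by spectral decomposition instead of
path sampling:

* **Wiener–Hermite expansion (WHE)** in the noise: `X = Σⱼ ∫ x⁽ʲ⁾ H⁽ʲ⁾ dτⱼ`,
  truncated at second order.  `x⁽⁰⁾(t)` is the mean, `x⁽¹⁾(t,t₁)` the
  Gaussian part, `x⁽²⁾(t,t₁,t₂)` the leading nonGaussian correction, and
  `Var[X] = ∫(x⁽¹⁾)² dt₁ + 2∬(x⁽²⁾)² dt₁dt₂`.
* **Generalized polynomial chaos (gPC)** in the random parameter: every
  kernel is expanded in orthonormal Legendre polynomials,
  `x⁽ʲ⁾ = Σₖ x_k⁽ʲ⁾ ψₖ`.  Galerkin projection yields a closed deterministic
  system for the doubly indexed kernels `x_k⁽ʲ⁾`, advanced by an explicit
  finite-difference scheme (stability bound `Δt < 1/a₀`), with Dirac
  forcings realized as diagonal jumps and kernel integrals by midpoint sums.

The payoff of the combined expansion is an additive variance budget

```
Var[X] = Var_par + Var_noise + Var_mix,
Var_par = (x₁⁽⁰⁾)²,   Var_noise = ∫(x₀⁽¹⁾)² + 2∬(x₀⁽²⁾)²,   Var_mix = ∫(x₁⁽¹⁾)² + 2∬(x₁⁽²⁾)²,
```

from which first-order sensitivity indices follow directly,
`S_noise = Var_noise/Var[X]` etc. — something sampling estimators only reach
through expensive nested Monte Carlo.  Euler–Maruyama, the exact pathwise
solution and a nested parameter-plus-noise sampler are included as
independent cross-checks, together with closed-form oracles (deterministic
logistic and Richards solutions, stationary gamma moments, geometric
Brownian motion).

## Worked example

Pure-noise run at the standard parameter point (`a₀ = 0.5`, `ε = 0.01`,
`x₀ = 0.5`, `λ = 0.01`, `Δt = 0.05`, horizon 40):

```
$ cat demo.cfg
a0 = 0.5
eps = 0.01
x0 = 0.5
lam = 0.01
dt = 0.05
t_end = 40.0
solver = whe
output_dir = demo_out

$ stochpop solve --config demo.cfg
INFO stochpop: stability bound: dt = 0.05 vs 1/a0 = 2
INFO stochpop: steady state: mean=49.9949 var_total=0.25314 (Gaussian 0.25313, nonGaussian 9.41e-06, nonGaussian share 0.00372%) converged=True
demo_out/whe_moments.csv
demo_out/whe_manifest.txt
```

The mean saturates just below the carrying capacity 50 (the stationary
gamma mean is `50 − λ²/2ε = 49.995`), the variance plateaus at 0.253
(gamma law: 0.250), and the nonGaussian correction is five orders of
magnitude smaller — the small-noise persistent regime is essentially
Gaussian.  Adding a 2% random growth rate (`a = 0.5 + 0.01ψ₁`, `λ = 0.02`):

```
$ stochpop solve --config demo2.cfg        # solver = gpc_whe, a1 = 0.01, lam = 0.02
INFO stochpop: steady state: mean=49.9797 var_total=2.01226  S_noise=50.3% S_par=49.7% S_mix=0.01%
```

A mere 2% parameter deviation doubles the steady-state variance: noise and
parameter uncertainty contribute about half each, and their interaction is
negligible (four orders of magnitude down).  `stochpop preset table2`
sweeps `a₁` from 0 to 0.035 and shows the parameter share climbing
monotonically from 0% to 92%.

CLI verbs: `solve` (config file), `preset {fig2,fig3,table1,fig5,table2,fig9,fig10}`,
`compare` (WHE vs Euler–Maruyama error table).  Outputs are tidy CSVs plus
a plain-text manifest that is itself a valid config file, so any run can be
repeated bit-identically.

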