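# malnut

Simulation pipeline for a four-compartment malnutrition model whose
dynamical law **crosses over in time**: classical ordinary differential
equations first, then a fractional differential operator with a chosen
memory kernel, and finally an Itô stochastic differential equation with
multiplicative white noise.  The package is aimed at modellers studying
maternal/child undernutrition dynamics — and, more generally, at anyone who
needs tested, seed-reproducible piecewise classical/fractional/stochastic
integrators with ensemble and ergodicity diagnostics.

## The model

Four compartments: nutrient-susceptible females `S_f`, malnourished boys
`M_b`, malnourished girls `M_g` and underweight individuals `U`
(continuous person-counts, rates per day):

```
dS_f/dζ = (B + ε) − (λ_b M_b + λ_g M_g + ϑ) S_f + δ_g M_g
dM_b/dζ = λ_b S_f M_b − (ϑ_b + γ_b + ϑ) M_b + χ_b U
dM_g/dζ = λ_g S_f M_g − (γ_g + δ_g + ϑ) M_g + χ_g U
dU/dζ   = γ_b M_b + γ_g M_g − (χ_b + χ_g + ϑ) U
```

The stochastic variant perturbs each compartment multiplicatively,
`σ_k x_k dW_k(ζ)`, with independent Brownian motions `W_k`.  On a horizon
`[0, T]` split at `T1 ≤ T2` the law is classical on `[0, T1]`, fractional of
order `Λ ∈ (0, 1]` on `[T1, T2]` — with a power-law (Caputo),
exponential-decay (Caputo–Fabrizio) or Mittag-Leffler (Atangana–Baleanu)
kernel — and stochastic on `[T2, T]`, each regime starting from the previous
one's terminal state.

Two thresholds summarise the long-run behaviour: the deterministic basic
reproduction number

```
R0 = λ_g (B+ε) [(ϑ+ϑ_b)(ϑ+χ_b+χ_g) + γ_b (ϑ+χ_g)]
     / { ϑ (ϑ+ϑ_b) [ϑ (ϑ+γ_g+δ_g+χ_b+χ_g) + χ_b (γ_g+δ_g) + χ_g δ_g] }
```

and the noise-adjusted stochastic threshold

```
R0^s = λ_g λ_b / [(λ_b+ϑ−σ1²/2)(ϑ_b+γ_b−σ2²/2)(γ_g+δ_g+ϑ−σ3²/2)]
```

whose exceedance of 1 is the sufficient (Lyapunov) condition for the
stochastic model to admit a unique ergodic stationary distribution —
persistence of malnutrition as a fluctuating endemic state.

## Worked example

```python
from malnut import PiecewiseSchedule, baseline_scenario, piecewise_solve
from malnut.analysis import threshold_report

scenario = baseline_scenario()          # tabulated rates, y0=(30,2,4,1),
                                        # σ=(0.08,0.09,0.10,0.12)
print(threshold_report(scenario))
```

prints (abridged)

```
R0 = 0.077030   ngm_spectral_radius = 0.075368
R0_s = 1.125985   psi5 = 0.001325   classification = 'persist'
```

meaning the deterministic model alone is subcritical (`R0 < 1`: the
malnutrition-free state is stable) while the stochastic threshold exceeds 1,
so the noisy model satisfies the persistence certificate and `ψ5 > 0` is its
Lyapunov margin.  A full crossover run:

```python
schedule = PiecewiseSchedule(dz=0.01, T1=10.0, T2=20.0, T=30.0)
traj = piecewise_solve(scenario.params, scenario.noise, scenario.y0.as_array(),
                       schedule, order=0.95, kernel="power_law", seed=1)
```

produces 3001 grid points labelled by regime; the susceptible pool decays
from 30 to 0.445 by day 10 (classical), drifts to 0.367 by day 20
(fractional memory), and fluctuates around 0.20 by day 30 (stochastic),
with every deterministic-prefix state nonnegative:

```
state at t=   0 d: Sf= 30.0000  Mb= 2.0000  Mg= 4.0000  U= 1.0000
state at t=  10 d: Sf=  0.4454  Mb= 0.3934  Mg= 4.1581  U= 6.2914
state at t=  20 d: Sf=  0.3674  Mb= 0.1538  Mg= 0.8007  U= 3.0002
state at t=  30 d: Sf=  0.2020  Mb= 0.0521  Mg= 0.1304  U= 0.6522
```

The `examples/` directory holds one short narrative script per capability
(thresholds, piecewise runs, ensembles and histograms, convergence
verification, ergodicity, scenario perturbation).  A thin CLI wraps the same
calls: `malnut simulate|ensemble|thresholds|scenarios|validate --help`.

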