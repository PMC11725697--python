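# abundint — abundance-mediated species interaction models

Ecologists usually infer species interactions from co-occurrence: does
the presence of a dominant species change the occupancy of a subordinate
one?  But interaction strength is driven by *how many* individuals are
present, not merely whether any are.  `abundint` implements a
hierarchical framework in which the occupancy or abundance of one
species depends on the **latent abundance** of one or more others,
estimated from ordinary repeated detection/non-detection surveys (camera
traps, track plates, transects) — the cheap data ecologists actually
have, with imperfect detection handled explicitly.

It is aimed at quantitative ecologists studying intraguild predation,
predator- or disease-mediated competition, and trophic cascades from
unmarked survey data, and at methodologists who want a transparent,
fully-tested MCMC implementation to extend.

## The model

For a dominant species `D` observed as counts `y_ij ∈ {0..K}` of
detection subsamples at site `i`, occasion `j` (a Royle–Nichols model):

    N_i^D ~ Poisson(λ_i),        log λ_i = x_i'β
    p_ij  = 1 − (1 − r_ij)^{N_i^D}
    y_ij^D ~ Binomial(K, p_ij)

and for a subordinate species `S` modeled through occupancy:

    z_i^S ~ Bernoulli(ψ_i)
    logit ψ_i = β0 + β1 x_i1 + γ0·N_i^D + γ1·N_i^D·x_i2
    y_ij^S ~ Bernoulli(p_ij^S · z_i^S)

The γ terms are the abundance-mediated interaction: each additional
individual of `D` shifts the subordinate's state by γ0 on the link
scale, optionally modulated by an environmental covariate.  Any acyclic
directed network of two or more species can be declared, with each
species' state variable chosen as abundance or occupancy, year-specific
intercepts for multi-year designs, and interactions on state or
detection submodels.  A matched co-occurrence variant (interactions as a
function of presence `z^D` instead of `N^D`) is available for
comparison.

Inference is a bespoke Metropolis-within-Gibbs sampler (numba-compiled):
exact categorical draws from the truncated full conditionals of the
discrete latent states, adaptive random-walk updates for coefficients,
and joint "ridge" moves for intercept/interaction pairs.  See
`docs/methods.md` for the full account.

## Worked example

Simulate the two-species constant-interaction design (300 sites, 4
occasions, r_D = 0.5, p_S = 0.5, λ_D = 1, mean ψ_S = 0.5, γ0 = −1) and
refit it:

```python
from abundint import preset_study2, simulate_dataset, fit, McmcConfig

scenario = preset_study2(300, 4, varying=False)
data, truth = simulate_dataset(scenario, seed=11)
result = fit(scenario.graph, data, McmcConfig(seed=5))
print(result.summaries.round(3).to_string(index=False))
```

prints

```
        parameter   mode   mean    sd   lo95   hi95  rhat  rhat_upper      ess
D:state:Intercept -0.156 -0.146 0.085 -0.315  0.019 1.000       1.001 1130.548
  D:det:Intercept -0.001  0.075 0.109 -0.141  0.290 1.001       1.002 1080.053
S:state:Intercept  1.081  1.026 0.234  0.602  1.524 1.002       1.006 1417.855
S:state:gamma0<D> -1.028 -0.988 0.218 -1.425 -0.581 1.001       1.004 1804.732
  S:det:Intercept -0.108 -0.099 0.093 -0.280  0.080 1.001       1.004 1725.837
```

Reading the interaction row: the posterior mode of γ0 is −1.03 with 95%
CrI [−1.42, −0.58] — the generating value −1 is recovered, every R̂
upper bound is below the 1.1 convergence rule, and `result.converged` is
True.  `D:state:Intercept` is log λ_D (truth 0) and the detection
intercepts are logit r_D and logit p_S (truth 0).

The same pipeline is scriptable from the shell:

```
abundint simulate --preset study2 --n-sites 300 --seed 11 -o data/
abundint fit --config data/model.json --data data/ -o fit/
abundint diagnose fit/
abundint study --preset study1 --lambda-d 0.5 --variants both --reps 25 --seed 1
```

Every command writes a JSON manifest with the full configuration and
seeds, so runs are exactly reproducible.

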