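# isolim

Linear inverse ecosystem models (LIM) for pelagic nitrogen food webs, with
stable-isotope (δ¹⁵N) constraints.

## The problem

Field programs measure only a handful of rates in a planktonic ecosystem —
net primary production, nitrate uptake, mesozooplankton grazing, sediment-trap
export — yet want the full web of nitrogen flows between phytoplankton,
protists, mesozooplankton, detritus and the dissolved pools. A LIM phrases
this as an under-determined linear system over the unknown flow vector
**x** (mmol N m⁻² d⁻¹):

- **Ex = f** — steady-state mass balance of each living/non-living
  compartment (9 equations for the built-in 35-flow web);
- **Ax ≈ b** — measurement constraints with uncertainty σ (±10% of the
  measured value);
- **Gx ≥ h** — physiological priors (e.g. grazer gross growth efficiency
  between 10 and 40% of ingestion).

`isolim` solves this system four ways:

| approach   | what it does |
|------------|--------------|
| `l2mn`     | equality/inequality-constrained least squares; among zero-residual solutions picks the minimum Σx² (lsei semantics) |
| `mcmc`     | Metropolis mirror random walk on {Ex=f, Gx≥h}, weighted by the measurement likelihood exp(−½σ⁻²‖Ax−b‖²) |
| `l2mn15`   | `l2mn` plus a grid search over the six unmeasured δ¹⁵N values |
| `mcmc15`   | a **joint** random walk over the flows *and* the unmeasured δ¹⁵N values, rebuilding the isotope constraint rows at every step |

The isotope extension adds ten linearised ¹⁵N mass-balance rows to **A**.
With ratios R = δ·R_N2/1000 + R_N2 and fractionation coefficients
α = exp(ε/1000) per process (nitrate uptake ε = −5‰, ammonium uptake −10‰,
excretion −5‰, egestion −2‰, remineralisation −1‰), each compartment's row
balances ¹⁵N inflow against outflow, e.g. for nitrate:

```
R_upno3·EXT→NO3 − (R_NO3·α_no3)·NO3→CYA − (R_NO3·α_no3)·NO3→DTM = 0
```

Four compartments' δ¹⁵N are measurable at sea (exogenous NO₃⁻,
mesozooplankton, DOM, sinking detritus); the remaining six (NO₃⁻, NH₄⁺, both
phytoplankton, both protist grazers) are treated as unknowns — sampled
jointly with the flows in `mcmc15`.

## Worked example

Four steady-state ecosystem snapshots ship as built-in scenarios
(`diazo_coastal`, `diazo_mesohaline`, `nemuro_coastal`, `nemuro_offshore`),
each with the measurements handed to the inverse model and the withheld
"true" indices used for evaluation.

```python
from isolim import (get_scenario, build_problem, solve_l2mn,
                    run_chain, run_joint_chain, ChainConfig)

fx = get_scenario("diazo_mesohaline")          # N2-fixation-rich ecosystem
problem, _ = build_problem(fx)                 # 35 flows, 9 + 4 constraints
sol = solve_l2mn(problem)

ens = run_chain(problem, ChainConfig(n_iter=100_000, seed=1))
_, rows = build_problem(fx, with_isotopes=True)
joint = run_joint_chain(problem, rows, ChainConfig(n_iter=100_000, seed=2))

def fix_share(flows):                          # % of uptake from N2 fixation
    fix = flows[..., 1] + flows[..., 2]
    tot = fix + flows[..., 3:7].sum(axis=-1)
    return 100 * fix / tot

print(f"truth  : {100*fx.truth['n2_fixation']/fx.truth['total_n_uptake']:.1f}%")
print(f"L2MN   : {fix_share(sol.x):.1f}%")
print(f"MCMC   : {fix_share(ens.flows).mean():.1f}%")
print(f"MCMC+15N: {fix_share(joint.flows).mean():.1f}%")
```

Output (seeds as above):

```
truth  : 10.5%
L2MN   : 27.9%
MCMC   : 11.1%
MCMC+15N: 9.4%
```

The minimum-norm solution exaggerates the fixation share (it suppresses
recycled ammonium production, which makes fixation look cheap); the sampling
approaches land close to the truth. The same pattern drives the headline comparison across
all four scenarios: the mirror chain systematically *underestimates* the
nitrate share of uptake, and the isotope-aware joint chain cuts that bias by
roughly a third.

The CLI mirrors the library:

```bash
isolim fixtures
isolim sample-mcmc --scenario diazo_mesohaline --with-isotopes \
    --iters 100000 --seed 1 --out runs/meso15
isolim indices --flows runs/meso15/flows.csv
isolim evaluate runs/* --truth diazo_mesohaline
```

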