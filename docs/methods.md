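# Methods

## Model

The food web has 9 mass-balanced compartments — nitrate (NO3), ammonium
(NH4), cyanobacteria/small phytoplankton (CYA), diatoms/large phytoplankton
(DTM), heterotrophic nanoflagellates (HNF), microzooplankton (MIC),
mesozooplankton (MES), detritus (DET), dissolved organic matter (DOM) — and
four external nodes (allochthonous nitrate EXT, dinitrogen NFX, sinking
particles SNK, higher trophic levels HTL). The 35 directed flows (mmol N
m⁻² d⁻¹) are: external nitrate input; N₂ fixation into both phytoplankton;
NO3 and NH4 uptake by both phytoplankton; grazing (CYA→HNF, CYA→MIC,
DTM→MIC, DTM→MES, HNF→MIC, HNF→MES, MIC→MES, MES→MES); detritivory by all
three grazers; losses of every living compartment to DET and DOM; grazer
excretion to NH4; DET→DOM and DOM→NH4 remineralisation; and the two exports
DET→SNK and MES→HTL. Steady state gives `Ex = 0` (the self-carnivory flow
MES→MES cancels in the MES row and is constrained only through the
inequality priors). Because the right-hand side is zero and all priors are
ratios, the hard-constraint set `{Ex=0, Gx≥h}` is a *cone*; the scale of a
reconstruction is fixed only by the measurement likelihood (the NPP row in
particular). Several design choices below deal with that conic geometry.

Measurements enter as approximate rows with σ = 10% of the measured value:
net primary production (total uptake + fixation − phytoplankton DOM
exudation; always present), nitrate uptake, mesozooplankton grazing
(DTM→MES), and sediment-trap export (DET→SNK). "Withholding" drops any of
the last three, singly or in pairs (7 configurations per scenario).

### Inequality priors

The prior set (all ratios, configurable in `default_inequalities`):
non-negativity on all flows; grazer gross growth efficiency 10–40% of
ingestion; grazer assimilation efficiency 50–90% (egestion 10–50% of
ingestion); grazer excretion (NH4 + DOM) 10–100% of ingestion;
phytoplankton DOM exudation 2–55% of gross production. These are the
standard planktonic-LIM bounds; only the GGE range is pinned by the source
material for the built-in scenarios, so published point values that depend
on the remaining bounds are reproducible only approximately. Biomasses and
temperature are carried in the scenario fixtures but unused by default; an
ingestion cap scaled by biomass·exp(0.0693·T) would slot in here but is not
enabled because its coefficient cannot be validated.

## Solvers

**L2MN.** Stage 1 minimises the σ-weighted residual of `Ax≈b` subject to
the hard constraints (dense primal active-set QP; a 10⁻¹² ridge keeps the
Hessian definite; a rank-revealing QR prunes dependent working-set rows;
`trust-constr` is a fallback for stalled iterations). Stage 2 minimises
Σx² subject to the additional equalities `Âx = Âx₁` — for a convex
quadratic the minimiser set is exactly the feasible set with the fitted
values pinned, so this reproduces lsei's tie-break without a second
tolerance. The active-set start point is the measurement-anchored interior
point below, *not* the LP vertex: the apex x=0 of the cone is active in
every homogeneous row at once and is a maximally degenerate vertex.

**Feasible/interior point.** A Chebyshev-like centre: maximise the minimum
inequality slack subject to `Ex=f`, with the measurement rows imposed as
exact equalities when consistent (this pins the scale of the cone and
centres the sampler start); total flow is capped to keep the LP bounded.
Infeasibility reporting solves a phase-1 relaxation and names the
constraint needing the largest slack.

**Mirror chain.** The walk lives in coordinates `q` of an orthonormal null
space `Z` of `E` (SVD; 26 dimensions for the full web). A proposal is a
Gaussian step reflected off the inequality hyperplanes segment-by-segment
(first crossing, reflect the remaining trajectory); the map is an isometry,
so the proposal stays symmetric. A cascade that exceeds 1000 reflections is
rejected in place. Acceptance follows `min(1, exp(−(res₁−res₀)/2))` with
`res = σ⁻²‖Ax−b‖²`; with no approximate rows every mirrored proposal is
accepted and the chain samples the polytope uniformly (validated against
Dirichlet moments on a simplex).

Step sizes: per-direction extents are probed by LP (min/max along each
null-space direction; conic directions are capped at 10× the start point's
total flow) and scaled by `jump_scale` (default 0.05). During burn-in a
global factor is retuned every window (a tenth of the burn-in, at most 1000
steps) toward an acceptance rate of 0.2–0.5, multiplying by the ratio of
observed to target rate (clamped). Uniform chains skip tuning — their
acceptance rate carries no information about step quality. Defaults:
100 000 iterations, 10 000 burn-in, thin 10, single seeded
`numpy.random.default_rng` per chain; identical seed ⇒ identical ensemble.

## Isotopes

δ‰ ↔ ratio conversions use R = δ·R_N2/1000 + R_N2 with R_N2 = 0.0036765
(atmospheric air ¹⁵N/¹⁴N; results are insensitive to the constant because
it nearly cancels between terms). Process fractionation coefficients are
α = exp(ε/1000) with ε_NO3 = −5‰, ε_NH4 = −10‰, ε_exc = −5‰ (excretion to
NH4 *and* DOM), ε_eg = −2‰ (egestion to DET), ε_rem = −1‰ (DET→DOM and
DOM→NH4). N₂ fixation introduces nitrogen at 0‰. The ten balance rows (nine
compartments + whole-system) put a coefficient ±R_source·α_process on each
flow; phytoplankton losses and predation transfers are unfractionated, and
the MES self-loop carries no term (an unfractionated self-loop moves
identical ¹⁵N in both directions). MES, DET (≡ sinking detritus) and DOM
take measured δ values; NO3, NH4, CYA, DTM, HNF, MIC are the six unknowns,
bounded in [−2, +16]‰ by default (spans every shipped scenario's δ values
with margin).

Row uncertainty: σ_row = 0.10 · Σ_flows |x_ref|·|R·(1−α)| over the row's
fractionating terms — i.e. 10% of the mass flow times the expected
fractionation — floored at 10⁻⁴·R_N2 so degenerate reference flows cannot
produce zero-weight rows. (The floor sits well below the smallest
single-flow fractionation signal, 0.1·R_N2·(1−e^{−0.005}).) In the joint
sampler the reference flows are the *current* proposal by default
(`sigma_mode="current"`); `"initial"` freezes them at the starting point —
both are provided because the reference choice is a genuine open question.

**Steady-state deltas.** For a known mass-balanced x the nine compartment
balances are linear in the compartment ratios; solving them (given the
boundary δ of exogenous nitrate and fixation) yields the isotopic state the
web relaxes to. This is the generator of synthetic δ truths and the
transcription oracle: rebuilding the rows at the solved deltas must
annihilate the generating flows to 10⁻¹⁰.

**Grid search (L2MN+15N).** Full product grids are guarded by an
evaluation-count limit (10⁷ — a 0.25‰ grid over six dimensions of [−2,16]
is 73⁶ ≈ 1.5·10¹¹ and must be run in `mode="coordinate"`, an axis-sweep
descent). Ties break by residual, then Σx², then lexicographic δ.

**Joint sampler (MCMC+15N).** Each iteration moves both blocks of the
state: a mirrored flow jump and a Gaussian δ jump (default scale 0.25‰,
matching the grid resolution) reflected into the prior bounds, each
Metropolis-accepted against the shared likelihood with the ten isotope
rows rebuilt for every proposed δ. The block updates are sequential rather
than a single joint accept because the two blocks see very different
likelihood sharpness: with one joint acceptance rate, whichever block
limits acceptance drives the adaptive tuner to freeze the *other* block's
walk (observed as δ credible intervals collapsing to the step size, or
flow steps shrinking a thousand-fold). Each block's step size adapts on
its own acceptance rate during burn-in. δ starts at the steady-state
solution of the initial feasible point (clipped to bounds; midpoints on
failure). Ensemble columns: 35 flows then the 6 δ values.

When the isotope-row σ track the current flows, the acceptance uses the
effective residual `σ⁻²‖Ax−b‖² + 2Σlog σ(x)` — the log term is the
Gaussian normalisation, without which a state-dependent σ lets the chain
drift toward weak-constraint (large-flow) states and dilutes the isotope
information.

## Indices and evaluation

Fifteen ecosystem indices summarise a flow vector: fixation; total uptake;
per-producer NPP (uptake − own DOM exudation); protozoan grazing
(CYA→HNF + CYA→MIC + DTM→MIC); mesozooplankton and protozoan carnivory;
secondary production (MES→HTL); guild gross growth efficiencies (ingestion
from outside the guild minus NH4/DOM/DET losses, over ingestion — internal
transfers HNF→MIC and MES→MES cancel at guild level); trophic levels
(TL = 1 + diet-weighted prey TL; producers and detritus at TL 1, so
detritivory does not inflate TL; the MES self-loop is solved as part of the
induced linear system; the protozoan TL is the ingestion-weighted mean of
HNF and MIC); and the herbivorous (DTM→MES/NPP), multivorous
((HNF→MES + MIC→MES)/NPP) and microbial-loop (DOM→NH4/NPP) shares of NPP.
The multivorous definition is the protist-mediated share of mesozooplankton
ingestion; path-tracing alternatives exist and cross-model agreement on
this index is not guaranteed.

Derived quantities reported from chains (fractions, indices, CIs) are
computed per sample and then summarised — a CI of a sum is the CI of
per-sample sums; the posterior "fixation share" is the mean of per-sample
shares. 95% intervals are empirical 2.5/97.5 percentiles.

Run evaluation pools, per index, the truth and all run estimates, fits a
two-parameter Box-Cox transform by profile maximum likelihood and
standardises the pool; a run's score is the sum of squared standardised
errors over the fifteen indices. The Box-Cox likelihood has a flat ridge
(shift → ∞ with compensating power tends to an affine map), so the
implementation uses the geometric-mean-scaled transform (which absorbs the
Jacobian and is numerically stable on the ridge), bounds the shift at 100
pool ranges, and falls back to the affine transform on degenerate fits.

## Synthetic ground truths

`generate_synthetic_truth` stands in for an independent forward model: it
draws a flow vector uniformly from the prior polytope — on its section at
NPP = 1, since a cone has no uniform measure (the anchor is a pure scale
choice; every prior is a ratio) — via a 50 000-step uniform mirror chain
thinned ×50 (reduced sizes are used in tests), solves the steady-state δ
field for an exogenous-nitrate δ drawn from [4, 14]‰, and emits rate
measurements with multiplicative Gaussian noise (sd 10%, the measurement
uncertainty the solvers assume). The four "measurable" δ values pass
through exactly. What this emulates: a self-consistent steady ecosystem
observed with noisy rate measurements. What it does not: structural
mismatch between the observed ecosystem and the inverse model's topology —
the built-in scenarios (whose generating models differ structurally from
the LIM web) cover that axis, but only at the index level, since their full
flow decomposition is not published. Passing recovery tests therefore
demonstrate statistical, not structural, robustness.

## Problem sizes and numerical defaults

Chains in the shipped tests and the acceptance script use 40 000–110 000
iterations (10 000–20 000 burn-in, thin 10); synthetic truths in tests use
8 000–15 000 generator steps. Feasibility tolerance 10⁻⁸ (absolute, flow
units); null-space and rank tolerances 10⁻¹⁰; QP convergence 10⁻¹⁰ with an
enumeration-oracle-verified active-set method. Scenario values are audited
against an embedded SHA-256 checksum.

## Known limitations

- Single currency (nitrogen), single layer; no δ¹³C or C:N coupling,
  though the row-builder structure extends to any linear tracer.
- The inequality set beyond the documented GGE bound is a reconstruction of
  standard practice; point reproductions that hinge on it carry a few
  percentage points of irreducible uncertainty (see the mean
  nitrate-underestimate comparison in the acceptance report).
- Single-chain diagnostics only (acceptance rate, determinism, trace
  export); no multi-chain convergence statistics.
- With state-dependent isotope-row σ (`sigma_mode="current"`) the target
  density is defined through the effective residual above; the alternative
  fixed-σ mode (`"initial"`) is a plain Gaussian likelihood. The two modes
  give similar but not identical posteriors; which reference the field
  convention intends is genuinely open, so both are first-class options.
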