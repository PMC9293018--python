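# Methods

## Model

The package models a well-mixed batch co-culture of a phototrophic diatom
and a heterotrophic marine bacterium in a mineral medium with no external
carbon source, over the time scale of a month. Light and CO₂ are treated
as unlimited and do not appear as state variables. Carbon flows from the
diatom to the bacterium through two dissolved-organic-matter pools:
exudate (`DOM_E`, photosynthates released by living cells at a constant
per-cell rate λ) and dead biomass (`DOM_B`, fed by diatom death). Both
pools also lose material to the environment at first-order rates
(`delta_DOME`, `delta_DOMB`), representing DOM that is never taken up.

Diatom growth is generalized logistic with carrying capacity `CC_D`.
Death rates of both organisms are damped by their own realized growth
rate, `δ = ν_δ / (1 + μ)`: an actively growing population dies more
slowly. Bacterial growth is Monod-limited by each DOM pool and carries
the same self-damping factor, which makes the growth law self-referential:

    μ_B = ν_μB/(1 + μ_B) · S,   S = DOM_E/(DOM_E+K_DOME) + DOM_B/(DOM_B+K_DOMB)

### Resolving the self-referential growth law

`μ_B (1 + μ_B) = ν_μB S` is a quadratic with a unique nonnegative root

    μ_B = (−1 + √(1 + 4 ν_μB S)) / 2,

which is the exact fixed point, smooth in all inputs and free of iteration
error; it is the default (`mu_B_resolution="quadratic_fixed_point"`). An
explicit mode dropping the 1/(1+μ_B) damping is provided for sensitivity
comparison. A test verifies the root against bisection on
`μ(1+μ) − ν_μB S` to 1e−10 over 1,000 random draws.

### DOM consumption bookkeeping

Written literally, both DOM balance equations subtract the full gross
growth flux `μ_B B`, which double-counts uptake (2 μ_B B consumed per
μ_B B of growth) and can drain an empty pool while the other sustains
growth. The default `split` mode apportions the single gross flux between
the pools in proportion to their Monod fractions, so the DOM budget closes
exactly: with washout off, cumulative production ∫(λ+δ_D)D dt minus
cumulative consumption ∫μ_B B dt equals the pool change (verified to
integrator tolerance). The `literal` mode is retained behind a flag for
fidelity checks. In both modes the bacterial equation is identical.

### Units and yield

DOM pools are denominated in bacterial-cell equivalents ml⁻¹: one DOM
unit converts to one bacterial cell. A yield multiplier
(`ModelOptions.yield_cells_per_dom`, default 1) rescales consumption if a
different stoichiometry is wanted. Time is in days throughout; the
sampling cadence of the underlying experimental design is 7 days.

### Other conventions

- The exudation term −λD in the diatom equation (exudation costs cell
  biomass) is kept, toggleable via `exudation_costs_biomass`.
- `CC_B` (a bacterial carrying capacity) is accepted by the parameter
  container and config parser for completeness but enters no rate law; the
  config reader warns about this.
- Inside the RHS, state components are clamped to 0 before rate
  evaluation. This protects adaptive steppers from tiny negative
  overshoots without altering the solution for nonnegative initial data;
  with the clamp, every negative RHS term vanishes as its state variable
  reaches 0, so trajectories remain nonnegative.

## Simulation

Integration uses `scipy.integrate.solve_ivp` with the adaptive explicit
Runge–Kutta 4(5) pair (default tolerances rtol 1e−8, atol 1e−10),
reporting on a uniform daily grid by default. Accuracy is validated
against two closed forms: pure exponential bacterial decay (no diatoms, no
DOM ⇒ μ_B = 0, δ_B = ν_δB) and the Verhulst solution for the diatom alone
(λ = ν_δD = 0); both agree to better than 1e−6 relative at days 7–28.

Two scenario sweeps are built in: scaling λ over fractions of its baseline
value (default levels 0, 0.25, 0.5, 0.75, 1, horizon 100 days — only the
range endpoints are canonical, the intermediate levels are a choice), and
scaling the initial DOM pools upward (multipliers 1–5, 28 days). Lag time
is operationalized as the first grid time at which B reaches twice its
inoculum (threshold configurable); when B never doubles the lag is
reported as NaN. The diatom death rate can be swept the same way
(`swept_symbol="delta_D"`); no quantitative anchor exists for it.

## Fitting

### Objective

Counts span ~10⁴–10⁸ ml⁻¹, so the default objective compares
`g(x) = log10(x + 1)` (the +1 count ml⁻¹ keeps zeros finite); a linear
scale is available. Each replicate contributes its own squared deviation
by default (`fit_to_replicates`), fitting per-time means is a flag, and
per-series inverse-variance weighting of `g(obs)` is optional. The
diatom:bacterium count-ratio series can be added to the objective; the
orientation is configurable since either convention is defensible.

### Optimizer

The minimizer is a Nelder–Mead simplex hybridized with simulated
annealing: during comparisons every stored vertex value is perturbed
upward by `−T ln u` and every trial value downward by a like amount, so
uphill moves are accepted at high temperature; at T = 0 the scheme is
exactly the standard downhill simplex (verified against scipy's
Nelder–Mead on a quadratic). The temperature cools geometrically (default
factor 0.9) from T₀ = the starting objective value; the simplex is
re-seeded at each temperature around the current chain point with step
sizes shrinking as √(T/T₀), and the whole schedule restarts from the
incumbent best (default 3 restarts, 50 steps per temperature). A
zero-temperature polish runs last. All schedule knobs and the polish
tolerances live on `FitConfig` and are logged in the result. T₀ should be
on the scale of the objective barriers to be crossed; the default (the
starting objective value) behaves well when the start is poor.

Free parameters with strictly positive bounds are searched in log10 space;
trial points are projected onto the bounds box, and parameters ending
within 1e−9 (relative) of a bound are flagged in the result. Fits are
bit-reproducible given `rng_seed`.

Inside the objective the ODE is solved with LSODA at rtol 1e−6: the
search visits corners of the bounds box (large rates with small
half-saturations) that are stiff enough to stall an explicit RK method,
while the final reported objective is re-evaluated at the simulator's
tight tolerances.

### Goodness of fit

R² defaults to the squared Pearson correlation between per-time replicate
means and predictions, with the two-sided p-value of
`t = r√(n−2)/√(1−r²)` on n−2 degrees of freedom; the 1 − SS_res/SS_tot
definition (which can be negative) is available by flag. With five time
points the printed p-values of the correlation test do not disambiguate
the convention used elsewhere for the same statistic (per-replicate n,
regression F, …), so no claim is made that any one convention reproduces
externally reported p-values; both the series vectors and the method flag
are in the caller's hands.

## Synthetic data

The generator emulates the co-culture's sampling design: 5 time points at
7-day intervals over 28 days, 3 replicates, counts ~10⁴–10⁸ ml⁻¹.
Observation noise is multiplicative lognormal with a chosen coefficient of
variation (default 0.10, mid-range for plate and haemocytometer counts),
in the mean-unbiased parameterization `mean · exp(σZ − σ²/2)`,
σ = √ln(1+cv²), so noiseless fits are consistent; a Poisson counting
model is the alternative. Values below a detection floor (default 10
counts ml⁻¹) are censored to the floor and flagged. Noise draws are keyed
by (seed, species, replicate, time), so designs sharing a seed produce
identical observations at common sampling times — densifying a schedule
never reshuffles the noise elsewhere, which makes design comparisons
paired.

The shipped reference parameter set (`reference_truth`) is synthetic: it
was chosen once to reproduce the qualitative shape of the real experiment
(inocula 1×10⁵ and 2×10⁵ ml⁻¹, ~14-day bacterial lag, near-linear diatom
rise toward ~10⁷ ml⁻¹, exudate dominating over detritus) and is not a set
of fitted values from any study. What the generator does **not** emulate:
replicate-level correlations, contamination, cross-counting error between
species, or any real dispersion structure beyond a constant CV — so
passing recovery tests demonstrate the pipeline's correctness and the
design's information content under these assumptions, not performance on
real plate counts.

## Parameter recovery and problem sizes

Closed-loop recovery (`parameter_recovery_experiment`) draws datasets,
refits each, and aggregates per-parameter relative errors and per-series
R². Free parameters start at the midpoint of their bounds (geometric for
positive bounds), never at the truth. The headline experiment fits the
three parameters governing the bacterium's carbon supply — ν_μB, λ,
K_DOME — with the rest frozen, over bounds chosen as biologically
plausible ranges (growth 0.05–20 day⁻¹, exudation 10⁻³–2 day⁻¹,
half-saturation 10⁴–10⁹ cell-equivalents ml⁻¹), 20 datasets at cv = 0.05,
annealing with 2 restarts × 30 temperatures × 25 steps. Statistical
property tests (error monotone in noise level; denser sampling not worse)
use the cheap zero-temperature simplex path with 20–60 datasets, since
those one- and two-parameter objectives are unimodal.

The bounds matter for more than speed: ν_μB and K_DOME are strongly
correlated along a ridge (below saturation only their ratio is well
constrained by five time points), and in an unrealistically wide box the
annealer can stall on that ridge at a small but nonzero objective.
Restricting the search to plausible ranges removes the degeneracy at this
design; users fitting real data should expect the same trade-off and
consider fixing one of the pair or measuring DOM directly.

## Known limitations

- No spatial structure, light/pH/nutrient sub-models, demographic noise,
  or more than two species; no steady-state or bifurcation analysis.
- No uncertainty quantification beyond the annealing trace; the recovery
  experiment's error distributions are the intended substitute at the
  synthetic level.
- Censored observations enter the objective at the floor value (flagged
  but not down-weighted).
- The lag-time statistic is grid-resolution limited (daily by default).
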