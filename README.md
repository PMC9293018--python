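# microloop

Population dynamics of a diatom–bacterium co-culture: a four-variable ODE
model with logistic and Monod kinetics, a simplex + simulated-annealing
parameter-fitting engine for sparse replicated count series, scenario
sweeps, and a synthetic-data generator for closed-loop validation.

## The problem

In the marine microbial loop, heterotrophic bacteria grow on dissolved
organic matter (DOM) released by phototrophs. In a batch co-culture of a
diatom and a marine bacterium with no added carbon source, the bacterium
can only grow on diatom-derived carbon, which arrives through two routes:
photosynthates actively exuded by living cells, and material released by
dead cells. `microloop` models this system for people who run such
co-cultures and want to ask quantitative questions of their count data:
which carbon route dominates, what exudation rate is consistent with the
observed bacterial growth curve, and how the system responds when carbon
supply is perturbed.

## The model

Four state variables: bacteria `B` (CFU ml⁻¹), diatoms `D` (cells ml⁻¹),
and two DOM pools in bacterial-cell equivalents ml⁻¹ — exudate `DOM_E` and
dead-biomass `DOM_B`:

    dB/dt     = (μ_B − δ_B) B
    dD/dt     = (μ_D − δ_D − λ) D
    dDOM_E/dt = λ D   − c_E B − δ_DOME · DOM_E
    dDOM_B/dt = δ_D D − c_B B − δ_DOMB · DOM_B

with rates

    μ_D = ν_μD (1 − D / CC_D)                      (Verhulst growth)
    δ_D = ν_δD / (1 + μ_D)                         (growth-damped death)
    μ_B = ν_μB/(1+μ_B) · [ DOM_E/(DOM_E + K_DOME)
                          + DOM_B/(DOM_B + K_DOMB) ]  (Monod, self-damped)
    δ_B = ν_δB / (1 + μ_B)

The bacterial growth law is self-referential; it is resolved exactly as
the nonnegative root of `μ_B (1 + μ_B) = ν_μB · S`, where `S` is the sum
of the two Monod fractions. Consumption fluxes `c_E, c_B` split the gross
growth flux `μ_B B` between the pools in proportion to their Monod
fractions (a literal per-pool `μ_B B` mode is retained behind a flag).
All rates are per day. Exudation is a constant per-cell rate λ,
consistent with a healthy, near-linearly growing diatom population.

Parameters are estimated by minimizing the squared deviation between
log10-transformed observed and predicted counts with a hybrid of the
downhill simplex and simulated annealing (temperature-perturbed vertex
comparisons, geometric cooling, simplex restarts), and fit quality is
reported as squared Pearson R² per series (bacteria, diatoms, and their
cell-count ratio).

## Worked example

Simulate the shipped reference co-culture (a synthetic parameter set that
reproduces the qualitative design: inocula of 1×10⁵ bacteria and 2×10⁵
diatoms per ml, a two-week bacterial lag, diatoms rising near-linearly
toward ~10⁷ cells ml⁻¹ over 28 days):

```python
from microloop import reference_truth, integrate, daily_grid, lag_time

truth = reference_truth()
traj = integrate(truth.params, truth.init, daily_grid(28))
for day in (0, 7, 14, 21, 28):
    print(f"day {day:2d}  B = {traj.B[day]:.3e}  D = {traj.D[day]:.3e}")
print("bacterial lag time:", lag_time(traj), "days")
```

prints

```
day  0  B = 1.000e+05  D = 2.000e+05
day  7  B = 9.138e+04  D = 9.465e+05
day 14  B = 2.455e+05  D = 3.515e+06
day 21  B = 2.713e+06  D = 7.490e+06
day 28  B = 8.863e+06  D = 9.608e+06
bacterial lag time: 14.0 days
```

The bacterium holds steady for the first two weeks (deaths roughly balance
growth on the still-scarce DOM), then grows two orders of magnitude once
the diatom population has accumulated enough exudate — the signature
dynamics of this co-culture.

The same pipeline from the shell: generate a noisy synthetic observation
table, refit it, and sweep the exudation rate:

```sh
microloop synth --config params.json --cv 0.05 --seed 7 --out obs.csv
microloop fit   --obs obs.csv --config params.json \
                --fit-config fit.json --seed 7 --out-prefix run
microloop sweep --config params.json --symbol lam \
                --levels 0,0.25,0.5,0.75,1.0 --horizon 100 --out sweep.csv
```

`params.json` is a flat JSON file of the parameter, initial-state and
option fields (write one with `microloop.io.write_model_config`); the fit
writes a key-value report (`run_report.txt`) with the objective value,
per-series R² and p-values, and a `run_params.json` directly reusable by
`simulate` and `sweep`. Every command writes a manifest recording its
inputs, seed and package version.

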