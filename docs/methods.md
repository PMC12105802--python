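# Methods

## Scope

`stua` quantifies how spatial uncertainty in a simulation output propagates
between two model times. It has three layers:

1. **Propagation indices** (`stua.indices`) — pure functions of a per-cell
   uncertainty measure `U` at times `t1` and `t2`.
2. **Per-cell variance / total-effects sensitivity** (`stua.sobol`) — the
   paired-ensemble Monte Carlo machinery that produces such a measure.
3. **Tobacco Town** (`stua.town`, `stua.experiments`) — a grid agent-based
   model of daily cigarette purchasing used as the worked application, with
   two reference experiments (wages, smoking rates).

## Propagation indices

With `s = |U_t1| + |U_t2|`, the irrelevance index is

    I = alpha * s - beta**(-s),      alpha > 0, beta >= 1.

`I` rises strictly in `s` (for `beta >= 1`), is `-1` at `s = 0`, and crosses
zero at a unique threshold `lambda_I` solved by bisection from
`alpha * s = beta**(-s)` (tolerance 1e-10, bracket `[0, max(1, 1/alpha)]`,
doubled if floating point grazes the end; at `beta = 1` the root is exactly
`1/alpha`). Cells with `I <= 0` — the boundary included — are excluded:
their uncertainty is insignificant at both times. The constraint
`beta >= 1` guarantees `beta**(-s) <= 1`, so no high-uncertainty cell
(`s > 1/alpha`-ish) can be screened out.

The relevance index on the surviving cells is

    R = eta * U_t2**3 + rho * (U_t2 * |U_t1|)**3,   eta > 0, rho >= 0.

Both terms carry `U_t2**3`, so `sign(R) = sign(U_t2)`; `|R|` is
non-decreasing in `eta`, `rho`, `|U_t1|` and `|U_t2|`. Cells classify as
relevant-positive (`R > tol`), relevant-negative (`R < -tol`) or near-zero
(`|R| <= tol`); the near-zero tolerance defaults to 0.05, a presentation
choice (no canonical value exists) sized to the `[-1, 1]` range of a
sensitivity measure.

Factor selection is mediated by closed-form thresholds:
`lambda_U = (lambda_R / eta)**(1/3)` is the `|U_t2|` magnitude at which the
eta-term alone reaches the emphasis level `lambda_R`, and
`eta = lambda_R / lambda_U**3` inverts it. The edge-case bound on `rho` is
`(1 / |U_t1 * U_t2|)**kappa`; the exponent is exposed because two
conventions are coherent — `kappa=3` mirrors the cubic term of `R` (bound
64 at the 0.5/0.5 edge case), while `kappa=1` states the bound on the
product scale (bound 4 at the same edge case). Default `kappa=3`; neither
is asserted as uniquely correct.

## Variance maps and the total-effects field

The base input matrix `A` holds `m` sample rows of named column blocks
(here: per-agent wages and smoking rates). `A*_j` equals `A` except that
the focus block `j` is independently redrawn from the same distribution.
Sampling is quasi-random: one scrambled Sobol' sequence of dimension
(total width + focus width); the base matrix uses the leading dimensions
and the redraw the trailing ones (the radial construction). Drawing the
redraw from a separately scrambled stream is wrong — two scramblings of
the same sequence are point-wise correlated, which biases paired
estimators; this is why the redraw shares the joint stream.

Per occupied cell and recorded time,

    V  = population variance (divide by m) of the A-ensemble outputs,
    VC = population variance of the A*_j-ensemble outputs,
    S  = (V - VC) / V   where V > 0, undefined (NaN) where V = 0.

Paired ensembles run with **common random numbers**: per-run seeds are
derived from (master seed, row index), so a model that ignores the focus
column produces `B*_j == B` bitwise and `S == 0` exactly — a structural
null test the suite asserts.

Because the redraw preserves the marginal of `j`, `E[V] = E[VC]` and `S`
scatters around zero with spread that grows with the output's true
sensitivity to `j`. Regional contrasts in `|S|` — not the magnitude of `S`
itself — therefore carry the signal. The classical Jansen total-order
estimator `mean((f_A - f_A*)^2) / (2 V)` over the same paired ensembles is
provided as an independent, consistently-scaled cross-check (it recovers
the analytic total index on the toy model); it is not the default
reported measure.

Cells with `V = 0` (unoccupied, or occupied by non-purchasers) are
reported as undefined rather than zero: no variance decomposition exists
there.

## Tobacco Town

A `W x H` grid of land plots (default 32 x 32); a plot can house any
number of human agents but at most one object (outlet or workplace).
Defaults: 302 agents, 85 outlets, up to 1024 workplaces. Placement order
is outlets (distinct cells), then homes (uniform over non-outlet cells,
with replacement, so plots may house several agents), then workplaces on
the remaining free cells — the requested 1024 cannot coexist with 85
outlets and object-free homes on 1024 cells, so the workplace count
truncates to the free cells (~660). All layout structure is a function of
the layout seed alone and is held fixed across ensemble runs so that
output differences are attributable to the sampled inputs.

**Movement.** A commute route is drawn once per agent at initialization:
from home to work, each step uniform among the Moore (8-neighbour) cells
that strictly decrease Euclidean distance to the target. Strict decrease
on a finite grid guarantees termination; the 8-neighbourhood guarantees a
qualifying neighbour always exists off-target (the 4-neighbourhood can
dead-lock on diagonals). The evening trip retraces the same route. The
outlet visit happens on the morning trip (the model statement allows
either trip; one had to be fixed). Route randomness does not feed the
purchase output, so per-day re-simulation of movement is not performed.

**Purchasing.** Each day an agent buys iff its smoking rate is positive
and its cigarette inventory (in cigarettes, 20 per pack) is below the
daily rate. Inventory is kept in cigarettes, not packs, because the
trigger compares it with a per-day cigarette rate. The detour distance
`d_r` is twice the minimum Chebyshev distance from any route cell to the
nearest outlet (out-and-back), precomputed at initialization. The cost of
`q` packs is

    C_r(q) = (d_r/s + gamma) * w * zeta + d_r * f/e + q * price(q)

with `s` travel speed, `gamma` hours per stop, `w` annual wage, `zeta`
the wage-to-hourly conversion (default 1/2080, a full-time work year),
`f` fuel price, `e` fuel efficiency. The agent buys the `q` in
`{1..q_max}` minimising `C_r(q)/q`, ties to the smallest `q`, subject to a
per-trip budget of `purchase_budget_frac * w` (default 7.2e-4 of the
annual wage, ~4.5 packs at the default price and mean wage; at least one
pack is always affordable). The budget cap is the deliberate wage→output
channel: with any non-increasing pack-price schedule the amortised
per-pack cost `(fixed + q*price)/q` is strictly decreasing in `q`, so the
argmin is always `q_max` and wages would otherwise have *no* effect on
purchases at all. Agents evaluating what they can buy given their wage
motivates the cap; setting `purchase_budget_frac=None` disables it (the
suite asserts the sensitivity field is then identically zero for the
wages focus). Consumption (the daily rate) is drawn down after any
purchase, which makes day-1 purchases non-trivial for smokers starting
empty. Daily purchased cigarettes accumulate at the agent's home plot;
the recorded output is the **mean spatial purchase**: per plot, mean
cigarettes bought that day per resident.

Input draws are truncated to their supports: wages positive, smoking
rates rounded to non-negative integers (the normal tails are otherwise
unbounded).

The per-agent quantity choice is constant within a run (prices and
distances are static), so the ensemble path computes it once and advances
30 days of inventory recursions with array operations; the object-level
`step_day` implements the same dynamics agent by agent, and the suite
asserts the two paths produce identical grids.

## Reference experiments

The grid splits at the vertical mid-line: west = columns `[0, W/2)`. Per
experiment one behavioural input is the focus column, drawn per agent
from region-dependent normals — wages: mean 50 000, SD 5 000 west / 500
east; smoking rates: mean 20, SD 10 west / 2 east; the non-focus input is
sampled from its own distribution in both ensembles (identically, since
only the focus column is redrawn). Recorded days are 1 and 30 over a
30-day horizon (every smoker purchases at least once in 30 days). Index
factors default to `alpha=2, beta=2, eta=2, rho=1` for the wages
experiment (low sensitivity magnitudes → low screening threshold
`lambda_I ≈ 0.38`, steep relevance curve) and `alpha=1, beta=1, eta=1,
rho=0.5` for the rates experiment (`lambda_I = 1`, flat relevance curve).
The packaged default ensemble size is m = 500 per set (the reference
study setting is 3 000; 500 keeps a desk run in seconds while leaving the
regional contrast statistically clear). Outputs are the eight maps —
V, VC at both days, U = S at both days, I and R — plus the category grid
and a per-region summary that reports percentages against both the
occupied-cell and the all-cell denominators, since either population can
be of interest.

## What the synthetic set-up does and does not show

All inputs are configuration-driven; there is no empirical calibration.
The generator reproduces the *structure* of the application — fixed
abstract layout, region-split input dispersion, purchase dynamics — not
any empirical wage/consumption distribution, commuting network or outlet
geography of a real region. Passing tests therefore demonstrate the
correctness and reproducibility of the indices, estimators and dynamics,
and the qualitative east/west contrast under wider western input
dispersion; they do not certify empirical counts or percentages of
relevant units, which depend on unpublished input distributions. At the
packaged ensemble sizes the as-defined `S` estimator concentrates near
zero, so with the reference factors most or all cells are screened out
(`I <= 0`); the informative signal at desk scale is the regional contrast
in `|S|`, which the acceptance suite checks over five independent
replicates.

## Numerical choices

- Missing sentinel: NaN everywhere (grids, CSV round trips write empty
  cells).
- Bisection tolerance 1e-10; variance maps use the stable two-pass form
  and are asserted against a brute-force oracle at 1e-12.
- Quantity argmin guards float ties by rounding per-pack costs to 12
  decimals before `argmin` (first minimiser = smallest q).
- Jansen estimates are clipped to `[0, 1 + 1e-6]` for reporting (the raw
  estimator is non-negative but can overshoot 1 by Monte Carlo noise).
- Grid CSVs store floats with `repr` (shortest round-trip), so
  write-then-read is bit-identical.
- Seeds: all derived via `numpy.random.SeedSequence`, kept below 2^31.

## Known limitations

- Two time points only; no multi-step trajectories or spatio-temporal
  clustering of the indices.
- One uncertainty measure wired end-to-end (the total-effects field);
  the index layer accepts any caller-supplied field.
- Single transport mode by default (per-mode fuel/speed is config).
- No policy levers (outlet removal, price caps) and no smoking
  initiation/cessation dynamics.
- The wage channel is a stylised budget cap; richer affordability or
  outlet-choice behaviour would change the wages experiment's magnitudes
  (not the machinery).
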