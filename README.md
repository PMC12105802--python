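# stua — spatio-temporal uncertainty propagation for spatial ABMs

Spatially explicit simulations carry per-cell output uncertainty that
changes over simulated time. Comparing two uncertainty maps by eye is
unreliable, so `stua` computes per-cell *propagation indices* between two
model times `t1` and `t2` for any per-cell uncertainty measure
`U` (for instance a total-effects Sobol sensitivity index):

- **Irrelevance index** `I = α·s − β^(−s)` with `s = |U_t1| + |U_t2|`
  (`α > 0`, `β ≥ 1`). Cells with `I ≤ 0` are insignificant at both times
  and are screened out; the screening threshold on `s` is the root
  `λ_I` of `α·s = β^(−s)`.
- **Relevance index** `R = η·U_t2³ + ρ·(U_t2·|U_t1|)³` (`η > 0`,
  `ρ ≥ 0`) on the surviving cells. `sign(R) = sign(U_t2)`: positive cells
  are driven by the focus input at `t2`, negative cells by the other
  inputs, near-zero cells were relevant at `t1` only.
- Closed-form factor selection: `λ_U = (λ_R/η)^(1/3)` links `η` to the
  `|U_t2|` magnitude emphasised at relevance level `λ_R`.

The uncertainty measure is produced by a paired-ensemble total-effects
layer: per cell, `S = (V − VC)/V`, where `V` is the output variance over
runs of a base sample matrix `A` and `VC` over a companion `A*` whose
focus column is independently redrawn (quasi-random radial sampling,
common random numbers across the pair). A Jansen total-order estimator
over the same pair serves as an independent cross-check.

The worked application is **Tobacco Town**, a grid ABM of smoking
behaviour: agents commute between home and work, and smokers whose
cigarette inventory falls below their daily rate detour to the outlet
nearest their route, buying the pack count that minimises per-pack cost
(travel time valued at their wage + fuel + packs). Two reference
experiments perturb per-agent wages or smoking rates with wider western
than eastern dispersion and track the mean cigarettes purchased per
resident per cell at days 1 and 30.

## Worked example

Pick index factors from the closed-form thresholds, then run the wages
experiment end to end:

```bash
$ stua thresholds --alpha 2 --beta 2 --eta 2 --lambda-r 0.1
lambda_I(alpha=2.0, beta=2.0) = 0.383332
lambda_U(eta=2.0, lambda_R=0.1) = 0.368403
```

So with `α = β = 2` a cell survives screening when
`|U_day1| + |U_day30| > 0.383`, and with `η = 2` a day-30 sensitivity
magnitude above 0.368 is emphasised at relevance level 0.1.

```python
import numpy as np, stua

art = stua.run_stua_experiment(
    stua.wages_spec(m=500, layout_seed=0, sampling_seed=1, run_seed=2)
)
masks = stua.region_masks(art.occupied.shape)
west = np.nanmean(np.abs(art.U_t2.S[masks["west"] & art.occupied]))
east = np.nanmean(np.abs(art.U_t2.S[masks["east"] & art.occupied]))
print(f"mean |U(day 30)|  west: {west:.4f}   east: {east:.4f}")
```

prints

```
mean |U(day 30)|  west: 0.0495   east: 0.0000
```

The wider western wage dispersion (SD 5 000 vs 500) produces a clearly
larger day-30 sensitivity magnitude in the west; in the east the wage
redraw leaves purchases bitwise unchanged, so `S` is exactly zero there.
Because the paired-redraw estimator scatters tightly around zero at this
ensemble size, the classification step then screens out all cells at
`λ_I ≈ 0.383` (`art.summary` reports 130/130 west and 134/134 east
excluded) — the regional contrast in `|S|`, not the raw magnitudes, is
the informative signal at desk scale. `art.grids()` exposes the eight
maps (V, VC, U at both days, I, R) and
`stua.viz.render_propagation_panel(art, "panel.png")` renders the
four-panel figure.

The same pipeline is scriptable from the shell:

```bash
stua experiment --focus wages --runs 500 --seed 0 --out out/wages
stua render --artifacts out/wages --out out/wages_maps
```

Every command writes a `manifest.json` (seeds + config digest) from which
the outputs reproduce bit for bit.

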