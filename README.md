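# maskgap

Small-area supply–demand gap estimation for rationed goods.

During a rationing program (the motivating case: adult surgical masks sold
through registered pharmacies at a fixed quota of nine masks per person per
two weeks), the only large-scale record of who got served is each store's
inventory telemetry. `maskgap` turns those raw 10-minute stock traces into
a village-level map of relative supply and of the probability of
undersupply, for analysts in public health and resource allocation.

The pipeline:

1. **Inventory preprocessing** — hourly stock decrements → masks sold per
   day → average customers served per day per store (sales / quota).
2. **Change of support** — Voronoi service areas around stores, then
   area-weighted areal interpolation of customer counts onto village
   polygons (homogeneous-density assumption).
3. **Demand benchmark** — expected counts `E_i = r·Pop_i` with
   `r = ΣY_i/ΣPop_i`; raw relative risk `ρ_i = Y_i/E_i` (`ρ < 1` ⇒
   undersupply).
4. **Bayesian hierarchical models** — four log-linear count models with
   offset `E_i`:

   ```
   Y_i ~ Poisson(λ_i = E_i ρ_i)            or  NB(λ_i, ϑ), Var = λ + λ²/ϑ
   log ρ_i = b₀ + b₁x₁ + … + b₆x₆ [+ u_i + ν_i]
   u_i | u₋ᵢ ~ N(mean of neighbors, σ_u²/N_i)   (intrinsic CAR / BYM)
   ν_i ~ N(0, σ_ν²)
   ```

   with covariates store count, log median income and four land-use
   shares; vague `N(0, 1000)` priors on the `b`'s and `Gamma(10⁻⁴, 10⁻⁴)`
   on the precisions. Sampling is a numba-compiled Metropolis-within-Gibbs
   with an interweaving move that makes short chains mix (see
   `docs/methods.md`).
5. **Outputs** — posterior RR per village with credible intervals,
   exceedance probabilities `Pr(RR < 1)`, DIC/WAIC/MAPE/MSE model
   comparison, VIF screening, choropleth maps, and a reproducibility
   manifest.

A fully seeded synthetic-data generator (`maskgap.synthgen`) emulates the
whole study — inventory traces with restocking, village tessellations,
covariates, and counts drawn from the BYM model at known parameters — so
every stage is testable without the original restricted-access archive.

## Worked example

Run the whole pipeline on a 200-village synthetic region:

```python
import maskgap as mg

cfg = mg.RunConfig(out_dir="demo_run", seed=11, n_villages=200,
                   n_stores=100, region_size=18_000.0, n_days=5,
                   chains=2, iterations=2000, burnin=1000, thin=2)
out = mg.run(cfg)
```

or equivalently `maskgap run --out demo_run --seed 11` with the same
settings in a config JSON. The run directory contains, among others,
`scores.csv`:

```
          model       DIC      WAIC  MAPE    MSE   p_DIC  p_WAIC
        poisson 14412.082 15222.574 2.051 21.289   6.828 666.221
         negbin  2129.939  2135.634 4.273 18.800   8.203  12.333
poisson_spatial  1479.875  1424.484 0.041  0.004 195.022 100.696
 negbin_spatial  1843.447  1775.029 0.228  0.371 221.335 116.641
```

The spatial Poisson model fits this region best (lowest DIC/WAIC), and its
posterior-mean RRs track the raw RRs closely (MAPE 0.041 on the RR scale)
— the aspatial models smooth the RR surface away (MAPE 2.05). Per-village
results are in `villages_poisson_spatial.csv`:

```
village_id  rho_mean  rho_q025  rho_q50  rho_q975  pr_under
     V0000     5.238     4.053    5.238     6.514     0.000
     V0001     0.153     0.065    0.146     0.275     1.000
     V0002     0.395     0.274    0.388     0.540     1.000
     V0003     2.002     1.308    1.996     2.795     0.000
     V0004     0.548     0.275    0.529     0.913     0.988
```

Village V0001 received ~15% of its population-share supply and is flagged
as undersupplied with probability 1.0; V0000 is a strongly over-served
village (RR ≈ 5). In this run the overall service rate is r = 0.0097
customers per adult per day, the median raw RR is 0.93, and 90 of 200
villages have Pr(RR < 1) > 0.95. `map_rr_poisson_spatial.png` and
`map_pr_under_poisson_spatial.png` show the corresponding choropleths
(color scale anchored at RR = 1).

The CLI exposes each stage separately (`maskgap simulate`, `preprocess`,
`allocate`, `fit`, `evaluate`, `run`); see `--help`.

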