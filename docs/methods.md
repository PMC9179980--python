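# Methods

`maskgap` estimates where a rationed good was under- or over-supplied at
the level of small administrative areas ("villages"), given only per-store
inventory telemetry, store locations, and village polygons with population
and covariates. This note records the model, the algorithms, the synthetic
data generator, and the numerical choices, in the order the pipeline runs.

## 1. From inventory traces to customers served

Each store reports its stock level on a 10-minute grid. Sales appear as
decrements, deliveries as jumps. The preprocessing is deliberately simple:

1. aggregate the stock to one value per clock hour, keeping the **last**
   observation in each hour (a stock level is a state, not a flow, so the
   end-of-hour value is the meaningful summary); hours with no observation
   are skipped and the next difference spans the gap;
2. per calendar day, sum the absolute values of the **negative** hourly
   differences — this is that day's masks sold, `I_t^s`;
3. average over the `T` calendar days that have at least one observation
   (a store whose feed starts late is not diluted by empty days);
4. divide by the rationing quota — **9** masks per person per two weeks in
   the study window — to convert masks/day into customers/day.

A restock landing in the same hour as sales partially cancels them (only
the net hourly change is observed). This under-counts sales slightly; the
bias is inherent to the procedure and is left uncorrected, which is why
the synthetic-data tests select collision-free traces when asserting exact
recovery.

## 2. Change of support: stores to villages

Store-level customer counts live at points; the model needs counts on
village polygons. Two classical steps bridge the gap:

* **Voronoi service areas.** Each store's catchment is the set of
  locations nearer to it than to any other store (plain Euclidean
  distance, planar metric coordinates). Cells are clipped to the study
  region, since the raw outer cells are unbounded and area ratios would
  not exist. Exactly coincident stores are merged with summed counts
  before tessellation.
* **Areal interpolation.** Under a homogeneous-density assumption, a
  village receives from each cell `count_cell × area(cell ∩ village) /
  area(cell)`. When the villages tile the region this conserves the total
  count exactly (asserted to 1e-9 relative in tests). Overlay slivers
  below 1e-9 m² are dropped; a degenerate zero-area cell donates its count
  to the village containing its generator.

The interpolated count is fractional; it is rounded half-to-even to `Y_i`
for the count likelihoods (the unrounded value is kept in `Y_frac`). The
village covariate "store count" is a plain point-in-polygon count with a
deterministic lowest-id tie-break on boundaries.

## 3. Demand side

The expected count is `E_i = r · Pop_i` with `r = ΣY_i / ΣPop_i` the
overall service rate, so `ΣE = ΣY` by construction and the raw relative
risk `ρ_i,raw = Y_i / E_i` has E-weighted mean exactly 1. `ρ < 1` flags
undersupply relative to the area's population share. Villages with zero
population get `E_i = 0`, an undefined offset, and are excluded from the
model likelihood (they are flagged and reported, not silently dropped).

## 4. The four hierarchical count models

With offset `E_i` and covariates `x_1..x_6` (store count, log median
income, business/residential/mixed/school area shares):

* Poisson: `Y_i ~ Poisson(λ_i)`, `log(λ_i/E_i) = b_0 + Σ_j b_j x_ij`
* negative binomial: same predictor, `Var(Y_i) = λ_i + λ_i²/ϑ` (NB2;
  the Poisson is the `ϑ → ∞` limit)
* Poisson spatial / NB spatial (Besag-York-Mollié): add `u_i + ν_i`,
  where `u` is intrinsic CAR — `u_i | u_{-i} ~ N(mean of neighbors,
  σ_u²/N_i)` under queen contiguity — and `ν_i ~ N(0, σ_ν²)` iid.

Priors: `N(0, 1000)` per fixed effect, `Gamma(0.0001, 0.0001)` on both
precisions `1/σ_u²`, `1/σ_ν²`, `Gamma(0.01, 0.01)` on `ϑ`. The ICAR term
is kept identifiable against the intercept by recentring `u` to sum to
zero on every connected component after each sweep; islands (no
neighbors) have `u_i` fixed at 0 and rely on `ν_i`. The ICAR precision
rank used in the conjugate update is (active sites − components).

Per-village outputs are posterior draws of `ρ_i = exp(predictor)`, their
mean/quantiles, and the undersupply probability `Pr(ρ_i < 1)` as the
fraction of draws below the threshold.

### Sampler

Posterior sampling is Metropolis-within-Gibbs, compiled with numba:

* **Warm start**: ~25 damped IWLS (Newton) steps toward the penalized
  Poisson mode, then a per-chain overdispersed jitter on the proposal
  scale, so split-R-hat means something at short run lengths.
* **Fixed effects**: one joint random-walk proposal per iteration, shaped
  by the Cholesky factor of the inverse expected information
  `(X'WX + I/1000)⁻¹` (`W = λ` for Poisson, `λϑ/(λ+ϑ)` for NB), scalar
  scale adapted toward 0.25 acceptance during burn-in, shape refreshed
  every 200 burn-in iterations.
* **Random effects**: single-site random-walk Metropolis for `u_i`
  (ICAR full conditional as prior) and `ν_i`, scales adapted toward 0.44.
* **Interweaving ("ridge") move**: propose `b → b + δ`, `ν → ν − Xδ`
  jointly. The linear predictor is unchanged, the likelihood cancels
  exactly, and acceptance depends only on the two Gaussian priors. This
  targets the near-flat ridge between fixed effects and the unstructured
  effect that otherwise makes the conditional scan mix at R-hat > 2 even
  for modest problems; with it, 2-chain × 2000–4000-iteration runs give
  usable effective sample sizes on 1000-village regions in seconds.
* **Precisions**: conjugate Gamma draws. **ϑ**: random walk on `log ϑ`.

Convergence is summarized by split-R-hat and effective sample size
(computed with ArviZ) on the fixed effects; R-hat above 1.1 flags the fit
as non-converged in the output rather than raising.

Defaults are 4 chains × 5000 iterations (2500 burn-in, thinning 5); the
validation experiments run 2 chains × 3000–4000 iterations, which the
interweaving move makes adequate at the ~1000-village scale they use.

## 5. Model comparison and diagnostics

* **DIC** = `D̄ + p_D`, conditional variant: the point deviance is
  evaluated at the posterior means of *all* parameters, random effects
  included, as hierarchical disease-mapping software conventionally does.
* **WAIC** = `−2(lppd − p_WAIC)` with `p_WAIC = Σ_i Var_draws(log p_i)`;
  observations with `p_WAIC,i > 0.4` trigger a recorded warning (common
  for BYM models, where per-area random effects make the pointwise
  variance large — rankings remain the portable quantity).
* **MAPE / MSE** compare the posterior-mean RR with the raw RR on the
  relative-risk scale. The RR scale is chosen because error magnitudes of
  order 0.002–2 are only consistent with RR units, not counts, at
  median counts of ~100; count-scale versions are emitted alongside for
  transparency. MAPE excludes raw-RR-zero villages (division by zero) and
  reports how many were excluded.
* **VIF** per covariate from OLS of each on the others plus intercept;
  values ≥ 10 would flag multicollinearity.

## 6. The synthetic-data generator

The generator emulates the study conditions end to end, so every stage is
testable without the restricted-access archive:

* **Region**: a square tiled by Voronoi cells of uniform random points —
  1488 villages and 1774 stores over a 57 km side at study scale (≈1.6 km²
  per village, matching a metropolitan tessellation); experiments use
  smaller regions with the side scaled as 40·n meters, which keeps the
  cell size — and hence the adjacency structure — comparable at n = 1000.
* **Population**: lognormal, median 4268 adults (study-scale median),
  σ = 0.8.
* **Covariates**: store count ~ min(Poisson(1.1), 9); income lognormal
  (median 439, σ = 0.25, thousand-currency units, so log-income spans
  ~log 222–log 1031); the four land-use shares from a
  Dirichlet(0.4, 1.3, 1.1, 0.25, 3.0) draw (business, residential, mixed,
  school, other), which reproduces the observed quartiles and keeps the
  four shares summing below 1.
* **Inventory**: 49 days of 10-minute traces; daily realized sales are
  Poisson around the store mean (lognormal across stores, median 900
  masks/day ≈ 100 customers/day at quota 9), spread multinomially over
  09:00–21:00 bins; restocks refill to capacity with probability 0.7/day
  at a uniform bin (the real archive's restocking pattern is undocumented,
  so this is a free knob, not a calibrated one); stock is floored at zero
  with lost sales, and a ledger records the decrements actually applied.
* **Counts**: `u` is sampled from the ICAR's proper subspace by
  eigendecomposition of `D − A` with null eigenvalues removed (hence
  exactly sum-to-zero per component, islands exactly 0), `ν` iid normal,
  and `Y_i` Poisson or NB2 around `E_i ρ_i`. Truth defaults are the
  study-scale coefficient vector (intercept 3.702; slopes 0.124, −0.565,
  0.559, −2.821, −0.990, 0.467) and precisions 0.497 (spatial) and 6.380
  (iid), giving raw RR surfaces spanning ~0–19 with median near 0.85.
* **Reproducibility**: one global seed feeds named per-component
  substreams, so a fixed seed reproduces every artifact bit-identically
  even when only part of the generator is re-run.

What the generator does *not* emulate: road-network catchments, commuter
in/out-flows, heterogeneous within-village population density, logistics
irregularities beyond random refills, and per-customer purchase behavior.
Passing recovery tests therefore demonstrates correctness of the
algorithms under the model's own assumptions, not robustness of the model
to real-world violations of them.

## 7. Validation experiments and problem sizes

* Recovery/model-selection: 20 replicates of 1000-village regions,
  simulated from the Poisson spatial model at the truth above; all four
  models refitted per replicate with 2 chains × 3000 iterations. Checked:
  95% CI coverage per coefficient (expected ≥ 80% of replicates), mean
  posterior-mean bias (< 0.1), DIC/WAIC both selecting the generating
  model (≥ 18/20), and spatial-vs-aspatial MAPE/MSE ratios (≥ 5×).
  Coverage of the weakest-identified coefficients (intercept, income,
  business share) sits near the 80% bar: their posterior spread at
  n = 1000 is of the same order as the realization-to-realization
  variation induced by the random effects, so the minimum-coverage
  statistic fluctuates between experiment seeds. The mean-bias and
  selection statistics are stable.
* Overdispersion: NB-spatial fit on NB data (ϑ = 1.6, n = 1488) recovers
  ϑ within ±0.5; on near-Poisson data (ϑ = 10⁶) the NB and Poisson
  spatial fixed-effect posteriors agree within 2 posterior sds.
* Exceedance calibration: with lognormal(0,1) draws, `Pr(RR < 1)` is 0.5
  (Φ(0)) within Monte Carlo error and monotone in the threshold.
* Geometry: Voronoi membership is cross-checked against brute-force
  nearest-neighbor search; interpolation against a 10⁶-point Monte Carlo
  rasterization; adjacency against an O(n²) pairwise intersection test;
  the aspatial Poisson posterior against the GLM maximum-likelihood fit.

## 8. Known limitations

* The restock-within-hour cancellation bias is not corrected.
* Fixed effects in the BYM models are weakly identified against the
  unstructured effect by design; interpret slope posteriors accordingly.
* The conditional DIC variant and the MAPE/MSE scale are conventions;
  rankings between models are the robust output, not absolute values.
* `Pr(RR < 1)` is a posterior tail probability under the fitted model; it
  inherits any model misspecification.
* Geometry is strictly planar; inputs in geographic coordinates must be
  projected first.
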