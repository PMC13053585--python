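# Methods

## The problem and the estimation strategy

Paired abundance monitoring of insects and insectivores is observational:
both trophic levels respond to shared weather and to unmeasured year-level
shocks, sites differ statically in habitat quality, and indices carry
observation noise.  A single regression of insectivore change on insect
abundance therefore risks both mirage links (shared drivers) and missed
links (noise, nonlinearity, lags).  The package's answer is a
*specification* approach: three tiers with complementary strengths —
descriptive association, nonlinear prediction, and confounding-robust
linear panel estimation — run on the same paired cell-year table, so the
evidence can be read jointly.

## Synthetic landscape generator (`synthgrid`)

Latent dynamics live at the level of 100 km cells; sites are noisy
observation replicates of their cell.  Per cell *i* and year *t* (u =
insect, v = insectivore log-abundance):

    u_it = a_I + s^I_i + λ_I u_i,t−1 + γ_IT T_it + γ_IP P_it − δ v_i,t−1 + c_t + η_it
    v_it = a_B + s^B_i + λ_B v_i,t−1 + β₀ u_it + β₁ u_i,t−1 + γ_BT T_it + γ_BP P_it + c_t + ξ_it

with static cell intercepts s ~ N(0, σ_site²), a single national year
shock c_t ~ N(0, σ_year²) entering *both* equations (that is what two-way
fixed effects are supposed to absorb), and weather anomalies T (°C) and P
(per 100 mm) shared by both levels.  Initial states sit at the
deterministic coupled fixed point and 50 burn-in years are discarded, so
emitted series are stationary.  All randomness flows from one seed through
fixed per-component sub-streams; output is bit-reproducible.

Weather is built from four seasonal fields (spring/summer/autumn/winter):
climatology + a north–south temperature (and east–west precipitation)
gradient + an iid national year shock of SD σ_year (precipitation scaled
×25 mm/°C) + local cell-by-season noise of SD σ_weather.  The annual
value is exactly the mean (temperature) / sum (precipitation) of the four
seasonal values; spring, summer, winter and annual rows are emitted,
autumn stays latent.  σ_weather defaults to 0.1 °C: national interannual
anomalies are deliberately the dominant weather signal, which makes the
climate covariates nearly year-level (they confound M1, are absorbed by
year effects in M2/M4, and retain just enough local variation to stay
identified alongside year fixed effects).

Observation: each site carries a static lognormal effect
exp(N(0, σ_site²)); visit counts are Poisson (or negative binomial with
size `nb_dispersion`) around exp(latent + site effect); whole site-years
are deleted with probability `p_missing`.  Insect "species" indices split
the cell index across three pseudo-species with fixed proportions
(0.5/0.3/0.2) and lognormal measurement noise (SD 0.2 on the log scale),
so the order-level summation step is exercised.

Scenario presets define the study conditions used in tests:

| preset | β₀ | β₁ | δ | γ (T, P per level) | σ_year | interpretation |
|---|---|---|---|---|---|---|
| `bottom_up` | 0.4 | 0.15 | 0 | 0.1, 0.05 | 0.02 | clean prey→predator coupling, low noise |
| `null_confounded` | 0 | 0 | 0 | 0.5, 0.3 | 0.3 | no coupling; strong shared weather + shocks |
| `top_down` | 0 | 0 | 0.3 | 0.1, 0.05 | 0.2 | predator suppresses prey |
| `uncoupled` | 0 | 0 | 0 | 0.1, 0.05 | 0.02 | `bottom_up` minus all coupling |

`bottom_up` keeps year shocks near zero by construction: it isolates the
coupling pathway so estimator bias can be measured against β₀ alone;
shared-shock confounding is exactly what `null_confounded` probes.

What the generator does **not** emulate: spatially correlated process
noise beyond the single national shock, age/stage structure, detection
covariates, life-stage mismatch between the recorded and consumed insect
stages, and scheme-specific sampling designs.  Passing tests therefore
demonstrate estimator correctness under the stated model, not fidelity of
the real monitoring schemes.

## Indices (`indices`)

Bird index: counts summed across distance categories within a visit
(flyover rows dropped unless the species sings over its territory), then
the maximum across a year's visits.  Bat index: passes summed across
sections of *completed* transects, yearly maximum, and sites never
occupied in any year removed.  Order index: species values summed within
group per site-year; a site-year with no species rows is missing, whereas
observed all-zero counts yield an index of 0 (zeros are data; gaps break
runs).  The pitfall-trap year index fits a Poisson site+year fixed-effects
GLM (IRLS) and reports exp(year effect) normalised to the earliest year
observed at every site (else earliest overall), with delta-method SEs; a
disconnected site×year design is rejected.  This log-linear two-factor
index is the standard construction and is used here in place of any
scheme-specific variant; it accepts a single site (year effects then
saturated).

## Gridding (`gridding`)

Cells are floor(coordinate/scale); nesting is exact by construction, and
the 100 km ancestor of each analysis cell is its clustering "region".
Cell values are *unweighted* means across sites (site counts retained for
diagnostics).  Pairing is an inner join on cell × year; weather is joined
through the region.  Standardisation (z-score, n−1 denominator) is
applied only where a tier needs it (EDM embedding, displays); the panel
tier works on raw indices.  Sites near cell edges stay in their cell — no
proximity re-pairing.

## Association tier (`association`)

Runs: the longest gap-free stretch of consecutive years per cell, kept
only if ≥ 10 years and ≤ 50% zeros (ties → most recent run).  The
decomposition smooths with tricube-weighted local linear regression
(span 0.75 of the run, never fewer than 5 points in a window, 2
robustness iterations); remainder = observed − trend, so the additive
identity is exact.  Numerically the smoother is applied to residuals of
the global OLS line with a centred x axis — identical in exact arithmetic
and exact for linear inputs in floating point.  Trend directions use
per-cell OLS slopes with method-of-moments empirical-Bayes shrinkage
toward the across-cell mean (a light stand-in for a random-slopes mixed
model; direction classification, the only downstream use, is insensitive
to the difference, and plain OLS is available).  Sign agreement uses the
exact two-sided binomial (doubled smaller tail, capped at 1) at p₀ = 0.5;
exactly-zero slopes carry no direction and are excluded.  Remainder
correlations are per-cell cross-taxon Pearson r over ≥ 5 shared years,
summarised by the mean and a t-based 95% CI; the alternative per-year
across-cell reading is provided as `cross_cell_year_correlations`.

## Prediction tier (`gpedm`)

Embedding: per cell, the longest consecutive-year run in which every
variable of the model is present; targets keep their calendar year.
Predictors are insectivore lags 1..E (E = 3, delay 1 year), optionally
insect lags 1..E, and the chosen season's temperature and precipitation.
Insect predictors deliberately exclude lag 0 so prediction stays strictly
ex-ante (ARD can shrink unused lags; a lag-0 flag exists).  Weather
enters at the target year by default (the growth *into* year t is driven
by year-t weather; switchable to lagged).  Columns and target are
z-scored pooled across cells.

Kernel: k = (1−ve)·exp(−Σ_d φ_d²(x_id−x_jd)²)·r_ij with r_ij = 1 within a
cell and ρ across cells; noise ve on the diagonal only.  On the
standardized target the total variance is fixed at 1, bounding ve ∈ (0,1).
MAP estimation maximises the Gaussian log marginal likelihood plus
independent half-normal priors on each φ_d (scale 1.0 per standardized
column; weakly informative) with flat priors on ve and ρ, over
(log φ, logit ve, logit ρ) with analytic gradients, L-BFGS-B, 5 seeded
starts (one fixed anchor), objective tolerance 1e−6, 500 iterations, box
bounds on the transformed parameters to avoid overflow, and Cholesky
jitter retries (1e−8 ×10 up to 1e−4).  Leave-one-timepoint-out uses the
closed-form identity at the full-data optimum (A = C⁻¹: mean_i = y_i −
(Ay)_i/A_ii, var_i = 1/A_ii); hyperparameters are not re-fitted per fold.
R² = 1 − SSE_loo/SST.  Note the pooled standardization means persistent
between-cell level differences contribute predictable variance, so
absolute R² values are generous; the tier's conclusions rest on the
*difference* between paired arms, not on absolute skill.

The suite fits 10 models per pairing × scale: weather set ∈ {none,
spring, summer, winter, annual} × insect ∈ {out, in}, giving five
head-to-head comparisons; winners are decided on leave-one-out R².

## Causal-inference tier (`panelfe`)

Growth is Δlog(y+1) between consecutive observed years; the same log(y+1)
transform is used for the lagged-abundance regressor, keeping the
equation internally consistent.  Units with more than 50% zeros in the
insectivore series are dropped before growth rows are formed.  A
`transform="identity"` option treats values as already log-scale — the
recovery and calibration experiments run on the generator's latent states
through exactly this path (the generator retains truth for that purpose);
the log(y+1) observation path cannot reproduce a latent-scale coefficient
exactly by construction.

Fixed effects are eliminated by demeaning (one factor directly; two
factors by alternating projections to a scale-relative tolerance of
1e−10, up to 500 sweeps).  The within-estimator is verified against
indicator-variable OLS.  Cluster-robust covariance is CR1:
(XᵀX)⁻¹[Σ_g X_gᵀe_g e_gᵀX_g](XᵀX)⁻¹ · G/(G−1) · (N−1)/(N−K), with K
counting the absorbed effects (units, plus years−1 with year effects) —
conservative by design; singleton clusters reduce CR1 exactly to HC1.
Inference is two-sided t with G−1 degrees of freedom.  Clustering is
one-way: units at 100 km, regions (which subsume units under nesting) at
50/10 km; a two-way unit+region inclusion–exclusion combination is
available behind a flag.  Insect covariates are z-scored by default so
coefficients are per SD of the insect index (off for recovery runs, which
need the generative scale); the link summary counts specifications
significant at two-sided 0.05 with no multiplicity correction.

Known small-sample behaviour: with a lagged state variable the
within-estimator carries the classical O(1/T) attenuation, ≈ (1+λ)/T
(about 0.06 at λ = 0.7, T = 30).  No dynamic-panel correction is applied
— deliberately, matching the estimator under study — and the
density-dependence recovery check allows for this attenuation (tolerance
0.09 on λ_B − 1) while the contemporaneous coupling β₀ is unaffected
(given u_t−1, v_t−1 is uninformative about the innovation in u_t).

## Problem sizes in tests and the acceptance script

Monte-Carlo experiments use: recovery — 60 units × 30 years, 100
replicates (60 in the script); null calibration — 40 units × 14 years,
500 replicates (300 in the script), sized so CR1 has enough clusters for
its nominal level; EDM discrimination — 9 cells × 18 years, 50 datasets
per scenario (30 in the script) with 3 optimizer starts.  These sizes
were chosen as the smallest at which the asymptotics being tested are
expected to hold, and they are stated here so results can be reproduced
exactly.

## Known limitations

- The generator's functional form *is* the analysis model run forward;
  recovery tests validate the estimators, not the adequacy of the model
  for any real scheme.
- The association tier's mixed model is replaced by shrunken per-cell
  OLS slopes; magnitudes (not used downstream) would differ from REML.
- The pitfall-trap index's error family and zero handling follow the
  standard Poisson log-linear construction; scheme-specific variants may
  differ.
- One-way clustering at the region level is an interpretation of an
  ambiguous design point; the two-way combination is provided but not
  default.
- No convergent cross-mapping, surrogate-data tests, multistep
  forecasting, dynamic-panel corrections, instrumental variables or
  spatial-error models.
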