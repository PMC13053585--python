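# trophiclink

Do changes in insect abundance drive the population dynamics of the
insectivores that eat them?  Paired national monitoring schemes (transect
bird counts, bat pass surveys, moth traps, butterfly transects, freshwater
kick-samples, pitfall traps) offer site-level abundance indices for both
trophic levels, but at different places and times, and both levels respond
to the same weather — a recipe for mirage correlations.  `trophiclink`
implements a three-tier assessment of trophic links on a shared spatial
grid, together with a synthetic landscape generator with known ground
truth so every estimator can be validated against the coupling
coefficients that produced the data.

The three tiers, run on insectivore/insect series paired within 100, 50
and 10 km grid cells:

1. **Association** — each cell series is split by a loess smoother into a
   long-term trend and a remainder of interannual deviations.  Agreement
   of trend *directions* across cells is tested with an exact binomial
   sign test, and per-cell Pearson correlations of the remainders are
   summarised with a t-based confidence interval.
2. **Prediction** — hierarchical Gaussian-process empirical dynamic
   modelling (GP-EDM): time-delay embedding (lag 1 year, up to E = 3
   lags), a squared-exponential kernel with automatic relevance
   determination and an across-cell dynamic correlation ρ, MAP
   hyperparameters, and leave-one-timepoint-out R² computed in closed
   form.  Ten models per pairing and scale (5 weather sets × insect lags
   in/out) give five head-to-head Granger-style comparisons.
3. **Causal inference** — the linearised Gompertz growth model

   `Δlog(y_it+1) = λ' log(y_it−1+1) + b₀ Insect_it + b₁ Insect_it−1 [+ climate] + Site_i [+ Year_t] + ε_ir`

   estimated by within-demeaning under four specifications (unit FE;
   unit+year FE; each ± annual temperature and precipitation), with CR1
   cluster-robust standard errors (clusters = units at 100 km, 100 km
   regions at finer scales) and t(G−1) inference.

The generator (`trophiclink.synthgrid`) runs the same Gompertz equations
forward as a data-generating process: cell-level latent log-abundances
with optional bottom-up (contemporaneous + lagged) and top-down coupling,
shared seasonal weather responses, static site heterogeneity, national
year shocks, Poisson/negative-binomial visit counts and missing
site-years.  Scenario presets (`bottom_up`, `null_confounded`,
`top_down`, `uncoupled`) encode the study conditions used throughout the
tests.

## Worked example

```python
from trophiclink import pipeline

cfg = pipeline.RunConfig(
    seed=7, scales_m=(100_000, 50_000),
    sim=dict(n_cells_x=2, n_cells_y=2, years=16, sites_per_cell_per_taxon=3),
    edm={"n_starts": 1, "E": 2},
)
pipeline.run_pipeline(cfg, "artifacts/demo")
```

This simulates a 2×2-cell landscape (default scenario: weakly
weather-coupled, no trophic coupling is *not* assumed — the default
`SimConfig` has β₀ = 0), builds site indices, aggregates and pairs them,
and writes `report.md` plus machine-readable CSV/JSON artifacts.  From an
actual run of the above:

```
## Association tier (trend agreement and remainder correlations)
| pairing             | scale_m | n_cells | k_agree | p     | mean_r |
| insectivore|insects | 100000  | 4       | 4       | 0.125 | 0.477  |
| insectivore|insects | 50000   | 5       | 4       | 0.375 | 0.354  |

## Causal-inference tier (link summary)
| pairing             | scale_m | term       | n_significant | direction |
| insectivore|insects | 100000  | insect_t   | 0             | none      |
| insectivore|insects | 50000   | insect_t   | 2             | positive  |
```

Reading: all four 100 km cells agree in trend direction, but with only
four cells the sign test cannot reject chance (p = 0.125); remainders are
positively correlated (mean r ≈ 0.48); two of the four panel
specifications flag a positive contemporaneous insect effect at 50 km.
The EDM winner matrix in the same report shows which of the five
comparisons preferred the insect-inclusive arm.  A command-line interface
exposes the same pipeline (`trophiclink run --seed 7 --outdir artifacts`).

## Layout

- `src/trophiclink/synthgrid.py` — synthetic landscape generator + scenarios
- `src/trophiclink/indices.py` — scheme-specific site×year×taxon indices
- `src/trophiclink/gridding.py` — nested grid assignment, aggregation, pairing
- `src/trophiclink/association.py` — tier 1 (loess decomposition, sign test)
- `src/trophiclink/gpedm.py` — tier 2 (hierarchical GP-EDM)
- `src/trophiclink/panelfe.py` — tier 3 (fixed-effects Gompertz panel)
- `src/trophiclink/pipeline.py`, `cli.py`, `report.py` — orchestration
- `docs/methods.md` — model details, defaults, numerical choices, limitations
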