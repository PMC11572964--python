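# Methods

## Model and measurement

Cooling efficiency at analytical-unit size S is defined operationally: tile
the city with square units of side S, reduce each unit to its percent canopy
cover Ptree ∈ [0, 100] and mean land-surface temperature (°C), and take the
absolute OLS slope of LST on Ptree across units. The bivariate regression is
deliberate — CE is a descriptive efficiency, not a causal effect adjusted for
covariates — and a positive (warming) slope is retained as |slope| with a
warning rather than excluded, since the absolute-value definition carries no
exclusion rule.

The scaling relation is CE(S) = k·S^β. It is fitted by OLS of ln CE on ln S
(the conventional linearization), giving closed-form 95% intervals: β's from
the slope's t interval, k's by exponentiating the intercept bounds. A direct
nonlinear least-squares fit (initialized from the log-log solution, asymptotic
intervals) is available by flag; it matters only when CE values near zero or
negative slopes make log space awkward. Points are unweighted by default —
the design treats each scale's estimate as one observation on the scaling
curve — with 1/se² weighting behind a flag.

Model selection follows a significance rule: the power law is kept when its
scale term has p ≤ 0.01; otherwise a quadratic CE = c₀ + c₁S + c₂S² is fitted
(joint F-test p of the two scale terms reported) and returned. The "fitness"
comparison is logged as both forms' R²; the p-threshold decides. The fallback
form matters on extreme-heat days, where transpiration limits make CE concave
in S rather than monotone.

Multi-date runs pool by fitting one regression to the concatenated
(ln S, ln CE) points across dates rather than averaging per-date parameters;
per-date fits are attached for dispersion reporting. Pooling points is the
statistically simpler estimator; both views are always available.

## Whole-city prediction and goal inversion

The planning quantities are CE at the whole-city scale,
CE_city = k·S_city^β, and the inverted canopy goal,
goal (%) = ΔT_target / CE_city. S_city defaults to the largest ladder size
(the largest analytical units are the planning-relevant scale); √(city area)
can be passed instead. CE_city's interval is the mean-response prediction band
of the log-log regression at ln S_city, exponentiated; the goal interval
inverts the CE interval endpoint-wise, which is exact for a monotone transform
and conservative relative to the delta method. Extrapolation beyond the fitted
scale range warns; evaluating a concave quadratic beyond its fitted range is
refused outright, because it soon predicts negative efficiencies.

## Scale ladder and aggregation

Units are w×w blocks of base pixels with w odd: 1, 3, 5, …, w_max (120 m
pixels give 120–2760 m for w_max = 23 and 120–4440 m for w_max = 37).
Arbitrary width ladders are available behind a flag for sensitivity analysis.
Grids anchor at the raster's top-left corner; partial tiles at the right and
bottom edges are discarded so all units have equal support. A unit is dropped
when fewer than `min_valid_fraction` (default 0.5, a common zonal-statistics
convention) of its pixels are valid — valid meaning LST and cover both present
and, if a boundary mask is supplied, inside the city. Fine binary canopy is
first reduced to fractional cover per base cell (fraction of valid fine pixels
equal to 1; cells with more than half their fine pixels missing become
nodata). No implicit resampling ever occurs: non-integer resolution ratios and
misaligned footprints are rejected at load time.

## Synthetic data

The tabular generator is the truth model for parameter recovery: at each
scale S it draws Ptree ~ Uniform(0, 100) (Beta(2, 2) optional) and sets
LST = a − (k·S^β)·Ptree + ε, ε ~ N(0, σ²). Defaults are the study conditions
used throughout the tests: k = 0.057 °C/%, β = 0.165, the twelve 120–2760 m
scales, 1000 units per scale, σ = 0.5 °C. The residual σ is nominal — no
empirical unit-level noise level is available to calibrate it — and the
baseline a = 40 °C is a typical clear-sky summer daytime LST. The intercept
may optionally vary by scale (free per-scale baselines), default constant.

The raster generator emulates the hypothesized mechanism rather than any
specific imagery: canopy is a Gaussian random field (FFT-free Gaussian
convolution, correlation range 360 m) thresholded at the empirical quantile
matching the cover target (realized cover therefore hits the target to within
discretization); LST is baseline − 5 °C·cover − 5 °C·smooth(cover, 600 m) +
N(0, 1 °C) per 120 m pixel on a 120×120 grid. The neighborhood-smoothed term
mimics patch-size-dependent evapotranspiration: larger analytical units
internalize more of it, so estimated CE rises with scale; setting it to zero
yields scale-free CE of 0.05 °C/%. The magnitudes put base-scale CE in the
0.05–0.2 °C/% range typical of summer daytime analyses. What the generator
does **not** emulate — sensor radiometry, classification error, anisotropic
urban form, spatially autocorrelated noise — bounds what passing tests show:
they validate the estimation chain under the assumed statistical structure,
not the remote-sensing provenance of real inputs.

All randomness flows from one integer seed via `numpy.random.SeedSequence`
spawning, so every stage is independently and bit-for-bit reproducible.

## Numerical choices and degenerate inputs

- CE regression via `scipy.stats.linregress`; an HC3 robust-SE option exists
  but is off by default (the reference procedure is plain OLS).
- Scales with zero Ptree variance or fewer than 3 units are skipped with a
  warning; fewer than 3 usable scales aborts (no scaling fit is possible).
- Non-positive CE values cannot enter log space: they are dropped with a
  warning, and if more than half would be lost the fit switches to direct
  space.
- Confidence level is fixed at 95% throughout.
- Pipeline exit codes distinguish validation failures (2) from computation
  failures (1).
- The Magnus coefficients for saturation vapor pressure are the WMO set
  (6.112 hPa, 17.62, 243.12 °C); VPD = es(T)·(1 − RH/100).

## Problem sizes

Recovery experiments use 200 replicates of 12 scales × 1000 units; raster
experiments use 120×120-pixel grids aggregated up to 9×9-pixel units over
20–50 seeds. These sizes give Monte-Carlo standard errors on the recovered
exponent of ~1e-4, comfortably below the ±0.01 bands checked, while keeping
the full suite fast on a single CPU.

## Known limitations

- Plain OLS ignores spatial autocorrelation of unit residuals; standard
  errors at small scales are likely optimistic on real rasters.
- The quadratic fallback's selection threshold (p > 0.01) is a convention;
  near the boundary the chosen form can flip between dates.
- Whole-city CE is an extrapolation whenever S_city exceeds the largest
  aggregated scale; the warning is the only guard.
- Weather correlations with few dates (the realistic regime, ~5–10 scenes per
  city) have wide sampling variability; the permutation-calibrated p-values
  are exact only under exchangeability.
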