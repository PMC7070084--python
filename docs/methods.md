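# Methods

## Model

Foliar concentrations are modelled on the observation level as

    y_ijkt = x_ijkt' beta + u_country(i) + u_plot(ij) + u_species(ijk) + e_ijkt

with independent Gaussian random intercepts at each nesting level and a
continuous-time first-order autoregressive residual within each tree
series: corr(e_t, e_t') = phi^|t−t'| (phi in [0, 0.99]), which matches a
corCAR1 structure at unit spacing and handles gapped series. Trend fits
use `x = (1, year − first_year)`; attribution fits use driver terms (see
below) with plot and species-within-plot intercepts.

### REML estimation

The residual scale is profiled out. The free parameters are the variance
ratios lambda_k = sigma_k²/sigma_e² (optimised as log lambda, bounded to
[1e−10, 1e8]) and phi (logistic-transformed). The criterion

    (n−p) log(sigma_e²_hat) + log|W| + log|X' W⁻¹ X|,  W = R(phi) + sum_k lambda_k Z_k Z_k'

is minimised with L-BFGS-B from fixed starting values (all random SDs at
half the marginal SD, i.e. ratio 1; phi = 0.3), function tolerance 1e−10,
with a Nelder–Mead polish if line search fails; fits are deterministic
given the data. W is inverted through the Woodbury identity; a random
factor whose levels coincide one-to-one with the AR(1) series (e.g.
species-within-plot when each series is one tree) is *folded* into the
per-series block as lambda·J, which keeps the per-evaluation cost at one
small Cholesky per distinct time pattern plus a (levels × levels) solve.
Correctness of both paths is pinned by dense-matrix GLS and brute-force
REML oracles and an independent cross-check against R's nlme::lme with
corCAR1 (slope agreement ~1e−5 on seeded panels).

Denominator degrees of freedom use a between–within split at the series
level: coefficients varying within series get N − (number of series) −
p_within, others (number of series) − p_between. This is an approximation
(documented, configurable only by editing one function); p-values should
be read accordingly.

Variance ratios are floored at 1e−10; fits at the floor are flagged
(`MixedFit.boundary`). On exactly noiseless data the profiled scale is
clamped away from zero; fixed effects remain exact because y lies in the
column space of X.

### Percent change

100 × slope × (year span) / baseline. The default baseline is the model
prediction at the first observed year (the fitted intercept, since year
is centred there); a `period_mean` baseline is available because the
period percentage is otherwise ambiguous.

### Attribution by counterfactual freezing

For each driver d in {CO₂, MAT, MAP, oxidised N, reduced N, S deposition}
the design carries the site mean of d over the site's observed panel rows
(so anomaly columns average to zero per site exactly), the temporal
anomaly, a mean × anomaly interaction, and all first-order anomaly ×
anomaly pairs; tree growth (dbh first difference, cm yr⁻¹) is optional.
Stepwise backward–forward selection at alpha = 0.05 drops the least
significant droppable term (main effects are protected while a retained
interaction contains them) and re-offers dropped terms; re-entry
candidates are screened by a GLS t-test at the current variance
parameters and accepted only if significant in a full refit. If nothing
survives, an intercept-plus-year null model is returned with a warning.

Contributions: the year-trend of the final model's fixed-effect
predictions is the `year` coefficient of a year-only mixed model refit on
the predictions with the same grouping and correlation (a plain-OLS trend
is available via `trend_estimator="ols"`). Freezing driver d replaces its
anomaly column with the per-site median of the anomalies and recomputes
every interaction column involving d. The frozen trends reuse the
prediction-trend model's weight vector, so each contribution is an exact
linear functional c_d' beta_hat; its SE is sqrt(c_d' V c_d) with V the
fixed-effect covariance (delta method, exact given the variance
parameters — validated against a 200-replicate parametric bootstrap to
within 20%). The unknown term is observed trend minus the sum of
contributions, with SE by quadrature under an independence assumption.
Drivers absent from the final model contribute exactly 0 ± 0.
Contributions are per-year rates by default; `per_period=True` multiplies
by the year span. Marginal/conditional variance explained follows the
standard mixed-model decomposition var(Xβ)/(var(Xβ)+Σσ²_k+σ²_e), using
the stationary residual variance.

### Rates and the ensemble regressor

Theil-Sen slopes are the median of all pairwise slopes; pairs with equal
times are skipped, and an even count uses the midpoint of the two central
slopes (a lower-median convention is available). Trees need more than
five measurements to contribute a rate. The mapping ensemble refits a
pluggable regressor on replicate 80/20 splits and averages replicate
predictions; the reference configuration is a feed-forward network with
two 128-unit rectified-linear hidden layers, with linear and
gradient-boosted alternatives for settings where the architecture is not
under study (the fast paths are used throughout the test suite).
Extrapolation flagging uses the training covariates' bounding box — a
deliberate simplification of a convex-hull test. Grid cells are abstract
covariate-rate cells; no geographic masking is attempted.

### Meta-analysis

lnRR is computed as ln Xi − ln Xn (bitwise antisymmetric under arm swap)
with sampling variance (1/nᵢ)(Sᵢ/Xᵢ)² + (1/nₙ)(Sₙ/Xₙ)². A published
variant of this variance wraps the sum in an outer logarithm; that
expression is negative whenever the sum is below one, cannot be a
variance, and is therefore refused with an explanatory error
(`strict_paper_formula=True`). Effects are divided by the ppm of CO₂
added (sensitivity per ppm, assuming log-linearity in the increment) and
rescaled to +50 ppm — the increment observed over the monitoring period —
before pooling. Random-effects pooling uses inverse-variance weights with
the DerSimonian–Laird moment estimator of tau² by default (REML
switchable); pooling is cross-checked against R's metafor::rma to 1e−8.

## Synthetic panel generator

The generator emulates the monitoring design the estimators assume:
5 countries × 4 plots × 3 species observed annually 1990–2016 (biennial
or sparser sampling via a dropout probability), latitudes spread over
40–64 °N so that all three latitude bands (boundaries at 46 and 58 °N;
the boundary year belongs to the more northerly band's southern edge) are
populated. Driver series carry the period's documented changes: CO₂
+50 ppm from 355 (one global series, linear), oxidised/reduced N
deposition −25% and S deposition −65% from 6/6/12 kg ha⁻¹ yr⁻¹, warming
of 0.048/0.044/0.034 °C yr⁻¹ and precipitation change of +50/0/−100 mm
yr⁻¹ over the span for north/central/south.

Concentrations are baseline + Σ beta_d × (driver − first-year reference)
plus nested intercepts and AR(1) residuals. Default baselines
(N 23, P 1.5, K 8, S 1.8, Ca 6, Mg 1.2 mg g⁻¹) are typical European
foliar values; default betas put the whole trend on CO₂ and are sized so
the period declines are about −5/−11/−8/−6/−7% for N/P/K/S/Mg with Ca
flat. Noise SDs (country 1.5, plot 1.5, species 1.0, residual 1.0 mg g⁻¹,
phi 0.5) are stated for N and scale proportionally with each element's
baseline, keeping relative variability uniform across elements.

`default_scenario()` adds realistic interannual driver variability
(MAT 0.5 °C, MAP 80 mm, deposition 0.4–0.8 kg ha⁻¹ yr⁻¹, CO₂ 0.3 ppm).
This is a deliberate departure from noise-free trend lines: with zero
interannual variability every driver anomaly within a latitude band is
exactly proportional to (year − mean year), the saturated attribution
design is rank-deficient, and no multi-driver model can be fitted. The
chosen SDs are of the order of observed European interannual variability
and were fixed once as part of the study conditions.

What the generator does **not** emulate: measurement error distinct from
process noise, non-Gaussian concentration distributions, spatially
correlated random effects, species-specific driver responses, nonlinear
or threshold driver effects, and missingness that is informative rather
than random. Passing recovery tests therefore demonstrate estimator
correctness under the stated model, not robustness to these departures.

The meta-corpus generator draws each study's true lnRR as
per-ppm-truth × Δppm plus optional between-study noise, then adds
within-arm sampling error to the reported means (arm SDs are a fixed
coefficient of variation of the arm mean); non-positive simulated means
are resampled (or raised, per policy).

## Problem sizes used in the shipped checks

Recovery coverage uses 100 replicate panels of 20 plots × 3 species × 27
years; stepwise operating characteristics use 50 + 50 replicates of a
3 × 3 × 2 panel; the bootstrap comparison uses one 10-plot × 2-species
panel with 200 replicates; meta-analytic coverage uses 100 corpora of 100
studies. The acceptance script reports the same quantities at moderately
reduced replicate counts, which its JSON records alongside each value.

## Known limitations

- The family-wise null operating characteristic of stepwise selection at
  per-term alpha = 0.05 over six candidate drivers is ~74% clean, not
  90%+: retaining no spurious term among six quasi-independent candidates
  cannot be guaranteed at that per-term level (per-driver retention is
  calibrated at ~5%). Controlling the family-wise rate would require a
  multiplicity-adjusted entry/stay level, which the procedure
  deliberately does not apply.
- Attribution is correlational: contributions quantify how much of the
  modelled trend travels through each driver's temporal variation, not a
  causal effect.
- Delta-method SEs condition on the estimated variance parameters; the
  bootstrap comparison bounds, but does not remove, the residual
  optimism.
- The between-within df approximation can be liberal for severely
  unbalanced panels.
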