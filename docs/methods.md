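# Methods and design notes

This note documents the models implemented in `searchimpact`, the choices
made where the design was genuinely open, and what the synthetic-data
experiments do and do not establish.

## The estimation problem

The response is a monthly search-intensity index: an integer on a 0–100
scale measuring a term's share of all queries in a country, normalized so
its in-sample maximum is 100.  The question is whether a policy
intervention (a lockdown) changed such a series, where "changed" means a
difference from the unobservable counterfactual path the series would have
followed with no intervention.  All models here produce such a
counterfactual for the post-intervention window from information available
before it; the effect is observed minus counterfactual.

## Structural time-series model

Observation equation:

    y_t = μ_t + γ_t + βᵀ x_t + ε_t,     ε_t ~ N(0, σ_ε²)

**Trend** μ_t, four specifications:

- *local level*: μ_t = μ_{t−1} + u_t;
- *local linear*: adds a slope, μ_t = μ_{t−1} + δ_{t−1} + u_t,
  δ_t = δ_{t−1} + v_t;
- *semi-local linear*: the slope is a stationary AR(1) around a long-run
  mean, δ_t = D + φ(δ_{t−1} − D) + v_t with |φ| < 1.  φ and D are sampled
  (φ with a standard-normal prior truncated to (−1, 1); D with a diffuse
  normal prior).  A stationary slope is less variable than a random walk,
  which matters over long forecast horizons;
- *Student local linear*: the local linear trend with heavy-tailed level
  and slope innovations, implemented by per-time normal scale-mixture
  latents λ_t ~ inverse-gamma(ν/2, ν/2) so u_t | λ_t ~ N(0, σ_u² λ_t).
  ν defaults to 30 and is configurable; only the innovation distribution
  is heavy-tailed, the variance priors stay inverse-gamma.

**Seasonality**: the sum-to-zero dummy form with S = 12,
γ_t = −Σ_{i=1}^{S−1} γ_{t−i} + w_t, kept in the state vector as S−1 lags.
State dimension is therefore 12 (local level) or 13 (trends with a slope).

**Regression**: a static coefficient vector β under a spike-and-slab
prior.  Each covariate carries a Bernoulli inclusion indicator with prior
probability (expected model size)/(number of covariates), default expected
size 3.  Conditional on inclusion, the slab is Zellner-style:
β_S ~ N(0, σ_ε² A_S⁻¹) with prior precision
A = (κ/n)(½ XᵀX + ½ diag(XᵀX)) and information weight κ = 0.01·n prior
observations; the diagonal averaging keeps A positive definite for
collinear designs.  σ_ε² carries an inverse-gamma prior worth 0.01·n
observations at one-half the sample variance (expected R² = 0.5).  These
hyperparameters are package defaults, configurable via `SpikeSlabPrior`.

**Sampler**: Gibbs with three blocks per sweep — (1) the full state path by
the Durbin–Koopman mean-correction simulation smoother (chosen over
backward-sampling recursions because it needs no inversion of predicted
covariances and so tolerates zero innovation variances exactly); (2)
innovation variances from conjugate inverse-gamma conditionals given the
state disturbances (priors worth 0.01·n observations at guesses of 0.1·sd(y)
for the level and 0.01·sd(y) for slope and seasonal), plus φ, D, and the
Student scale latents where applicable; (3) the regression by one
spike-and-slab indicator scan with conjugate odds, then β and σ_ε from
their conditionals.  Default 1000 sweeps with a 20% burn-in.  Initial
states are proper: level at the first observation with variance var(y),
seasonal states at zero with variance var(y) (a diffuse-but-proper prior
avoids the numerical cancellation a 10⁶-scale diffuse initialization causes
inside the simulation smoother).

**Prediction**: each retained draw is propagated through its own
transition equations with fresh innovations and its own β applied to the
post-period covariates, giving the full posterior predictive distribution
of the no-intervention path.  Models are trained strictly on the
pre-intervention window and never re-estimated on post data.

## Causal impact and the two-step covariate screen

Effect summaries per draw: pointwise (observed − predicted), average over
the post window, cumulative, and relative (cumulative effect ÷ cumulative
counterfactual; a relative effect of 11.22 means a ~1122% elevation, −1.00
total suppression).  The scalar used for the significance call is the
**average** pointwise effect (the cumulative version is monotone-equivalent);
significance means its central 95% credible interval excludes zero, and the
tail-area probability is the posterior mass on the null side of the
detected sign (a one-sided Bayesian p-value).  The point relative effect is
the posterior median.  Whether relative effects are reported as averages or
cumulative ratios was an open choice; the cumulative ratio is the default
and the average form is reachable from the stored draws.

Counterfactual validity requires covariates the intervention did not move.
The two-step screen fits a covariate-free structural model to every
candidate covariate (same trend specification as the second-step model)
and excludes those whose own effect is significant at 95%.  Global series
(real activity, oil) are kept a priori — a national lockdown does not move
them; the stringency index is excluded a priori because it is constructed
from the intervention itself.  Covariates constant over the training
window (pandemic series under breakpoint zeroing) carry no counterfactual
information: the screen marks them affected when they vary afterwards, and
the impact estimator additionally drops constant-pre columns outright —
an unidentifiable slab coefficient on an all-zero column would only inject
prior noise into the counterfactual.  Covariates that pass are
standardized by pre-window mean and sd inside the estimator.

## Dynamic mixture models

With n = 12 candidate covariates (the constant term always included — the
stringency index stays in this roster), all K = 2¹² = 4096 subset
regressions y_t = x_tkᵀθ_tk + ε_tk are enumerated as state-space
components whose coefficients drift as random walks.  Initial coefficients
are zero with diagonal covariance 10 (on standardized data), initial
weights 1/K.  Each step: every component's Kalman update, then weights
multiplied by the component's one-step predictive density and renormalized
(log-space accumulation, weight floor 10⁻³⁰⁰).

Two quantities the construction leaves unspecified are declared defaults,
not inferences: the state-innovation covariance W_tk is implemented as
forgetting-factor inflation of the state covariance (default 0.99; an
explicit diagonal-W mode exists), and the per-component observation-noise
variance is tracked by an exponentially weighted residual variance
(weight 0.95, or a fixed value).  Inputs are standardized on the
pre-intervention window; pandemic covariates whose pre-window sd is
degenerate (< 1% of the full-sample sd) fall back to the full-sample scale
so post-period values do not explode.  Post-period forecasting freezes
states and weights at their end-of-pre values — updating on post data
would absorb the causal effect into the counterfactual — and
de-standardizes with the stored pre-window constants.  No significance
testing is built on the mixture: in the study design it serves as a
counterfactual-forecast competitor, not an inference engine.

## Difference-in-differences

y_t = α₀ + α₁ᵀ(year dummies) + α₂ᵀ(month dummies) + α₃λ_t + α₄ᵀx_t + ε_t,
with λ_t = 1 during and after the lockdown.  Covariate sets: none (0),
deaths only (1), {cases, deaths, epu, gpr} (2), all twelve (3); lagged
variants shift x by one month and drop the first row.  The "fixed effects"
variants are numerically identical to the dummy form under OLS and are
kept as separately named roster entries only.  The pooled panel form
stacks countries with country dummies, divides each response by its
full-sample mean, and assumes no intervention for the no-lockdown
countries.  Estimation is OLS on the reduced design (reference year,
month, and country dropped); a degenerate all-pre or all-post λ is flagged
and the dummy removed rather than raised.  Standard errors for α₃ use the
conventional homoskedastic formula — serial correlation is a known
weakness of this design and no inference is drawn from it downstream.
For the forecast-comparison layer, each DiD model contributes its
no-lockdown counterfactual: fitted values with λ forced to zero — this
puts it on the same footing as the structural and mixture forecasts.

## Benchmarks and the comparison layer

- *No-change*: every post month equals the last pre-intervention value.
- *Auto-ARIMA*: differencing order by repeated KPSS tests, then a stepwise
  neighbourhood search over (p, q) up to (5, 5) minimizing AIC, with fits
  whose AR/MA roots fall within 1.01 of the unit circle rejected as
  inadmissible (the usual guard against unit-root pile-up).  Deterministic
  given the input.  On a single white-noise sample AIC occasionally admits
  a spurious term; the parsimony property asserted in tests is
  majority-of-samples.

All models are compared on the post-intervention window under quadratic
loss (an in-sample mode — one-step fits on the pre window — exists behind
the `eval_window` flag, since "fit to the observed data" and "forecast
comparison" framings are both defensible; post-window is the default).
The Diebold–Mariano statistic uses the loss differential's sample variance
(truncation at h−1 = 0 lags for one-step losses), the Harvey correction
factor √((T+1−2h+h(h−1)/T)/T), and Student-t reference with T−1 degrees of
freedom; exact ties return p = 0.5.  The Model Confidence Set uses the
range statistic over pairwise t-ratios, a moving-block bootstrap of the
loss rows (block length 3 months, 1000 resamples, seeded) for its null
distribution, eliminates the model with the largest standardized loss
disadvantage while the equal-ability null is rejected at confidence 0.90,
and reports sequential p-values.  Exact loss ties never trigger
elimination.  Like other bootstrap max-t procedures, the set is mildly
anti-conservative in small samples (the full equal-ability set survives
somewhat less than 90% of the time at T = 60); the dominated-model
elimination and best-model retention properties asserted in the tests are
robust to this.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes:
latent trend + 12-month seasonality + static regression + Gaussian noise,
affine-mapped so the pre-intervention range spans [5, 95], rounded to
integers and clipped to [0, 100] (the margin avoids systematic boundary
censoring; the marginal distribution of real search indices is not
modeled, and the affine map is this package's choice).  Macro covariates
are stationary AR(1) paths (persistence 0.9, unit innovation sd); pandemic
covariates are exactly zero before a breakpoint month (default one month
before the intervention, mirroring an epidemic that begins just before
policy responds) and follow smooth log-normal pulses, a lagged death
curve, a decaying reproduction rate, and a piecewise-constant stringency
path afterwards.  Intervention effects are additive on the index scale
with step, pulse, or geometric-decay shapes, recorded together with the
pre-injection counterfactual.  One seed drives everything through
deterministic substreams keyed by country and term, so identical seeds
give bit-identical panels.

What the generator does **not** emulate: search-index sampling noise and
renormalization quirks, cross-country language differences, integer
censoring at 0/100 in the bulk of the data, or cross-sectional dependence
between countries.  Passing calibration tests on these panels therefore
establishes internal correctness of the machinery under the model's own
assumptions, not robustness to the messiness of real search data.

## Problem sizes in the test and acceptance runs

The statistical checks run at sizes chosen to make their Monte-Carlo error
small relative to the asserted bands while keeping the default suite
fast: support recovery at 180 months × 12 covariates × 20 replicates
(1000 sweeps); impact calibration at 72 + 6 months with 500 sweeps —
200 replicates for coverage, 100 for the null; DM size at T = 16 × 1000
replicates; MCS behavior at 60 months × 5 models × 50 replicates × 1000
bootstraps; mixture concentration at 150 months × 16 components × 20
replicates, plus one full 4096-component run over 210 months.  The
acceptance script reruns the same designs at the sizes recorded in its
output.

## Known limitations

- The regression coefficients inside the structural model are static; a
  time-varying β would require a different identification strategy.
- Spike-and-slab odds are computed by dense Cholesky per indicator — fine
  for 12 covariates, not for hundreds.
- The mixture's 2ⁿ enumeration is exact but exponential; the resource
  guard refuses n > 20.
- DiD inference is homoskedastic-only by design, and the pooled panel's
  rescaling makes its α₃ scale country-dependent.
- Monthly aggregation means all effects are long-horizon averages; nothing
  here speaks to within-month dynamics.
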