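# Methods

This note documents the models, the estimation choices, and the limits of
what the test suite can show. Stage codes throughout: `Sd` seedling, `SR`
juvenile single rosette, `MR` juvenile multiple rosette, `SF`/`MF` flowering
single/multiple rosette (monocarpic: they die after seed set), `IA` inactive
(alive belowground, no rosette).

## Census model and fate resolution

One census per year (July). A tag's history is reconstructed retrospectively:

- a gap of 1–2 years flanked by observations is imputed as `IA`;
- absence for ≥ 3 consecutive seasons with no reappearance becomes a single
  `DEAD` row at the *first* missing year;
- a trailing gap shorter than 3 years is right-censored — the inactive/dead
  distinction needs a future reappearance, so no row is emitted;
- a flowering ramet's last record is followed by `DEAD` the next year
  (monocarpy), regardless of gap length.

New rosettes are classified by the field rule: cotyledons ⇒ seedling
(regardless of distance); otherwise > 10 cm from the nearest tag ⇒ new
vegetative sprout; otherwise the observation is attributed to the nearest
existing tag. A missing distance on a first observation is an error, not a
default. Resolution is idempotent, and `tabulate_transitions` then counts
each tracked ramet exactly once per year into an origin→fate table, with
recruits (tags first seen in year *t*, excluding the initial tagging census)
tallied by entry stage and per plot.

## Vital rates

Fate distributions are multinomial per origin stage; to keep every estimated
set of outgoing probabilities summing to one, each origin is decomposed into
a chain of conditionals whose denominators are all observable:

1. survival (any living fate vs dead),
2. flowering given survival,
3. `MF` given flowering,
4. `IA` given surviving non-flowering,
5. `MR` given aboveground non-flowering.

Unconditional probabilities are products along the path; the reconstruction
is exact for raw proportions (an algebraic identity, tested on random count
tables) and remains a valid simplex after each conditional is smoothed
separately. The chain order follows the biology (death first, then the
reproductive decision, then dormancy, then architecture) and is configurable.
Structural zeros are configurable too; defaults: seedlings do not flower in
their first year, and inactive ramets do not re-emerge directly as `MF`.

Each conditional is a binomial GLMM, logit link, fixed intercept plus one
Gaussian year random intercept. Because the only random effect is a scalar
per year, the marginal likelihood factorizes into 1-D integrals evaluated by
41-node Gauss–Hermite quadrature — essentially exact — and (μ, log σ) are
optimized directly (Nelder–Mead, two starts). Per-year estimates are
posterior means of μ + b_t, which shrink each year toward the fixed effect
in proportion to its information; a year with no trials gets the fixed-effect
mean, flagged `fixed-effect-substituted`. Boundary data (all successes or
all failures pooled) have no interior MLE and are reported as the raw rates,
flagged `degenerate`, without intervals. Interval half-widths combine the
posterior variance of b_t with the curvature-based variance of μ̂; simulated
coverage at the study's design (20 years × 4 plots) runs slightly above the
nominal 95%.

Recruitment uses the same machinery with Poisson likelihood and log-exposure
offsets. Exposures: seedlings at *t+1* per flowering ramet (`SF`+`MF`) at
*t* — there is no seed bank, so all seedlings come from last year's seed
rain; anonymous sprouts per capita of the `SR`+`MR`+`IA` pool at *t*, the
stages that can plausibly own a hidden taproot. Pooling plot-level counts
within a year is exact under a shared year effect (the year total is
sufficient).

## Projection matrices

The 6×6 annual matrix is the sum of three labelled components: survival
transitions (columns sum ≤ 1; `SF`/`MF` columns identically zero),
fecundity (row `Sd`, columns `SF` and `MF`, value *f*), and sprout
recruitment (per-capita rates added to rows `SR`/`MR`/`SF`/`MF` in each of
the pool columns `SR`, `MR`, `IA` — consistent with the per-capita exposure
definition, so expected recruits equal rate × pool size). λ is computed by
power iteration (tolerance 1e-12, eigendecomposition fallback for
non-converging cases such as periodic supports) and matches a full
eigendecomposition to < 1e-10. The stable stage distribution is the right
eigenvector of the Perron root; a repeated dominant root (e.g. reducible
matrices) is ambiguous and yields a uniform-over-support vector with a
warning, or an error in strict mode. Transient growth is exp((N_{t+1} −
N_t)/N_t) by default with the plain ratio as an alternative mode; the two
agree to second order.

## SPEI

Thornthwaite PET from monthly mean temperature: annual heat index
I = Σ(T/5)^1.514 over positive months, exponent a(I) by the standard cubic,
PET = 16(10T/I)^a for 0 < T < 26.5 °C, the polynomial branch above, zero at
or below freezing, all scaled by day length (from solar declination at the
site latitude) and month length. The water balance D = PPT − PET is
aggregated to rolling k-month sums (k = 1 for all demographic analyses;
k = 12 available for descriptive plots), and per calendar month a
log-logistic distribution is fitted to the 1950–1989 reference values by
unbiased probability-weighted moments. The fit uses the generalized-logistic
parameterization (shape κ = −t₃), which is the same family but remains
stable when a month's sample happens to be left-skewed — the classic
(α, β, γ) identities fail there. SPEI = Φ⁻¹(F(D)), clipped to ±5.6σ.
Standardization is verified by simulation: reference-period per-month means
within ±0.05 and SDs within 1 ± 0.1.

The census-year drought index is the mean 1-month SPEI over the 14 months
from June of *t−1* through July of *t*; a value that is exactly zero counts
as non-drought (a measure-zero tie must break deterministically).

## Functional linear models

For response years *t* and lags m = 0…L (m = 0 is the July census month;
L = 19 reaches December of *t−2*; L = 11 for seedling recruitment reaches
August of *t−1*, the month of seed release):

    g(E[y_t]) = β₀ [+ γ·t] + Σ_m s(m)·x_{t,m}

The coefficient function s(m) is a cubic B-spline with basis dimension
min(10, L/2) and a second-difference penalty; the smoothing parameter is
chosen by REML (profiled scale), with penalized IRLS performance iteration
for binomial and Poisson responses. Responses are annual *aggregated data*
(successes/trials, counts with log-exposure offset, or log λ_t), not GLMM
point estimates, keeping the likelihood exact; the optional linear year
trend is off by default. Count families carry a quasi-likelihood dispersion
estimated from Pearson residuals and floored at 1 — annual counts are
overdispersed whenever year-level heterogeneity exceeds the weather signal,
and apparent underdispersion in a 19-point series is noise that would
otherwise inflate the test statistic.

Inference: pointwise 95% CIs from the Bayesian covariance of the penalized
fit; the overall test of s ≡ 0 is a Wald statistic on the fitted curve using
a rank-r pseudoinverse of its covariance, r = rounded effective degrees of
freedom, referred to an F distribution with the residual df (the dispersion
is estimated in every family). Approximate GAM p-values run low, so results
are screened at p < 0.01 before any lag window is reported; simulated null
rejection rates at that screen are 1–3% across families, including the
overdispersed case. Significant windows are maximal lag runs where the
pointwise CI excludes zero, labelled with sign and calendar months. Lag
length can be selected by minimum AIC over a candidate range (7–43 months);
the battery runner fits every demographic parameter × weather variable pair
and records non-convergence or zero-variance responses instead of raising,
mirroring how sparse vital rates behave in real data.

## Population viability analysis

Annual matrices are partitioned by the sign of the census-year mean SPEI.
Each replicate starts at N₀ = 50 ramets distributed by the stable stage
distribution of the study-period mean matrix and runs 50 years of i.i.d.
draws: drought-pool probability 0.9 (increased), uniform over *all* annual
matrices (no change — pool-proportional, not a 50/50 mixture), or 0.1
(decreased); 1000 replicates per scenario, per-scenario child seeds split
from one root seed. Stage vectors are continuous-valued — no demographic
stochasticity or integerization — which matches deterministic matrix
projection but understates extinction risk at very small sizes; treat
below-start fractions as comparative, not absolute. Accumulation is
rescaled on the fly (log-scale carry) so fast-growing replicates cannot
overflow; results are reported on both natural and log scales.

## Synthetic data

The generator is the package's ground-truth instrument, not a fixture. It
simulates the six-stage life cycle ramet by ramet: categorical fate draws
from the same conditional-chain parameterization the estimator uses (logit
baseline + per-rate year effect, SD 0.4 by default, + lag-kernel weather
effects), Poisson seedling and sprout recruitment, and an observation layer
in which inactive years emit no record, first observations carry the
distance/cotyledon fields, and a ramet unobserved for three censuses is
re-tagged on reappearance as a new sprout (as a field crew following the
3-year rule would do). Weather is seasonal-mean temperature plus AR(1)
anomalies (SD 1.8 °C, ρ 0.35) and gamma-distributed precipitation (CV 0.55)
around a summer-peaked monthly curve shaped like a semiarid continental
sand prairie; the bundled two-site study runs 1990–2009 censuses on 4 and 3
plots against 1950–2009 weather, with lag kernels on seedling recruitment
(precipitation, lags 0–11), and at the drier site also on SR survival
(precipitation, lags 0–13) and SR flowering (temperature, lags 12–18).

What the generator does *not* emulate, and passing tests therefore cannot
vouch for: spatial structure (the > 10 cm rule is encoded as an explicit
recruit flag, not geometry), measurement error in stage calls, management
effects (haying/grazing), density dependence, and within-year censusing
detail. One intrinsic observation limit is shared with real data: a ramet
that dies *while* inactive is indistinguishable from one that died
aboveground a year or two earlier, so truth-vs-pipeline equality tests use
configurations in which every inactive spell ends in a reappearance.

## Numerical and design choices

- Eigen tolerance 1e-12 (power iteration), eigendecomposition fallback after
  10⁴ iterations; SSD residual ‖Aw − λw‖∞ < 1e-8 enforced in tests.
- Gauss–Hermite order 41; σ ≥ 0 enforced by log-parameterization; a single
  informative year pins σ to 0 (unidentifiable).
- REML smoothing optimized on a 41-point log-λ grid then refined by bounded
  scalar minimization.
- Day-length correction uses standard solar-declination geometry; other PET
  variants (Penman–Monteith, Hargreaves) are out of scope.
- The FLM lag origin is the census month itself (m = 0 = July), so L = 19
  spans back to December two calendar years earlier.
- All pipeline randomness flows from one root seed split per module;
  reruns are byte-identical.
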