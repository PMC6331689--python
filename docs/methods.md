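# Methods

`resilipig` implements a phenotyping-and-genetics pipeline for disease
resilience in growing pigs, built around longitudinal records from
electronic feeders. This note documents the models, the numerical choices,
and what the synthetic cohort generator does and does not emulate.

## The phenotyping problem

In a natural disease-challenge barn, pigs that become ill eat less and
spend less time at the feeder. Day-to-day deviation of an individual's
feed intake from its own trajectory is therefore an observable, cheap and
repeatable proxy for resilience. The pipeline derives four such
phenotypes per animal from daily feed intake (FI, kg/day) and feeder
duration (DUR, min/day):

- **RMSE_FI, RMSE_DUR** — the root mean square error of the within-animal
  ordinary least squares regression of the daily value on age. The
  default denominator is n (a literal root-mean-square of residuals); a
  `ddof=2` option gives the regression standard error instead. The
  difference is negligible at the 60-day minimum but is pinned for
  reproducibility.
- **QR_FI, QR_DUR** — the animal's proportion of *off-feed* days. A
  single population-level 5% quantile regression of the daily value on
  age is fitted on the pooled days of all eligible animals across
  batches, then frozen; a day strictly below that line is off-feed (ties
  count as on-feed). The functional form is linear in age with an
  intercept, matching the visual form of the classification line.

Validation traits: mortality (0/1, died before slaughter), number of
individual treatments TRT (survivors only; group treatments are excluded
because the batch fixed effect absorbs them), and the treatment rate
TRT180 = (count / last-alive age) × 180, computed for animals reaching 65
days of age so that early deaths still receive a phenotype.

Eligibility: RMSE and QR phenotypes require at least 60 recorded
(observed or imputed) FI days. Without the minimum, animals dying early
in finishing would appear on the "resilient" end of the distributions
simply for lack of data.

## Record cleaning

Daily totals above 5 kg are set to missing (strictly greater; an exact
5.0 is kept) — a physiological cap on what a finishing pig eats in a day.
Missing intake and duration are then imputed by a 5-day rolling average
within animal, *centred* (±2 calendar days) and computed from
originally-observed values only, so a two-day adjacent gap fills from its
flanking observations and the result is independent of fill order. A
trailing window is available by flag (`centred=False`); whether the
original analysis used a centred or trailing window is not documented, and
the centred window is chosen because only it can fill a two-day gap from
both sides. Days with no observed neighbour within the window stay
missing and do not count toward eligibility.

## Growth curves and gain

Body weights arrive roughly every three weeks; daily weights are needed
for phase gains and feed-conversion endpoints. Each animal's weights are
fitted with a locally weighted polynomial regression (LOESS) with the
classical defaults: span 0.75, degree 2, tricube kernel, no robustness
iterations, evaluated pointwise (at each target age the q = ⌊0.75·n⌋
nearest observations get tricube weights scaled by the distance to the
q-th nearest, and a weighted quadratic is solved by least squares). The
tests lock this behaviour against an independently computed
pointwise-WLS oracle to 1e-6 kg. Animals with 2–3 weights (common among
early deaths) fall back to linear interpolation, flagged in the output;
animals with fewer than 2 weights get no curve. Predictions are never
extrapolated outside the observed age range, and phases are clipped to
the curve range.

Average daily gain is the OLS slope of predicted daily weight on age:
nursery ADG from quarantine entry to the first FI day, finishing ADG from
the first to the last FI day.

## Production traits

ADFI is the mean of non-missing daily FI over finishing. FCR is total
finishing feed over the gain between the LOESS-predicted weights at the
phase endpoints (non-positive gain yields a missing trait). Dressing
proportion is warm carcass weight over live weight. Lean yield is a fixed
Québec prediction polynomial in carcass backfat and loin depth,
evaluated exactly; over the observed carcass range it is dominated by
backfat (r ≈ −0.98 with backfat on simulated carcasses). RFI is the
residual of ADFI from a linear model with batch, finishing start age and
pen as fixed effects plus mean finisher body weight, finishing ADG and
ultrasound backfat as covariates (two-step). The body-weight covariate
defaults to the arithmetic mean of daily predicted weights;
`metabolic_bw=True` uses mean weight^0.75 instead. A one-step analogue —
the same covariates inside the animal model with ADFI as the response —
is available through the genetics module.

## Quantile regression numerics

The pinball (check) loss Σ ρ_τ(y − a − b·age) is minimized as a linear
program in its dual form (Koenker–d'Orey): maximize y'd subject to
X'd = 0 with d_i ∈ [τ−1, τ]; the coefficient estimates are the negated
multipliers of the two equality constraints (solved with HiGHS). The dual
has n box-bounded variables and two equality rows, which scales to the
~10^5 pooled animal-days of a cohort in about a second, whereas the
primal residual-splitting form with 2n+2 variables takes minutes. The two
forms share an optimum; tests verify the returned loss equals a
brute-force minimum over all lines through point pairs on every
enumerable instance, and that coverage brackets τ (strictly-below ≤ τ ≤
below-or-on). Ties in classification favour on-feed; any optimal basic
solution is accepted, so tests compare losses, not coefficients.

## Animal-model REML

Variance components are estimated for y = Xb + a + e with a ~ N(0,
K σ²_a), e ~ N(0, I σ²_e), where K is a relationship matrix over the
phenotyped animals:

- **A** (pedigree) by the tabular method; unknown parents are founders.
- **G** (genomic) as Z Z′ / Σ2pq with Z = M − 2p (VanRaden); monomorphic
  markers excluded.
- **H** (single-step blend): G is first rescaled so its mean diagonal and
  mean element match the genotyped pedigree block A22, then
  Gw = 0.95·G + 0.05·A22 enters the standard H construction. If H is not
  positive semi-definite the pedigree share is increased with a warning.
  The 0.95/0.05 and mean-matching constants follow common single-step
  practice.

**Univariate.** After one eigendecomposition K = U D U′, the restricted
likelihood is profiled on the variance ratio λ = σ²_a/σ²_e, with σ²_e
solved in closed form; λ is located by an 81-point grid on log λ ∈ [−8, 8]
plus bounded refinement, and λ = 0 is evaluated exactly so boundary
(zero-heritability) solutions are reachable and flagged. Standard errors
come from the inverse observed information in (σ²_a, σ²_e), with the
delta method for h²; at a boundary the information is evaluated on the
projection and SEs are approximate.

**Bivariate.** Unstructured 2×2 genetic and residual covariances, shared
fixed effects, complete-case animals (rows missing either trait are
dropped). In the eigenbasis of K the covariance is block-diagonal in 2×2
blocks V_j = d_j G0 + R0, so each likelihood evaluation is O(n).
Parameters are optimized through Cholesky factors (guaranteeing positive
semi-definiteness, |r_g| ≤ 1 and h² ∈ [0, 1]) by Nelder–Mead with a BFGS
polish, started from the univariate fits. Convergence is the optimizer's
success flag; the accepted-iterate likelihood trace is stored and is
non-decreasing by construction. SEs come from a finite-difference
observed information on the covariance scale with delta-method SEs for
h² and r_g; when the information matrix is singular (boundary or
near-degenerate fits, e.g. a trait with no genetic variance) SEs are
reported as missing rather than as meaningless large numbers.

Mortality is analyzed as a linear 0/1 trait. Fixed effects follow the
trait's recording window: batch + quarantine entry age for mortality and
treatment traits; batch + finishing start age + pen for finishing traits.
Bivariate runs pairing a wean-to-finish trait with a finishing trait use
batch + finishing start age, since complete-case animals all entered
finishing. Litter effects are not modelled. QR/RMSE phenotypes enter
untransformed; proportions are bounded and right-skewed, and a logit/log
transform is left to the caller.

## The synthetic cohort generator

No real cohort ships with the package, so the generator produces data
with the structure the analysis assumes. Its defaults emulate the scale
and summary statistics of a three-cycle natural-challenge experiment:
21 batches × 64 pigs, a half-sib pedigree (112 sires × 3 dams × ~4
piglets), ~26% wean-to-finish mortality, FI rising from ~1.5 kg/day at
finishing entry by ~0.0145 kg/day², ~70 min/day at the feeder, and
carcass means around 94 kg carcass weight / 0.78 dressing / 18 mm
backfat.

Three latent animal traits — susceptibility, appetite, growth — follow
the additive infinitesimal model down the pedigree with configurable
heritabilities (default 0.35 each) and genetic correlations (default:
susceptibility vs appetite −0.30, vs growth −0.40, appetite–growth
+0.50): sickness-prone pigs eat less and grow slower. Illness episodes
arrive as per-day Bernoulli onsets (rate 2 per 100 days at risk, drawn
unconditionally per day so that raising the rate only adds onsets — this
makes off-feed burden provably monotone in the rate), with log-normal
depth shifted by the animal's susceptibility, uniform 3–15 day length,
and a rectangular depth profile with 2-day onset/recovery ramps. Episode
severity (depth × length, "depth-days") above 1.85 triggers an individual
treatment; above 7.0 it kills the animal mid-episode and truncates all
its records. Both thresholds were calibrated once, by bisection on the
default configuration, to the ~26% mortality and ~2.4 treatments/180
days of the emulated study, and then frozen.

Duration co-drops with intake during episodes through an animal-specific
eating rate applied to the *expected* (illness-reduced) intake; its
healthy-day noise is independent of the intake noise, keeping duration
variance roughly flat in age. Growth follows a per-animal gain ramp
(0.20 → ~0.99 kg/day over 100 days), halved on episode days; weights are
recorded every 21 days with 1 kg error. Feeders occasionally mis-record
(0.2% implausible spikes above 5 kg, 1% lost days) to exercise the
cleaning stage. Optional switches: a sinusoidal batch severity
multiplier (seasonality; off by default), masking of sires in the
exported pedigree (the emulated study only had dams), and gene-dropped
SNP genotypes (founders in Hardy–Weinberg at uniform allele frequencies,
Mendelian transmission, so genomic and pedigree relationships agree in
expectation).

Realized cohort means at the default configuration (seed 1): mortality
0.27, RMSE_FI 0.466 kg, RMSE_DUR 13.05 min, ADFI 2.20 kg/day, FinADG
0.89 kg/day, FCR 2.58, TRT 2.01, TRT180 2.31, DRS 0.78.

What the generator does **not** emulate: pathogen identity and strain
dynamics, pen-level transmission (episodes are independent across
animals given the latent traits), within-day feeder-visit structure, feed
composition, heat stress, and real genotype linkage disequilibrium
(markers are unlinked). Passing tests therefore demonstrate that the
*pipeline* recovers the parameters of data with this structure — not
that any particular barn satisfies the structure.

## Problem sizes and tolerances

The test suite and the acceptance script run everything at desk scale,
chosen so a full run completes in minutes on one core: parameter-recovery
checks use 2,000 animals in 200 paternal half-sib families over 10
seeds; the end-to-end genetic check runs the full pipeline once on the
default 1,344-pig cohort; the quantile-coverage check pools >10^5
animal-days. Numerical tolerances: LOESS vs oracle 1e-6 kg; RMSE closed
forms 1e-12; LP loss vs enumeration 1e-8; REML likelihood vs grid oracle
1e-4; REML convergence |Δ log-lik| below optimizer tolerance (1e-10).

## Known limitations

- Bivariate REML requires complete cases and a single relationship
  matrix; per-trait fixed-effect sets and per-trait missingness patterns
  are not supported.
- SEs are asymptotic (observed information + delta method) and are
  unreliable at variance boundaries; they are reported as missing when
  the information matrix is singular.
- The H matrix is provided and tested structurally at desk scale; the
  pipeline's default genetic analysis uses the pedigree A matrix.
- Visit-level feeder-record cleaning is out of scope; daily totals are
  the input granularity.
- Threshold (liability) models for mortality are not implemented; the
  linear 0/1 model is used.
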