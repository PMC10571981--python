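# Methods

`bcsherd` implements a herd-level surveillance analysis of dairy-cow body
condition: cow-level risk models for transition-period outcomes, aggregation
of calvings into 21-day cohorts, quartile-threshold screening of cohort
exposure prevalence, and a per-cohort population-attributable-fraction time
series. This note documents the models, the synthetic data-generating
process, the numerical choices, and the limits of what the tests establish.

## Indicators

Body condition score (BCS) is scored on the 5-point scale in quarter-point
increments; `ΔBCS = BCS at reproductive release (40–60 DIM) − BCS at
calving`, so negative values are loss. The binary *exposure* is poor body
condition around the transition period:

    exposed  ⇔  BCS_calving < 3.0  or  loss (−ΔBCS) > 0.5

Both inequalities are strict: a cow calving at exactly 3.0 and losing
exactly 0.5 belongs to the protective class ("BCS ≥ 3 and losing ≤ 0.5").
Both cuts are tunable (`ExposureRule`, CLI `--bcs-cut` / `--loss-cut`).
Calving season uses Southern-hemisphere astronomical boundaries (Summer
21 Dec – 20 Mar, then quarterly); 29 February falls in Summer. Records
missing either score are excluded with a logged count, never imputed.

## Cow-level models

Per herd × parity stratum (heifer = parity 1; cow = parity ≥ 2), a logistic
model per binary outcome (anestrus, metritis, mastitis, AI by 80 DIM,
pregnancy by 100 DIM):

    logit P(y=1) = β0 + β1·(BCS − mean) + β2·(ΔBCS − mean)
                   + year + season [+ parity {2,3,4+} in the cow stratum]

Centering at the stratum mean makes exp(β1) the odds ratio per unit increase
over the mean. Milk at the first monthly test (30–40 DIM) gets the analogous
OLS model with DIM and DIM² added. Fitting is maximum likelihood via
statsmodels (Newton, gradient tolerance at the library default, max 100
iterations, with a BFGS fallback when sparse categorical cells make the
Hessian singular). Confidence intervals are Wald intervals on the log-odds
scale, exponentiated for reporting; profile intervals were not implemented
because Wald intervals match the conventional output of standard GLM
software and are cheap at these sample sizes. Separation is flagged when any
|coefficient| exceeds 15 on the log-odds scale; flagged fits are returned
with diagnostics, never silently. Reference levels — earliest calving year,
Summer, parity 2 — are arbitrary for the reported BCS/ΔBCS effects, which
are reference-free. Strata need ≥ 50 usable records and both outcome
classes; adjusters constant in a stratum are dropped and noted.

## 21-day cohorts

Calvings are binned into consecutive 21-day half-open intervals
`[origin + 21k, origin + 21(k+1))` per herd × parity stratum; 21 days
approximates one estrous cycle. The origin defaults to each stratum's first
calving date (the anchor is otherwise arbitrary) and can be fixed to a
calendar date. Cohorts with fewer than 20 calvings are retained in the
summary but excluded — consistently — from quartile computation, the median
split, screening, and the attributable-fraction series. Each cohort carries
its exposure prevalence, anestrus proportion, and `pd`, the exposed fraction
among its anestrus cases (undefined when the cohort has no cases).

Quartiles of cohort exposure prevalence use linear interpolation between
order statistics (numpy `method="linear"`, classical type 7) by default;
the method is switchable (e.g. `inverted_cdf` for the empirical-CDF
convention of some GLM software) because printed quartiles from other
datasets cannot disambiguate the convention. The high-anestrus label is
*strictly above* the median of cohort anestrus proportions; ties at the
median are labelled "not above".

## Threshold screening

Each quartile is offered as a threshold; a cohort is flagged when its
exposure prevalence is strictly above it. The flag's performance against the
high-anestrus label is summarized by sensitivity (`Se = P(flagged | high)`),
specificity, odds ratio with Wald CI, and AUC. For a single binary predictor
the ROC curve has one interior point, so the c-statistic is exactly
`(Se + Sp)/2` with tied predictions counted ½; a Mann–Whitney pair-counting
implementation cross-checks this identity in the tests. The odds ratio is
reported under the protective coding (odds of high anestrus for cohorts
at/below the threshold vs above), giving ORs < 1 when poor condition is
harmful; `--coding risk` reports the reciprocal, and the four cells are
always emitted so either orientation can be audited. The per-stratum
selection rule is maximal AUC, ties resolved toward the lower quartile.
Zero cells follow a warn-and-report policy by default (OR 0/∞, CI (0, ∞));
a Haldane–Anscombe +0.5 option exists.

## Attributable fraction

Per cohort, `AF_P = pd · (aRR − 1)/aRR`, the fraction of anestrus cases
avoided if no cow were exposed, assuming the exposure–anestrus association
is causal. The adjusted risk ratio comes from a stratum-level logistic model
`anestrus ~ exposure + year + season (+ parity)`. Because exp(β) from a
logistic model is an odds ratio, the default converts to a risk ratio by
marginal standardization (g-computation): mean predicted risk with everyone
exposed over mean predicted risk with everyone unexposed, averaged over the
observed covariate distribution. With no varying covariates this collapses
exactly to the crude risk ratio. An `or-as-rr` compatibility mode reports
exp(β) directly, since surveillance reports sometimes do; outputs are
labelled with the mode. The description "stratified by 21-day cohorts" is
internally tension-laden — year and season are constant within a cohort, so
cohort-wise models cannot adjust for them — hence the default fits one
adjusted model per stratum and combines it with cohort-specific `pd`; an
`arr_scope="cohort"` variant refits per cohort without year/season and logs
that caveat. Negative AF_P (protective estimate) is reported as-is with a
flag, never clipped. Bootstrap CIs for the aRR use a seeded nonparametric
percentile bootstrap over cows (500 resamples by default at the estimator;
the time series itself omits CIs unless requested, since the per-cohort
series carries no interval in the report format).

## Synthetic herd generator

The generator emulates the study design the analysis assumes: two herds ×
two parity groups over a four-year calving window. Per cow: calving date
uniform over the window; parity from a configurable mix over {1, 2, 3, 4+};
latent BCS at calving normal, rounded half-away-from-zero to the
quarter-point grid and clipped to [1, 5]; ΔBCS drawn as
`delta_mean + slope·(BCS − bcs_mean) + noise` with a negative slope encoding
"fatter cows at calving lose more", rounded to the grid, with the release
score clipped to [1, 5]; outcomes Bernoulli from configurable logistic
models; milk from the linear model with residual SD in kg/d. Outcomes are
generated from the *observed* (rounded, clipped) scores, so the fitted
cow-level models are correctly specified and recovery tests isolate the
estimator. Year and season effects, whose magnitudes are not pinned down by
the descriptive targets, are drawn once per config from N(0, 0.2) on the
log-odds scale and stored in the config (helper
`with_random_period_effects`), keeping generation a pure function of
config + seed; identical config and seed reproduce the table byte for byte.

Default two-herd study (`default_study_configs`): herd A ~5,000 calvings
over 4 years calving at mean BCS 3.30 (SD 0.30) and losing 0.5 on average;
herd B ~8,000 calvings at mean 2.90 (SD 0.35) losing 0.35, with higher
anestrus and mastitis baselines. Intercepts put marginal outcome rates in
the 10–30 % band typical of commercial grazing herds; BCS effects use
log-odds around −2 (anestrus) to +1.2 (AI by 80 DIM) per unit. These are
loose emulation defaults, not calibration targets. The acceptance script
runs this study at 1,200 cows/herd/year (9,600 records), a size at which
every stratum clears the 20-calvings-per-cohort filter while the whole
pipeline completes in seconds.

Outcome risk can act through the continuous centered scores, through the
binary exposure flag, or both. The distinction matters for ground truth:
`pd·(aRR−1)/aRR` identifies the counterfactual attributable fraction only
when the effect operates through the binary exposure itself, so the AF_P
recovery experiment (`afp_recovery_configs`: exposure log-odds 0, 0.5, 1.05,
1.85 over a 10 % baseline, spanning true AF_P ≈ 0, 0.2, 0.4, 0.6 at 20,000
cows per condition) uses the binary route, while coefficient-recovery
experiments use the continuous route. The independent truth is `true_afp`, a
common-random-numbers Monte-Carlo oracle: simulate covariates once, replay
the identical uniform draws under factual and counterfactual (all
BCS-mediated coefficients zeroed) linear predictors, and take
`(risk_f − risk_cf)/risk_f`; sharing the uniforms removes most Monte-Carlo
variance from the difference.

What the generator does *not* emulate: lactation curves, culling, pregnancy
loss, repeated lactations per cow, seasonal calving clusters, scorer
disagreement, or the exact empirical BCS frequency distributions of any real
herd. Passing recovery tests therefore show that the estimators recover the
parameters of a correctly specified data-generating process at realistic
sizes — not that real herd data satisfy those models. An optional
misclassification-noise knob for BCS scoring was considered and left out:
no agreement coefficient between scorers is available to set a realistic
magnitude, and a knob without a defensible default invites misuse.

## Numerical choices and degenerate inputs

- BCS grid snapping on input tolerates 1e-9; anything further off-grid is a
  rejected row with line number and reason.
- Quantiles/median: interpolated order statistics; permutation-invariant.
- Zero anestrus cohorts: AF_P emitted as missing with reason `no_cases`.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; bootstrap and generator streams are separate.
- Pipeline reports are plain CSV with a JSON manifest (config, seed,
  version, per-stage row counts); reruns are byte-identical.

## Known limitations

- Wald intervals can misbehave near separation; such fits are flagged
  rather than repaired (no Firth correction).
- The bootstrap refits the full logistic model per resample; at very large
  strata prefer fewer resamples or the point estimate.
- Single cow-level error term: no random effects for pen, scorer, or sire;
  mirroring the modelling scope, not a claim that clustering is absent.
- The stratum-level aRR applied to every cohort assumes a stable
  exposure–anestrus association over the study window; the per-cohort mode
  relaxes this at the cost of covariate adjustment.
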