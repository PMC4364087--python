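# Methods

This note documents the models implemented in `cfqrmap`, the synthetic
data they are exercised on, and the numerical and design choices made
where the underlying methodology leaves room.

## The mapping problem

The target is the EQ-5D-3L utility index under the UK general-population
TTO tariff. A state assigns one of three levels to five dimensions
(mobility, self-care, usual activity, pain/discomfort,
anxiety/depression); the tariff scores a state as

    U = 1 − c·1[any level > 1] − Σ_d δ_d(level_d) − n3·1[any level = 3]

with c = 0.081, n3 = 0.269 and per-dimension level-2/3 decrements bundled
in `data/uk_tto.yaml`. The attainable set is 243 values in [−0.594, 1];
the loader validates both anchors at load time. Utilities are held at full
precision; rounding happens only in report formatting.

The source instrument is the CFQ-R (teen/adult): 50 ordinal items (1–4)
in 12 domains. After reverse coding (so 4 = best), a domain score is
`100·(mean − 1)/3`, the unique linear map sending all-1s to 0 and all-4s
to 100. Missing items drop out of the mean; a domain is scored when at
least half its items are answered (a common half-scale convention — the
developer's official rule is not public, so this default is declared an
assumption and is configurable, as is the item→domain/reverse-coding map
in `data/cfqr_items.yaml`). For modelling, the Health-perceptions domain
and its items are excluded (everything else already measures health, so
they are redundant/collinear), as is item 43, a conditional sub-question.

## Estimators

Utilities pile up at 1 (the ceiling) and are bounded below, so three
families are provided.

**OLS** on the raw utilities (statsmodels under the hood). Predictions are
unbounded and can exceed 1.

**Upper-censored Tobit.** Observed y = min(y*, 1) with y* = xβ + σε,
ε ∼ N(0,1). Censored observations contribute log Φ((xβ−1)/σ). Estimated by
quasi-Newton (BFGS, analytic gradient, log-σ parametrisation) from OLS
starting values; to keep the optimizer well conditioned with 0–100-scale
domains and their squares in one design, the fit internally rescales
columns to unit RMS and maps coefficients and covariance back. Convergence
requires the max-absolute score below max(1e−8, 1e−6·n); a single L-BFGS-B
polish pass is attempted first if BFGS stalls on precision loss. The
covariance is the inverse of a finite-difference Hessian of the analytic
score (OPG fallback if that is not positive). The default prediction is
the censored expectation E[min(y*,1)|x], which cannot exceed the limit;
`mode="latent"` returns xβ. McFadden's pseudo-R² is reported against the
intercept-only fit.

**Two-part model.** Part 1 is a logit for P(utility = 1); part 2 a
Gaussian regression truncated to the interval (−0.594, 0.99), fitted to
the sub-ceiling respondents, with the same scaled-MLE machinery as the
Tobit. Parts are combined by the expected-value rule
EV = p + (1−p)·ŷ₂. Two conventions to note:

* Part-2 predictions default to the *linear predictor* xβ rather than the
  truncated-normal conditional mean (both are exposed). This matches how
  such mapping functions are commonly applied — published part-2
  coefficients are used as a plain linear formula — and means EV can
  exceed 1 only if ŷ₂ does. The conditional-mean mode
  (`mode="conditional"`) always stays inside the truncation interval.
* The truncation interval is treated as closed. The tariff's minimum
  (−0.594) coincides with the lower truncation bound, so a worst-state
  respondent sits exactly on it; the truncated likelihood is finite there.

Information criteria use AIC = 2k − 2ℓ and BIC = k·ln n − 2ℓ; for OLS, k
counts the regression coefficients (statsmodels convention), for the MLE
families it also counts σ. Two-part criteria are reported per part and
never summed, since the parts are fitted on different samples.

**Bias-corrected bootstrap.** `bootstrap_bc` resamples respondents with
replacement, reports the SD of the bootstrap estimates as the SE and
applies the BC (median-bias) correction z₀ = Φ⁻¹(share of bootstrap
estimates below the point estimate) to the percentile interval. No
acceleration term (that would be BCa). Degenerate distributions collapse
to a zero-width interval; the seed and replication count are recorded in
the output. Sandwich (robust) covariances are not currently produced by
the MLE classes; the bootstrap is the uncertainty route for them.

## The specification ladder

Eight predictor sets, each combinable with each family. Screening is a
*single pass*: fit the full model, keep predictors with p < 0.10, refit —
no stepwise iteration (the protocol wording does not describe one).
Squared-term candidates are the squares of the retained domains, screened
at the same level; interaction candidates are the pairwise products of
retained domains, likewise screened. Item designs are dummy coded with
the worst (poor-health) level as reference; item blocks are kept or
dropped whole using a joint Wald test on the block's dummies, since
dropping individual level dummies would break the ordinal coding. An item
is "unordered" when its level coefficients are not monotone non-decreasing
toward better health; model 7 dichotomises such items to
'no problems' vs 'other'. For the two-part family the ladder is resolved
per part — the ceiling logit and the truncated regression each screen
their own predictors — and item-level part-1 designs are always collapsed
to 2–3 levels per item (cells with fewer than 5 respondents in either
outcome class are merged toward worse health, then capped at 3 levels) to
keep the ceiling logit estimable. Model 8 adds age (years, linear) and a
male indicator to a base specification supplied as an argument (default:
the all-items model). Resolved designs are captured in a `DesignRecipe`
that rebuilds the identical column set on new data, which is what
cross-validation uses.

## Validation machinery

* RMSE/MSE on aligned observed/predicted vectors.
* ICC: the protocol names only "intraclass correlation"; this package
  computes ICC(A,1) — two-way random effects, absolute agreement, single
  measures — from the ANOVA mean squares of the stacked n×2 table. This
  variant penalises constant shifts, which is the property wanted when
  comparing predictions to observations.
* VIF per predictor (auxiliary-regression form), flag at 10; perfect
  collinearity reported as infinite.
* RESET: F-test of powers 2–4 of the fitted values in the OLS fit.
* Linktest: refit the *same family* on the linear predictor and its
  square; the squared term's significance is the misspecification signal.
  For OLS this reduces exactly to RESET with the single power 2.
* Misspecification verdicts use α = 0.05 (the protocol reports verdicts
  without stating a threshold; 0.05 is the conventional choice).
* Subgroup tables over observed-utility bands
  [−0.594, 0.1, 0.3, 0.6, 0.7, 0.8, 0.9, 1] — left-closed, right-open,
  last band closed (the banding convention is a package choice) — and over
  FEV1 severity (mild > 70 %, moderate 41–70 %, severe < 41 % predicted),
  with one-way ANOVA across populated groups; the dispersion column can
  report either the SD of predictions or the per-band RMSE and is
  labelled.
* Cross-validation: respondents are randomly partitioned into 4 folds
  (sizes differing by at most one); each fold is predicted by a model
  re-resolved (screening re-run) and re-fitted on the other three. A
  balance ANOVA compares observed means across folds. Fold assignment is
  a pure function of (n, k, seed).

## Synthetic cohorts

No respondent-level dataset is deposited, so the generator emulates the
statistical structure the mapping needs:

* One latent severity trait θ ∼ N(0,1) per respondent drives both
  instruments (conditional independence given θ), giving the CFQ-R↔EQ-5D
  dependence. The strength of that dependence is a free parameter of the
  generator (EQ-5D dimension loading 0.78, CFQ-R domain loadings 0.65),
  chosen to put observed-vs-predicted agreement in a realistic range
  (full-sample ICCs around 0.7); no published correlation pins it down.
* EQ-5D dimensions are ordinal-probit draws given θ. Their thresholds are
  calibrated *deterministically*: marginals are computed by 96-node
  Gauss–Hermite quadrature over θ combined with exact enumeration of the
  243 states, and three parameters (a shift of the level-1/2 thresholds,
  a shift of the level-2/3 thresholds, a common spread scale over a fixed
  cross-dimension pattern) are solved by root finding against the study
  marginals — ceiling share 0.19, negative share 0.03, mean 0.67.
  Calibration failure (targets unattainable or residual above ±0.02)
  raises an error reporting the achieved marginals.
* CFQ-R items add a shared domain effect (loading 0.30) and item noise;
  per-domain thresholds are solved (scalar root) so domain-score means
  match the study's descriptive table. The digestive-symptoms domain gets
  a near-zero loading so it does not track severity, mirroring the one
  domain that did not follow the FEV1 gradient. Reverse-worded items are
  stored at raw polarity so the scorer's reverse coding is exercised.
* Age (28.7 ± 8.9, clipped to 18–62) feeds weakly into the trait
  (loading 0.15); FEV1 %-predicted (65.7 ± 27.3, clipped to 17–99) tracks
  the trait with loading 0.55, giving the expected severity gradients.
* Fixed seeds give bit-identical tables; n = 0 returns an empty table with
  the full schema.

What the generator does **not** emulate: the empirical joint distribution
of any real cohort (item-level response patterns are exchangeable within
domain), informative missingness (generated data are complete), response
styles, and any direct age/gender effect on utility beyond the trait
channel. Passing tests therefore demonstrate that the estimators and the
pipeline recover known structure under the study's marginal conditions —
not that the published coefficients are correct for real patients.

A separate plain linear generator (`generate_linear`) draws uniform 0–100
predictors, builds squared terms, adds Gaussian noise and optionally
censors at 1 or truncates (by resampling) to (−0.594, 0.99); it is the
parameter-recovery harness for the published coefficients.

## Published mapping functions

The recommended domain-level Model 3 coefficients ship in
`data/published_model3.yaml` at full printed precision with their
bootstrapped SEs, validated at load against the two intercept anchors
(−0.09898 OLS; −0.22122 two-part part 2). The published table prints only
one constant for the two-part model; its magnitude places it on the
utility scale, so it is stored as the part-2 intercept and the part-1
intercept is recorded as explicitly unavailable — the two-part applicator
refuses to run unless the user supplies one (e.g. from a part-1 refit on
their own data). Domain-name aliases accept both label styles
("Emotional functioning"/"Emotion" etc.). Predictions are unclamped by
default; clamping to [−0.594, 1] is available and always flagged. Printed
rounding of the squared-term coefficients (single significant figure)
limits reproduction precision to about 1e−4 per 100² score units.

## Problem sizes and defaults

The default demonstration grid (`cfqrmap validate`, and the shape checks
in the test suite) uses a cohort of n = 2,000: large enough that all 24
models — including the ~140-column item-level Tobit and the collapsed
ceiling logit — are comfortably estimable, small enough to run in well
under a minute per family. Parameter-recovery checks use n = 10,000 with
noise SD 0.12 (the residual scale implied by the published fit
statistics); calibration checks use n = 10,000 draws against the
quadrature targets. Bootstrap defaults to 2,000 replications; tests use
smaller counts with seeds fixed.

## Known limitations

* The CFQ-R item map and reverse-coding list are declared assumptions
  (the licensed scoring manual is not reproducible here); results on real
  data require the user's own map file if it differs.
* Only the UK 3L tariff ships; other value sets can be supplied as YAML
  but cross-country mapping validity is the user's responsibility.
* Tobit/truncated covariances are asymptotic (numeric Hessian of the
  analytic score); for small samples prefer `bootstrap_bc`.
* The two-part EV with linear-predictor part 2 can exceed 1 when the
  part-2 formula itself does; use the conditional mode or clamping for
  economic models that require bounded utilities.
* Mean predictions from the two-part family on heavily truncated
  synthetic cohorts run a few hundredths above the observed mean — the
  linear-predictor convention trades calibration of the mean for
  faithfulness to how published two-part mappings are applied.
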