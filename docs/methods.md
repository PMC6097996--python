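# Methods

## Response model

Every trial is a two-alternative forced choice, so the item characteristic
curve is a four-parameter logistic with guessing fixed at 0.5, inattention
fixed at 1 and a single shared discrimination:

P(X = 1 | θ) = 0.5 + 0.5·logistic(a(θ − b)).

Ability θ lives on the population-standardised latent scale (mean 0, SD 1);
item difficulty b shares that scale. The logistic is evaluated through
`scipy.special.expit` so that arguments of order ±500 and beyond saturate
instead of overflowing — adaptive sessions can visit extreme θ − b. All
closed-form equalities in the tests are held to 1e−9 in double precision
unless a statistical tolerance applies.

An important consequence of the 0.5 guessing floor: the curve is not
symmetric in correct/incorrect, so flipping every response does **not**
negate the ability estimate (an error is more diagnostic than a success).
The symmetry that does hold — and is tested — is for the guessing-free
sub-model.

## Automatic item generation

An item is (track, beep-track accuracy, displacement direction, stimulus
order). Accuracy is the quartic-cosine transform d_r = cos⁴(πP) of the
lure's beat-fraction offset P ∈ (0, 0.5]; offsets beyond half a beat alias
onto the neighbouring beat, which bounds the domain. Difficulty is linear
in the radicals:

b = intercept + accuracy_effect·d_r + direction_effect·[behind].

The shipped defaults are intercept −5.393, accuracy effect 7.247, behind
effect −0.576, discrimination 1.166. Direction is dummy-coded behind = 1,
ahead = 0. Track-level random-effect summaries (intercept SD 2.121,
accuracy-slope SD 1.477, correlation −1.000) are carried as provenance
metadata only: their degenerate correlation makes them unstable, and they
are deliberately excluded from prediction. Stimulus order and track never
enter the difficulty prediction.

Accuracy grids are n equally spaced levels starting at `low` with step
(high − low)/n and the endpoint excluded (accuracy 1 would be a
zero-offset lure, i.e. a second target). The exact endpoint convention used
for the original grids is not published, so the grid helper takes `low`,
`high` and `n` explicitly rather than hard-coding one convention; the
default bank (100 levels on [0.5, 1)) puts the item nearest average
difficulty at about −0.01, which is what the default first-item target
expects. Banks come in two shapes: `factorial` (the full feature cross —
27×27×2×2 = 2,916 for calibration, 25×100×2×2 = 10,000 for the adaptive
test) and `paired` (one item per track with a seeded random
track-to-accuracy bijection and half/half direction and order splits, the
exploratory design). Item ids are deterministic functions of the features
so session logs are reproducible across runs.

## Ability estimation

* **Bayes modal** (interim): maximises log-likelihood plus a N(0, 1)
  log-prior by bounded scalar minimisation on [−6, 6] (tolerance 1e−6);
  with no data it returns the prior mode. Its SE includes the prior's
  information, 1/√(I(θ̂) + 1/σ²) — configurable, since the reference
  implementation's choice is not published.
* **Warm weighted likelihood** (final): solves score + J/(2I) = 0, with
  J = Σ P′P″/(P(1−P)), by sign-change bracketing on a 481-point grid plus
  Brent refinement; if several roots exist the one maximising the
  log-likelihood + ½·log I surrogate wins; if no sign change exists inside
  [−6, 6] the better boundary is returned with `converged=False`. The
  correction keeps all-correct and all-incorrect patterns finite. SE uses
  test information only.
* **EAP** (fixed-form scoring): posterior mean and SD over 61 Gauss–Hermite
  nodes rescaled for the Gaussian prior.

[−6, 6] covers the N(0, 1) population and the bank's difficulty span
(−2.35 to 1.82) with ample margin. Fisher (expected) information is used
throughout rather than observed information, matching standard IRT SE
reporting; which form backed the original SE figures is unstated, so this
is a declared choice.

## Adaptive sessions

Fixed length (default 25, at most the number of distinct tracks — a track
is never heard twice). The opening item is the bank item nearest the
configured difficulty target (−0.01 by default), stimulus order free.
Subsequent items come from the eligible set at minimal |b − θ̂| (Urry's
criterion); exact ties are broken by a seeded uniform draw, and a
`randomesque_set_size` above 1 widens the candidate set to the next-nearest
difficulties for exposure control (the original description says "randomly
selected from the subset … maximally close" without fixing a set size, so
the exact-minimum default is a declared choice). Interim SE-versus-length
curves are produced by re-running the WL estimator on each truncated
response prefix, matching how shorter test lengths were scored post hoc.

## Calibration

Both fitters maximise the marginal likelihood with ability integrated over
N(0, 1) by 61-node Gauss–Hermite quadrature, using analytic
posterior-weighted score functions inside L-BFGS-B (relative tolerance
1e−12, gradient tolerance 1e−8). Missing responses are ignorable, which is
consistent with adaptive administration under the fitted model. Standard
errors come from the inverse observed information (numerical Hessian); for
the per-item fitter this step is O(items²) function evaluations and can be
switched off. Conditional response probabilities are capped at 1 − 1e−12
so saturated logistics cannot produce −∞ log-likelihoods.

* `fit_constrained_3pl`: free per-item difficulties, one shared a
  (parameterised as log a). Items whose observed column is constant have
  no interior optimum; they are flagged and their estimates sit at the
  search bounds. Starting difficulties invert the observed proportions
  through the guessing-adjusted logit.
* `fit_explanatory_model`: difficulty replaced by the feature linear
  predictor; parameterised on the raw mixed-model scale (person effect
  a·θ plus fixed effects B), with c = −B/a and the discrimination equal to
  the person-effect SD. Reported on both scales; the delta-method SE for c
  ignores the covariance with a (a second-order term at these sample
  sizes).
* `regress_difficulty_on_features`: ordinary least squares via
  statsmodels, with fully standardised coefficients, adjusted R² and the
  overall F test — the two-stage route used in exploratory calibration.

Track-level random slopes are not fitted: the published calibration
reports convergence failures and omits them from prediction, so this
package stores their published summaries as metadata only.

## Diagnostics

* **Track screening** aggregates success per track and flags rates at or
  below chance + margin (default margin 0.05, catching "approximately at
  chance" rates like 52% against the 50% floor).
* **Yen's Q1** groups persons into 10 near-equal ability groups by EAP
  estimate (stable sort for ties; empty groups collapse), sums squared
  standardised gaps between observed and expected group success rates, and
  takes p-values from the rank of the observed statistic among 500
  parametric-bootstrap replicates (abilities redrawn N(0, 1), EAP scoring
  re-run per replicate), Bonferroni-corrected across items. The exact
  denominator convention of the original is referenced to external work
  without a formula; the standard (O−E)²/(E(1−E)) group form is used.
* **Two/three-way margins** compare each item pair's / triplet's joint
  response-pattern counts with model-implied probabilities integrated over
  the prior; a combination is flagged when its squared standardised
  residual exceeds 4 (a two-sigma stand-in for the unpublished flagging
  criterion; the threshold is a parameter). For n items the totals are
  exactly C(n,2)·4 and C(n,3)·8.
* **Modified parallel analysis** builds the tetrachoric correlation matrix
  (pairwise ML: thresholds from the margins, latent correlation optimised
  against the 2×2 multinomial likelihood, 0.5 continuity correction for
  empty cells — the estimation method is declared, not published), takes
  its second eigenvalue and compares it with the eigenvalues of datasets
  simulated from the fitted unidimensional model; p is the rank-based
  upper-tail proportion, so it lives in [1/(n_mc+1), 1].

## Stimulus processing

Beat consensus from drummer tap takes: apply each take's latency
correction, pick per drummer the two takes with the closest mean inter-tap
interval, pair onsets by nearest neighbour within half a period (robust to
a missing first/last tap), average beat-wise within and then across
drummers. "Phase difference" is defined here as 2π × the mean signed onset
discrepancy divided by the mean period — thresholds are published in
radians without a formula, and this definition reproduces the stated
conversions (0.6 rad = 9.5% of a beat, 0.7 rad = 11.1%). Screening applies
to the selected take pair before cross-drummer averaging. Lure schedules
displace each beat by P times the local inter-beat interval (the following
interval; the last beat reuses the preceding one). Beeps render as 20 ms,
1 kHz sine tones with a linear 10 ms fade (the fade curve is unspecified in
the source; linear is the declared choice), peak-normalised, at 44.1 kHz
mono; trials concatenate the two versions around 2 s of silence. Mixing
with copyrighted music excerpts and manual salience adjustment are out of
scope — the renderer emits the beep track alone.

## Synthetic data

The generators emulate the study designs: complete Bernoulli response
matrices under the model with θ ~ N(0, 1); balanced adaptively-missing
matrices where each person answers each track once and each accuracy level
once through a seeded random bijection; tap takes as true beats (optionally
tempo-drifting) plus a per-drummer constant motor offset and Gaussian
per-tap jitter. Default sizes mirror the original designs (27 items,
200–300 persons) so recovery tolerances are meaningful at desk scale.
What the generators do **not** emulate: real audio, masking and salience
effects, attention lapses, listening-condition shifts between sessions, and
heavy low-ability tails — so green tests certify the algorithms under the
model's own assumptions, not robustness to the ways real data violate
them.

The reliability experiment draws its default validation cohort from the
standard normal rather than from empirical ability estimates (which are
not available); this is justified by the model's population assumption.
Each participant takes two independent adaptive sessions (independent
response draws, tie-breaks and stimulus orders, all derived from one
master seed via spawned seed sequences); mean WL SE and between-session
Pearson r are reported per test length with percentile-bootstrap bands
over participants (default 1,000 resamples). With 500 participants the
simulation reproduces a mean SE near 0.67 after 25 items, near 0.88 after
15, and a test-retest r near 0.67; the analytic cross-check r ≈
1/(1 + SE²) holds to within Monte-Carlo noise. Problem sizes in the test
suite (60-participant curves, 40-person margins matrices, 40-replicate
consistency checks) were chosen as the smallest designs at which the
statistical assertions are stable across seeds.

## Known limitations

Difficulty prediction ignores track effects entirely, inheriting the
calibration's decision; predicted difficulties top out near 1.82, so very
high abilities are measured with elevated SE (and very low abilities hit
the bank floor at −2.35). The explanatory SEs neglect the a–B covariance.
The margins criterion and the Q1 denominator are declared stand-ins for
unpublished formulas. No exposure control beyond track exclusion, and only
fixed-length termination, are implemented.
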