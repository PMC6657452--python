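# Methods

`catqol` simulates and evaluates a multi-domain quality-of-life (QoL)
assessment delivered two ways — a computerized adaptive test (CAT) and a
fixed-length questionnaire — crossed with three feedback conditions
(none, graphical, graphical + tailored text), and implements the ordinal
statistics used to compare the resulting user-experience ratings. This
note records the models, the defaults and why, and what the synthetic
generators do and do not emulate.

## Measurement model

Items are polytomous and follow the partial credit model (PCM), the
Rasch-family model for ordered categories. An item with categories
`0..m` has step thresholds `b_1..b_m` on the same logit scale as the
latent trait θ:

    P(X = k | θ) ∝ exp( Σ_{j≤k} (θ − b_j) ),    empty sum for k = 0.

Consequences used throughout: the expected score `E[X|θ]` is strictly
increasing in θ; Fisher information equals `Var(X|θ)` and also
`dE[X]/dθ` (observed and expected information coincide in the Rasch
family); the joint log-likelihood of independent item responses is
strictly concave in θ.

**Trait estimation.** Maximum likelihood over a bounded interval,
θ ∈ [−4, 4] logits, via 1-D bounded maximisation with tolerance 1e-6
(concavity makes the maximiser unique; the "break ties toward 0" rule
is therefore vacuous in practice but documents intent for degenerate
float plateaus). All-minimum and all-maximum response patterns have an
infinite MLE; they are clamped to the bound with `converged=False`.
Clamping keeps the standard error finite so scoring and feedback remain
computable for extreme respondents. `SE = 1/√(Σ item informations)` at
the estimate, `+inf` when total information is zero. Item calibration is
out of scope: banks are inputs.

## Adaptive engine

Per domain, the loop is: initialise θ at 0 (the population mean; no
prior information exists at session start), select the unadministered
item with maximum Fisher information at the provisional θ (ties broken
by lexicographic item id for determinism), administer, re-estimate, and
stop at the first of

1. `SE < se_stop` after at least `min_items_per_domain` items
   (defaults 0.45 logits and 2 — the SE is undefined before any
   response and unstable after one);
2. bank exhausted (if the last estimate already satisfies rule 1 the
   session is labelled `se_reached`, keeping the stop label and the
   final SE mutually consistent);
3. an optional per-domain item cap.

`se_stop = 0.45` corresponds to marginal reliability ≈ 0.80 under a
unit-variance trait. The stopping rule is applied per domain and the
four domain sessions run independently; reported item counts are the
sum over domains. Maximum-information selection is the standard CAT
criterion; no exposure control or content balancing is modelled.

**0–100 reporting scale.** `z = (θ − norm_mean)/norm_sd` against
configurable per-domain reference-population norms (the package default
is the simulation truth, mean 0 / SD 1), then
`score = clip(50 + (100/6)·z, 0, 100)`, so ±3 reference SD spans the
scale and 50 is the population mean. The mapping is linear and
configurable; only the 0 (worst) .. 100 (best) endpoints are
contractual.

## Fixed-length scoring

BREF-style: negatively worded items are recoded `x → k+1−x` on their
`1..k` scale, a domain score is the mean of non-missing items rescaled
linearly to 0–100 (`(mean−1)/(k−1)·100`). A domain with more than 20%
of items missing is reported missing, never imputed. The 4–20
intermediate used by published scoring syntaxes is the same linear map
composed differently and is exposed as an extra column for parity.

## Feedback

Deterministic per condition: `none` → empty bundle; `graphical` → one
0–100 bar per domain; `graphical_text` → bars plus a per-domain message
chosen by banding the score against the population mean on the 0–100
scale. Bands are ±5 points, boundary-inclusive into "average" — the
band geometry is configurable since only the qualitative
lower/average/higher structure is contractual. Every message
interpolates the numeric score and domain name; rendering is a pure
function (byte-identical output for identical input). Charts are
emitted as data (JSON bars) with an optional matplotlib rendering;
geolocated support links are replaced by static per-(domain, band)
configuration.

## Ordinal statistics

All implemented from first principles and cross-checked in the test
suite against independent oracles.

* **Cliff's delta** `d = (#{x>y} − #{x<y})/(n_x n_y)`, computed exactly
  from the dominance matrix. 95% CI: Cliff's consistent variance
  estimator with the normal quantile, truncated to [−1, 1]. The
  estimator's calibration is itself verified by simulation (empirical
  sampling SD vs mean estimated SE).
* **Wilcoxon rank-sum**, two-sided, unpaired. Pooled n ≤ 20: exact —
  the rank-sum null is enumerated over all splits of the pooled
  multiset with midranks, so ties are handled by construction. Above
  20: tie-corrected normal approximation with continuity correction.
  Likert data are tie-heavy, which is why the tie-corrected form is the
  default rather than the classical no-ties variance. An all-constant
  pooled sample yields P = 1 with a warning.
* **Evidence convention**: P < .005 "significant", .005 ≤ P < .05
  "suggestive", else null; boundaries strict. No further
  multiple-testing adjustment is applied.
* **Loevinger's H** for polytomous items via weighted Guttman errors:
  item-step popularities order the pooled steps of a pair; a response
  cell's weight is its number of inverted step pairs (a less popular
  step passed while a more popular one is failed); `H_ij = 1 − F/E`
  with F the weighted observed errors and E their expectation under
  independence given the marginals. Item and scale H are the
  corresponding error-sum ratios. This is algebraically the
  covariance / maximum-covariance formulation (comonotone coupling of
  the marginals), and the tests verify that equivalence directly. Step
  popularity ties are broken deterministically (item index, then step);
  pairs with zero expected errors are excluded with a warning. The
  automated item selection procedure (AISP) is the greedy variant:
  seed with the best pair at the lower bound (.3), grow by the item
  that maximises scale H while all within-scale item coefficients stay
  above the bound. The Z-based significance screen of the full
  procedure is omitted — at this package's sample sizes (n ≥ ~200) it
  never binds, and omitting it keeps the selection deterministic.
  Scale classification: weak < .3, strong > .5, medium between
  (boundaries assigned to the middle class).
* **Cronbach's alpha** `k/(k−1)·(1 − Σvar_i/var_total)` with n−1
  variances; zero total variance raises.

## Synthetic generators

The generators are pure functions of (config, seed) and define the
study conditions; their defaults are not tuning knobs.

**Item banks.** Per domain (physical, psychological, social,
environment), 25 six-category items whose centers span [−2, 2] logits
with step offsets ±1.3, ±0.65, 0 plus N(0, 0.15²) jitter. A single
`dispersion` scalar multiplies center spread and jitter (0 → identical
items). These defaults were chosen so that the SE < 0.45 rule ends
adaptive sessions after roughly 4–5 items per domain — about 18 of the
96-item fixed-length-equivalent total across four domains, i.e. a
~25% reduction against a 24-item fixed comparator, the regime the
package is meant to study.

**Respondents.** θ ~ N(0,1) per domain, independently across domains
(real QoL domains correlate; see limitations), responses sampled from
the PCM.

**Acceptability surveys.** Each respondent carries a shared normal
"favourability" latent (SD 1.7); each of the four 0–4 Likert items
discretizes latent + unit-logistic noise at fixed cutpoints
(−4.1, −2.8, −1.3, 0.95). The shared latent induces inter-item
correlation (Cronbach alpha ≈ 0.75, scale H ≈ 0.4 at the defaults, a
coherent single scale); the cutpoints put the response mass toward the
agree end (control-arm total mean ≈ 11.5 of 16), matching the skew
toward positive ratings that acceptability items show in practice.
Between-condition effects are pure location shifts of the latent. The
population distribution of the 0–16 total is computed exactly —
Gauss-Hermite quadrature (61 nodes) over the shared latent and 4-fold
convolution of the conditional item pmf — so each arm's shift is
calibrated by bracketing root-find until the *population* Cliff delta
versus the control arm equals its target to ~1e-10 (the delta is
strictly increasing in the shift; unattainable targets raise an error
reporting the achievable range). Default targets: per-arm deltas 0.09
(fixed/graphical), −0.11 (cat/none), 0.01 (cat/graphical) versus the
fixed/no-feedback control, and a single shared shift for both
graphical+text arms calibrated so the *pooled* graphical+text versus
pooled no-feedback population delta is 0.22.

Attention-check failures are Bernoulli at 68/1454 per respondent; arm
enrollment is the target analyzed size (226, 247, 219, 223, 211, 260)
inflated by 1/(1−rate), so ~1454 enroll and ~1386 survive the filter in
expectation, with binomial jitter. Feedback-viewing seconds are
log-normal with per-arm medians 115/132/124/147 s and log-SD 0.55
(right-skewed, as viewing-time data are); absent in no-feedback arms.
Appraisal items (graphical/text accuracy and clarity) are drawn from
fixed categorical distributions with ~82–95% agreement. Demographics
(age, gender, working status) are sampled from fixed marginals and are
descriptive only.

**What passing tests do not show.** The generator emulates location-
shifted, positively-massed ordinal ratings with an exchangeable
correlation structure. Real survey data have item-specific difficulty
and discrimination, respondent styles (straight-lining, extreme
responding), missingness, and correlated QoL domains — none modelled.
Recovery of a calibrated delta here demonstrates the estimator and
pipeline are correct, not that any real feedback effect has that size.

## Pipeline and report

`run_study`: generate surveys → drop flagged respondents → simulate the
adaptive assessment for CAT-arm respondents (PCM responder at the true
trait) and the 24-item fixed form for the others → render feedback for
feedback arms → compute the report: arm-vs-control effect tables
(total + 4 items), pooled contrasts (graphical+text vs none, graphical
vs none, CAT vs fixed), scale H and alpha, appraisal distributions,
viewing-time medians with effects versus the fixed/graphical reference
arm, and the CAT item-count reduction `(24 − mean items)/24`. Rounding
follows reporting convention: means/SDs and deltas to 2 decimals,
percentages to 1. All randomness flows from one seed through
`SeedSequence` spawns; repeat runs are byte-identical.

## Problem sizes

Defaults run the full study scale (1454 enrolled; ~690 adaptive
respondents × 4 domains) in ~10 s. The test suite uses reduced sizes
chosen to keep each check sharp but quick: 500 simulated respondents
for adaptive-engine behaviour, 200 random instances per oracle-
equivalence check, 50 survey replicates for delta recovery, 200
replicates for null calibration (analysis stage only, since the null
property concerns the survey comparisons, not the assessment
simulation). `scripts/acceptance.py` reruns everything from scratch at
these sizes in well under a minute.

## Known limitations

* Estimation bounds, extreme-pattern handling and the 0–100 mapping are
  package choices; original adaptive QoL instruments do not publish
  theirs, so cross-instrument score comparability is not claimed.
* Domain traits are generated independently; multidimensional item
  selection is out of scope.
* The greedy AISP can differ from the genetic-search variant on items
  near the lower bound.
* Cliff CI uses the symmetric normal form; near |δ|≈1 the asymmetric
  transform would be preferable.
* The fixed-form simulation uses one common step structure for all
  items rather than item-specific calibrations.
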