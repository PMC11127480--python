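# Methods

`screenpp` implements the censor-and-weight approach to per-protocol effects
of sustained screening strategies in administrative claims, with a synthetic
claims generator whose known parameters provide a computable counterfactual
truth. This note records the model, the conventions, and the design choices
that were genuinely open.

## Time, data model, and cohort rules

All person time is measured in integer months since the beneficiary's 50th
birthday; negative months are pre-50 history. The simulation step is one
month; the analysis discretizes follow-up into 3-month age bins, bin *t*
covering months [3t, 3t+3), i.e. ages [50 + t/4, 50 + (t+1)/4), with t = 0
... 59 and an administrative end at month 180 (age 65).

Cohort construction follows the standard claims workflow:

- **Eligibility**: the earliest maximal contiguous full-benefit, non-dual
  enrollment period covering strictly more than 6 months (back-to-back spans
  merge). **Baseline** is the later of month 0 and eligibility start + 6
  months, so at least 6 months of claims history precede every baseline.
- **Diagnoses**: HIV and colon cancer require 1 inpatient claim or 2
  outpatient claims at most 24 months apart (inclusive; the diagnosis month
  is the first claim of the qualifying pair — the usual claims-algorithm
  convention); all other conditions require a single claim. A colon cancer
  with an anal-cancer claim within ±3 months (inclusive, either order) is
  reclassified as other cancer at the colon diagnosis month; ties between
  cancer types go to colon cancer.
- **Exclusions**, in fixed order: no qualifying span; baseline at or after
  span end; age ≥ 65 at baseline; any cancer-related claim at or before
  baseline; any endoscopy before age 50. Claims at month ≤ baseline count as
  history, which keeps baseline strictly before follow-up end.
- **Follow-up** ends at the first of colon cancer, other cancer, death,
  disenrollment (span end), administrative end, with tie precedence in that
  order. Exposure (HIV) is fixed at baseline.
- Unexposed **controls** can be down-sampled (simple random sample, floor of
  the fraction, exposed always kept), mirroring the 25% control design of
  claims studies at this scale.

## Screening protocols and adherence censoring

An endoscopy claim is a *screening* if it is the first observed or falls more
than `washout_months` (default 12, sensitivity 6) after the last observed
endoscopy of any kind; closer repeats are treated as diagnostic/follow-up
procedures. Pre-baseline (post-50) screenings advance the protocol clock.

A protocol of cadence *k* years (K = 12k months) with bandwidth *b* (default
3) censors follow-up at the earliest of:

- **(a) too late** — more than K + b months have elapsed since the last
  screening (or since baseline, for the first screening, with a configurable
  initiation grace defaulting to K + b) without a new one; the deviation
  month is `anchor + K + b + 1`, clamped to baseline + 1 when a stale
  pre-baseline clock would otherwise predate follow-up;
- **(b) too soon** — a screening arrives less than K − b months after the
  *previous screening* (the first screening is exempt: baseline is not an
  endoscopy).

Within a 3-month bin, events take precedence over censoring (censoring
mid-bin would discard an observed outcome), and among censoring types
disenrollment > protocol > administrative. The month-to-bin map is
t = ⌊month/3⌋.

## Estimator

For each exposure group, cause-specific discrete hazards per bin are weighted
event counts over weighted risk sets (delayed entry: a beneficiary
contributes only from their baseline bin, under the assumption that entrants
at different ages are exchangeable at shared ages). The discrete
Aalen–Johansen product-sum combines them:

    S(t) = Π_{s≤t} (1 − h_c(s) − h_d(s)),
    CIF_c(t) = Σ_{s≤t} S(s−1) h_c(s),  CIF_d analogous,

so CIF_c + CIF_d + S = 1 identically. Risks are conditional on being alive
and cancer-free at cohort entry. Contrasts are RD = CIF_c^exposed −
CIF_c^unexposed and RR = ratio (reported as missing where the reference risk
is 0), tabulated at ages 55/60/65. Empty risk sets yield zero hazards with a
logged gap flag.

## Weights

Three stabilized components multiply:

- **Exposure**: P̂(own group) / P̂(own group | race/ethnicity, sex, state,
  period) from a logistic model on the analysis sample.
- **Adherence** and **disenrollment** censoring: pooled per-interval logistic
  models of being censored by that type among at-risk rows, fit separately
  within exposure group; denominators use the baseline covariates plus
  time-updated comorbidity category (0/1/≥2, entered as two indicators) plus
  time; numerators use time only. Time enters as a restricted quadratic in
  t/60 by default (a coarse categorical option exists; at these scales the
  two were indistinguishable). The cumulative weight at t is the product of
  per-interval ratios through t. Strata with no censoring events of a type
  get constant-1 weights with a logged warning.
- **Truncation**: combined weights are capped at the 99.5th percentile by
  default (configurable; 100 disables). The truncation report records the
  cut point and count.

Nuisance logistic models are fit by an in-package Newton–Raphson solver with
step halving (unpenalized MLE; cross-checked against standard GLM software to
1e-8 in the tests). The solver exists because bootstrap resampling refits
thousands of such models; it raises a named-covariate error on suspected
separation (|coefficient| > 30) or non-convergence.

Confidence bands are nonparametric percentile bootstrap over beneficiaries
(not person-intervals), default 200 replicates, deterministic given a seed;
replicate failures are logged and skipped, with more than 20% failures an
error. Warm starts for replicate fits come only from the full-data fit, so
repeated calls are bit-identical.

## Synthetic claims generator

The generator emulates the data features that make this design hard:

- baseline confounding of HIV by sex, race/ethnicity, state and calendar
  period (logistic model; prevalence ≈ 5%, enrolled-before-50 fractions 0.38
  / 0.15 by HIV status, baseline-age median ≈ 56y);
- **comorbidity as an age process**: conditions accrue from age 45 at a
  constant monthly rate (HIV multiplies it) *independently of coverage*;
  conditions present at entry are revealed by claims at the entry month,
  later gains by claims at the gain month. Running comorbidity on age rather
  than on enrollment time makes the age-exchangeability assumption of the
  estimator hold exactly: the comorbidity mix at a given age does not depend
  on when the beneficiary entered. (With accrual tied to enrollment time,
  risk sets dominated by recent entrants are systematically healthier than
  any no-censoring population at the same age — a composition difference no
  covariate weight can undo. The same phenomenon is a caveat for real claims
  data, where measured comorbidity does accumulate with observation time.)
- behavioural endoscopy uptake: a monthly logistic hazard rising with months
  since the last endoscopy (a "due for screening" ramp), higher with
  comorbidity and HIV, plus short-gap diagnostic repeats that the washout
  rule must discard;
- cancer, death and disenrollment as monthly hazards with age trends and
  multiplicative covariate effects; death competes; other cancers censor;
  disenrollment is informative through comorbidity, sex and race/ethnicity.
  Past screenings multiply the colon-cancer hazard by θ per screening
  (default 0.85, capped at 5; repeats within the washout confer no extra
  protection);
- a claim-emission layer: diagnoses emit 1 inpatient claim or an outpatient
  pair (probability 0.35 inpatient; confirmation one month later), extra
  outpatient repeats, spurious lone outpatient claims in disease-free people
  (at most one per person per category, so they can never satisfy the
  two-claim rule), anal-cancer claims accompanying colon claims at 0–6 month
  offsets (some inside, some outside the reclassification window), and
  death claims that end the enrollment span. Events run only while enrolled
  and aged ≥ 50.

Disenrollment defaults to 1.5%/month (median enrollment ≈ 4–5 years) — a
moderated churn chosen so that late-age risk sets remain informative; real
Medicaid churn can be substantially faster.

## Counterfactual truth

`true_counterfactual_risk` computes the estimand the weighted pipeline
targets, by Monte Carlo: the same population process (entry model, delayed
entry, comorbidity ageing, death as competing event, other cancers
censoring), with disenrollment disabled and adherence enforced — behavioural
screening uptake runs, screenings that would come sooner than K − b months
after the previous one are suppressed, and a screening is forced at the last
allowed month so nobody deviates. This grace-period regime, not a rigid
fixed calendar, is what censor-and-weight estimates: adherent beneficiaries
screen at natural times inside the allowed window. Outcomes pass through the
same claims-diagnosis layer as the analysis (the estimand is *diagnosed*
colon cancer, so emission misses and the anal reclassification apply in both
worlds). Covariates are drawn from their marginal law and reweighted by
P(HIV = a | X) to obtain the exposure group's covariate mix without
rejection sampling. Monte-Carlo error shrinks as 1/√n_sim.

## Validation experiment design

- **Oracle equivalence** uses a 200-person cohort with entry fixed at
  baseline because the external Aalen–Johansen reference does not support
  left truncation; delayed entry is validated separately against a direct
  risk-set walk.
- **Truth recovery** (100,000 beneficiaries, 10-year protocol, untruncated
  weights) sets θ = 1 (screening causally inert) while keeping comorbidity →
  endoscopy/cancer/death confounding and informative disenrollment. With
  θ < 1 and delayed entry, adherent risk sets at older ages are dominated by
  recent entrants with short screening histories, while the no-censoring
  counterfactual population carries full histories; this screening-history
  selection is invisible to covariate-based weights and is a real limitation
  of the estimator class (it can even make the estimated risk under a
  2-year protocol exceed that under a 10-year protocol while the true
  ordering is the reverse). θ = 1 switches that channel off so the
  experiment measures exactly what weighting can and should fix.
- **Null coverage** (50 cohorts of 5,000, 100 bootstrap replicates) must
  first be a genuine null: besides the direct hazard effects, the indirect
  path exposure → comorbidity accrual → cancer/death has to be severed, or
  the "null" RD is truly nonzero and band coverage correctly drops as
  information grows. The experiment also uses a balanced exposure mix and a
  cancer hazard high enough for events in both arms by age 55: with a
  realistic 5% prevalence and incidence at that cohort size an arm often has
  no events, the RD bands collapse to a point, and interval coverage is
  degenerate rather than wrong (a known failure mode of percentile
  bootstrap with very sparse events).
- The 10-year (average-risk) cadence is the default protocol for the
  large-sample checks because its risk sets are largest; the 2-year protocol
  exercises the boundary rules in the oracle tests.

## Numerical choices and degenerate inputs

- Inclusive windows throughout (≤ 24 months; ±3 months): the conservative
  reading at month resolution.
- Hazards in empty bins are 0 (flagged), which keeps curves defined when
  risk sets run out.
- `argmin` tie-breaking implements the event-precedence order directly.
- Weight products are computed as segmented exponential sums of logs.
- Bootstrap bands ignore NaN risk ratios (reference risk still 0) bin-wise.
- Generator validation rejects probabilities outside [0,1], hazards outside
  [0,1), θ outside (0,1], naming the offending field.

## Known limitations

- Within-bin censoring dilutes hazards slightly: a beneficiary censored
  mid-bin counts as at risk for the whole 3-month bin (~1–2% relative on
  hazards at the default churn). Any discrete-time estimator built on
  person-interval tables shares this.
- Percentile bootstrap intervals are unreliable when an arm has ≲ 2 events.
- The weights correct selection only through measured covariates; screening-
  history selection under delayed entry (θ < 1) and disenrollment-driven
  diagnosis misses are quantified in the tests but not correctable by design.
- The generator abstracts real coding systems to categorical claim labels
  and omits state policy differences, billing detail, and claim-quality
  artifacts beyond spurious singletons.
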