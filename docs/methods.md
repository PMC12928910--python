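# Methods

`paintrial` implements the complete endpoint-derivation and analysis
machinery of a three-arm, placebo-controlled acute-pain trial on the
bunionectomy model, together with a synthetic trial generator so the whole
pipeline can be exercised and verified without patient data. This note
records the models, conventions and numerical choices the package makes,
and what the synthetic data do and do not establish about real trials.

## The trial design being modelled

Subjects undergoing unilateral first-metatarsal bunionectomy are randomized
1:1:1 to a high dose, a low dose, or placebo, in permuted blocks of six
stratified by study site (eight sites by default). Pain is self-reported on
the 11-point numeric pain rating scale (NPRS, 0–10) at twenty nominal hours
from end of surgery (0, 1, 2, 3, 4, 6, 8, 10, 12, 16, 20, 24, 30, 36, 42,
48, 54, 60, 66, 72), each collected within ±10 minutes. Rescue analgesia is
intravenous acetaminophen 1 g q6h PRN (≤4 g/24 h), with tramadol 50 mg q4h
PRN (≤300 mg/24 h) for subjects who cannot take or do not respond to
acetaminophen. The primary endpoint is summed pain intensity through 48 h
(SPI48), the area under the NPRS-versus-time curve by the trapezoidal rule;
the key secondary endpoint is SPI48 for the low dose, protected by serial
(fixed-sequence) gatekeeping at two-sided α = 0.05.

## Endpoint derivation

**Windowing.** Each NPRS record is assigned to at most one nominal hour.
The window for nominal `t_k` is the half-open interval
`(t_k − (t_k − t_{k−1})/2, t_k + (t_{k+1} − t_k)/2]`, with the first window
starting at 0 and the last ending at 72. If several records fall in one
window the one closest in absolute time wins; an exact tie keeps the
earlier record (a stable, time-ordered rule; only the midpoint rule itself
is forced by the design). Pre-operative (`pre_dose`) records are excluded —
the efficacy clock starts at end of surgery.

**Rescue windows.** Every acetaminophen dose opens a 6-h window, every
tramadol dose a 4-h window. A dose given strictly before the previous
window closes chains with it; the merged window ends at the maximum member
end. All nominal values inside a window are replaced by the score recorded
immediately before the earliest dose of the chain, *overriding* observed
values (post-rescue scores reflect the rescue drug, not the study drug).
Using the earliest chain member's pre-dose score for the whole merged
window is the conservative choice; per-segment carry scores would use
later, typically lower, pre-dose values.

**Imputation rule order.** Rules apply deterministically in this order,
chosen so that rescue masking is neutralized before any carry rule runs:

1. rescue-window replacement (above);
2. worst-observation-carried-forward (WOCF) from the time of an adverse-
   event or lack-of-efficacy discontinuation onward (off-protocol rescue is
   handled as lack of efficacy), where "worst" is the maximum genuinely
   recorded value — observed or rescue-carried — up to the event time;
3. leading missing values (e.g. a subject not yet awake at hour 0) take the
   median of observed same-arm scores at that timepoint (even-count medians
   average the middle pair; fractional values are allowed);
4. last-observation-carried-forward for remaining gaps — except cells after
   an other-cause withdrawal, which are flagged for multiple imputation.

Restricting WOCF maxima and arm medians to genuinely recorded cells makes
the whole rule set idempotent: re-running imputation on its own output is a
no-op, which the test suite asserts on full simulated trials. A subject
with no usable observations at all (e.g. randomized but never operated)
receives the arm median profile; such subjects stay in the ITT analysis by
design.

**Multiple imputation.** Flagged cells are imputed 20 times by arm-wise
sequential (monotone) regression of each timepoint on up to three preceding
timepoints, with residual variance drawn from its scaled inverse-chi-square
posterior, coefficients from their normal posterior, predictive noise
added, and draws clamped to [0, 10]. The analysis value of a flagged cell
is the across-imputation mean (matching the "mean of the 20 imputed data
sets" convention); Rubin's-rules pooling of endpoint-level estimates is
available via `paintrial.inference.pool_rubin` for sensitivity use. The
degenerate case (donors with zero residual variance) imputes the donor mean
with no noise. At least two complete donors per arm are required.

**SPI/AUC.** The trapezoid runs over the union of actual-time observed
points (all efficacy records, regardless of windowing, with the rescue and
WOCF replacements applied) and imputed nominal points placed at their
nominal hours. Because collections jitter within minutes of the boundary
hours, the curve is extended flat across end gaps of at most 0.5 h; larger
gaps are an error. The implementation agrees with an independent fine-grid
midpoint-Riemann oracle to better than 1e-6 relative error over 1000 random
piecewise-linear series, is additive over subintervals, and is monotone in
the endpoint hour.

**Consumption and time to rescue.** Drug totals are summed over half-open
intervals `[start, end)`; tramadol is additionally expressed in morphine
equivalents at a configurable factor (default 0.1, i.e. 50 mg tramadol ≙
5 mg MEQ — the conversion is conventional, not dictated by the design).
Time to first rescue is the earliest dose time; subjects with no use, or
first use after 72 h, are censored at 72 h, and subjects without surgery
are excluded.

**Populations.** ITT = all randomized; mITT = dosed with at least one
post-surgery NPRS; PPS = mITT without major protocol deviations (nesting
PPS ⊆ mITT ⊆ ITT holds by construction); observed-data ITT re-analyzes ITT
under minimal imputation (rescue windows plus grid completion, no
WOCF/MI).

## Statistical inference

Each pairwise contrast fits a separate linear model on the two arms' data
only, with treatment and site as fixed effects. Least-squares means average
the cell predictions with *equal weight* over site levels (the classic
unweighted-margins convention; the design does not state its weighting),
so with a single site the LSMs reduce exactly to raw arm means and the
contrast p value to the pooled-variance two-sample t-test — an identity the
tests assert to machine precision. CIs and p values use the t distribution
on the residual degrees of freedom. Sites represented in only one arm are
dropped with a warning (configurable to an error).

Serial gatekeeping tests the primary hypothesis at full α and the key
secondary only upon primary success; its truth table is exhaustively
tested, and a 5000-replicate three-arm null simulation confirms the
family-wise error stays within two Monte-Carlo standard errors of α.

Time to first rescue uses Kaplan–Meier curves with median and quartiles
(non-estimable quartiles reported as NaN) and a Cox proportional-hazards
model with a single treatment indicator and Efron tie handling, fitted per
active arm versus placebo; the partial-likelihood maximum matches a
brute-force grid oracle on a six-subject fixture to 1e-4. Rescue-user risk
differences per day window use the Newcombe hybrid-score CI (bounded and
well behaved at extreme proportions) and a Pearson chi-square p value.
Patient-global-assessment categories are coded poor = 0 … excellent = 4 by
default; the origin is configurable since only a coding-relative mean is
recoverable.

## Synthetic trial generator

The generator reproduces the statistical structure the analysis assumes;
its defaults are calibrated to the published arm-level summaries of the
bunionectomy setting.

- **Latent pain.** Each arm has a log-normal-shaped mean trajectory
  `peak · exp(−(ln(t/t_peak))²/(2w²))`: zero at hour 0 (regional block),
  peaking around 5 h, decaying slowly. Defaults: placebo peak 7.2 NPRS
  (w = 2.35, t_peak 5.5 h), low dose 4.6 (w = 1.85), high dose 3.8
  (w = 1.7), giving placebo/low/high SPI48 means near 273/165/132
  score-hours. Subjects add a normal random intercept (SD 2.0), sites a
  normal effect (SD 0.25), observations normal noise (SD 1.0); scores are
  rounded half-up and clamped to 0–10.
- **Rescue decisions.** A per-hour hazard
  `0.06 · exp(0.75·(pain − 4) − 0.012·t)` (active while current pain > 0)
  is evaluated at scheduled hours and interval midpoints. A dose masks 2.5
  NPRS points of pain for the drug window, which feeds back into later
  hazard and observed scores. The drug is acetaminophen unless its gap/cap
  rules block it (or the subject is one of the 8% acetaminophen-intolerant,
  who receive tramadol); if neither drug is available while pain is at or
  above threshold, the subject discontinues for lack of efficacy with
  probability 0.35 per blocked attempt. Generated data never violate the
  dosing caps (asserted by scan). Under these defaults ≈94% of placebo
  subjects use rescue within 72 h versus ≈56% (high dose), with median
  first-use times near 3/10/30 h for placebo/low/high — in the region of
  the published 4.0/12.2/31.5 h and rescue-free fractions 2.7/33.6/42.8%.
- **Intercurrent events.** AE discontinuations use per-arm rates
  3.3/2.0/0.7%, other-cause withdrawals 2%, off-protocol rescue 0.7%,
  missed surgery 0.9%, never-dosed 0.5%; event times are uniform, and
  follow-up truncates at the event. Ten percent of hour-0 assessments are
  missing (anesthesia recovery) plus 1% sporadic missingness.
- **Secondary scales.** PGA and SIS are driven by the subject's mean latent
  pain over the preceding 24 h with ordinal/rounded noise; the nausea scale
  is a low-level nuisance with no arm effect.
- **Seeding.** One master seed; each subject draws from an independent
  substream keyed by subject index, so enlarging a trial never perturbs
  existing subjects, and the whole pipeline is byte-reproducible.

What the generator does *not* emulate: pharmacokinetics, site-level
operational differences beyond an additive effect, adverse-event taxonomy,
correlated dropout (events are independent of the pain path except for
lack-of-efficacy), or the discreteness artifacts of real e-diary data.
Passing tests therefore establish the *internal* correctness and operating
characteristics of the machinery under a realistic data-generating process,
not the clinical conclusions of any particular trial.

## Operating characteristics

`power_closed_form` evaluates two-sample t-test power. The exact
noncentral-t value at the design point (d = 0.4, n = 130/group, two-sided
α = 0.05) is 0.8949; the large-sample normal approximation underlying the
classic sample-size formula gives 0.8971, which is the figure that rounds
to the conventional "90% power" design statement. Both are exposed
(`exact=True/False`) and documented because Monte-Carlo simulation of the
actual t-test converges to the exact value, not the approximation.

`simulate_power` estimates power either from plain two-group normal draws
(vectorized, used for the 20,000-replicate agreement check with the closed
form) or by running the full generate → derive → gatekept-ANCOVA pipeline
per replicate. `simulate_null_fwer` drives the real gatekeeping rule with
three identical arms. `recovery_report` measures bias, RMSE and 95%-CI
coverage of the primary LSMD, the high-dose log hazard ratio and the day-1
risk difference across replicate trials; because rounding, clamping and
rescue-carry make the population values analytically intractable, truth is
estimated once from a single very large trial (20,000 subjects per arm,
Monte-Carlo error ≈1 score-hour on the LSMD against a CI half-width of
≈20). Replicate seeds derive from the master seed via a counter stream.

Problem sizes used by the shipped checks — 500 replicate trials at 150 per
arm for coverage, 5,000 replicates for the null error rate, 20,000 for
power agreement, and a 20,000-per-arm truth run — were chosen so each check
resolves its tolerance comfortably on a single CPU.

## Known limitations

- The trial's exact LSMD confidence intervals are narrower than independent
  pooling of the published per-arm SEs would suggest; the variance
  expression used there is not recoverable, so the package reports standard
  model-based CIs.
- The carry score for chained rescue windows, the boundary convention of
  WOCF at the event instant (applied at, not strictly after, the event
  hour), and the MEQ factor are conventions the design leaves open; all are
  configurable or documented above.
- Sequential multiple imputation over long monotone gaps accumulates
  prediction drift and a small positive bias near the scale floor (clamped
  draws); one-step-ahead recovery is accurate to well under 0.3 NPRS in the
  shipped checks.
- The generator's rescue-hazard model is a parsimonious two-parameter
  exponential form; it reproduces first-use medians and rescue-free
  fractions only approximately (placebo rescue-free ≈6% versus the
  published 2.7%).
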