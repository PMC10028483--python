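# Methods

This note documents the models, rules, and numerical choices behind
`pnukit`, and what the synthetic validation studies do and do not show.

## Design overview

The package implements an active-comparator, prevalent new-user cohort
analysis of incident osteoarthritis (OA) under metformin versus
sulfonylurea, in five stages: claims simulation, cohort construction,
comorbidity scoring, matching, and survival analysis. Time is integer
days since 1970-01-01; every interval is half-open `[start, end)`, which
makes gap and duration arithmetic exact.

## Cohort construction

**Phenotypes.** Type 2 diabetes and OA both use a two-code rule: two
family codes separated by ≥ 14 days (boundary inclusive). The phenotype
date is the first code of the earliest qualifying pair — for a sorted
code list this is the earliest code whenever the span from earliest to
latest reaches 14 days. The incident-OA date is the first qualifying
code on or after the landmark; choosing the first rather than the second
code of the pair matches the incident-diagnosis intent and the analogous
diabetes convention.

**Treatment episodes.** Coverage intervals
`[fill_date, fill_date + days_supply)` are unioned per person and drug
class; an uncovered run of ≥ 90 days splits episodes, and the treatment
stop date is the supply exhaustion that begins the gap (measuring the
gap from supply exhaustion, not from the fill date, is the stricter of
the two readings and is configurable).

**Eligibility.** Age ≥ 40 at index (computed from birth year, as claims
rarely carry full birth dates); a qualifying diabetes phenotype on or
before the index fill; ≥ 1 year of continuous enrollment — bridging
administrative gaps ≤ 30 days — covering the span from one year before
the diabetes diagnosis through the index date; no type 1 diabetes codes
in any available history; no same-day initiation of both drugs; no
combination metformin-sulfonylurea products; no OA, inflammatory
arthritis, or joint-replacement claims before day 90 after index (so a
code on day 89 excludes, one on day 90 is an outcome); and ≥ 90 covered
days in the episode beginning at index.

**Group asymmetry.** A metformin-then-sulfonylurea person contributes a
record to both groups (their sulfonylurea record flagged
`prior_metformin`); a sulfonylurea-then-metformin person contributes
only a sulfonylurea record, censored at the switch. A metformin record
is likewise censored when a sulfonylurea is started, so exposure during
follow-up always equals the group label.

**Follow-up.** From `index + 90` days (the landmark; OA within the
first 90 days is treated as likely prevalent) to the earliest of: OA
phenotype date, joint replacement, treatment stop, first non-study
antidiabetic fill, switch, disenrollment, study end. A same-day tie
between an event and a censoring cause counts as the event
(conservative for incidence). Follow-up is endpoint-specific: an OA
diagnosis does not censor the joint-replacement endpoint, which is why
joint-replacement person-time exceeds OA person-time. Months are
days/30, so the identity *follow-up = treatment duration − 3 months*
holds exactly for every record (the landmark is exactly 3 such months);
person-years are days/365.25.

## Charlson comorbidity score

The Quan ICD-9/ICD-10 category mappings with the original Charlson
weights (1/2/3/6), shipped as an editable YAML fixture
(`pnukit/data/charlson_quan.yaml`). Matching is prefix-based on
normalised codes (dots stripped, upper case), longest prefix winning;
hierarchy pairs (mild vs moderate-severe liver disease, diabetes with
vs without complication, malignancy vs metastatic tumor) count only the
severer member. Scoring uses all available history strictly before the
reference date; a 1-year window would be an easy restriction but full
history is consistent with the exclusion lookback. Note that in an
all-type-2-diabetes cohort the diabetes categories contribute to every
score; this shifts the scale by a constant-like amount and is irrelevant
to balance or adjustment.

## Time-conditional propensity-score matching

One exposure set per sulfonylurea record, in chronological order.
`delta_t` is the days from the person's first metformin fill to the
sulfonylurea index, 0 without prior metformin — the only reading that
covers both prior-metformin strata. A metformin record is a candidate
when it belongs to a different person and is still at risk (on drug,
uncensored, outcome-free) at its own offset within `delta_t ± 15` days,
i.e. its at-risk offset reaches `max(0, delta_t − 15)`. Because
candidacy reduces to that single threshold, candidate lists are
represented implicitly and materialised on demand, which keeps
instances with tens of thousands of candidates per set cheap while
remaining exactly equivalent to explicit lists.

The propensity model is the stratified conditional-logistic (softmax)
partial likelihood — one case (the sulfonylurea member) and the
candidates as controls per set — maximised by Newton iterations,
converging when the relative log-likelihood change is < 1e-8 (≤ 100
iterations); on separation or non-convergence the fit falls back to a
ridge penalty (λ = 1e-4) and is flagged. Covariates: age, sex,
race/ethnicity (reference White), Charlson score, and treatment
duration, defined as study-drug-covered days before the set anchor.
Since candidates at risk at the matched offset have, by construction,
the same covered span as the anchor, that column is within-set constant
and is dropped automatically by a within-set-variance filter — the set
structure itself absorbs treatment duration, which is exactly the
design's intent. Sets with more than `ps_max_controls_per_set` (default
50) candidates contribute a seeded random subsample to the fit;
risk-set sampling of controls leaves the conditional likelihood
consistent, and matching still searches the full candidate list using
the fitted linear predictor.

Greedy matching processes sets chronologically, takes the remaining
candidate with the smallest |score difference| (ties: earlier candidate
index date, then lower person id — determinism), removes it from all
later sets, and drops anchors with no remaining candidate (counted, not
raised). No caliper applies in the primary design, and matching is
invariant to monotone transforms of the score within sets because only
within-set order matters.

The sensitivity design restricts to persons only ever exposed to a
single study drug, follows them past treatment stop (censoring only by
disenrollment or study end), fits a plain logistic propensity model on
the same covariates (with actual treatment duration, which is
informative there), and matches greedily on the logit score with a
caliper of 0.2 × SD of the pooled logit scores; a degenerate zero-SD
caliper raises. If the plain logistic fit separates, a ridge-penalised
Newton fit (always positive-definite Hessian) supplies the scores.

**Balance.** Continuous SMD `(m1 − m2) / sqrt((s1² + s2²)/2)`;
K-level categorical covariates use the multivariate Mahalanobis
formulation over K−1 proportions, which reduces to the familiar binary
formula at K = 2. Constant covariates report 0.

## Survival analysis

Incidence rates are `1000·E/PY` (an identity held to machine precision)
with log-scale Wald 95% CIs, `IR·exp(±1.96/√E)`; zero events report
rate 0 with the exact Poisson upper bound `3.69/PY`, flagged. The IRR
CI is `exp(ln IRR ± 1.96·√(1/E1 + 1/E0))`. Log-scale and rate-scale
Wald intervals for the *rates* differ in the final printed digit at
large counts; the package standardises on the log scale, which also
reproduces the motivating study's OA IRR interval.

Cox models use lifelines with Efron tie handling (day-granular data are
heavily tied). Crude mode fits exposure alone; adjusted mode expands
age, sex, race/ethnicity, region, education, Charlson score, and
outpatient visit frequency against fixed reference levels, pooling
dummy levels with fewer than 10 members into the reference. A fit that
fails from separation retries with a light ridge penalty and says so in
the result's notes. Matched pairs are treated as independent (no
cluster-robust variance), also noted. Monotone likelihood (an arm
without events) raises an error naming the arm. Kaplan-Meier curves are
the product-limit estimator, equal to one minus the empirical CDF when
nothing is censored. The stratified analysis runs the Cox pipeline
separately within the prior-metformin and no-prior-metformin matched
strata, skipping (and logging) empty or inestimable strata.

## Synthetic claims generator

The generator's defaults describe a plausible commercial-claims
diabetes population over a 2003–2019 study window: index age ≈ 62
(SD 11.5), 58% male, race/ethnicity and region mixes typical of a
privately insured US population, outpatient visit frequency gamma with
mean 7/year; enrollment spells of several years with a 10% interruption
probability; 30-day fills; roughly one-year persistence per drug
(exponential, 30-day minimum); metformin first-line for 90% of
initiators with 15%/10% switching probabilities; a 4% chance of any
other antidiabetic; and a baseline OA hazard of 0.04/person-year
(≈ the sulfonylurea-arm rate in the motivating study), with log-hazard
covariate effects of +0.02 per year of age, −0.2 for men, and +0.05 per
Charlson point. OA onset is sampled exactly, by inversion of the
piecewise-constant cumulative hazard over the person's exposure
timeline, with the hazard multiplied by `exp(true_log_hr_oa)` during
metformin coverage; each observed onset emits ≥ 2 OA codes ≥ 14 days
apart (onsets whose confirming code cannot fall inside the observation
window stay latent and emit nothing, as they would in real claims).
Joint replacements occur only after OA onset, at a configurable rate.
Small fixed shares of persons carry the exclusion phenotypes (prevalent
OA, inflammatory arthritis, type 1 diabetes codes, combination
products, same-day dual starts) so every eligibility rule is exercised.

`inject_confounding` re-draws the first-line drug with log-odds shifted
by the configured covariate coefficients while holding the marginal
sulfonylurea count exactly fixed (rank-based assignment with logistic
noise), relabels the affected fills, and re-simulates outcomes so the
causal structure stays consistent with the new exposure pattern.

What the generator does *not* emulate: real code frequencies or
vocabularies (one representative code pair per phenotype family),
dosing and adherence variation, mortality (disenrollment subsumes it),
seasonality, provider structure, or time-varying covariates. Passing
tests therefore demonstrate that the *pipeline* is correct and unbiased
under the stated generative model, not that any particular real-world
estimate is right.

## Validation studies and problem sizes

The acceptance studies run at sizes chosen to give adequate events on a
single CPU: parameter recovery simulates 50 000 persons with equal
first-line shares (~19 000 records per arm, ~1000 OA events) and a true
hazard ratio of 0.75, checking that crude and adjusted Cox intervals
bracket the truth; confounding removal simulates 60 000 persons with
realistic channeling (older, sicker, more often male toward
sulfonylurea; ~9400 sulfonylurea vs ~39 000 metformin records),
requiring pre-matching SMDs > 0.1 on the channeled covariates and
post-matching SMDs < 0.1 on all of them; null calibration fits the
crude Cox model on 1000 two-arm exponential replicates of 2000 records
at true HR 1 and requires a ≤ 6.5% rejection rate at the nominal 5%
level. Matching primitives are checked against literal step-by-step
reference implementations on exhaustive small instances, and episode
and person-time arithmetic against day-by-day scans.

## Known limitations

No dose or adherence modelling; no competing-risks analysis or
proportional-hazards diagnostics beyond the exported curves; no 1:k or
optimal matching and no weighting; conditional-logistic control
sampling trades a little efficiency for tractability on very large
exposure sets; matched-pair correlation is ignored in the variance of
matched analyses (flagged in outputs); and the enrollment-continuity
reading (one bridged spell covering diagnosis lookback through index)
is the strictest of the plausible interpretations.
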