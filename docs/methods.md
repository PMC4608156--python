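# Model and methods

## The decision problem

`crc_cea` evaluates mass colorectal-cancer (CRC) screening from a
healthcare-provider perspective: a cohort enters at age 50, is followed to
age 75 in annual cycles, and is offered one of six strategies — no
screening, annual or biennial guaiac fecal occult blood testing (G-FOBT),
annual or biennial immunologic FOBT (I-FOBT), or colonoscopy every 10
years.  The output per strategy is discounted per-person cost, life-years
(LY) and quality-adjusted life-years (QALY); the comparison across
strategies yields ICERs, a dominance classification, the efficiency
frontier, and the ceiling-ratio (willingness-to-pay, λ) ranges on which
each frontier strategy is optimal.

## Natural history

Fourteen Markov states in four sections: pre-cancer (normal epithelium,
low-risk polyp, high-risk polyp), undiagnosed CRC stages I–IV, diagnosed
CRC stages I–IV, and three absorbing death states (CRC, screening
complication, other causes).  Disease flow is one-directional
(adenoma–carcinoma sequence); normal epithelium and low-risk polyps carry
no direct one-year cancer risk; incident cancer arises from high-risk
polyps and enters undiagnosed stage I by default (configurable split over
stages I–III).  Undiagnosed cancer may progress one stage per cycle and
presents symptomatically with a stage-specific annual probability, which
triggers diagnosis; diagnosis freezes stage progression but not
mortality.  Stage-specific CRC mortality applies to undiagnosed and
diagnosed disease alike.  Other-cause mortality is all-cause minus CRC
mortality by sex and quinquennial age band (clamped at zero), and is the
only channel through which age enters the transition structure.

**Competing risks within a cycle** are resolved by sequential
conditioning in a fixed order — death (CRC-specific first, then
other-cause), then symptomatic diagnosis, then progression — so every row
of the transition matrix sums to one by construction for any admissible
inputs.  The event order is a modelling choice; the annual-cycle
literature does not pin it down, and this order makes each row auditable
in closed form.

## Screening overlay

Screening acts at the start of each cycle, before the natural-history
transition; a positive stool test leads to a follow-up colonoscopy within
the same cycle.  Participation is memory-less: 60 % per routine round,
80 % for follow-up and surveillance colonoscopy, 100 % after symptomatic
presentation (defaults; all configurable).  Colonoscopy is perfectly
sensitive and specific.  Any polyp found is removed (polypectomy) and the
patient returns to normal epithelium on a surveillance track —
colonoscopy every 5 years after a low-risk polyp, annually after a
high-risk polyp.  Track holders skip routine stool testing (surveillance
supersedes it); a clean surveillance colonoscopy keeps the patient on the
same track with the interval clock reset; a missed surveillance round
stays due in every later cycle.  Diagnosed patients leave the screening
programme.  False positives incur colonoscopy cost and complication risk
but no state change and no surveillance track.

Colonoscopy harms: per-procedure bleeding and perforation probabilities
with case-fatality fractions; the fatal fraction moves to
death-from-complication.  Complication treatment costs are charged as
their per-procedure expectation on every colonoscopy (cohort-level costs
are exact expectations; only the within-branch cost split is
approximate).  One specialist-visit unit cost accompanies each
follow-up/surveillance colonoscopy episode.

The cohort state space is the product of the 14 health states with 9
surveillance sub-states (none; low-risk track with a 0–5-year counter;
high-risk track with a 0–1-year counter), i.e. 126 expanded states.  Both
the screening phase and the natural-history phase are linear operators on
this space, which is what makes the deterministic engine exact and fast
(~20 ms for all six strategies and both sexes) and lets the
microsimulation sample from literally the same matrices.

## Accounting

Life-years integrate the alive cohort mass, QALYs the utility-weighted
occupancy (SF-6D-style weights; death anchors 0, full health 1; the
default set gives normal epithelium 1.0 and equal stage-specific weights
to undiagnosed and diagnosed disease).  Costs comprise screening-phase
event costs (test kits, colonoscopies, polypectomies, expected
complication costs), a first-year-of-diagnosis cost per stage (charged at
the diagnosis cycle, whether found by screening or symptomatically), and
a continuing-phase cost per later year in a diagnosed state, with the
terminal year priced as a continuing year.

State-membership streams (LY, QALY, continuing cost) are evaluated on
cycle boundaries and half-cycle corrected by the trapezoid rule; one-off
event costs are charged in full at their event cycle.  All streams are
discounted at 3.5 %/year with the first cycle undiscounted (t = 0 at
entry); the horizon truncates at age 75 with no extrapolation.  Per-sex
runs (male/female mortality tables) are mixed 50:50 by default.

## CEA layer

ICERs are computed unrounded; reproduction of printed tables uses exact
rational arithmetic on the printed decimal strings and half-away-from-zero
rounding.  Dominance: strictly dominated strategies (weakly worse in both
dimensions, strictly in one) are removed first; the effectiveness-sorted
remainder is then pruned wherever the incremental-ICER ladder fails to
increase strictly (extended dominance) until the frontier remains.  The
optimal strategy at ceiling ratio λ is the frontier strategy whose
incremental ICER is the largest value ≤ λ; a λ exactly on a boundary
therefore selects the more effective strategy, while the report writer
prints the conventional `[0, r1], (r1, r2], (r2, +∞)` interval text.
Ties in effectiveness break toward lower cost; exact ties in both
dimensions collapse to the first-listed strategy.

## Uncertainty analysis

*One-way*: any dotted parameter path is re-run at user-supplied bounds
(validated against the full invariants before any run) and reported as
the ICER interval of a chosen strategy pair; tornado ordering is by
interval width.  *Multivariate*: named utility-set scenarios (ramsey,
ness, sharp, all-ones) swap the whole utility vector.  *PrSA*:
probabilities, rates, utilities and compliance draw from beta
distributions, costs from log-normals, both parameterised by
method-of-moments from (mean, standard error); default standard errors
are 10 % of the mean for probabilities and 20 % for costs, reflecting
typical literature uncertainty, since the study's own distribution table
is not publicly printed.  When only a (min, max) range is known it is
treated as a 95 % central interval.  The discount rate, time horizon and
the registry-derived mortality inputs (CRC mortality by stage and the
life-table mortality bands) are never drawn.  Draws are independent
across parameters and iterations and fully seeded.  CEACs evaluate, per
iteration and λ, the net-monetary-benefit maximiser over *all* strategies
(each iteration has its own frontier), on a default λ grid of 0–100,000
in steps of 500.

## Validation machinery

The individual-level microsimulation samples life histories from exactly
the per-cycle operators the cohort engine uses, charging each individual
the expected cost/utility of the states it visits; its means are
therefore unbiased estimators of the cohort-engine outputs and the
package tests agreement within 3 standard errors at 100,000 individuals
over 20 random parameter sets.  The trial-replication routine runs a
screening and a no-screening arm, accumulates undiscounted person-years
(trapezoid) and CRC deaths over a trial-length follow-up, and reports the
mortality-rate ratio and percent reduction.  Configurations for the
Funen, Nottingham and Minnesota G-FOBT trials ship with their design
settings and an empty slot for the published reduction values, which are
not printed in the main text.

## Synthetic parameter sets

`synthesize_parameters(seed, difficulty)` generates random valid inputs
for property testing.  It emulates the *structure* of the real disease
process — adenoma incidence above malignant conversion, CRC mortality
rising with stage, utilities non-increasing with severity, FOBT
sensitivity rising with lesion severity, I-FOBT strictly better than
G-FOBT in sensitivity and specificity, age-increasing mortality — but not
any calibrated magnitude: passing property tests demonstrates internal
consistency (conservation, oracle agreement, monotonicities) on such
inputs, not agreement with Hong Kong epidemiology.  The packaged fixture
is likewise split: main-text values are source-tagged `paper`, everything
standing in for the unpublished supplementary tables is tagged
`placeholder` and announced by the loader, so fixture runs characterise
the machinery, not the published base case.

## Numerical choices and limitations

Row-stochasticity holds to 1e-12 and cohort mass conservation to 1e-10 by
construction; the engine raises with the cycle index on non-finite
occupancy.  Problem sizes used by the shipped tests: 100,000 individuals
per microsimulation check, 10,000 PrSA iterations on the fixture, 1,000
random outcome sets against the frontier oracle.  Known limitations: no
colon/rectum site stratification, no hybrid FOBT-plus-endoscopy
strategies, no disability-adjusted life-years, single-sample stool tests,
no correlation structure between PrSA draws, 1-year cycles without
tunnel states, and cost memory limited to the first-year/subsequent-year
split.
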