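# Methods

## The decision problem

The package evaluates whether one round of FIT-based colorectal-cancer
screening in Bulgaria is good value compared with no screening, from the
payer's perspective, for the patients who actually have CRC. Only true CRC
patients are modelled: the analysis asks what earlier-stage detection is
worth, not how many cancers the test finds (FIT sensitivity/specificity and
colonoscopy follow-up outcomes are out of scope, matching the programme,
which did not collect them). All inputs are published constants shipped in
`src/crcua/data/parameters.yaml`.

## Cohort model

Four mutually exclusive states: *undiagnosed CRC*, *diagnosed stage I–II*,
*diagnosed stage III–IV*, *dead* (absorbing; accrues nothing). Annual
cycles, 50-cycle horizon, discount rate 3.5%/yr applied to costs and
utilities after the first year. The whole cohort enters undiagnosed; the
arm's stage split at diagnosis (with screening 67/33, without 46/54) routes
it to the diagnosed states. Early-stage patients progress to the advanced
stage with annual probability 2.43% and die with 1.87%; advanced-stage
patients die with 14.76%. The annual probabilities are derived at full
floating precision from the 5-year literature quantities under a
constant-hazard assumption:

* mortality: `1 − s5^(1/5)` from SEER 5-year survival (91% / 45%);
* progression: `1 − (1 − c5)^(1/5)` from the pooled Danish 5-year
  recurrence CIF. The pooling is the unweighted mean of the four
  site-by-stage values (6.80, 9.50, 11.60, 18.40%) = 11.575%; no
  colon/rectal case-mix weights are published, and the unweighted mean
  reproduces the published 11.58%.

Utilities: 0.74/yr (stage I–II), 0.46/yr (stage III–IV), 0 (dead). Costs
(EUR; BGN at the fixed 1.95583 peg): screening €7.84 once, in the screening
arm only; colonoscopy €498.08 once at diagnosis; stage III–IV treatment
€6,417.85 (see *Calibration*); palliative care €1,076.78 on the transition
to death. Background (non-CRC) mortality is excluded — the published model
specifies only stage-specific CRC mortality — so survival is optimistic at
high ages in both arms equally; the incremental results are far less
affected than the absolute totals.

## Structural variants and calibration

The published description fixes the state space and parameters but not the
cycle-level accounting. Each open choice is a field of `StructuralVariant`:

| Axis | Options (default first) |
| --- | --- |
| diagnosis timing | one cycle undiagnosed, then split / split at entry |
| undiagnosed-year utility | full health 1.0 / stage-weighted mean |
| half-cycle correction | off / on |
| stage III–IV treatment accrual | excluded / once per entry / every cycle |
| colonoscopy charged to | all diagnosed / early-stage only |
| one-time transition-cost discounting | departure cycle / arrival cycle |
| discount convention | 1/(1.035)^t from t = 0 / 1/(1.035)^(t+1) |

`crcua.cua.calibrate_variant` evaluates both arms under every variant of a
64-point grid (all axes above except per-cycle treatment accrual and
shifted discounting, which move totals by far more than the search
resolution) and ranks variants by the summed relative error against the
four published per-patient totals. To avoid display rounding, the targets
are the published cohort-level totals divided by the 747 detected patients
(e.g. €849,515.95 / 747 = €1,137.2369).

The winner — shipped as the package default — is: one undiagnosed year at
full health, membership rewards at cycle start without half-cycle
correction, colonoscopy charged to all diagnosed patients, transition costs
discounted at the departure cycle, **and no per-patient accrual of the
€6,417.85 advanced-stage treatment cost**. It reproduces the published
costs to <0.01% (€1,137.17 / €1,204.26 vs €1,137.24 / €1,204.31), the QALY
totals to 1.2–1.5% (8.558 / 6.979 vs 8.457 / 6.878), and the headline
increments almost exactly (−€67.09 vs −€67.07; +1.579 vs +1.579).

The treatment-cost exclusion is not a modelling preference; it is an
arithmetic consequence of the published totals. Charging €6,417.85 to the
33% of the screening arm diagnosed at stage III–IV already costs €2,118 per
patient — nearly twice the arm's entire published total of €1,137.24 — and
charging it on progression alone still adds ≈ €1,360. The coefficient a
least-squares fit assigns to any treatment-cost term is ≈ 0. The published
per-patient cost difference between the arms is therefore driven by the
*timing* of palliative-care spending (screening-arm patients die later, so
the same palliative cost is discounted more) plus the €7.84 screening fee,
not by avoided treatment. The €6,417.85 cost instead drives the five-year
budget projection, where it reproduces the published savings. Users who
want a clinically complete cost accrual can select
`late_cost_recurrence="once_on_entry"`; the incremental saving then grows
by roughly an order of magnitude, strengthening (not reversing) dominance.

Two conventions deserve a note. First, "discounting after the first year"
and the standard factor 1/(1+r)^t with t = 0 for the first cycle are the
same rule; the alternative variant discounts from the first cycle,
1/(1+r)^(t+1). Second, discounting one-time transition costs at the cycle
in which the transition initiates (the departure cycle, as TreeAge accrues
transition rewards inside the source cycle) rather than the arrival cycle
is what reconciles an undiagnosed first year on the utility side with
undiscounted diagnosis costs on the cost side; with arrival-cycle
discounting the best achievable cost error is ≈ 3.4% on both arms.

## Incremental analysis and detected cohort

Deltas are screening minus no screening. Cheaper-and-more-effective is
*dominant*, the reverse *dominated*, same-sign deltas define an ICUR
(Δcost/ΔQALY), exact ties are *equivalent*; a zero QALY delta with nonzero
cost is classified by cost alone. The detected cohort applies the Slovenian
FIT detection rate (862/15,310 = 5.63%) to the 13,263 Bulgarian positives,
rounding half-up: 746.7 → 747. The published campaign table's header counts
13,281 positives while its age strata (and the published CUA text) sum to
13,263; the function takes the count as an explicit argument and the
reproduction uses 13,263, matching the published 747.

## Probabilistic sensitivity analysis

Each iteration draws every cost from a normal distribution (SD = 20% of the
base value, truncated at 0), each utility from a gamma distribution
(SD = 20%; draws above 1 are clamped to 1 and counted — the gamma family is
implemented as published even though its support exceeds the utility
scale), and each probability and stage-split early fraction from a beta
distribution (SD = 10%), all parameterized by method of moments and sampled
independently (no correlation structure is published). Late stage fractions
are the complement of the sampled early fraction. Draws that fail model
validation are redrawn and logged. The seed fully determines the result.
Acceptability is the fraction of iterations with incremental net monetary
benefit WTP·ΔQALY − Δcost ≥ 0 at €44,081.03/QALY (stored as the published
constant; the underlying GDP-per-capita figure for "3× GDP" is not
published). With 1,000 iterations the acceptability is ≈ 99%, matching the
published 99.1%; nearly all failures are iterations where the two sampled
stage splits cross.

## Budget projection and GDP contribution

Population: 2,233,977 × (1 − 0.01147)^k, carried unrounded, displayed
rounded half-up. New cases: unrounded population × 0.000431. Stage cells:
unrounded cases × share, rounded per cell (the 2026 cell reproduces only
from unrounded cases: 940.88 × 0.33 → 310); avoided cases are differences
of the rounded cells; column totals come from unrounded yearly sums (which
is why the published "without screening" total is 2,541 while its five
printed cells sum to 2,540). Savings use the unrounded avoided chain ×
€6,417.85. The published yearly savings exceed this computation by ≈ 0.1%
(their unrounded chain is unrecoverable); agreement is within 0.2%.

GDP: per-working-capita = €93,946,530,472.80 / 3,900,300 = €24,087.00;
contribution = (QALYs gained × 56% working share) × per-capita GDP under
the published one-QALY-equals-one-work-year assumption, reported as a
theoretical projection. The published intermediate of 662.08 working-age
QALYs does not follow from the published inputs (0.56 × 1,179.59 = 660.57);
the module computes from the stated inputs, giving €15.91M vs the published
€15,947,405.22 — both round to the €15.9M headline.

## Campaign statistics

Positivity is positives/tested per stratum or union of strata; the
published rates reproduce exactly (overall 14.22%, male 18.2%, female
11.9%, ages 50–74 14.4%). The age margin covers 93,218 of 93,381
participants; the 163-record remainder is exposed as an unspecified-age
cell and union rates use per-stratum denominators. Channel shares support
two denominators because the published ones are internally inconsistent:
the printed channel counts sum to 90,184, of which television's 41,192 is
45.68% (and 44.11% of all participants) — neither equals the printed
45.1%. Cost per participant computes to €7.83 (€731,340.27/93,381), not
the printed €7.84; the computed value is returned and the delta surfaced
rather than resolved.

## Synthetic data

`generate_participants` draws independent records with sex, age band and
channel from the published marginals and FIT results from per-cell
positivities built by proportional scaling (age-band rate × sex-rate
ratio), clamped to [0, 1]; suspicious results are drawn independently at
25/93,381. Multiplicative scaling matches both margins only up to a small
residual (≈ 0.005 percentage points on the overall rate), which the tests
tolerate explicitly. The generator emulates the published margins and
nothing else — no within-person correlation, geography, or temporal uptake
structure — so passing tests validate the analytics pipeline, not any
epidemiological claim about real participants.

`microsim_cohort` simulates independent individual trajectories with
per-cycle multinomial transitions from the same transition matrix and
reward rules as the cohort engine. Its sample means converge to the cohort
totals at rate 1/√n, making it a brute-force oracle: the suite checks
agreement within 3 standard errors at n = 100,000 for every variant of the
calibration grid (a fixed seed keeps the 256 comparisons reproducible;
shared draws across variants correlate them, and the observed worst
deviation is well under 1 SE).

## Numerical choices and problem sizes

* Probabilities and money are double precision throughout; rounding to the
  published precision happens only in display columns and summaries.
  Detected-patient and projection counts round half-up (floor(x + 0.5)).
* Occupancy conservation is asserted at 1e-9; the engine validates
  row-stochasticity and rejects negative stay probabilities.
* Degenerate inputs: horizon 0 is a legal engine input producing an empty
  trace (config files require ≥ 1); zero-variance PSA specs return the base
  value bitwise, so the degenerate PSA limit equals the base case exactly;
  empty campaign strata raise a dedicated error distinct from a zero rate.
* Default problem sizes — 1,000 PSA iterations, 20-seed stability checks,
  n = 100,000 microsimulation per variant, full-scale (93,381-record)
  synthetic campaigns — run the whole suite in well under a minute; they
  are the published analysis sizes wherever one is published.

## Known limitations

* The calibrated structure is a reverse-engineered reconstruction; the
  1.2–1.5% residual on absolute QALY totals suggests a further small
  convention difference in the original build that the published
  information cannot identify. The incremental results, which the
  conclusions rest on, reproduce to within 0.1%.
* No background mortality, tunnel states, re-screening rounds, age
  structure, or FIT test-performance modelling — matching the published
  scope.
* The projection is deterministic (no uncertainty propagation) and assumes
  the screening stage-shift applies to every incident case from 2024
  onward.
* The GDP contribution inherits the published full-productivity
  assumption and should be read as an upper bound.
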