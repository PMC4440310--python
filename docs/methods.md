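# Methods

## Scope and design

`quotasim` projects the supply side of a regional anaesthesia workforce under
a restrictive immigration scenario: training intake is frozen at a constant
quota, certified foreign trainees must leave (strict return policy), and
demand is held at its baseline level. It is a discrete-time (annual-step)
stochastic microsimulation: state-to-state moves are driven by individual
covariates (age, gender, nationality, seniority, working-time) interacting
with hard capacity constraints, which is why the model is run person-by-person
with Monte-Carlo replication rather than as an aggregate Markov chain with
fixed transition matrices.

States: TRAINING → (certification) → TRANSITION → (vacancy-chain promotion) →
FIXED → (retirement) → RETIRED, with DEPARTED as an absorbing side state for
foreign staff removed by the return policy. DEPARTED is bookkeeping only; the
four-state census is unaffected by how departures are labelled.

## Inputs

All quantitative inputs are the published marginal distributions of a
cross-sectional survey of the region's 413 active anaesthetists (416
respondents of 506 listed; 66 in training, 99 in transition, 248 in fixed
posts), shipped in `src/quotasim/data/params.yaml`:

| parameter | default | units | role |
|---|---|---|---|
| quota | 66 | persons | training posts refilled every year |
| fixed_capacity | 244 | persons | permanent posts kept filled from transition |
| training_state_years | 5 | years | official residence before certification |
| desired retirement age | N(62, 3.1) / N(60, 2.8) | years | men / women, truncated to [55, legal 65/64] |
| foreign_departure_hazard | calibrated (default run: 0.01) | 1/year | annual exit probability of foreign transition staff |
| part_time share | 97/412 | — | probability a person works part-time |
| part_time weight *w* | calibrated (default run: 0.575) | FTE | hours fraction of part-timers |
| transition FTE demand | baseline headcount (99) | FTE | denominator of the gap |

The survey allowed item non-response, so marginals have different totals; each
is normalised within its own total. The published nationality cross-tab sums
(66/100/249 by position) differ from the pooled position counts (66/99/248) by
one person in two positions; the loader accepts a slack of two per position
and the cross-tab proportions are used as conditional probabilities.

The fixed-post capacity is 244 rather than the surveyed 248: the published
projection holds fixed posts constant at 244, so the four extra surveyed posts
are treated as positions not refilled once vacated.

## Synthetic cohort

The person-level survey records are not available, so each replicate draws a
fresh synthetic roster. Attributes are sampled independently from their
marginals except:

- **nationality** is drawn conditional on position and **hospital type**
  conditional on nationality (the two published cross-tabulations);
- **age** is drawn conditional on career stage. Trainees are uniform on
  [26, 35] and transition staff uniform on [33, 45]. Fixed staff receive the
  *residual* of the printed age-band marginal: within each band the cohort-wide
  age density is taken as flat, the training/transition windows are subtracted,
  and fixed staff fill what remains (mostly ages 45–56 plus the whole 56+
  band). This construction reproduces the printed band marginal in expectation;
  per-state uniform windows alone cannot (they over-fill ≤35 and starve 46–55).
- **desired retirement age** for people sampled into the 56+ band is drawn
  length-biased (reweighted by `ret − 56`), the stationary-renewal form of
  "still active past 56", and their age is then uniform on [56, ret). Without
  the length bias the first-year retirement outflow is overstated by ~25 %.

`years_in_state` at initialisation is uniform over a state-typical residence
window (training [0, 5], transition [0, 4], fixed [0, age − 33]) — a
stationary-entry assumption. New entrants under the quota refill are aged
uniform [26, 30] with gender/part-time status from the overall marginals and
the trainee pool's nationality mix (24 foreign in 66).

`validate_cohort` runs per-marginal chi-square tests (significance 0.01)
against the sampling expectations, pooling sparse cells (Cochran's rule) and
flagging marginals whose expected counts are too small to test. The default
413-person roster and a ~100 000-person roster both pass every testable
marginal.

**What the generator does not emulate:** any joint structure beyond the two
printed cross-tabs (e.g. age × part-time, gender × position), secular trends
in feminisation or part-time work, and intensive-care anaesthetists. Passing
tests therefore show fidelity to the published marginals, not to the
unpublished person-level data.

## Calibration

Two scalars are not published anywhere and are solved from printed anchor
values:

1. **Foreign departure hazard** *h*: grid search on [0, 0.5] in steps of 0.01,
   minimising the squared error of the simulated transition medians against
   the published end-2014 (93) and end-2024 (58) values, with common random
   numbers across grid points (200 replicates each). The default run selects
   *h* = 0.01.
2. **Part-time weight** *w*: closed-form inversion of the baseline condition
   "10 % of transition FTE unfilled at end-2014":
   `w = ((1 − gap/100)·demand/headcount − (1 − p)) / p` with *p* the baseline
   part-time share among transition occupants. The default run gives
   *w* ≈ 0.575, i.e. part-timers at ~58 % of full time.

The end-2024 FTE gap is *not* anchored and serves as validation: the default
run yields a median of ~50 % (within the published 42–59 band).

## Numerical choices

- Percentages are rounded half-up to integers for display; unrounded values
  are kept internally.
- Percentile bands are empirical 2.5/97.5 percentiles with linear
  interpolation; point estimates are medians.
- Promotion ties are broken by longest state residence, then older age, then
  lower person id, making every replicate reproducible.
- Randomness: one master seed feeds a `numpy` `SeedSequence`; calibration and
  production runs, and each replicate within them, consume independent spawned
  substreams. Re-running with the same seed reproduces every output file
  byte-for-byte (manifest timestamp aside).
- Degenerate inputs are defined, not special-cased: zero quotas leave pools
  empty, empty promotion pools leave vacancies unfilled, zero-SD retirement
  distributions collapse to their mean.
- Default problem sizes: 1000 replicates for projections, 200 per grid point
  for calibration — enough for ±1 stability of the reported medians while
  keeping a full calibrated run around two minutes on one core.

## Verification

The engine is checked against an independently coded aggregate
stock-and-flow recurrence on six degenerate scenarios (all stochastic elements
collapsed), requiring exact equality of every census; plus property tests for
conservation of persons, the quota and capacity invariants, monotonicity of
the transition pool in quota and hazard, percentile ordering, and bit-level
seed reproducibility.

## Known limitations

- The published projection's person-level inputs and transition probabilities
  were never released. The calibrated default run reproduces the published
  95 % bands in 10 of 11 years for transition posts and 9 of 11 for
  retirements, the end-2024 transition median (55, published 58 with band
  49–66), the 2014 retirement count (12) and the end-2024 FTE gap (median
  ~50 %, published band 42–59) — but not the published 38 % headline decline:
  the simulated decline is 44 % because the simulated end-2014 median stays at
  99 (the published projection drops to 93 in its first year) while retirement
  outflow, driven here by a flat-within-band age density, is steady at
  ~12–13/year rather than low-early/high-late. Both discrepancies trace to the
  unpublished within-band age structure of the original cohort; the departure
  hazard cannot absorb them, since raising it lowers both endpoint medians
  together and leaves the decline ratio at 44 % or above.
- Demand is static by design (supply-side model): no population growth,
  surgical-volume trends, or feminisation/part-time drift.
- Results describe one region's anaesthesia workforce under one stylised
  policy reading; hospital-level stratification is out of scope beyond the
  descriptive 49 % district share.
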