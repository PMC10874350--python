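# Methods

This note documents the models, conventions and design choices behind
`keyrhythm`: what each pipeline stage computes, what the synthetic cohort
generator does and does not emulate, and where the genuinely open choices
were made.

## Time conventions

All timestamps are naive local clock time in a single study timezone. The
analysis bins events by the local clock, so the package performs no timezone
or DST arithmetic anywhere; multi-site or travelling cohorts would need
times pre-converted to each participant's local clock. An event belongs to
the calendar date and time-of-day of its **press** timestamp; the release
timestamp is validated (`release ≥ press`) and carried through I/O, but no
dwell-time feature is computed. Timestamps are held at millisecond
resolution end to end, and files round-trip bit-exactly at that resolution.

A study calendar is `n_weeks` (default 5) seven-day weeks from `start_date`;
week *w* covers `[start + 7(w−1), start + 7w)` days, half-open. The first
`n_adjustment_weeks` (default 1) are discarded as a habituation period for a
newly installed keyboard.

## Five-bin diurnal profiles

The day is tiled by five half-open bins: sleep [00:00, 06:00), morning
[06:00, 12:00), afternoon [12:00, 17:00), evening [17:00, 21:00), night
[21:00, 24:00). Per participant and study date the pipeline records the
five bin counts and their total; days with zero events are materialised
explicitly, because the completeness filter needs them.

**Completeness.** A week is complete iff all 7 of its days have at least one
keystroke; a participant is included iff at least 3 of the 4 post-adjustment
weeks are complete. "At least one keystroke" is the strictest operational
reading of a complete day: in press/release metadata a silent day and a
logging gap (e.g. the participant switched back to another keyboard) are
indistinguishable, so any threshold above zero would be arbitrary. Only
days inside complete weeks enter a participant's averages, so a partially
missing week never biases a profile — inclusion and averaging use the same
unit (the week).

**Averaging.** `mean_counts` is the per-bin mean over all included days,
zero days included. Ratio profiles are the mean over *active* days (total >
0) of each day's `counts/total` vector — the per-day ratio average, not the
ratio of summed counts. Averaging per-day ratios weights each day equally
regardless of volume; the pooled alternative (`ratio of summed counts`,
which weights heavy days more) is available as
`participant_profile(..., ratio_method="pooled")` but is not the default.
Zero-total days are skipped in ratio means because 0/0 is undefined; a
weekday or weekend variant with no active day is reported as undefined
(`None`, or an exception under `strict=True`) and the participant is
excluded from the similarity test with a logged reason — never silently
scored 0 or 1. Weekend means Saturday and Sunday.

## Quadratic shape coefficient

Each participant's five mean counts are fitted with an ordinary
least-squares degree-2 polynomial; the quadratic coefficient `a2` summarises
the diurnal shape (concave/evening-peaked vs convex/late-night). The default
abscissa is the **bin index 1…5**, reproducing the common fit-a-vector
idiom, even though the bins span unequal numbers of hours (6/6/5/4/3); bin
midpoint clock hours (3, 9, 14.5, 19, 22.5) are available via
`fit_quadratic(y, x=BIN_MIDPOINT_HOURS)` and the pipeline's `fit_abscissa`
switch. Both are legitimate; the index default was chosen because the
five-point profile, not clock time, is the object being summarised, and no
claim is made that either matches any particular prior analysis.

For the equally spaced default the solve uses the discrete orthogonal (Gram)
polynomial basis: with `z = x − 3`, the contrasts `(1)`, `z` and `z² − 2`
are mutually orthogonal, so the OLS coefficients are three independent inner
products. This is algebraically identical to a generic polynomial
least-squares fit (a property test pins it to `numpy.polyfit` at 1e−8) but
numerically exact when the profile is itself a low-degree polynomial —
profile `(1, 4, 9, 16, 25)` returns exactly `(a2, a1, a0) = (1, 0, 0)`.

The fit quality `r` is the Pearson correlation between observed and fitted
values; for a constant profile it is **undefined** (reported as `None`), not
zero, since zero would wrongly suggest "no agreement". Group-level curves
average the member *fitted* curves, and the group `r` correlates the group
mean observed profile with that average.

## Weekday/weekend cosine similarity

Per participant, the cosine of the weekday and weekend mean **ratio**
profiles (scale invariance makes counts and ratios equivalent up to the
per-day normalisation; ratios are used because the weekly rhythm, not the
volume, is the target). For nonnegative profiles the value lies in [0, 1],
equalling 1 iff the profiles are proportional. A zero vector raises rather
than defaulting. The group comparison is per-participant similarity followed
by Welch's t between groups — not a single similarity of group-mean
profiles — so between-person variance enters the test correctly. The
denominator is computed as `sqrt((u·u)(v·v))`, which keeps simple rational
cases (e.g. cos((1,2,0,0,0),(2,1,0,0,0)) = 0.8) exact in floating point.

## Statistical battery

All three tests are computed from the textbook formulas, with scipy
supplying only the reference distributions:

- **One-way ANOVA**: `F = MS_between / MS_within`, p from the upper tail of
  `F(k−1, N−k)`. If every group is internally constant, F is reported as 0
  (equal means) or ∞ with p = 0 (unequal means), flagged `degenerate` rather
  than raised, so a pipeline run surfaces the pathology instead of crashing.
- **Tukey–Kramer**: `q_ij = |m_i − m_j| / sqrt(MS_within/2 · (1/n_i + 1/n_j))`
  with p from the studentized-range distribution at `k` groups and the ANOVA
  within degrees of freedom. The Kramer harmonic term is required because
  the study design is unbalanced (group sizes such as 18/26/10/5).
- **Welch's t**: unequal-variance two-sample t with Welch–Satterthwaite
  degrees of freedom, two-sided.

α = 0.05 throughout, and deliberately **no** correction across the five
per-bin ANOVAs or the six pairwise Welch tests: the pipeline reports every
test with its raw p and flags the very-severe-vs-no similarity contrast as
the single pre-declared headline. Tests touching any group with fewer than
two included participants are skipped with an explicit report note.
Cross-implementation tests pin all three statistics to scipy
(`f_oneway`, `tukey_hsd`, `ttest_ind(equal_var=False)`) at 1e−6 over 100
seeded datasets.

## Synthetic cohort generator

Typing is modelled as an inhomogeneous Poisson process with
piecewise-constant daily intensity: five per-bin rates (expected keystrokes
per day), switched between a weekday and a weekend set. Finer-than-bin
structure is unidentifiable from bin totals, so events are placed uniformly
within their bin (press at millisecond resolution; release = press + a
40–250 ms dwell). Every draw is recorded as ground truth, and binning a
generated log reproduces the recorded draws integer-exactly — the invariant
that lets replicated simulation studies run on the recorded counts directly
instead of materialising millions of events per replicate.

Defaults (chosen once, as the study conditions the generator emulates):

| group       | n  | weekday rates (sleep…night) | weekend rates |
|-------------|----|------------------------------|---------------|
| no          | 18 | 200, 700, 1100, 1700, 800    | 350, 450, 900, 1300, 1500 |
| moderate    | 26 | 250, 650, 1050, 1650, 900    | 400, 500, 900, 1250, 1450 |
| severe      | 10 | 250, 600, 900, 1300, 750     | 350, 400, 750, 1050, 1250 |
| very_severe | 5  | 1300, 350, 700, 900, 1350    | identical to weekday |

The three lower-loneliness groups peak in the evening on weekdays and shift
toward night with a quieter morning on weekends; the very-severe group is
night+sleep-peaked with no weekday/weekend difference, and severe has a
somewhat lower daily volume. Daily totals of ≈3,800–4,600 give
≈110,000–130,000 keystrokes over the four analysis weeks — a realistic
monthly volume for a young adult cohort.

- **Activity multiplier**: each participant's rates are scaled by a
  mean-one lognormal draw with log-scale sd σ = 0.55, reproducing a
  between-person coefficient of variation ≈ 0.6 in total volume
  (`CV = sqrt(exp(σ²) − 1)`) while leaving ratio profiles untouched.
- **Dropout**: whole days vanish independently with probability 0.022. A
  week survives intact with `(1 − p)⁷`, so the chance of failing the
  3-of-4 rule is `1 − (1−q)⁴ − 4q(1−q)³` with `q = 1 − (1−p)⁷`; p = 0.022
  puts that at ≈ 10%, a realistic attrition level for a five-week passive
  sensing study.
- **ULS-8 responses** are rejection-sampled uniform item vectors constrained
  to the participant's group band. The analysis consumes only the banded
  total, so no latent-trait model is warranted.
- **Determinism**: one master seed; each participant's randomness comes from
  a spawned child of the master `SeedSequence`, so cohorts are bit-identical
  across reruns and participants are independent streams.

**What the generator does not emulate.** Within a group, participants differ
only in overall volume (and Poisson noise) — there is no between-person
variation in diurnal *shape*, no day-to-day autocorrelation, no typing
sessions or burstiness, no seasonal or holiday structure, and no content or
typing-speed features at all. Group contrasts on synthetic cohorts are
therefore far cleaner than any real cohort would be: F and t statistics come
out one to two orders of magnitude larger than plausible field values.
Consequently, passing simulation tests demonstrates that the pipeline
*recovers directions and calibrates its type-I error correctly*, not that
real data would reach significance at these sample sizes.

## Simulation studies and problem sizes

`run_simulation_study` repeats generate-cohort → headline analysis
(sleep-bin ANOVA, quadratic-coefficient ANOVA with group mean signs, Welch
on cosine similarity for very-severe vs no) and tabulates rejection and
direction-recovery rates. The shipped studies use 59-participant cohorts at
full activity scale: 2,000 replicates for null calibration in the test
suite (1,000 in the acceptance script) and 100 replicates for direction
recovery — sizes at which the binomial error on a 5% rate is ≈ 0.5
percentage points and a ≥ 90% recovery criterion is sharp, while a full run
stays within a couple of minutes on one CPU.

## Known limitations

- The completeness rule's "active day" threshold (≥ 1 keystroke) cannot
  distinguish a genuinely silent day from a logging gap; both cost the week.
- Equal-index abscissa for the quadratic fit ignores unequal bin widths; use
  the midpoint-hours switch when clock-time curvature is the question.
- The per-day ratio average weights a 50-keystroke day equally with a
  5,000-keystroke one; use the pooled switch when volume weighting is
  wanted.
- Ordering of simultaneous presses within a millisecond preserves file
  order; no claim is made about the capture order of multi-touch input.
- The statistical battery is exactly the classical one: no mixed-effects,
  nonparametric or multiplicity-corrected alternatives are provided.
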