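# keyrhythm

Diurnal smartphone-keystroke profiling versus loneliness level.

`keyrhythm` is a reusable analysis pipeline for studies that relate a
person's *when-they-type* pattern — timing metadata of anonymized keyboard
press/release events, with no key content — to their loneliness level
measured by the 8-item short-form UCLA Loneliness Scale (ULS-8). It is aimed
at digital-phenotyping researchers who have per-participant keystroke event
logs and questionnaire responses and want the complete, auditable chain from
raw events to group-level statistics. Because such cohorts are rarely
shareable, the package also ships a synthetic cohort generator with recorded
ground truth, so every stage of the analysis can be run, inspected and tested
without real participant data.

## The analysis

For each participant, each study day is tiled by five clock-time bins —
sleep [00:00, 06:00), morning [06:00, 12:00), afternoon [12:00, 17:00),
evening [17:00, 21:00), night [21:00, 24:00) — and each keystroke is counted
in the bin of its press timestamp. The first study week is an adjustment
period and is dropped; a week is *complete* when all 7 of its days show at
least one keystroke, and a participant is included when at least 3 of the 4
remaining weeks are complete. For included participants the pipeline
computes, over the days of their complete weeks:

- the mean daily typing count per bin, `c = (c_1, …, c_5)`, and the mean
  daily typing-count ratio per bin (each day's bin counts divided by that
  day's total, averaged over active days), overall and split into weekday
  and weekend variants;
- the quadratic shape coefficient: the `a2` of the least-squares fit
  `c_x ≈ a2·x² + a1·x + a0` over bin indices `x = 1…5`. An evening-peaked
  day shape is concave (`a2 < 0`); a late-night/U shape with high sleep and
  night counts is convex (`a2 > 0`);
- the weekday/weekend similarity
  `cos(u, v) = u·v / (‖u‖₂‖v‖₂)` of the weekday (`u`) and weekend (`v`)
  mean ratio profiles — 1 when the week does not change a person's typing
  rhythm.

Group-level inference across the four ULS-8 bands (*no* 8–13, *moderate*
14–20, *severe* 21–25, *very severe* 26–32; items 7–8 reverse-coded) uses a
one-way ANOVA per time bin and for `a2`, Tukey–Kramer post-hoc comparisons,
and Welch's t-tests on the cosine similarity for every group pair, with the
very-severe-vs-no contrast flagged as the headline.

## Worked example

```python
from keyrhythm.synth import default_config, generate_cohort
from keyrhythm.pipeline import analyze_cohort

bundle = generate_cohort(default_config(seed=5), events=False)
day_counts = {pid: bundle.day_counts(pid) for pid in bundle.participant_ids}
report = analyze_cohort(day_counts, bundle.uls8, bundle.config.calendar, seed=5)
print(report.to_text())
```

prints

```
keyrhythm analysis report
==========================

participants included: 55 of 59

group summary
  no           n=18  ULS-8 12.39 (0.92)  keystrokes 123,382 (49,654)
  moderate     n=22  ULS-8 18.27 (1.75)  keystrokes 97,057 (49,757)
  severe       n=10  ULS-8 22.20 (1.55)  keystrokes 127,600 (61,210)
  very_severe  n=5   ULS-8 27.00 (1.00)  keystrokes 114,061 (71,219)

one-way ANOVAs (per time section and quadratic coefficient)
  sleep          F = 24.15  df = (3,51)  p = 0.0000 *
  morning        F = 3.49  df = (3,51)  p = 0.0221 *
  afternoon      F = 2.58  df = (3,51)  p = 0.0637
  evening        F = 2.91  df = (3,51)  p = 0.0431 *
  night          F = 1.29  df = (3,51)  p = 0.2880
  quadratic_a2   F = 38.13  df = (3,51)  p = 0.0000 *

weekday/weekend cosine similarity (group means)
  no           n=18  cosine 0.9256 (0.0026)
  moderate     n=22  cosine 0.9469 (0.0024)
  severe       n=10  cosine 0.9455 (0.0028)
  very_severe  n=5   cosine 0.9999 (0.0001)

pairwise Welch's t on cosine similarity
  no vs moderate: t = -26.80, df = 35.2, p = 0.0000 *
  no vs severe: t = -18.71, df = 17.8, p = 0.0000 *
  very_severe vs no: t = 121.19, df = 17.2, p = 0.0000 *  [headline]
  ...
```

Reading the output: 4 of the 59 generated participants were excluded by the
complete-weeks filter. The sleep-bin ANOVA is strongly significant because
the very-severe group's generative profile concentrates typing in the
late-night hours; the positive headline Welch t says that group's weekday
and weekend rhythms are more alike than the no-loneliness group's. (With no
within-person shape variation beyond Poisson noise, synthetic effect sizes
are much larger than anything expected from real cohorts — see
`docs/methods.md`.)

The same pipeline runs from files on disk:

```sh
keyrhythm simulate cohort/ --seed 5            # events/*.csv, uls8.csv, calendar.yaml
keyrhythm analyze cohort/events cohort/uls8.csv cohort/calendar.yaml out/
keyrhythm simstudy --n-replicates 100 --seed 1 # replicated power/calibration study
```

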