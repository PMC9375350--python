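# Methods

This note records the models, conventions and numerical choices behind
`carietrack`, and what the synthetic cohorts do and do not emulate.

## Data model

A cohort is a long-format exam table (child × visit × tooth × surface
→ modified-ICDAS condition) plus per-child metadata.  Conventions:

- **Dentition.** 28 permanent teeth (FDI 11–17, 21–27, 31–37, 41–47);
  third molars are excluded, matching an 11–12-year-old population.
  Every tooth carries the same five surface slots (mesial, occlusal,
  distal, buccal, lingual); anterior teeth use the same scheme with
  OCCLUSAL read as incisal.  Field practice does not always score all
  140 slots — unerupted or unscoreable surfaces are simply absent from
  the table — and the generator's default of 126 scored surfaces per
  child reflects the observed average (28,415 surfaces / 226 children).
- **States.** `SOUND`, `NONCAV_A` (merged ICDAS 1–2, used when
  compressed-air drying is unavailable), `CAV3`–`CAV6`,
  `FILLED_SOUND`, `FILLED_NONCAV`, `FILLED_CAV`, `MISSING`, `CROWNED`.
- **Visits.** Indexed 0–3 at fixed six-month spacing; calendar dates
  are out of scope.
- **Attendance.** `ATTENDED` / `ABSENT` / `DROPPED` per visit;
  absence is transient, dropout absorbing.  `MISSING` surfaces are
  absorbing.  `validate_cohort` checks all invariants and returns
  violations as data.

## Transition classification

Baseline and follow-up states are first collapsed under a diagnostic
cutoff — `3-6` maps code A to sound (and `FILLED_NONCAV` to
`FILLED_SOUND`); `A-6` keeps it as a lesion — and each surface pair is
classified progression / regression / neither.  Intervals are
cumulative (baseline vs 6, 12, 18 months), because the stratum
comparisons are of cumulative increments at each follow-up.

The classification is total over all 8×8 collapsed-state pairs.
Beyond the core taxonomy (onset/worsening of decay, loss of the
surface, and reversals toward sound), several pairs require a
convention; ours are:

- Treatment of a sound or non-cavitated surface (→ any `FILLED_*`,
  `MISSING`, `CROWNED`) is **progression**: filling or extracting a
  surface that was not cavitated reflects disease/treatment incidence.
- Transitions *from* `MISSING` or `CROWNED` are **neither** (terminal
  states; a surface is progressed into them at most once).
- Transitions from `CAV` or `FILLED_CAV` are **neither** except the
  reversals `CAV→SOUND`, `FILLED_CAV→SOUND` and
  `FILLED_CAV→FILLED_NONCAV`; in particular filling an established
  cavity is expected care, not increment.
- `FILLED_SOUND→SOUND` is **regression**; new decay on a
  `FILLED_SOUND` surface is **progression**;
  `FILLED_NONCAV→FILLED_SOUND` is **regression** and
  `FILLED_NONCAV→NONCAV` **neither** (severity unchanged).
- Surfaces newly present at a follow-up (eruption) are classified
  against an implied `SOUND` baseline: newly erupted surfaces are
  caries-free, and excluding them would understate denominators.

Biologically implausible reversals are *not* filtered: the adjusted
increment corrects for the reversal rate in aggregate and cannot
distinguish plausible from implausible reversals.

## Adjusted caries increment

Per child, ADJCI = P·N/(R+N) on the surface-count scale.  When
R+N = 0 (every surface progressed) the expression is 0/0 and the
natural limit P is returned.  ADJCI is always in [0, P], monotone in P
and antitone in R.  Stratum cells report mean ± SD with the n−1
denominator; an empty stratum is flagged, never reported as zero.

## Statistics

- **Chi-square** homogeneity/independence via the Pearson statistic
  without continuity correction (`scipy.stats.chi2_contingency`);
  zero marginals raise a degenerate-table error.
- **Repeated-measures ANOVA**: the classical one-factor
  within-subject partition SS_total = SS_time + SS_subject + SS_error,
  F = MS_time/MS_error with df (2, 2(n−1)) for three time points, on
  complete cases (or one imputed completed set).  Zero error variance
  returns F = 0, p = 1 rather than NaN.  No sphericity correction by
  default; Greenhouse–Geisser is available (`correction="gg"`) and
  recorded in the result.  Post hocs are paired t-tests of 12-vs-6 and
  18-vs-6 months, Bonferroni ×2, reported raw and adjusted.
- **The 6-month cell** has no earlier reference; its evidence is a
  one-sample t of the 6-month increments against zero, multiplied by
  the same Bonferroni factor 2 so all three interval p-values sit on a
  comparable adjusted scale.
- **Weighted kappa** (κ_w = 1 − Σw·O/Σw·E) with linear weights by
  default — the weighting scheme is a convention, and linear is the
  more conservative choice — via `sklearn.metrics.cohen_kappa_score`.

## Multiple imputation

Children missing an interval (absent/dropped at baseline or a
follow-up) are completed by a hot-deck within risk stratum: each
missing child-interval draws a donor uniformly from the same stratum's
children observed at that visit and copies the donor's (P, R, N); the
same donor serves both cutoffs so the imputed counts stay coherent.
Imputation operates at the counts level because every downstream
statistic is a function of the counts; inventing surface-level
trajectories would add nothing but failure modes.  This is a declared,
simple substitute for a full chained-equations model: unbiased under
MCAR, respectful of the risk structure that drives increments, and
reproducible from a seed.  m defaults to 20.  Pooling follows Rubin's
rules (T = W + (1+1/m)B); the df is Rubin's classic formula, with the
Barnard–Rubin small-sample adjustment when a complete-data df is
supplied.  Stratum mean cells in the pooled increment table report the
Rubin point estimate with the average within-dataset SD.

## Recall rules

For each (risk, cutoff) cell the recommendation is the earliest
interval in {6, 12, 18} whose adjusted p falls below α (default 0.05,
strict inequality), else the 18-month study horizon.  Adding an
earlier significant interval can never lengthen a recommendation.
A `published_a6_override` flag caps every A-6 cell at 6 months: the
published policy recommendation extends 6-month recall to the
medium-risk stratum whose own comparisons are non-significant, so
reproducing that table requires an explicit, audited departure from
the evidence rule.

## Synthetic cohorts

The generator emulates the study conditions end to end:

- 90/69/67 children in the low/medium/high strata (226 total), with
  sociodemographics drawn per stratum at the observed conditional
  frequencies;
- 126 surfaces per child, baseline states i.i.d. from the observed
  baseline distribution (97.54% sound, 1.81% code A, the remainder
  cavitated; no filled/missing surfaces at baseline, matching the
  baseline table);
- per-risk six-month Markov kernels over the 11 raw states, applied
  once per step.  The structural rates (severity progression 0.08,
  filling 0.03, extraction 0.004 per step on cavitated surfaces;
  small A→sound and rare cavity→sound reversals so the ADJCI
  adjustment is exercised) are fixed across strata; the incidence
  rates (sound→A, sound→cavity, A→cavity) increase strictly with risk
  and were calibrated once, by root-finding on the exact kernel-power
  expectation, so the plug-in expected stratum mean ADJCI at 18
  months matches the published means (low 0.18 / medium 0.70 / high
  1.95 at cutoff 3–6; 1.11 / 2.48 / 4.01 at A-6);
- attendance per visit with absorbing dropout, at rates fit to the
  observed attendance table (absence 2.7/11.2/5.9/0%, new dropout
  0/13.3/5.6/1.1% per visit).

`GroundTruth` carries each child's realized P/R/N per interval
(computed from the latent states, attendance notwithstanding) and the
kernel-implied expectations.  The plug-in expectation
S·p_P·p_N/(p_R+p_N) is exact up to the negligible P = S edge case,
since E[R/(S−P) | P] = p_R/(1−p_P) for the multinomial counts.

**What the generator does not emulate.** Surfaces evolve
independently within a mouth, so between-child variance is
binomial-small: simulated stratum SDs (≈0.3–1.5 surfaces) are well
below the published ones (≈0.6–4.3), and significance is reached
earlier than in the real cohort — in particular the simulated
medium-risk stratum triggers 6-month recall where the study's did
not.  A child-level lognormal frailty multiplier on progression rates
(`frailty_sd`, off by default; its scale is a free choice) adds
clustering for sensitivity analyses.  Risk is assigned, not derived:
the Cariogram itself (diet, plaque, fluoride inputs) is treated as a
black box.  Passing pipeline tests on these cohorts demonstrates
correctness of the machinery, not real-world effect sizes.

## Problem sizes and tolerances

The test suite runs the study-sized cohort (226 children) for
end-to-end checks, 1,000 children for conservation sweeps, a 10×
cohort (2,260 children, fixed seed) for parameter recovery within 3
Monte-Carlo SEs, and 1,000 null simulations of 60 children × 3 times
for the ANOVA type-I-error check (familywise post hoc rate ≤ α within
3 MC SEs).  Printed percentages use decimal round-half-up (1 decimal
for attendance/demographic tables, 2 for surface distributions) and
always re-derive from the counts beside them; where a published
percentage disagrees with its own printed counts (e.g. a high-risk
share of 29.7 vs 67/226 = 29.6), the count-derived value is reported.
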