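# Methods

This note documents the models and procedures implemented in `scanopt`,
the defaults and why they were chosen, and what the synthetic-data
generator does and does not emulate. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Data model and conventions

Time is float seconds and every interval is half-open `[start_s, end_s)`,
so per-animal behavior bouts and visibility spans tile a session without
ambiguity. Occurrence values are carried on the 0–100 percent scale
throughout (matching how such results are conventionally reported).

A **continuous record** (`SessionTimeline`) stores every bout and every
visibility span per animal. A **scan table** stores, per scan time, the
number of visible animals in each behavior; counts over behaviors sum to
the visible count, because each visible animal is in exactly one
behavioral state at an instant. A tidy **occurrence table**
(`session_id, method, behavior, value`) is the unit of all downstream
analysis.

Scan times follow the end-of-interval convention: `k·Δ` for
`k = 1..⌊T/Δ⌋`, giving 12 scans per 2-h session at Δ = 10 min, 8 at
15 min, 4 at 30 min and 24 at 5 min. With this anchor every 30-min scan
coincides with a 15-min and a 10-min scan when the intervals divide; a
study whose scans are anchored differently can set the `offset_s`
parameter. The state "at" a scan time t is the state of the half-open
interval containing t, with t = T resolving to the final bout, so the
boundary scan at the end of the session is well defined.

Two scan modes exist. `instantaneous` (default) reads each visible
animal's exact state at t — correct for simulated data, where the state is
known. `window_majority` emulates a human observer watching a short window
`[t − w, t]` (w = 10 s by default): an animal is counted when visible for
at least half the window and scored with the behavior occupying the
largest share of it, ties resolved toward the behavior active at t.

**Occurrence.** For scan data, a behavior's session value is the mean over
scans of `100·count/visible_count`. A scan with no visible animal is a 0/0
proportion; such scans are dropped from the mean and logged rather than
imputed as zero. For continuous data the value is
`100 · (visible animal-seconds in the behavior) / (total visible
animal-seconds)`; weighting by visibility makes the continuous value the
best any observation method could have attained. Under either method the
values over behaviors sum to 100.

## Synthetic flocks

Each animal is an independent renewal sequence: segment behaviors are
drawn i.i.d. with probability `w_b ∝ ρ_b / m_b` (ρ = target occupancy,
m = mean bout seconds) and segment durations are `Exponential(m_b)`;
adjacent identical segments merge into bouts. By the renewal-reward
theorem the long-run fraction of time in behavior b is exactly ρ_b in
expectation — the property that makes the configured time budget a usable
gold standard. Exponential durations are the maximum-entropy choice given
a mean; field data on bout-length distributions for this setting are not
available, so only the means are exposed as parameters.

Visibility is an independent alternating on/off renewal process with
configurable on-fraction (default 0.85, mean visible span 300 s). Because
it is independent of behavior, thinning by visibility leaves occurrence
unbiased — a property the tests check directly.

Group effects multiply the occupancy vector per behavior and renormalize,
i.e. they act on the same ratio scale on which the Tweedie GLM reports
effects, so a configured 2.0× factor is the estimand of the downstream
"OR".

The packaged preset (`table3_preset`) uses a 20-behavior free-range
broiler ethogram whose target occupancies span ~0.05%–31% of visible
animals, including one behavior (Sleeping) with an exactly zero budget so
the zero-variance paths downstream stay exercised. Default bout means are
a simulator choice, graded by behavioral class: resting/roosting postures
minutes (120–180 s), locomotion and feeding tens of seconds (15–60 s),
comfort and agonistic events seconds (8–40 s, dust bathing 120 s). The
defaults mirror the motivating study design: 50 animals per pen, 2-h
sessions.

What the generator does **not** emulate: diurnal or day-to-day rhythm (the
`day` label carries no effect), social contagion or any dependence between
animals, spatial structure, and observer error in the continuous record.
Consequently, passing tests demonstrate the statistical machinery under
known ground truth — not that any particular interval is adequate for a
given real husbandry system, where bout lengths and between-session
heterogeneity must come from the data.

## Reliability: intraclass correlation

Ratings matrices are subjects × raters (sessions × methods for
among-method agreement; scans for interobserver data). The two-way crossed
ANOVA without replication yields MS_rows, MS_cols, MS_error, from which
the classical forms are computed (n subjects, k raters):

- consistency, single: `(MSR − MSE) / (MSR + (k−1)·MSE)`
- absolute agreement, single: adds `k·(MSC − MSE)/n` to the denominator
- average-measure forms: `(MSR − MSE)/MSR` and
  `(MSR − MSE)/(MSR + (MSC − MSE)/n)`

Confidence bounds are the exact F-distribution bounds (Satterthwaite
degrees of freedom for the absolute-agreement case; Spearman–Brown step-up
for average measures), and the p-value is from `F = MSR/MSE` with
`(n−1, (n−1)(k−1))` df. When the single-measure lower bound falls below
the Spearman–Brown pole at `−1/(k−1)` the average-measure lower bound is
reported as −∞ rather than the spurious large value a naive evaluation
produces. A matrix with no between-subject variance (e.g. a behavior never
observed under any method) returns a result flagged
`undefined_reason = "zero variance"` instead of raising, and identical
columns give ICC = 1 with a degenerate (1, 1) interval.

Defaults: among-method agreement uses average measures with absolute
agreement — "agreement" is the question actually asked of the three
intervals — while consistency remains available because common SPSS
workflows default to it; the choice is a config flag and is echoed in the
output. Labels follow the poor/fair/good/excellent convention with
cut-points 0.40, 0.60 and 0.75 (upper class inclusive).

## Accuracy

**Reference selection.** Each candidate interval is scored against the
continuous values pooled over (session, behavior) pairs: R² of the OLS
regression of truth on candidate, MAE and RMSE of the raw differences. The
winner by majority of {max R², min MAE, min RMSE} becomes the reference;
a tie goes to the shortest interval (more scans can only add information),
and the tie-break is logged.

**Binning.** Behaviors are categorized on their mean reference occurrence:
low ≤ 0.49% < medium ≤ 3.50% < high, boundaries inclusive on the low
side. Catch-all behaviors flagged `excluded_from_binning` in the ethogram
are counted in occurrences but skipped here.

**Error scores** are signed raw differences in percentage points,
test-minus-reference, so negative means the longer interval
underestimates. (A relative variant would confound with the Bland–Altman
percent mode, so the raw definition is the default.) Category summaries
use t-based CIs and flag categories whose CI excludes zero. Error
distributions of two intervals are compared with the related-samples
Wilcoxon signed-rank test: zeros discarded before ranking, exact two-sided
p for n ≤ 25 when the |differences| are tie-free, otherwise the normal
approximation with continuity correction; an all-zero difference set is
vacuous and returns p = 1 with a warning.

**Bland–Altman.** Differences are reference-minus-comparison; the x-axis
is always the pair mean. Bias is the mean difference, the limits of
agreement are bias ± 1.96·SD (sample SD, ddof = 1). The 1.96 multiplier is
fixed; no small-sample t correction is applied, matching the conventional
definition. In percent mode differences are expressed relative to the
*reference* value (the best estimate of truth), not the pair mean — the
pair mean is also computable but the reference denominator answers "by
what fraction of the true value does the longer interval err". Pairs with
a zero reference value have no defined relative difference; they are
dropped and counted in `n_dropped` rather than silently imputed.

## Method-effect and group-effect inference

**Friedman test** across methods within sessions uses midranks and the
standard tie correction. For small tables (n ≤ 12 blocks, k ≤ 4 methods by
default) the p-value is exact: the tie pattern within a block is
permutation-invariant, so the permutation distribution of the rank-sum
statistic over all `(k!)^n` equally likely within-block orderings is
computed by dynamic programming over column rank sums (midranks doubled to
integers). Larger tables use the chi-square approximation with k−1 df. A
table whose blocks are all internally constant carries no information and
returns p = 1.

**Post hoc**: all pairwise Wilcoxon tests, p-values multiplied by the
number of comparisons (Bonferroni, capped at 1), summarized as a compact
letter display computed from the maximal cliques of the
non-significance graph (brute-force clique enumeration; k is small).

**Tweedie GLM.** Occurrence values are non-negative with exact zeros, so
they are modeled with a power-variance-function GLM, `V(μ) = μ^p` with
1 < p < 2, log link, fitted by IRLS (via statsmodels). The power is not
identifiable from the designs this package targets and is not profiled;
the default p = 1.5 sits mid-range and is configurable. Dispersion is
estimated by Pearson χ²/df; CIs are Wald on the ratio scale,
`exp(β ± 1.96·se)`. The exponentiated coefficient is a mean (rate) ratio;
the output labels it "OR" because that is the label used in the applied
literature this workflow serves. The sampling-day label enters as a fixed
numeric covariate — no working-correlation (GEE) or random-effect
structure is fitted, a deliberate simplification documented here. A group
whose responses are all zero has no finite log-mean and is rejected with a
pointer toward choosing a different behavior or variance power.

**Comparing effects between intervals** uses
`z = (β₁ − β₂)/√(se₁² + se₂²)` with a two-sided normal p. The test assumes
*independent* estimates; two intervals fit on the same sessions are
positively correlated, which makes the test conservative in that use. For
that reason the null-calibration experiment estimates the two coefficients
from independently simulated studies, where the independence assumption
holds and the rejection rate should sit at the nominal level.

## Pipeline

`run_pipeline` chains the stages (occurrences → reference → binning →
among-method ICC → Friedman/post hoc, error summaries, Bland–Altman raw
and percent → per-interval GLMs and effect comparisons) and records a
status per stage; a failing stage marks its dependents skipped with a
reason instead of aborting. The pipeline draws no random numbers, so a
bundle is a pure function of the config and timelines; provenance carries
a config hash, the seed and the package version, and re-running yields
hash-identical JSON. Every dropped datum (zero-visible scans,
zero-reference pairs, skipped GLMs) is logged at WARNING and exported to
`warnings.log`. By default the validity stage models one behavior per
occurrence category (the category's median behavior by reference
occurrence) — deterministic and representative; the set is configurable.

## Experiment protocols and problem sizes

The `experiments` module fixes the simulation protocols used by the tests
and the acceptance script. Sizes follow the motivating design (50 birds,
2-h sessions) unless the check targets a smaller flock:

- *recovery*: 10 sessions × 20 animals; continuous occurrence vs target,
  tolerances ±2 points for budgets ≥ 5% and ±0.5 below.
- *MAE ordering*: 50 replicate studies of 16 continuously scored sessions
  × 50 animals; fraction of replicates with MAE(10) < MAE(15) < MAE(30).
- *funnel*: one 10-session × 50-animal study; mean |percent difference|
  (10 vs 30 min) per occurrence category.
- *detection*: 100 replicate two-group studies (10 sessions/group, 50
  animals) with a 2.0× effect on Attacking; per-interval rejection rates
  of the group term at α = 0.05.
- *null calibration*: 100 pairs of independent null studies
  (8 sessions/group, 15 animals, Hiding at 10 min); rejection rate of the
  Altman–Bland z-test.

All child seeds derive deterministically from a single master seed via
`numpy.random.SeedSequence`, so identical configurations are bit-identical.

## Known limitations

- Independence across animals understates the variance of per-scan counts
  relative to socially synchronized flocks; among-method ICCs and GLM SEs
  on simulated data are correspondingly optimistic.
- The Bland–Altman percent mode divides by the reference value, which is
  itself noisy; for very rare behaviors the relative differences are
  heavy-tailed and the normal-theory LoA are descriptive rather than
  inferential.
- No repeated-measures correction is applied to limits of agreement
  computed from multiple sessions of the same pens.
- The Tweedie power is assumed, not estimated; conclusions about SEs at a
  mis-specified power inherit quasi-likelihood robustness but not
  efficiency.
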