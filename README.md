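# scanopt

Tools for choosing — and defending — a **scan-sampling interval** for group
behavioral observation.

In studies of group-housed animals (the motivating setting is free-range
broiler chickens, ~50 birds per pen scored from 2-h video sessions),
recording every behavior bout continuously is the gold standard but rarely
feasible. Instead observers *scan* the group every Δ minutes and count how
many visible animals are engaged in each ethogram behavior. The interval Δ
trades observer time against information, and there is no general rule for
picking it. `scanopt` implements a multistep workflow for making that
choice quantitative, plus a flock simulator that provides ground-truth
continuous records so every step can be validated end to end:

1. **Feasibility/accuracy screening** — compare candidate intervals with
   continuous scoring via the R² of the regression of true on sampled
   occurrence, the mean absolute error (MAE) and the root mean square error
   (RMSE); pick the reference interval by majority over the three criteria.
2. **Reliability** — two-way intraclass correlation coefficients
   (single/average measures, consistency or absolute agreement) with exact
   F-based 95% CIs, to quantify agreement among observers or among
   intervals.
3. **Accuracy** — behaviors binned into low (≤ 0.49%), medium (≤ 3.50%)
   and high occurrence; signed error scores with t-based category CIs,
   Friedman + Bonferroni-corrected Wilcoxon comparisons across intervals,
   and Bland–Altman agreement plots: bias = mean difference, limits of
   agreement = bias ± 1.96·SD of the differences, in raw percentage points
   or as a percent of the reference value.
4. **Validity** — occurrence of selected behaviors modeled per interval
   with a log-link Tweedie GLM (variance V(μ) = μ^p, 1 < p < 2, which
   tolerates exact zeros); group effects reported as mean ratios
   (conventionally labeled "OR"), and effects estimated under different
   intervals compared with the Altman–Bland z-test
   z = (β₁ − β₂)/√(se₁² + se₂²).

The simulator builds each animal as an independent renewal process:
segment behaviors are drawn with probability ∝ occupancy/mean-bout-length
and exponential durations, so by renewal-reward the long-run time budget
equals the configured occupancy exactly in expectation. Visibility is an
independent on/off renewal process, and group effects act multiplicatively
on the occupancy vector — the same ratio scale the GLM estimates. The
packaged preset reproduces a realistic free-range occurrence spectrum
spanning ~0.05% (Allo-grooming) to ~31% (Roosting) of visible animals.

## Worked example

`examples/04_validity_group_effects.py` simulates two groups of 50 birds
(10 sessions each) where group B attacks **2.0×** as often as group A, and
asks whether 10-min and 30-min scans support the same conclusion:

```
10min: OR(B vs A) = 1.444 (95% CI 1.021-2.041), p = 0.0376
30min: OR(B vs A) = 2.550 (95% CI 0.853-7.626), p = 0.0939

Altman-Bland comparison of the two effects: z = -0.97, p = 0.332
The simulated truth is a 2.0x mean ratio on Attacking occurrence.
```

Both intervals estimate an effect in the right direction, but only the
10-min scans (12 per session) detect it — the 30-min CI (4 scans per
session) is too wide to exclude a ratio of 1. That is the core practical
message for rare behaviors; `examples/03_accuracy_bland_altman.py` shows
the complementary Bland–Altman view, where the mean |percent difference|
between intervals funnels from ~111% for low-occurrence behaviors down to
~16% for high-occurrence ones, so long intervals remain acceptable when
only frequent behaviors matter.

The other examples cover simulation + sampling (`01`), among-method ICC
(`02`) and the one-call pipeline with report export (`05`). A thin CLI
mirrors the stages:

```bash
scanopt simulate --config sim.yaml --out timelines/
scanopt sample --timelines timelines/ --intervals 600,900,1800 --out scans/
scanopt run --timelines timelines/ --out report/
```

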