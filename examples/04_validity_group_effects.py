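"""Validity: does the interval change the estimated group effect?

Simulates a two-group study in which group B attacks twice as often as
group A, fits a log-link Tweedie GLM of the Attacking occurrence per
sampling interval, and compares the estimated effects between intervals
with the Altman–Bland z-test.  The short interval estimates the true mean
ratio (2.0) with a tighter CI; the long interval may fail to exclude 1.
"""

import pandas as pd

from scanopt import (
    GroupEffectConfig,
    GroupSpec,
    SamplingScheme,
    compare_effect_sizes,
    fit_tweedie_glm,
    occurrence_from_scans,
    scan_sample,
    simulate_study,
    table3_preset,
)

base = table3_preset(n_animals=50, seed=23)
study = GroupEffectConfig(
    base=base,
    groups=(GroupSpec("A"), GroupSpec("B", effects={"Attacking": 2.0})),
    sessions_per_group=10,
)
timelines = simulate_study(study)

fits = {}
for interval, label in ((600.0, "10min"), (1800.0, "30min")):
    rows = []
    for tl in timelines:
        occ = occurrence_from_scans(
            scan_sample(tl, SamplingScheme(interval_s=interval), base.ethogram)
        )
        rows.append(
            {"value": float(occ.loc[occ["behavior"] == "Attacking", "value"].iloc[0]),
             "group": tl.group, "day": tl.day}
        )
    fits[label] = fit_tweedie_glm(pd.DataFrame(rows))
    t = fits[label].term("group[B]")
    print(
        f"{label}: OR(B vs A) = {t['or']:.3f} "
        f"(95% CI {t['ci_low']:.3f}-{t['ci_high']:.3f}), p = {t['p']:.4f}"
    )

ta = fits["10min"].term("group[B]")
tb = fits["30min"].term("group[B]")
cmp = compare_effect_sizes(ta["coef"], ta["se"], tb["coef"], tb["se"],
                           pair=("10min", "30min"), behavior="Attacking")
print(
    f"\nAltman-Bland comparison of the two effects: z = {cmp.z:.2f}, p = {cmp.p_value:.3f}"
)
print("The simulated truth is a 2.0x mean ratio on Attacking occurrence.")
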