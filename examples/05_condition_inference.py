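"""Mixed-model comparison of recording conditions.

Simulates a summary table of fast-spindle densities for 20 subjects over
PRE/IN/POST conditions with a known inflight shift of +1.5 spindles/min,
fits the random-intercept linear mixed model

    density ~ Condition * Stage + Melatonin + (1 | subject)

and prints type-III F-tests, estimated marginal means and the
Tukey-adjusted pairwise condition contrasts.
"""

import numpy as np
import pandas as pd

from sleeposc import ModelSpec, fit_lmm, report_table

rng = np.random.default_rng(4)
rows = []
for s in range(20):
    intercept = rng.normal(0, 0.5)
    for cond in ("PRE", "IN", "POST"):
        mels = ("placebo",) if cond == "POST" else ("placebo", "active")
        for stage in ("N2", "N3"):
            for mel in mels:
                y = (2.5 + (1.5 if cond == "IN" else 0.0)
                     + (-0.8 if stage == "N3" else 0.0)
                     + intercept + rng.normal(0, 0.3))
                rows.append((f"S{s:02d}", cond, stage, mel, y))
table = pd.DataFrame(rows, columns=["subject_id", "condition", "stage",
                                    "melatonin", "value"])

res = fit_lmm(table, ModelSpec(response="fast_spindle_density"))
print("type-III F-tests (Satterthwaite dfs):")
print(res.anova.round(3).to_string(index=False))
print("\nestimated marginal means per condition:")
print(res.emms.round(3).to_string(index=False))
print("\nTukey-adjusted pairwise contrasts:")
print(report_table({"fast_spindle_density": res}).round(3).to_string(index=False))
print(f"\nShapiro-Wilk on conditional residuals: p = {res.shapiro_p:.3f}")
# the IN-PRE effect size should recover the simulated +1.5 shift within
# its confidence interval
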