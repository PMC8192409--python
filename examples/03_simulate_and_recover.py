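"""Simulate a cohort with known truth and check parameter recovery.

Generates 16 runners with true (CS, d') drawn from cohort-typical
distributions, trials at 90-120% of peak speed with Var(t) ~ t noise,
fits the statistically appropriate t(s)-WLS procedure, and measures how
well the known true parameters are recovered.
"""

import numpy as np

from critspeed import CohortConfig, fit, generate_cohort
from critspeed.fitting import FittingProcedure, ModelVariant, Regression

TS_WLS = FittingProcedure(ModelVariant.T_OF_S, Regression.WLS)

config = CohortConfig(n_subjects=16, noise_cv=0.05, seed=42)
sim = generate_cohort(config)
truth = sim.truth.set_index("subject_id")

rows = []
for subj in sim.subjects:
    res = fit(subj, TS_WLS)
    cs_t = truth.loc[subj.subject_id, "true_cs_mps"]
    dp_t = truth.loc[subj.subject_id, "true_dprime_m"]
    rows.append((subj.subject_id, cs_t, res.params.cs, dp_t, res.params.d_prime))

print(f"{'subject':<8} {'CS true':>8} {'CS fit':>8} {'d_ true':>8} {'d_ fit':>8}")
for sid, cs_t, cs_f, dp_t, dp_f in rows[:5]:
    print(f"{sid:<8} {cs_t:8.3f} {cs_f:8.3f} {dp_t:8.1f} {dp_f:8.1f}")
print("...")

rel_cs = [(r[2] - r[1]) / r[1] for r in rows]
rel_dp = [(r[4] - r[3]) / r[3] for r in rows]
print(
    f"\nmedian relative error: CS {100 * np.median(rel_cs):+.2f}%, "
    f"d' {100 * np.median(rel_dp):+.2f}%  (n = {len(rows)} runners)"
)
print(
    "With 5% CV noise on the ~6-min trial the appropriate WLS fit recovers\n"
    "CS to well under a percent; d' is harder (it is the curvature of only\n"
    "four points) and scatters more."
)
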