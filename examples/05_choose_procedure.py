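"""Which fitting procedure is statistically appropriate for my protocol?

The answer depends only on which variable the protocol fixes (speed,
distance, or time): the error-carrying variable must sit on the vertical
axis and the fixed one on the horizontal axis.  The selector classifies
all six directed model forms for each design.
"""

import pandas as pd

from critspeed import ExperimentDesign, Variable, recommend

for fixed in (Variable.SPEED, Variable.DISTANCE, Variable.TIME):
    rec = recommend(ExperimentDesign(fixed_variable=fixed))
    print(f"\n=== protocol fixes {fixed.value} ===")
    print(pd.DataFrame(rec.as_table())[["form", "status", "weight_target"]]
          .to_string(index=False))

print("\n=== fixed power, extremely high, on an ergometer ===")
rec = recommend(
    ExperimentDesign(fixed_variable=Variable.SPEED, extreme_power_context=True)
)
print(pd.DataFrame(rec.as_table())[["form", "status"]].to_string(index=False))
print(
    "\nEvery design has exactly two WLS-appropriate forms, two with the\n"
    "wrong dependent variable, and two endogenous forms (correlated errors\n"
    "on both axes) for which no regression method exists."
)
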