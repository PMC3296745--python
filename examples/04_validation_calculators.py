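"""Orthogonal-validation arithmetic: qPCR copy number and FISH ratios.

The qPCR rule: normalize the target assay by the reference assay, divide
by the median normalized value of the controls, multiply by 2 (controls
are diploid).  The FISH rule: mean target signals over mean control
signals across scored nuclei.
"""

import numpy as np
import pandas as pd

from dosagescan import validation_calc

rng = np.random.default_rng(1)

rows = []
for _ in range(3):  # triplicate measurements of a line at 4 copies
    ref = rng.lognormal(0, 0.05)
    rows.append(("line", 2.0 * ref * rng.lognormal(0, 0.05), ref, False))
for c in range(10):
    for _ in range(3):
        ref = rng.lognormal(0, 0.05)
        rows.append((f"ctrl{c}", ref * rng.lognormal(0, 0.05), ref, True))
qpcr = pd.DataFrame(rows, columns=["sample_id", "target", "reference",
                                   "is_control"])
cn = validation_calc.qpcr_copy_number(qpcr)
print(f"cell line copy number: {cn['line']:.2f} (planted 4)")
print(f"control median copy number: "
      f"{cn[[f'ctrl{c}' for c in range(10)]].median():.2f} (diploid = 2)")

control = rng.poisson(2.0, 30) + 1
target = rng.poisson(2.3 * control.mean(), 30)
fish = pd.DataFrame({"target_signals": target, "control_signals": control})
print(f"FISH signal ratio: {validation_calc.fish_signal_ratio(fish):.2f} "
      f"(planted 2.3)")
# A ratio near 2.3 over >= 20 nuclei is the cytogenetic confirmation that
# the target band carries roughly twice the control band's copy number.
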