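#!/usr/bin/env python
"""Assay arithmetic on constructed validation-style tables.

Emulates the downstream bench readouts: qRT-PCR relative quantification
(2^-ddCt against a calibrator group) and dual-luciferase reporter ratios
(hluc/hRluc normalized to the negative-control treatment per construct),
with the wild-type + mimic group constructed at half the NC signal the way
a functional miRNA binding site behaves.
"""

import pandas as pd

import study
from cernapipe import assays

# qRT-PCR: target gene vs U6 reference across developmental groups
rows = []
for sample, group, tct, rct in (
    ("N1", "newborn", 24.0, 18.0),
    ("N2", "newborn", 25.0, 19.0),
    ("W1", "weaning", 23.5, 18.2),
    ("W2", "weaning", 23.9, 18.6),
    ("M6-1", "sixmonth", 22.8, 18.9),
    ("M6-2", "sixmonth", 23.2, 19.1),
):
    rows += [(sample, group, "target-gene", "target", tct + d) for d in (-0.1, 0.0, 0.1)]
    rows += [(sample, group, "U6", "reference", rct + d) for d in (-0.1, 0.0, 0.1)]
ct = pd.DataFrame(rows, columns=["sample", "group", "gene", "role", "ct"])
quant = assays.ddct(ct, calibrator="newborn")
summary = assays.ddct_group_summary(quant)
quant.to_csv(study.RESULTS / "06_ddct_quant.csv", index=False)
summary.to_csv(study.RESULTS / "06_ddct_groups.csv", index=False)
print("2^-ddCt relative expression (calibrator: newborn):")
print(summary.to_string(index=False))

# dual-luciferase: WT construct responds to the mimic, the mutant does not
luc = pd.DataFrame(
    [
        ("WT", "NC", 10.0, 5.0),
        ("WT", "NC", 12.0, 6.0),
        ("WT", "mimic", 5.0, 5.0),
        ("WT", "mimic", 6.0, 6.0),
        ("WT", "inhibitor", 10.5, 5.2),
        ("MT", "NC", 9.0, 4.5),
        ("MT", "mimic", 9.2, 4.6),
        ("MT", "inhibitor", 8.8, 4.4),
    ],
    columns=["construct", "treatment", "hluc", "hrluc"],
)
act = assays.luc_ratio(luc)
act_summary = assays.luc_group_summary(act)
act.to_csv(study.RESULTS / "06_luciferase_activity.csv", index=False)
print("\ndual-luciferase normalized activity (NC = 1 per construct):")
print(act_summary.to_string(index=False))
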