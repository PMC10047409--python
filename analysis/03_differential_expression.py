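#!/usr/bin/env python
"""Stage-wise differential expression, temporal profiles and DE-set overlap.

Runs the exact NB test on the miRNA matrix for the three pairwise stage
comparisons (p <= 0.05, |log2FC| >= 1), classifies temporal profiles,
computes the three-way Venn overlap of the DE sets and merges
sequence-identical matures in the core set.
"""

import pandas as pd

import study
from cernapipe import diffexp, pipeline

refs, truth, mirna_cm, _ = study.build_study()
factors = diffexp.normalize(mirna_cm)
de = pipeline.differential_expression(mirna_cm, factors=factors)

summary_rows = []
de_sets = {}
for comp, table in de.items():
    sig = table[table["significant"]]
    de_sets[comp] = set(sig["feature"])
    truth_dirs = {
        f: lab["directions"].get(comp, "none") for f, lab in truth.de_labels.items()
    }
    planted_here = {f for f, d in truth_dirs.items() if d != "none" and f in set(table["feature"])}
    recovered = len(de_sets[comp] & planted_here)
    summary_rows.append(
        {
            "comparison": comp,
            "n_up": int((sig["direction"] == "up").sum()),
            "n_down": int((sig["direction"] == "down").sum()),
            "n_planted_de": len(planted_here),
            "n_planted_recovered": recovered,
        }
    )
    table[table["significant"]].to_csv(
        study.RESULTS / f"03_de_mirnas_{comp}.tsv", sep="\t", index=False
    )

summary = pd.DataFrame(summary_rows)
summary.to_csv(study.RESULTS / "03_de_summary.tsv", sep="\t", index=False)
print(summary.to_string(index=False))

profiles = diffexp.classify_profiles(mirna_cm, factors)
counts = profiles.value_counts()
counts.rename_axis("profile").to_frame("n_features").to_csv(
    study.RESULTS / "03_profile_counts.tsv", sep="\t"
)
print("\ntemporal profile counts:")
print(counts.to_string())

venn = diffexp.venn_overlap(de_sets)
core = sorted(venn.core)
seqs = refs.mirna_seqs
merged, aliases = diffexp.merge_duplicate_matures(core, seqs)
venn.membership().to_csv(study.RESULTS / "03_venn_membership.tsv", sep="\t", index=False)
print(f"\nDE miRNAs overlapping all three comparisons: {len(core)}")
print(f"after merging sequence-identical matures: {len(merged)} "
      f"({sum(len(a) for a in aliases.values())} aliases removed)")
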