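#!/usr/bin/env python
"""Generate the synthetic study: references, ground truth, counts and reads.

Writes the count-level study (200 miRNAs / 300 lncRNAs / 2,000 mRNA 3'UTRs,
50 planted sponge triplets) and a reduced-depth read-level emulation.
Bulky artefacts (FASTA/FASTQ/count matrices) go to scratch/sim; a small
design summary goes to results/.
"""

import json

import study
from cernapipe import simdata

out = study.SCRATCH / "sim"
out.mkdir(parents=True, exist_ok=True)

refs, truth, mirna_cm, tx_cm = study.build_study()
refs.write_fasta(out / "references")
truth.to_json(out / "truth.json")
study.STUDY.to_json(out / "config.json")
mirna_cm.to_tsv(out / "mirna_counts.tsv", out / "samples.tsv")
tx_cm.to_tsv(out / "transcript_counts.tsv", out / "samples.tsv")

read_refs, read_truth = simdata.build_reference(study.READ_STUDY)
read_cm, _ = simdata.simulate_counts(study.READ_STUDY, read_truth)
read_refs.write_fasta(out / "read_references")
read_cm.to_tsv(out / "read_mirna_counts.tsv", out / "read_samples.tsv")
manifest = simdata.simulate_reads(study.READ_STUDY, read_refs, read_cm, out / "reads")

shapes = {}
for label in truth.de_labels.values():
    shapes[label["shape"]] = shapes.get(label["shape"], 0) + 1
summary = {
    "stages": mirna_cm.stages,
    "samples": list(mirna_cm.counts.columns),
    "n_mirna": len(truth.mirna_names),
    "n_lncrna": len(truth.lncrna_names),
    "n_mrna": len(truth.mrna_names),
    "n_planted_de_features": len(truth.de_labels),
    "planted_shape_counts": shapes,
    "n_planted_sites": len(truth.planted_sites),
    "n_planted_triplets": len(truth.planted_triplets),
    "read_level_samples": {s: info["n_reads"] for s, info in manifest.items()},
}
study.RESULTS.mkdir(exist_ok=True)
(study.RESULTS / "01_study_design.json").write_text(json.dumps(summary, indent=1) + "\n")

print(f"count-level study: {summary['n_mirna']} miRNAs, "
      f"{summary['n_lncrna']} lncRNAs, {summary['n_mrna']} mRNA 3'UTRs")
print(f"planted: {summary['n_planted_de_features']} DE features "
      f"({shapes}), {summary['n_planted_sites']} seed sites, "
      f"{summary['n_planted_triplets']} sponge triplets")
print(f"read-level emulation: {sum(summary['read_level_samples'].values())} reads "
      f"over {len(manifest)} libraries -> {out / 'reads'}")
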