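"""Shared study definition for the numbered analysis drivers.

One synthetic three-stage embryonic-muscle small-RNA study (D85/D105/D135,
three replicates each) with 50 planted sponge triplets; everything is
regenerated deterministically from the seed, so each driver can run
stand-alone.
"""

from pathlib import Path

from cernapipe import simdata

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

SEED = 1

#: count-level study at full scale
STUDY = simdata.SimulationConfig(seed=SEED)

#: read-level emulation at reduced depth (~30k reads per library) so the
#: FASTQ stage stays light; counts and reads are separate deterministic draws
READ_STUDY = simdata.SimulationConfig(
    seed=SEED,
    n_mirna=60,
    n_lncrna=10,
    n_mrna=20,
    frac_de=0.3,
    n_triplets=5,
    lib_size_range=(25_000, 40_000),
    contaminant_frac=0.10,
)


def build_study(config=STUDY):
    refs, truth = simdata.build_reference(config)
    mirna_cm, tx_cm = simdata.simulate_counts(config, truth)
    return refs, truth, mirna_cm, tx_cm
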