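import numpy as np
import pandas as pd
import pytest

from cernapipe import simdata
from cernapipe.containers import CountMatrix


@pytest.fixture(scope="session")
def small_config():
    """Small but complete study: 3 stages x 3 replicates, planted triplets."""
    return simdata.SimulationConfig(
        seed=11,
        n_mirna=40,
        n_lncrna=30,
        n_mrna=120,
        frac_de=0.3,
        n_triplets=8,
        lib_size_range=(20_000, 40_000),
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    refs, truth = simdata.build_reference(small_config)
    mirna_cm, tx_cm = simdata.simulate_counts(small_config, truth)
    return refs, truth, mirna_cm, tx_cm


@pytest.fixture(scope="session")
def small_reads(small_config, small_sim, tmp_path_factory):
    refs, truth, mirna_cm, _ = small_sim
    outdir = tmp_path_factory.mktemp("reads")
    manifest = simdata.simulate_reads(small_config, refs, mirna_cm, outdir)
    return manifest


def make_count_matrix(columns, stages, features=None):
    """Small CountMatrix from explicit columns (dict sample -> counts)."""
    counts = pd.DataFrame(columns)
    if features is not None:
        counts.index = features
    meta = pd.DataFrame(
        {
            "stage": stages,
            "replicate": list(range(1, len(stages) + 1)),
        },
        index=counts.columns,
    )
    return CountMatrix(counts.astype(np.int64), meta)
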