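import numpy as np
import pandas as pd
import pytest

from stemsig import synthetic_data as sd
from stemsig import scrna_pipeline as sc


def small_config(seed: int = 0) -> sd.SimConfig:
    """Down-scaled study conditions for fast unit tests."""
    pops = [
        sd.PopulationSpec("LSC", list(range(0, 50)), 2.0, (0.71, 0.19, 0.10)),
        sd.PopulationSpec(
            "Transition",
            list(range(25, 50)) + list(range(50, 75)),
            2.0,
            (0.57, 0.28, 0.15),
        ),
        sd.PopulationSpec("Blast", list(range(50, 100)), 2.0, (0.43, 0.37, 0.20)),
    ]
    return sd.SimConfig(
        seed=seed,
        n_genes=600,
        n_cells_per_population=120,
        populations=pops,
        s_gene_indices=list(range(300, 330)),
        g2m_gene_indices=list(range(330, 360)),
        bulk_groups=[
            sd.BulkGroupSpec("LSC", 3, list(range(0, 50)), 2.0),
            sd.BulkGroupSpec("Blast", 3, list(range(50, 100)), 2.0),
        ],
    )


@pytest.fixture(scope="session")
def cfg_small():
    return small_config()


@pytest.fixture(scope="session")
def sc_raw(cfg_small):
    return sd.gen_sc_counts(cfg_small)


@pytest.fixture(scope="session")
def sc_processed(sc_raw):
    """QC'd, normalized, cycle-scored, clustered small dataset."""
    a = sc.log_normalize(sc.qc_filter(sc_raw))
    a = sc.score_cell_cycle(
        a, a.uns["sim"]["s_genes"], a.uns["sim"]["g2m_genes"], seed=0
    )
    return sc.regress_scale_cluster(a, n_pcs=20, seed=0)


@pytest.fixture(scope="session")
def landscape():
    return sd.gen_peak_landscape(sd.SimConfig(seed=5))


@pytest.fixture(scope="session")
def bulk_small(cfg_small):
    table, truth = sd.gen_bulk_expression(cfg_small)
    return table, truth
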