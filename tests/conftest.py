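import numpy as np
import pandas as pd
import pytest

import heteroclust as hc

THRESHOLDS = {"t_label": 100.0, "tumour_label": 100.0, "specific_marker": 100.0}


@pytest.fixture(scope="session")
def competition_table():
    events, truth = hc.gen_competition_events(
        n_tumour=4000, n_t=4000, input_specific_fraction=0.2,
        planted_fold_change=2.0, cluster_fraction=0.2, seed=11,
    )
    return events, truth


@pytest.fixture(scope="session")
def sc_dataset():
    truth = hc.default_sc_truth(n_de_genes=30, de_log2fc=2.0)
    ds, tcr = hc.gen_sc_dataset(4, 1200, 400, sc_truth=truth, seed=7)
    return ds, tcr, truth


@pytest.fixture(scope="session")
def synapse_images():
    return hc.gen_synapse_images(12, 2, 0.5, seed=3)


@pytest.fixture(scope="session")
def centroid_table():
    return hc.gen_centroid_table(1500, niche_fraction=0.3, seed=5)


@pytest.fixture(scope="session")
def lr_table():
    return hc.gen_lr_tables(60, seed=4)
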