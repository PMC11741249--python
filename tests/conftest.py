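import numpy as np
import pandas as pd
import pytest

from tmatlas.qc import QCThresholds, apply_qc, cluster_cells, normalize_log_cp10k
from tmatlas.simulate import SimConfig, generate_count_matrix


@pytest.fixture(scope="session")
def small_sim():
    """Small planted limbal dataset shared across test modules."""
    cfg = SimConfig(n_cells_per_class=80, n_genes=600, seed=3)
    cm, truth = generate_count_matrix(cfg)
    return cfg, cm, truth


@pytest.fixture(scope="session")
def small_norm(small_sim):
    _, cm, truth = small_sim
    filtered, _ = apply_qc(cm, QCThresholds())
    norm = normalize_log_cp10k(filtered)
    return norm, truth


@pytest.fixture(scope="session")
def small_clusters(small_norm):
    norm, truth = small_norm
    labels = cluster_cells(norm, resolution=0.3, seed=0)
    return norm, truth, labels
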