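import numpy as np
import pytest

from bnpcp.io_tables import QuantTable
from bnpcp.synthetic_data import default_truth, simulate_table

BAIT = "SYN0001"
FLAT_IDS = ["SYN0002", "SYN0003", "SYN0004", "SYN0005", "SYN0006", "SYN0007", "SYN0008", "SYN0012"]
ENRICHED_IDS = ["SYN0009", "SYN0010", "SYN0011"]
ENTITY2_ONLY_IDS = ["SYN0013", "SYN0014"]
ENTITY1_ONLY_IDS = ["SYN0015"]
BOTH_PARTNER_IDS = ["SYN0012"]


@pytest.fixture
def noiseless_truth():
    return default_truth(seed=0, noise_cv=0.0, dropout_rate=0.0)


@pytest.fixture
def noiseless_table(noiseless_truth):
    return simulate_table(noiseless_truth, 1)


@pytest.fixture
def small_table():
    """A 3-protein, 4-fraction table with one flagged record."""
    return QuantTable(
        protein_ids=["P1", "P2", "P3"],
        gene_names=["G1", "G2", "G3"],
        intensity=np.array(
            [[0.0, 2.0, 2.0, 0.0], [1.0, 1.0, 1.0, 1.0], [0.0, 0.0, 0.0, 0.0]]
        ),
        ibaq=np.array(
            [[0.0, 1.0, 1.0, 0.0], [0.5, 0.5, 0.5, 0.5], [0.0, 0.0, 0.0, 0.0]]
        ),
        flag_contaminant=np.array([False, False, False]),
        flag_reverse=np.array([False, True, False]),
        flag_only_by_site=np.array([False, False, False]),
        fraction_labels=["1", "2", "3", "4"],
    )
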