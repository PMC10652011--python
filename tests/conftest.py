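import numpy as np
import pandas as pd
import pytest

from crcisc.synthetic import (ScSimConfig, TcrSimConfig, simulate_sc_expression,
                              simulate_tcr_repertoire)


@pytest.fixture(scope="session")
def sc_cells():
    """2,000 simulated cells with the canonical MSI planted modules."""
    return simulate_sc_expression(ScSimConfig(n_patients=8,
                                              cells_per_patient=250, seed=7))


@pytest.fixture(scope="session")
def tcr_data():
    """Default repertoire: 150 planted clonotypes, exact reference matches."""
    return simulate_tcr_repertoire(TcrSimConfig(seed=7))


@pytest.fixture()
def toy_expression():
    """4 cells x 5 genes with hand-set values (includes an all-zero gene)."""
    return pd.DataFrame(
        [[0.0, 0.5, 1.0, 0.0, 2.0],
         [0.1, 0.0, 0.3, 0.0, 1.5],
         [0.4, 0.9, 0.0, 0.0, 0.1],
         [0.0, 0.3, 0.6, 0.0, 0.05]],
        index=[f"c{i}" for i in range(4)],
        columns=["g1", "g2", "g3", "g4", "IFNG"])


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
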