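import numpy as np
import pytest

from dualeb import ExpressionDataset, SimConfig, simulate_tissue_pair


@pytest.fixture(scope="session")
def default_pair():
    """One paired-tissue draw at the default study design (3000 x 16)."""
    return simulate_tissue_pair(SimConfig(seed=7))


@pytest.fixture(scope="session")
def small_pair():
    """A lighter paired draw for pipeline tests that refit repeatedly."""
    cfg = SimConfig(n_genes=600, n_de=20, seed=3)
    return simulate_tissue_pair(cfg)


@pytest.fixture()
def toy_dataset():
    """3 genes x 4 samples with hand-set values and balanced labels."""
    X = np.array(
        [
            [1.0, 2.0, 3.0, 4.0],
            [5.0, 5.5, 6.5, 7.0],
            [2.0, 1.0, 4.0, 3.0],
        ]
    )
    return ExpressionDataset(
        gene_ids=["Alpl", "Cirbp", "Eno1b"],
        sample_ids=["m1", "m2", "m3", "m4"],
        X=X,
        y=np.array([0, 0, 1, 1]),
        tissue="spinal",
    )
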