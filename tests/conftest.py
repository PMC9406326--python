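import numpy as np
import pytest

from cvfair.synthetic_data import load_paper_fold_table

DATASET_IDS = ("ISIC2017", "PH2", "PASCAL")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def fold_tables():
    """All six published fold tables keyed by (dataset_id, structure_id)."""
    return {
        (ds, st): load_paper_fold_table(ds, st)
        for ds in DATASET_IDS
        for st in ("complex", "real")
    }
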