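import numpy as np
import pandas as pd
import pytest

from pfp.io import ProteomeDB


@pytest.fixture
def small_proteome() -> ProteomeDB:
    """Three-gene proteome: canonical, isoform and Ribo-seq entries."""
    db = ProteomeDB()
    db.add("P00001", "MSTKAGLRVPEDFKWENQKRMATSLLKGERPDAAKYVR", "canonical", "GENEA")
    db.add("P00001-2", "MSTKAGLRVPEDFKWENQKR", "isoform", "GENEA")
    db.add("P00002", "MLVDKAGERPLMQSTWFYENRKKAAGDERPLVVMSTK", "canonical", "GENEB")
    db.add("ENST0001", "MAGTKQERPLDNWFYVKSTR", "riboseq", "GENEC")
    return db


@pytest.fixture
def feature_frame() -> pd.DataFrame:
    return pd.DataFrame([
        {"accession": "P00001", "feature_type": "signal", "start": 1, "end": 22,
         "label": "signal peptide"},
        {"accession": "P00001", "feature_type": "domain", "start": 25, "end": 35,
         "label": "kinase domain"},
        {"accession": "P00002", "feature_type": "coiled_coil", "start": 5, "end": 20,
         "label": "coiled coil"},
    ])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
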