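import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from lrxtalk import (
    CellAnnotation,
    ExpressionMatrix,
    LRPairTable,
    default_config,
    generate_dataset,
)
from lrxtalk.lr_resource import LRPair


@pytest.fixture
def tiny_matrix():
    """3 genes x 2 cells with entries (g1,c1)=5, (g3,c2)=2."""
    counts = sp.csr_matrix(np.array([[5, 0], [0, 0], [0, 2]]))
    return ExpressionMatrix(counts, ["g1", "g2", "g3"], ["c1", "c2"])


@pytest.fixture
def small_pairs():
    return LRPairTable(
        [
            LRPair("Thbs1", "Scarb1", "scavenger"),
            LRPair("Apoe", "Scarb1", "scavenger"),
            LRPair("Dll4", "Notch1", None),
        ],
        source_name="fixture",
    )


def make_annotation(records):
    """records: list of (barcode, crude, subtype, timepoint)."""
    df = pd.DataFrame(
        records, columns=["barcode", "crude_type", "subtype", "timepoint"]
    ).set_index("barcode")
    return CellAnnotation(df)


@pytest.fixture
def small_dataset():
    """Small generated dataset shared by aggregation/marker tests."""
    cfg = default_config(seed=7, n_cells_per_timepoint=300, n_genes=40)
    return cfg, *generate_dataset(cfg)


@pytest.fixture
def fixture_dir(tmp_path):
    """On-disk synthetic fixture triple + annotation + pairs."""
    from lrxtalk import write_dataset

    cfg = default_config(seed=11, n_cells_per_timepoint=250, n_genes=40)
    write_dataset(cfg, tmp_path)
    return cfg, tmp_path
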