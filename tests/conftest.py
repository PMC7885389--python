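import numpy as np
import pandas as pd
import pytest

from cox2prio.cohortio import (
    ClinicalTable,
    CopyNumberTable,
    ExpressionMatrix,
)


@pytest.fixture
def tiny_expr() -> ExpressionMatrix:
    """3 genes x 4 samples with hand-picked FPKM values."""
    return ExpressionMatrix(pd.DataFrame(
        {
            "S1": [0.0, 3.0, 7.0],
            "S2": [3.0, 3.0, 15.0],
            "S3": [15.0, 3.0, 31.0],
            "S4": [1.0, 3.0, 63.0],
        },
        index=["GA", "GB", "GC"],
    ))


@pytest.fixture
def tiny_clinical() -> ClinicalTable:
    return ClinicalTable(pd.DataFrame(
        {
            "ER": ["negative", "negative", "positive", "negative"],
            "PR": ["negative", "negative", "negative", "unknown"],
            "HER2": ["negative", "positive", "negative", "negative"],
            "PAM50": ["Basal", "HER2E", "LumA", "Basal"],
            "OS_time": [12.0, 30.0, 55.0, 20.0],
            "OS_event": [1, 0, 1, 1],
            "DMFS_time": [10.0, 28.0, 50.0, 18.0],
            "DMFS_event": [1, 0, 0, 1],
        },
        index=pd.Index(["S1", "S2", "S3", "S4"], name="sample"),
    ))


@pytest.fixture
def tiny_cna() -> CopyNumberTable:
    return CopyNumberTable(pd.DataFrame(
        {
            "S1": [2, 0, -1],
            "S2": [0, 1, 0],
            "S3": [2, 0, 0],
            "S4": [0, -2, 2],
        },
        index=["GA", "GB", "GC"],
    ))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
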