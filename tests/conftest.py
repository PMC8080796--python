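"""Shared fixtures and deterministic hypothesis configuration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from metabostage import FeatureMatrix, SampleMetadata

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


def make_feature_matrix(
    values, qc_interval=None, is_qc=None, batch=None, **kwargs
):
    """Build a FeatureMatrix from a 2-D array with simple run annotations."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if is_qc is None:
        if qc_interval:
            is_qc = np.array([(i % qc_interval) == 0 for i in range(n)])
        else:
            is_qc = np.zeros(n, dtype=bool)
    ids = [
        f"QC{i:03d}" if q else f"S{i:03d}" for i, q in enumerate(is_qc)
    ]
    cols = [f"F{j + 1:04d}" for j in range(values.shape[1])]
    return FeatureMatrix(
        pd.DataFrame(values, index=ids, columns=cols),
        np.arange(1, n + 1),
        np.full(n, "B1") if batch is None else batch,
        is_qc,
        **kwargs,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_metadata():
    return SampleMetadata(
        pd.DataFrame(
            {
                "stage": ["SCAD", "UA", "MI", "UA", "MI", "SCAD"],
                "age": [60, 65, 58, 70, 62, 55],
                "sex": [1, 0, 1, 1, 1, 0],
                "hypertension": [1, 1, 0, 1, 0, 0],
                "diabetes": [0, 1, 0, 0, 1, 0],
                "smoking": [0, 0, 1, 1, 0, 0],
                "LDLC": [2.5, 3.1, 2.0, 2.8, 2.2, 2.6],
                "HDLC": [1.0, 0.9, 0.8, 1.1, 0.7, 1.2],
                "TG": [1.4, 1.8, 1.2, 2.0, 1.5, 1.1],
            },
            index=[f"S{i:03d}" for i in range(1, 7)],
        )
    )
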