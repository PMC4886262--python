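import numpy as np
import pandas as pd
import pytest

import serumvar as sv
from serumvar.synthetic import STATUS_MEASURED


@pytest.fixture(scope="session")
def default_spec():
    return sv.build_effect_spec(seed=11)


@pytest.fixture(scope="session")
def discovery_cohort(default_spec):
    """Discovery-scale cohort: generated, degraded and preprocessed once."""
    sizes = {"discovery": sv.default_sizes()["discovery"]}
    matrix, meta = sv.generate_cohort(default_spec, sizes, seed=11)
    matrix, meta = sv.degrade(matrix, meta, default_spec, n_plates=5, seed=11)
    data, meta, report = sv.preprocess_pipeline(matrix, meta, seed=11)
    return data, meta, report


def make_matrix(values: np.ndarray, status: np.ndarray | None = None,
                prefix: str = "A") -> sv.AnalyteMatrix:
    """Wrap a raw array (and optional status array) as an AnalyteMatrix."""
    n, d = values.shape
    idx = pd.Index([f"S{i:04d}" for i in range(n)], name="sample_id")
    cols = [f"{prefix}{j:03d}" for j in range(d)]
    vals = pd.DataFrame(values, index=idx, columns=cols)
    if status is None:
        stat = pd.DataFrame(STATUS_MEASURED, index=idx, columns=cols)
    else:
        stat = pd.DataFrame(status, index=idx, columns=cols)
    vals = vals.where(stat == STATUS_MEASURED)
    return sv.AnalyteMatrix(vals, stat)


@pytest.fixture
def make_analyte_matrix():
    return make_matrix
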