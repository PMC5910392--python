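import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from miratio.io_qc import PanelCqTable

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def make_table(cq_rows, assays, groups, dataset="discovery", sample_ids=None):
    """Build a PanelCqTable from a list of per-sample Cq rows (NaN = undetected)."""
    cq = np.asarray(cq_rows, dtype=float)
    n = cq.shape[0]
    if sample_ids is None:
        sample_ids = [f"S{i + 1:02d}" for i in range(n)]
    idx = pd.Index(sample_ids, name="sample_id")
    detected = pd.DataFrame(np.isfinite(cq), index=idx, columns=assays)
    meta = pd.DataFrame({"group": groups, "dataset": dataset}, index=idx)
    return PanelCqTable(
        cq=pd.DataFrame(cq, index=idx, columns=assays), detected=detected, meta=meta
    )


@pytest.fixture
def toy_table():
    """3 samples x 4 assays, QC markers included, one undetected entry."""
    assays = ["hsa-miR-23a-3p", "hsa-miR-451a", "hsa-miR-16-5p", "hsa-miR-21-5p"]
    cq = [
        [20.0, 14.0, 25.0, 30.0],
        [25.0, 17.0, 26.0, 31.0],
        [21.0, 15.0, np.nan, 29.0],
    ]
    return make_table(cq, assays, ["SCC", "HD", "HD"])
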