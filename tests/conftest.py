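import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from woundmetab.datamodel import FeatureMeta, FeatureTable, SampleMeta

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_table(values, qc_orders=(), study_orders=(), days=None, treatments=None,
               wound_type="DPT", modes=None):
    """Small handcrafted FeatureTable: QC columns first, then study columns."""
    values = np.asarray(values, dtype=float)
    n_f, n_s = values.shape
    assert n_s == len(qc_orders) + len(study_orders)
    samples = [
        SampleMeta(f"QC{i}", o, "QC") for i, o in enumerate(qc_orders, 1)
    ]
    days = days or [7] * len(study_orders)
    treatments = treatments or ["AFSG"] * len(study_orders)
    samples += [
        SampleMeta(f"S{i}", o, "study", pig_id=f"P{i}", wound_type=wound_type,
                   treatment=treatments[i - 1], day=days[i - 1])
        for i, o in enumerate(study_orders, 1)
    ]
    modes = modes or ["pos"] * n_f
    features = [FeatureMeta(f"F{i}", 100.0 + i, 5.0, modes[i - 1]) for i in range(1, n_f + 1)]
    return FeatureTable(values, features, samples)


@pytest.fixture
def tiny_table():
    """3 features x (1 QC + 3 study) toy table."""
    return make_table(
        [[10, 1, 2, 3], [20, 4, 5, 6], [30, 7, 8, 9]],
        qc_orders=[7], study_orders=[1, 2, 3],
        days=[7, 14, 21],
    )
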