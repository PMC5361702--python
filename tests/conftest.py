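import numpy as np
import pandas as pd
import pytest

from metapeak.core_io import CompoundDB, PeakTable, SampleMeta
from metapeak.synthetic import simulate_peak_table


def make_peak_table(values, mask=None, feature_ids=None, sample_ids=None, **kw):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.isnan(values)
    if feature_ids is None:
        feature_ids = [f"f{i+1}" for i in range(values.shape[0])]
    if sample_ids is None:
        sample_ids = [f"s{j+1}" for j in range(values.shape[1])]
    return PeakTable(feature_ids, sample_ids, values, mask, **kw)


def make_meta(sample_ids, classes, batches=None, orders=None):
    n = len(sample_ids)
    if batches is None:
        batches = ["1"] * n
    if orders is None:
        orders = list(range(1, n + 1))
    return SampleMeta.from_columns(sample_ids, batches, classes, orders)


@pytest.fixture(scope="session")
def two_group_meta():
    """10 biological samples (5 case / 5 control) + 4 QCs, one batch."""
    ids = [f"s{j+1}" for j in range(10)] + [f"qc{j+1}" for j in range(4)]
    classes = ["case"] * 5 + ["control"] * 5 + [None] * 4
    return make_meta(ids, classes)


@pytest.fixture(scope="session")
def sim_small():
    """Shared small simulated dataset (complete, no drift/batch structure)."""
    return simulate_peak_table(
        n_features=60, n_case=15, n_control=15, n_batches=1, qc_every=5,
        drift="none", batch_sd=0.0, n_diff=10, effect_log2=1.5,
        mnar_strength=0.0, noise_sd=0.1, seed=11,
    )


@pytest.fixture(scope="session")
def sim_drift():
    """Shared drifting two-batch dataset for correction tests."""
    return simulate_peak_table(
        n_features=80, n_case=20, n_control=20, n_batches=2, qc_every=5,
        drift="linear", drift_magnitude=0.4, batch_sd=0.3, n_diff=0,
        mnar_strength=0.0, noise_sd=0.05, seed=7,
    )


@pytest.fixture()
def tiny_compound_db():
    return CompoundDB(
        pd.DataFrame(
            {
                "compound_id": ["C1", "C2", "C3"],
                "name": ["alpha", "beta", "gamma"],
                "formula": ["H2O", "C6H12O6", "C5H7NO3"],
                "monoisotopic_mass": [18.010565, 180.063388, 129.042593],
            }
        )
    )
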