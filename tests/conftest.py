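import numpy as np
import pandas as pd
import pytest

from connpred.connectome import EdgeIndexMap, SampleTable, assemble_samples
from connpred.simulate import CohortConfig, generate_cohort

#: Seed used for all frozen recovery runs in the suite.
STUDY_SEED = 1


@pytest.fixture(scope="session")
def meditator_cohort():
    """Default 12-subject planted-effect cohort (both conditions)."""
    return generate_cohort(CohortConfig.meditators(seed=STUDY_SEED))


@pytest.fixture(scope="session")
def fa_samples(meditator_cohort):
    return assemble_samples(meditator_cohort, "FA")


@pytest.fixture(scope="session")
def om_samples(meditator_cohort):
    return assemble_samples(meditator_cohort, "OM")


def make_sample_table(n_subjects=12, n_blocks=3, n_rois=10, seed=0,
                      signal_edges=(), signal_strength=1.0,
                      target="expertise"):
    """Small synthetic edge table: iid noise features with an optional
    linear target signal planted on chosen edge columns."""
    rng = np.random.default_rng(seed)
    edges = EdgeIndexMap(roi_ids=tuple(range(n_rois)))
    rows = n_subjects * n_blocks
    x = rng.standard_normal((rows, edges.n_edges))
    age = rng.normal(37.9, 9.4, n_subjects)
    exp = np.abs(rng.normal(16.4, 7.7, n_subjects))
    meta = pd.DataFrame({
        "subject_id": np.repeat([f"s{i:02d}" for i in range(n_subjects)],
                                n_blocks),
        "condition": "FA",
        "block": list(range(1, n_blocks + 1)) * n_subjects,
        "age": np.repeat(age, n_blocks),
        "expertise": np.repeat(exp, n_blocks),
    })
    y = meta[target].to_numpy()
    yz = (y - y.mean()) / y.std()
    for e in signal_edges:
        x[:, e] += signal_strength * yz
    return SampleTable(features=x, meta=meta, edges=edges)
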