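import numpy as np
import pytest

import rbefit as rf


@pytest.fixture(scope="session")
def reference():
    """Published iron-ion / X-ray group summaries and regression curves."""
    return rf.medaka_reference()


@pytest.fixture(scope="session")
def iron(reference):
    return reference.iron


@pytest.fixture
def iron_summary_csv(tmp_path, iron):
    path = tmp_path / "iron.csv"
    rf.write_dataset(iron, path)
    return path


@pytest.fixture
def raw_csv(tmp_path):
    """Small raw-dialect CSV with pooled and unsorted dose rows."""
    path = tmp_path / "raw.csv"
    path.write_text(
        "dose_gy,count\n1.0,2\n0.0,0\n1.0,2\n0.5,1\n1.0,2\n0.5,3\n0.0,0\n"
    )
    return path


def random_raw_dataset(rng: np.random.Generator) -> rf.DoseResponseDataset:
    """A random small raw-count dataset with at least 2 embryos per group."""
    k = rng.integers(2, 5)
    doses = np.sort(rng.choice(np.arange(0, 4, 0.25), size=k, replace=False))
    groups = []
    for d in doses:
        n = int(rng.integers(2, 8))
        counts = rng.poisson(rng.uniform(0.5, 30), size=n)
        groups.append(rf.DoseGroup.from_counts(float(d), counts.tolist()))
    return rf.DoseResponseDataset(label="random", groups=tuple(groups))
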