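import numpy as np
import pandas as pd
import pytest

from mirnorm import SimSpec, simulate_cq_dataset


@pytest.fixture
def toy_cq():
    """2 control + 2 case samples, target A shifted in the case group,
    reference assay B constant (the worked -ddCq example)."""
    return pd.DataFrame(
        {"A": [20.0, 20.0, 21.0, 23.0], "B": [18.0, 18.0, 18.0, 18.0]},
        index=["H1", "H2", "D1", "D2"],
    )


@pytest.fixture
def toy_groups(toy_cq):
    return pd.Series(["HC", "HC", "AD", "AD"], index=toy_cq.index)


@pytest.fixture
def small_dataset():
    """A deterministic 2x20-sample cohort over the default 7-candidate panel."""
    return simulate_cq_dataset(SimSpec(seed=7, n_per_group=20))


def write_csv(path, text):
    path.write_text(text)
    return str(path)


@pytest.fixture
def wide_cq_file(tmp_path):
    return write_csv(
        tmp_path / "cq.csv",
        "sample_id,miR-484,miR-93-5p\nS1,24.5,21\nS2,25.0,22\nS3,24.0,23\n",
    )


@pytest.fixture
def meta_file(tmp_path):
    return write_csv(
        tmp_path / "meta.csv",
        "sample_id,group,sex,age\nS1,HC,F,60\nS2,AD,M,70\nS3,AD,F,65\n",
    )
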