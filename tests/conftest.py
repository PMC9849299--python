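import numpy as np
import pandas as pd
import pytest

from qtap import SimConfig, generate_mrm_dataset
from qtap.config import GroupSpec, ProteinSpec


@pytest.fixture
def small_config():
    """Two groups × three proteins spanning the quantifiable range, one of
    them below any sensible detection floor."""
    return SimConfig(
        seed=42,
        groups=[GroupSpec(label="WT", n_samples=4), GroupSpec(label="AD", n_samples=4)],
        proteins=[
            ProteinSpec(name="ASCT1", abundance={"WT": 0.71, "AD": 1.5}, lloq=0.01),
            ProteinSpec(name="GLUT1", abundance={"WT": 46.0, "AD": 49.0}, lloq=0.01),
            ProteinSpec(name="OCT1", abundance={"WT": 0.0, "AD": 0.0}, lloq=0.15),
        ],
        n_transitions=3,
    )


@pytest.fixture
def noiseless_config(small_config):
    return small_config.model_copy(update={"noise_cv": 0.0, "biological_cv": 0.0})


@pytest.fixture
def noiseless_dataset(noiseless_config):
    records, truth = generate_mrm_dataset(noiseless_config)
    return noiseless_config, records, truth


def design_of(records: pd.DataFrame) -> pd.Series:
    return (records[["sample_id", "group"]].drop_duplicates()
            .set_index("sample_id")["group"])


@pytest.fixture
def rng():
    return np.random.default_rng(7)
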