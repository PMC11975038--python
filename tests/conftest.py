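import numpy as np
import pandas as pd
import pytest

from agevelo import AgingSimConfig, AgingWorld, gen_invitro_timecourse, gen_invivo_cohort


@pytest.fixture(scope="session")
def config():
    return AgingSimConfig(seed=1)


@pytest.fixture(scope="session")
def world(config):
    return AgingWorld(config)


@pytest.fixture(scope="session")
def invivo(config, world):
    return gen_invivo_cohort(config, world)


@pytest.fixture(scope="session")
def invitro(config, world):
    return gen_invitro_timecourse(config, world)


@pytest.fixture()
def toy_sheet():
    """Minimal valid sample sheet for two donors, two culture timepoints."""
    rows = []
    for donor, age in (("D1", 55.0), ("D2", 67.0)):
        for m in (0, 5):
            rows.append({
                "sample_id": f"{donor}_m{m}",
                "donor_id": donor,
                "chronological_age_at_baseline": age,
                "time_in_culture": m,
                "condition": "in_vitro_control",
                "cell_type": "fibroblast",
                "assay": "rna_bulk",
            })
    return pd.DataFrame(rows)


def make_predictions(sample_ids, ages):
    return pd.DataFrame({"sample_id": list(sample_ids),
                         "predicted_age": np.asarray(ages, dtype=float)})
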