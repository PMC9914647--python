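import pytest

from cogscore import CohortConfig, generate_cohort, pair_config
from cogscore.battery import battery_index, default_battery


@pytest.fixture(scope="session")
def battery():
    return default_battery()


@pytest.fixture(scope="session")
def battery_idx():
    return battery_index()


@pytest.fixture(scope="session")
def default_cohort():
    """Default three-group synthetic cohort (20/29/31), fixed seed."""
    return generate_cohort(CohortConfig(seed=7))


@pytest.fixture()
def strong_pair_cohort():
    """Two-group cohort with a large purely-direct effect on one sub-score."""
    cfg = pair_config(
        ("SCD", "HC"),
        n_per_group=100,
        subtasks={"ICT_RST_12": dict(c_direct=2.0, noise_sd=1.0)},
        seed=11,
    )
    return generate_cohort(cfg)
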