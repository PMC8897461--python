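import pandas as pd
import pytest

from csdstools.config import SimulationConfig


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A cheap cohort for structural tests."""
    return SimulationConfig(seed=7, n_control=6, n_stressed=8, rois_per_animal=2)


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    """The reference cohort (23 control / 26 stressed, susceptible 14/26)."""
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def behavior_cohort(default_config):
    from csdstools import synthetic

    return synthetic.gen_behavior(default_config)


def presence_table(rows):
    """Build a long-format spine table from (roi, spine, day, state) tuples;
    dendrite length fixed at 50 um."""
    return pd.DataFrame(
        [
            dict(roi_id=r, animal_id=r.split("_")[0], spine_id=s,
                 session_day=d, state=st, length_um=1.0,
                 dendrite_length_um=50.0)
            for r, s, d, st in rows
        ]
    )
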