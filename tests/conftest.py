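import pandas as pd
import pytest
from hypothesis import settings

from commrep.records import validate_records
from commrep.synthetic import CellDesign, SyntheticConfig, generate_dataset

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def make_records(rows):
    """Build a validated record table from (individual, partner_class,
    signal_type) triples plus optional attribute overrides."""
    defaults = {
        "species": "bornean",
        "setting": "wild",
        "group_id": "g1",
        "sex": "female",
        "age_years": 4.0,
        "social_goal": "play_affiliate",
    }
    table = []
    for k, row in enumerate(rows):
        entry = dict(defaults)
        entry.update(row)
        entry.setdefault("record_id", f"r{k}")
        table.append(entry)
    frame = pd.DataFrame(table)
    return validate_records(frame)


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down two-species scenario used across tests."""
    return SyntheticConfig(
        design=(
            CellDesign("bornean", "wild", "field_b", 5),
            CellDesign("bornean", "captive", "zoo_b1", 4),
            CellDesign("sumatran", "wild", "field_s", 4),
            CellDesign("sumatran", "captive", "zoo_s1", 4),
        ),
        effort_range=(40, 200),
        p_subthreshold=0.1,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    records, population, truth = generate_dataset(small_config, seed=42)
    return records, population, truth


@pytest.fixture(scope="session")
def default_dataset():
    records, population, truth = generate_dataset(SyntheticConfig(), seed=7)
    return records, population, truth
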