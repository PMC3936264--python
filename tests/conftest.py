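import pytest

from crowdcongruence.corpus import AliasDictionary, Hospital
from crowdcongruence.simulate import SimulationConfig, generate_study


@pytest.fixture(scope="session")
def small_study():
    """Mid-size synthetic study shared by read-only tests."""
    config = SimulationConfig(
        n_districts=6,
        hospitals_per_district=10,
        threads_per_district=30,
        corruption_rate=0.1,
        seed=11,
    )
    return generate_study(config)


@pytest.fixture
def tiny_registry():
    return [
        Hospital("D1-H1", "harbor bay clinic", "D1", 0.10, 2),
        Hospital("D1-H2", "maple hill clinic", "D1", 0.30, 1),
        Hospital("D1-H3", "cedar park clinic", "D1", 0.20, 1),
        Hospital("D2-H1", "river oak clinic", "D2", 0.25, 3),
    ]


@pytest.fixture
def tiny_aliases(tiny_registry):
    entries = {
        "harbor bay clinic": {"harbor bay clinic", "hbc", "harbor"},
        "maple hill clinic": {"maple hill clinic", "mhc", "maple"},
        "cedar park clinic": {"cedar park clinic", "cpc", "cedar"},
        "river oak clinic": {"river oak clinic", "roc", "river"},
    }
    hospital_ids = {h.canonical_name: h.hospital_id for h in tiny_registry}
    return AliasDictionary(entries=entries, hospital_ids=hospital_ids)
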