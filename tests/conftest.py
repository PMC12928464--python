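import datetime

import pytest
from hypothesis import HealthCheck, settings

from ugibvigil.model import DrugMention, Reaction, Report, dataset_from_records
from ugibvigil.synthetic import default_config, generate

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def toy_dataset():
    """10 deduplicated reports: 4 mention Anticoagulin (2 with a UGIB PT),
    6 do not (1 with a UGIB PT) -> a=2, b=2, c=1, d=5."""
    reports = [
        Report(f"R{i:02d}", f"C{i:02d}", datetime.date(2020, 1, i + 1))
        for i in range(10)
    ]
    drugs = [DrugMention(f"R{i:02d}", "Anticoagulin") for i in range(4)]
    drugs += [DrugMention(f"R{i:02d}", "Placebocillin") for i in range(4, 10)]
    reactions = [
        Reaction("R00", "Haematemesis", 10018830),
        Reaction("R01", "Gastric haemorrhage", 10017788),
        Reaction("R02", "Nausea", 99000001),
        Reaction("R03", "Headache", 99000002),
        Reaction("R04", "Haematemesis", 10018830),
        Reaction("R05", "Nausea", 99000001),
        Reaction("R06", "Nausea", 99000001),
        Reaction("R07", "Headache", 99000002),
        Reaction("R08", "Nausea", 99000001),
        Reaction("R09", "Headache", 99000002),
    ]
    return dataset_from_records(reports, drugs, reactions, deduplicated=True)


@pytest.fixture(scope="session")
def small_synth():
    """Small default-world sample with duplicate case versions."""
    cfg = default_config(n_reports=2000, seed=42, duplicate_rate=0.2)
    dataset, truth = generate(cfg)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def large_synth():
    """200k reports with one injected (rare drug, rare PT) pair at rr=10."""
    cfg = default_config(
        n_reports=200_000,
        seed=11,
        duplicate_rate=0.0,
        injected_associations=(("Ticagrelor", "Mallory-Weiss syndrome", 10.0),),
    )
    dataset, truth = generate(cfg)
    return cfg, dataset, truth
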