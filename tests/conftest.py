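import pytest
from hypothesis import HealthCheck, settings

from herbnet.corpus import FormulaCorpus

settings.register_profile(
    "herbnet",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("herbnet")

# Worked example: three formulae over ten herbs whose relative-position
# matrix B is known cell by cell.
TABLE1_RECORDS = [
    ("F1", ["herb_4", "herb_2", "herb_9", "herb_6"]),
    ("F2", ["herb_4", "herb_8", "herb_1", "herb_10",
            "herb_2", "herb_5", "herb_3", "herb_7"]),
    ("F3", ["herb_1", "herb_6"]),
]

# Expected B entries keyed by (formula_id, herb name); absent herbs are 0.
TABLE1_B = {
    "F1": {"herb_4": 0.25, "herb_2": 0.5, "herb_9": 0.75, "herb_6": 1.0},
    "F2": {"herb_4": 0.125, "herb_8": 0.25, "herb_1": 0.375, "herb_10": 0.5,
           "herb_2": 0.625, "herb_5": 0.75, "herb_3": 0.875, "herb_7": 1.0},
    "F3": {"herb_1": 0.5, "herb_6": 1.0},
}


@pytest.fixture
def table1_corpus() -> FormulaCorpus:
    return FormulaCorpus.from_records(TABLE1_RECORDS)


def random_records(rng, n_herbs, m_formulae, k_max=6):
    """Random small corpus records: distinct herbs, random order."""
    names = [f"h{j}" for j in range(1, n_herbs + 1)]
    records = []
    for i in range(m_formulae):
        k = int(rng.integers(1, min(k_max, n_herbs) + 1))
        idx = rng.choice(n_herbs, size=k, replace=False)
        records.append((f"F{i}", [names[j] for j in idx]))
    return records
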