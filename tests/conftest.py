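import numpy as np
import pytest

from poolrfi.io_formats import PedigreeRecord, PedigreeTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def trio_pedigree():
    """Sire, dam, one offspring."""
    return PedigreeTable(
        [
            PedigreeRecord("S1", None, None, "M"),
            PedigreeRecord("D1", None, None, "F"),
            PedigreeRecord("O1", "S1", "D1", "M"),
        ]
    )


@pytest.fixture
def fullsib_pedigree():
    """Two founders, two full sibs, and an offspring of the full sibs."""
    return PedigreeTable(
        [
            PedigreeRecord("S1", None, None, "M"),
            PedigreeRecord("D1", None, None, "F"),
            PedigreeRecord("A", "S1", "D1", "M"),
            PedigreeRecord("B", "S1", "D1", "F"),
            PedigreeRecord("C", "A", "B", "M"),
        ]
    )


def random_pedigree(rng, n_founders=10, n_offspring=40):
    """Random multi-generation pedigree for oracle tests."""
    records = [
        PedigreeRecord(f"F{i}", None, None, "M" if i % 2 == 0 else "F")
        for i in range(n_founders)
    ]
    males = [r.animal_id for r in records if r.sex == "M"]
    females = [r.animal_id for r in records if r.sex == "F"]
    for k in range(n_offspring):
        sire = males[rng.integers(len(males))]
        dam = females[rng.integers(len(females))]
        sex = "M" if rng.random() < 0.5 else "F"
        rid = f"X{k}"
        records.append(PedigreeRecord(rid, sire, dam, sex))
        (males if sex == "M" else females).append(rid)
    return PedigreeTable(records)
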